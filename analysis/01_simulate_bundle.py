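#!/usr/bin/env python
"""Generate the synthetic chordate input bundle all later steps consume.

Writes orthogroups, ohnolog labels, per-species gene coordinates, the two
expression matrices, gene trees, the GO ontology + annotations and the
latent truth table under bundle/, plus a run manifest under results/.
"""

from pathlib import Path

from chorddup.pipeline import RunConfig, run

ROOT = Path(__file__).resolve().parent.parent
CFG = RunConfig(bundle_dir=ROOT / "bundle", out_dir=ROOT / "results",
                seed=20, n_orthogroups=5000)

if __name__ == "__main__":
    outputs = run("simulate", CFG)
    print(f"wrote {len(outputs)} bundle files under {CFG.bundle_dir}")
    print("panel: 3 amphioxus + 4 vertebrate species, "
          f"{CFG.n_orthogroups} orthogroups, seed {CFG.seed}")
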
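#!/usr/bin/env python
"""Genome organization of orthologs and duplicates between two amphioxus.

Builds the one-to-one ortholog dotplot (midpoint coordinates), classifies
within-species paralog pairs as tandem / distant intra-chromosomal /
inter-chromosomal, and calls chromosome homology partners with
fusion/fission detection.
"""

from pathlib import Path

import pandas as pd

from chorddup.pipeline import RunConfig, run

ROOT = Path(__file__).resolve().parent.parent
CFG = RunConfig(bundle_dir=ROOT / "bundle", out_dir=ROOT / "results",
                seed=20, n_orthogroups=5000)

if __name__ == "__main__":
    run("synteny", CFG)
    pairs = pd.read_csv(CFG.out_dir / "duplicate_locations_pairs.tsv", sep="\t")
    print("paralog pair location classes (%):")
    print((100 * pairs["class"].value_counts(normalize=True)).round(1).to_string())
    calls = pd.read_csv(CFG.out_dir / "chromosome_homology.tsv", sep="\t")
    print(f"\n{len(calls)} chromosomes called; "
          f"{(calls['call'] == 'fusion_or_fission').sum()} fusion/fission")
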
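#!/usr/bin/env python
"""Test whether duplication co-occurs between the two lineages.

Builds the 2x3 intersection of amphioxus (single / SSD) against vertebrate
(single / ohnolog / SSD) categories over shared orthogroups, tests each
cell with a hypergeometric test (Bonferroni over 6 cells), and reports the
copy-number association among jointly duplicated orthogroups.  With the
generator's enrichment factor of 1.7 the jointly-duplicated cells come out
significantly enriched, as in the real data.
"""

import json
from pathlib import Path

import pandas as pd

from chorddup.pipeline import RunConfig, run

ROOT = Path(__file__).resolve().parent.parent
CFG = RunConfig(bundle_dir=ROOT / "bundle", out_dir=ROOT / "results",
                seed=20, n_orthogroups=5000)

if __name__ == "__main__":
    outputs = run("enrich", CFG)
    report = pd.read_csv(CFG.out_dir / "coduplication_enrichment.tsv", sep="\t")
    show = report[["category_a", "category_b", "observed_pct", "expected_pct",
                   "fold", "log2_fold", "p_bonferroni"]]
    print(show.round(3).to_string(index=False))
    assoc_path = CFG.out_dir / "copy_number_association.json"
    if assoc_path.exists():
        assoc = json.loads(assoc_path.read_text())
        print(f"copy-number association: Spearman rho = {assoc['spearman_rho']:.3f} "
              f"(n = {assoc['n']} jointly duplicated orthogroups)")
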
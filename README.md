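# chorddup

Comparative profiling of gene-duplication histories between two chordate
lineages — an amphioxus panel (*B. lanceolatum*, *B. floridae*,
*B. belcheri*) and a vertebrate panel (zebrafish, chicken, mouse, human) —
for researchers studying how small-scale duplications and whole-genome
duplications (WGD) shape gene repertoires.

Amphioxus lack the two rounds of WGD ("2R") at the origin of vertebrates,
so every amphioxus duplicate is small-scale, while vertebrate duplicates
split into small-scale duplicates (SSD) and 2R ohnologs.  The package asks
whether, despite this mechanistic difference, the *same orthogroups* tend
to duplicate in both lineages, whether the same functional categories
tolerate duplication, and whether duplicates specialize their expression
the same way.

## What it computes

Given an orthogroup table (Broccoli/OrthoFinder-style TSV), gene
coordinates (GFF3/BED), ohnolog lists with WGD-round labels, an ontology
(OBO) with gene→term associations, TPM expression matrices, gene trees
(newick) and BLAST tabular hits:

1. **Duplication profiles** — an orthogroup is duplicated in a species when
   that species has ≥ 2 members; duplicated in a lineage when any of its
   species is.  Vertebrate duplicated orthogroups containing a 2R ohnolog
   gene are reclassified `ohnolog`; orthogroups duplicated only in the
   teleost and known to be 3R-retained are demoted to single-copy.
2. **Co-duplication enrichment** — the 2×3 intersection of amphioxus
   {single, SSD} × vertebrate {single, ohnolog, SSD} categories over shared
   orthogroups, each cell tested with a hypergeometric test
   (Bonferroni-corrected), reporting observed/expected percentages, the
   fold ratio and its log2; plus Spearman/χ² association of mean copy
   numbers (dichotomized at ≤ 2.5 mean copies).
3. **Tree validation** — lineage monophyly on unrooted gene trees by edge
   bipartitions.
4. **GO parallelism** — annotations propagated up the ontology
   (is_a/part_of), transferred through orthology symmetrically between
   human and amphioxus, then per-term duplication percentages compared
   between lineages (terms with ≥ 50 genes on both sides).
5. **Expression** — per-condition mean TPM; Tau specificity,
   τ = Σᵢ(1 − xᵢ/x_max)/(n − 1); presence/absence over 7 matched
   amphioxus↔zebrafish conditions; per-ortholog differences in expressed
   condition counts, per duplicate copy and for the union of duplicates
   (the subfunctionalization signature); boxplot-convention group
   summaries.
6. **Synteny** — one-to-one ortholog dotplots by gene midpoints, paralog
   location classes (tandem = consecutive genes on a chromosome, distant
   intra-chromosomal, inter-chromosomal), chromosome homology with
   fusion/fission calls.
7. **Annotation evidence** — strong/weak/none evidence from similarity hits
   (coverage > 75% of query and subject, e-value < 1e-8 → strong; e-value
   < 1e-4 → weak) and expression breadth (> 3 libraries → strong); genes
   retained when ≥ 1 strategy is strong; CDS↔protein correspondence with a
   10% mismatch allowance.

A synthetic-data generator (`chorddup.simulate`) produces complete input
bundles with known latent structure — co-duplication enrichment factor,
ohnolog/3R labels, tandem fraction, topology-scramble rate,
subfunctionalization probability — so every stage is testable without
external data and every estimate can be checked against the parameter that
generated it.

## Worked example

The numbered scripts under `analysis/` run the whole study on a generated
bundle (5000 orthogroups, seed 20):

```bash
python analysis/01_simulate_bundle.py
python analysis/02_duplication_profiles.py
python analysis/03_coduplication_enrichment.py
```

`02` prints the per-species prevalence table — e.g.

```
            pct_dup_genes  pct_dup_orthogroups  mean_genes_per_dup_orthogroup
Blan                 42.1                 17.5                            3.4
Drer                 53.0                 26.0                            3.2
Hsap                 48.7                 23.2                            3.1
```

i.e. roughly half of each species' genes sit in duplicated orthogroups
while only a fifth to a quarter of orthogroups are duplicated.  `03` prints
the intersection cells; with the generator's enrichment factor of 1.7 the
jointly duplicated cells come out enriched:

```
category_a category_b  observed_pct  expected_pct  fold  log2_fold  p_bonferroni
       ssd    ohnolog          11.2           6.3 1.779      0.831           0.0
       ssd        ssd           7.6           4.1 1.843      0.882           0.0
```

`04`–`08` continue with tree validation (validation rate 0.860 with a
topology-scramble rate of 0.2 — trees with one tip per lineage are
trivially monophyletic and raise the rate above 1 − q), GO parallelism
(rank correlation 0.98 across 120 terms), expression deltas (per-copy mean
+0.26 toward the single-copy side, union mean −0.03), paralog location
classes, and evidence retention.  The same stages are exposed as a CLI
(`chorddup <stage> --bundle-dir bundle --out results --seed 20`); each
stage writes TSV/JSON artifacts plus a manifest with input hashes so reruns
are verifiably identical.

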
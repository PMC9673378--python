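# Methods

## Duplication status model

The unit of analysis is the orthogroup: a set of genes descended from one
gene in the last common ancestor of the species panel.  Orthogroup
inference itself is upstream (Broccoli/OrthoFinder output is consumed, not
produced), which fixes an important convention: duplications older than the
panel's root are split into separate orthogroups upstream, so every
duplication we count postdates the amphioxus–vertebrate split.

Per lineage, an orthogroup is `absent` (no genes), `single_copy` (every
present species has exactly one gene), or `small_scale_dup` (any species
has ≥ 2).  The mean copy number averages over species with ≥ 1 gene —
absence is treated as loss, not as copy number zero, which is the reading
consistent with using a ≤ 2.5 mean-copy threshold to dichotomize "low"
copy numbers.

Two corrections apply only to the WGD-bearing (vertebrate) lineage:

- **2R reassignment.** A duplicated orthogroup containing at least one
  listed 2R ohnolog gene becomes `ohnolog`.  The reassignment applies only
  to orthogroups already duplicated: ohnolog status is a sub-division of
  duplication, and a single-copy orthogroup with a stray 2R-listed gene
  stays single-copy.
- **3R demotion.** An orthogroup whose only duplicated vertebrate species
  are the designated teleost(s), with at least one of those genes on the
  3R list, is demoted to single-copy, so the teleost-specific WGD does not
  inflate the small-scale count.  One listed gene suffices (the retention
  of the pair is established by a single labeled member), and the 2R check
  takes precedence.

Amphioxus ohnolog status is structurally impossible — the lineage has had
no WGD — and the code enforces that.

The joint class (both-single / A-specific / B-specific / parallel /
lineage-specific) partitions orthogroups; ohnolog counts as duplicated for
joint classing.

## Co-duplication enrichment

The universe is orthogroups with ≥ 1 gene in each focal lineage.  The
amphioxus axis can be judged either on the lineage status or on a single
focal species' own copy number (the published presentation uses the single
species; both views are computed).  Expected cell counts assume marginal
independence; each cell gets a hypergeometric test — upper tail when the
cell is at or above expectation, lower tail otherwise, with the direction
reported — Bonferroni-corrected over the 6 cells of the 2×3 design (the
divisor is configurable since only "Bonferroni" is specified upstream).

One deliberate quirk: the published worked example labels the ratio
7.3/4.3 = 1.7 a "log2 fold change", but 1.7 is the plain ratio
(log2 = 0.76).  Both numbers are emitted; the headline `fold` is the plain
ratio so the printed example is reproduced, and `log2_fold` carries the
binary logarithm.

## Tree validation

Maximum-likelihood gene trees are unrooted, so monophyly is decided on
edge bipartitions: lineage L is monophyletic iff some edge separates
exactly the L tips from the rest.  Tips mapping to neither focal lineage
are pruned (equivalently, bipartitions are intersected with the mapped tip
set).  Lineages with ≤ 1 tip are trivially monophyletic; trees with < 3
mapped tips are flagged untestable and excluded from the validation-rate
denominator (how such trees were scored upstream is unstated; excluding
and counting them is the transparent choice).  Multifurcations are
accepted as-is.

## GO parallelism

Propagation closes each gene's term set over is_a and part_of ancestry
(standard GO practice; other relation types are ignored).  Transfer is
orthology-based and deliberately symmetric: within each orthogroup
containing both the source (human) and target species, the union of the
source genes' terms is assigned to every member *including the source
genes*, so neither side is annotated more restrictively.  The ≥ 50-gene
filter applies after transfer and propagation, per side.  No correlation
test accompanies the per-term comparison: GO terms overlap through the
DAG and are not independent observations.

## Expression

Tau specificity, τ = Σᵢ(1 − xᵢ/x_max)/(n − 1), is computed on untransformed
per-condition mean TPM by default, with an explicit log2(TPM+1) switch
(the choice changes values and is surfaced rather than hidden).  Genes
with no expression anywhere are flagged undefined.

"Expressed" means mean TPM ≥ 1 in a condition.  The upstream analysis used
a database-specific background call whose exact definition is not
reproducible here; a fixed threshold of 1 TPM on condition means is the
conventional stand-in, configurable, and the tests sweep it.  The seven
matched amphioxus↔zebrafish conditions (embryo↔embryo, male
gonads↔testis, muscle↔muscle, neural tube↔brain, gut↔intestine,
gills↔pharyngeal gill, hepatic diverticulum↔liver) ship as data, not
code; blastula, female gonads and epidermis are excluded for divergent
expression.

Breadth deltas follow the species-A-minus-species-B convention.  For a
1:many orthogroup, each duplicate copy is compared to the single ortholog
(per-copy deltas), and the union of the copies' condition sets gives the
union delta.  Skewness is the adjusted Fisher–Pearson sample statistic.
Boxplot summaries use linear-interpolation quartiles (documented because
quartile conventions differ) and 1.5×IQR whiskers with outliers excluded.

## Synteny

Tandem means strictly consecutive ranks on a chromosome (a configurable
max-intervening-genes parameter, default 0, supports sensitivity
analysis).  Location classes are reported both per paralog pair and
aggregated per orthogroup (tandem if any pair is tandem, else
intra-distant if all members share a chromosome, else inter-chromosomal)
because the natural counting unit is ambiguous; the pair-level tally is
the default.  Chromosome homology partners are chromosomes receiving
≥ 20% of a chromosome's one-to-one orthologs — a threshold that separates
a ~50/50 fusion signal from background scatter — and a chromosome with
≥ 2 partners is called fusion-or-fission.

## Annotation evidence

The published similarity thresholds read "query length/alignment length
> 0.75"; taken literally that ratio is ≥ 1 for ungapped alignments and
the rule would be vacuous, so the ratios are read as alignment *coverage*
of query and subject (> 75%).  Expression evidence: > 3 libraries strong,
0 none; the unassigned "exactly 3" case is conservatively weak (the
strong rule says strictly "more than 3").  A gene is retained when any
strategy is strong.  CDS↔protein correspondence translates with the
standard code, compares positionally, counts length differences as
mismatches, and passes at ≤ 10%.

## Synthetic data generator

The generator's defaults are the study conditions.  Species panel: 3
amphioxus + 4 vertebrates with realistic chromosome counts; 5000
orthogroups by default (large enough for binomial intervals of a few
percent on every recovered parameter while keeping the full analysis in
seconds); ~35% lineage-specific orthogroups; lineage duplication
probabilities 0.30 (amphioxus) and 0.38 (vertebrates) chosen so the
realized per-species prevalence matches the real panel (just under 20% of
an amphioxus species' orthogroups duplicated, ~23–26% in vertebrates,
40–50% of genes in duplicated orthogroups); extra copies geometric with
mean ≈ 2.2 per duplicated species; 60% of duplicated vertebrate
orthogroups 2R-tagged; 5% teleost-only 3R cases; tandem fraction 0.25;
scramble probability 0.2 (matching the ~80% published monophyly
validation); subfunctionalization probability 0.7; expression lognormal
(μ=2, σ=1 on log scale, ≈7 TPM median) with 5% dropout and two replicates
per condition.

Co-duplication is drawn from the exact joint Bernoulli with
P(dup_A ∧ dup_B) = f·P(dup_A)·P(dup_B) — the marginalized form of a shared
duplicability cause, and the simplest mechanism matching the fold
definition.  Infeasible f raises with the feasibility bound.  Tandem
placement uses gene *blocks*: a tandem copy joins its predecessor's block,
and later insertions land between blocks, so no insertion can separate a
tandem pair.  Scrambled trees swap one tip between the two lineage clades,
which provably breaks monophyly of both lineages whenever each has ≥ 2
tips; trees where scrambling cannot break monophyly are never marked
scrambled, and parameter-recovery tests condition on ≥ 2 tips per side.
GO terms sample member orthogroups with weights driven by a per-term
duplicability θ, either shared between lineages (creating the cross-lineage
per-term trend) or drawn independently per lineage (flat trend) — the
switch the recovery test exercises.  Each component draws from its own
stream spawned from the master seed, so bundles are byte-identical per
seed and disabling one component does not shift the others.

What the generator does *not* emulate: sequence evolution (no nucleotide
or protein sequences beyond small CDS fixtures), assembly or annotation
artifacts, inparalog ambiguity in orthogroup inference, correlated
expression noise across conditions, and realistic GO DAG shape (terms form
random trees, not the curated ontology).  Passing tests therefore
demonstrate correctness of the statistical machinery and recoverability of
the generative parameters, not robustness to real-data pathologies such as
homology detection failure or mis-assembled haplotypes.

A separate constructive fixture (`build_counts_fixture`) realizes exact
per-species count targets (total/duplicated genes and orthogroups, plus
the subset shared with the other lineage, with unassigned genes making up
the difference between gene totals and orthogroup membership) so published
summary tables can be replayed through the same summary code paths.

## Numerical choices and degenerate inputs

Quartiles by linear interpolation; Spearman and χ² from scipy with a
guard for degenerate contingency margins; hypergeometric tails from
scipy's exact distribution; Bonferroni capped at 1.  Tau raises on
all-zero vectors; copy-number association requires ≥ 3 jointly duplicated
orthogroups; empty enrichment universes, empty expression groups and
malformed input lines raise with specific messages.  Coordinates are
1-based inclusive internally (GFF3 convention) with conversion at the BED
boundary; ranks break ties by end then gene id.

## Known limitations

Chromosome homology calls use a fraction threshold rather than reciprocal
segment matching, so very uneven fusions (e.g. 90/10) fall below the
default partner threshold on the minor arm.  The Broccoli output layout
accepted (tab-separated species columns, comma- or space-separated
members) is a documented guess at the dialect; both member separators are
accepted.  Evidence classification is per database; any cross-database
weighting can be applied downstream.
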
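"""GO-term duplication parallelism between lineages.

Annotations are first propagated up the ontology (a gene annotated to a
term is annotated to every ancestor over is_a/part_of), then transferred
across species through orthology: within each orthogroup containing both
the annotation-source species (human) and the target species, every member
inherits the union of the source genes' terms — the source genes included,
so neither side is annotated more restrictively than the other.  Per-term
duplication percentages are then compared between lineages under three
definitions of vertebrate duplication: small-scale only, ohnolog only, or
either.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .types import (
    ChorddupError,
    DUPLICATED_STATUSES,
    LineageProfile,
    OHNOLOG,
    OrthogroupTable,
    SMALL_SCALE_DUP,
)

DUP_DEFINITIONS = ("ssd_plus_ohno", "ssd_only", "ohno_only")
_DEF_STATUSES = {
    "ssd_plus_ohno": DUPLICATED_STATUSES,
    "ssd_only": frozenset({SMALL_SCALE_DUP}),
    "ohno_only": frozenset({OHNOLOG}),
}


def ancestor_closure(parents: Mapping[str, set[str]]) -> dict[str, frozenset]:
    """Reflexive-transitive ancestor sets for every term; raises on a cycle."""
    closure: dict[str, frozenset] = {}
    WHITE, GREY, BLACK = 0, 1, 2
    color = {t: WHITE for t in parents}

    def visit(term: str) -> frozenset:
        if color.get(term, WHITE) == BLACK:
            return closure.get(term, frozenset({term}))
        if color.get(term) == GREY:
            raise ChorddupError(f"cycle in ontology at term {term}")
        color[term] = GREY
        acc = {term}
        for p in parents.get(term, ()):
            acc.update(visit(p))
        color[term] = BLACK
        closure[term] = frozenset(acc)
        return closure[term]

    for t in list(parents):
        visit(t)
    return closure


def propagate_annotations(parents: Mapping[str, set[str]],
                          gomap: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """Close each gene's term set under ancestry (idempotent; never removes)."""
    closure = ancestor_closure(parents)
    out: dict[str, set[str]] = {}
    for gene, terms in gomap.items():
        closed: set[str] = set()
        for t in terms:
            closed.update(closure.get(t, frozenset({t})))
        out[gene] = closed
    return out


def transfer_annotations(source_gomap: Mapping[str, set[str]],
                         table: OrthogroupTable,
                         source_species: str,
                         target_species: str) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Transfer annotations through orthology between two species.

    For every orthogroup containing both species, the union of the source
    genes' terms is assigned to all target genes *and back to all source
    genes* in the orthogroup, so the two sides are annotated symmetrically.
    Genes in orthogroups lacking the partner species are excluded from both
    outputs.
    """
    target_map: dict[str, set[str]] = {}
    source_sym: dict[str, set[str]] = {}
    for og in table:
        src = table.genes(og, source_species)
        tgt = table.genes(og, target_species)
        if not src or not tgt:
            continue
        union: set[str] = set()
        for g in src:
            union.update(source_gomap.get(g, ()))
        for g in tgt:
            target_map[g] = set(union)
        for g in src:
            source_sym[g] = set(union)
    return target_map, source_sym


def per_term_duplication(target_map: Mapping[str, set[str]],
                         source_map: Mapping[str, set[str]],
                         table: OrthogroupTable,
                         profile: LineageProfile,
                         min_genes: int = 50,
                         namespaces: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-GO-term duplication percentages on both sides.

    For each term: the number of annotated genes per side, the percentage of
    target (amphioxus) genes whose orthogroup is duplicated in the target
    lineage, and the percentage of source (vertebrate) genes whose
    orthogroup is duplicated under each of the three definitions.  Terms
    with fewer than ``min_genes`` annotated genes on either side are
    dropped.
    """
    g2og = table.gene_to_orthogroup
    prof = profile.table

    def dup_flags(status_col: str):
        status = prof[status_col]
        return {d: set(status.index[status.isin(s)]) for d, s in _DEF_STATUSES.items()}

    dup_a = dup_flags("status_a")  # target lineage
    dup_b = dup_flags("status_b")  # source (vertebrate) lineage

    term_genes_t: dict[str, set[str]] = {}
    term_genes_s: dict[str, set[str]] = {}
    for gene, terms in target_map.items():
        for t in terms:
            term_genes_t.setdefault(t, set()).add(gene)
    for gene, terms in source_map.items():
        for t in terms:
            term_genes_s.setdefault(t, set()).add(gene)

    rows = []
    for term in sorted(set(term_genes_t) & set(term_genes_s)):
        gt = term_genes_t[term]
        gs = term_genes_s[term]
        if len(gt) < min_genes or len(gs) < min_genes:
            continue
        row = {
            "term_id": term,
            "namespace": namespaces.get(term, "") if namespaces else "",
            "n_genes_target": len(gt),
            "n_genes_source": len(gs),
        }
        # Target (amphioxus) lineage: all duplication is small-scale, so the
        # three definitions collapse to the lineage's own duplicated set.
        dup_ogs_a = dup_a["ssd_plus_ohno"]
        n_dup_t = sum(1 for g in gt if g2og.get(g) in dup_ogs_a)
        row["pct_dup_target"] = 100.0 * n_dup_t / len(gt)
        for d in DUP_DEFINITIONS:
            n_dup_s = sum(1 for g in gs if g2og.get(g) in dup_b[d])
            row[f"pct_dup_source_{d}"] = 100.0 * n_dup_s / len(gs)
        rows.append(row)
    cols = ["term_id", "namespace", "n_genes_target", "n_genes_source",
            "pct_dup_target"] + [f"pct_dup_source_{d}" for d in DUP_DEFINITIONS]
    return pd.DataFrame(rows, columns=cols)


def parallelism_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """The three paired percentage series (one per vertebrate duplication
    definition), long format, ready for plotting.

    No correlation test is attached: GO terms overlap through the DAG and
    are not independent observations.
    """
    if stats.empty:
        return pd.DataFrame(columns=["dup_definition", "term_id", "namespace",
                                     "n_genes_source", "pct_dup_source",
                                     "pct_dup_target"])
    frames = []
    for d in DUP_DEFINITIONS:
        frames.append(pd.DataFrame({
            "dup_definition": d,
            "term_id": stats["term_id"],
            "namespace": stats["namespace"],
            "n_genes_source": stats["n_genes_source"],
            "pct_dup_source": stats[f"pct_dup_source_{d}"],
            "pct_dup_target": stats["pct_dup_target"],
        }))
    return pd.concat(frames, ignore_index=True)


def plot_parallelism(summary: pd.DataFrame, path: str, namespace: str | None = None):
    """Three-panel scatter of per-term duplication percentages (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if namespace:
        summary = summary[summary["namespace"] == namespace]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharex=True, sharey=True)
    for ax, d in zip(axes, DUP_DEFINITIONS):
        sub = summary[summary["dup_definition"] == d]
        ax.scatter(sub["pct_dup_source"], sub["pct_dup_target"],
                   s=sub["n_genes_source"] / 20, alpha=0.4, color="black")
        ax.set_title(d)
        ax.set_xlabel("% duplicated (vertebrate)")
    axes[0].set_ylabel("% duplicated (amphioxus)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
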
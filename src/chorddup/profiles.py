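"""Per-orthogroup duplication status and per-species summary tables.

Classification rules
--------------------
An orthogroup is *duplicated in a species* when that species has >= 2
members in it, and *duplicated in a lineage* when at least one species of
the lineage is duplicated.  Within the WGD-bearing lineage (vertebrates),
duplicated orthogroups containing at least one 2R ohnolog gene are
reclassified as ``ohnolog``; orthogroups whose only vertebrate duplications
sit in the designated 3R species (the teleost) and are known 3R-retained
are demoted to single-copy so the 3R WGD does not masquerade as small-scale
duplication.  The 2R check takes precedence over the 3R demotion.
"""

from __future__ import annotations

import itertools
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    ABSENT,
    A_ONLY,
    A_SPECIFIC_DUP,
    B_ONLY,
    B_SPECIFIC_DUP,
    BOTH_SINGLE,
    ChorddupError,
    DUPLICATED_STATUSES,
    LineageConfig,
    LineageProfile,
    OHNOLOG,
    OhnologList,
    OrthogroupTable,
    PARALLEL_DUP,
    SINGLE_COPY,
    SMALL_SCALE_DUP,
)


def copy_number_matrix(table: OrthogroupTable) -> pd.DataFrame:
    """Orthogroup x species matrix of member counts (0 for absent species)."""
    species = table.species
    data = np.zeros((len(table), len(species)), dtype=int)
    ogs = table.orthogroup_ids
    sp_idx = {sp: j for j, sp in enumerate(species)}
    for i, og in enumerate(ogs):
        for sp, genes in table[og].items():
            if genes:
                data[i, sp_idx[sp]] = len(genes)
    return pd.DataFrame(data, index=ogs, columns=species)


def _lineage_state(counts: pd.Series) -> tuple[str, float]:
    present = counts[counts > 0]
    if present.empty:
        return ABSENT, float("nan")
    mean_copies = float(present.mean())
    if (present >= 2).any():
        return SMALL_SCALE_DUP, mean_copies
    return SINGLE_COPY, mean_copies


def _joint_class(status_a: str, status_b: str) -> str:
    if status_a == ABSENT and status_b == ABSENT:
        return "both_absent"  # cannot occur when the two lineages cover the panel
    if status_b == ABSENT:
        return A_ONLY
    if status_a == ABSENT:
        return B_ONLY
    dup_a = status_a in DUPLICATED_STATUSES
    dup_b = status_b in DUPLICATED_STATUSES
    if dup_a and dup_b:
        return PARALLEL_DUP
    if dup_a:
        return A_SPECIFIC_DUP
    if dup_b:
        return B_SPECIFIC_DUP
    return BOTH_SINGLE


def lineage_status(table: OrthogroupTable, cfg: LineageConfig,
                   ohnologs: OhnologList | None = None,
                   cnm: pd.DataFrame | None = None) -> LineageProfile:
    """Classify every orthogroup's duplication status in the two focal lineages.

    Applies, in order: the per-lineage count rule, the 2R ohnolog
    reassignment (WGD lineage only, duplicated orthogroups only) and the 3R
    demotion (only-teleost duplications known to be 3R-retained become
    single-copy).  ``mean_copies`` averages counts over the lineage's species
    that have at least one member (absence is loss, not copy number zero).
    """
    if cnm is None:
        cnm = copy_number_matrix(table)
    for sp in cnm.columns:
        cfg.lineage_of(sp)  # raises on species missing from the config
    lin_a, lin_b = cfg.focal_pair
    sp_a = [s for s in cnm.columns if cfg.species_to_lineage.get(s) == lin_a]
    sp_b = [s for s in cnm.columns if cfg.species_to_lineage.get(s) == lin_b]
    ohnologs = ohnologs or OhnologList()
    g2r = {ln: set() for ln in (lin_a, lin_b)}
    g3r: set[str] = set()
    if len(ohnologs):
        for sp, gene, rnd in ohnologs.records:
            ln = cfg.species_to_lineage.get(sp)
            if rnd == "2R" and ln in g2r:
                g2r[ln].add(gene)
            elif rnd == "3R" and sp in cfg.wgd_3r_species:
                g3r.add(gene)

    rows = []
    for og in table:
        counts_a = cnm.loc[og, sp_a] if sp_a else pd.Series(dtype=int)
        counts_b = cnm.loc[og, sp_b] if sp_b else pd.Series(dtype=int)
        status_a, mean_a = _lineage_state(counts_a)
        status_b, mean_b = _lineage_state(counts_b)

        # 2R ohnolog reassignment: only within the WGD lineage, only for
        # orthogroups already duplicated there.
        for lineage, status_name in ((lin_a, "a"), (lin_b, "b")):
            if lineage != cfg.wgd_lineage:
                continue
            status = status_a if status_name == "a" else status_b
            if status != SMALL_SCALE_DUP:
                continue
            members = {
                g for sp in (sp_a if status_name == "a" else sp_b)
                for g in table.genes(og, sp)
            }
            if members & g2r[lineage]:
                if status_name == "a":
                    status_a = OHNOLOG
                else:
                    status_b = OHNOLOG
            else:
                # 3R demotion: all duplicated species are 3R species and at
                # least one of their members is a known 3R ohnolog.
                wgd_sp = sp_a if status_name == "a" else sp_b
                counts = counts_a if status_name == "a" else counts_b
                dup_sp = [s for s in wgd_sp if counts[s] >= 2]
                if dup_sp and all(s in cfg.wgd_3r_species for s in dup_sp):
                    genes_3r = {g for s in dup_sp for g in table.genes(og, s)}
                    if genes_3r & g3r:
                        if status_name == "a":
                            status_a = SINGLE_COPY
                        else:
                            status_b = SINGLE_COPY

        rows.append((og, status_a, status_b, mean_a, mean_b,
                     _joint_class(status_a, status_b)))

    df = pd.DataFrame(rows, columns=["orthogroup_id", "status_a", "status_b",
                                     "mean_copies_a", "mean_copies_b",
                                     "joint_class"]).set_index("orthogroup_id")
    return LineageProfile(table=df, lineages=(lin_a, lin_b))


def species_summary(table: OrthogroupTable, cfg: LineageConfig,
                    total_genes: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Per-species duplication prevalence table.

    Columns mirror the standard presentation: total genes, duplicated genes
    (genes in orthogroups where the species itself has >= 2 copies) and %,
    the same restricted to orthogroups shared between the two focal lineages
    ("orthologous genes"), orthogroup counts, and mean genes per duplicated
    orthogroup.  ``total_genes`` lets the caller supply per-species totals
    that include genes not assigned to any orthogroup.
    """
    cnm = copy_number_matrix(table)
    lin_a, lin_b = cfg.focal_pair
    sp_a = [s for s in cnm.columns if cfg.species_to_lineage.get(s) == lin_a]
    sp_b = [s for s in cnm.columns if cfg.species_to_lineage.get(s) == lin_b]
    shared = (cnm[sp_a].sum(axis=1) > 0) & (cnm[sp_b].sum(axis=1) > 0)

    rows = []
    for sp in cnm.columns:
        counts = cnm[sp]
        present = counts > 0
        dup = counts >= 2
        n_genes = int(counts.sum())
        total = int(total_genes[sp]) if total_genes and sp in total_genes else n_genes
        dup_genes = int(counts[dup].sum())
        orth_genes = int(counts[shared].sum())
        orth_dup_genes = int(counts[shared & dup].sum())
        n_og = int(present.sum())
        n_dup_og = int(dup.sum())
        mean = dup_genes / n_dup_og if n_dup_og else float("nan")
        rows.append({
            "species_id": sp,
            "lineage": cfg.species_to_lineage.get(sp, ""),
            "total_genes": total,
            "dup_genes": dup_genes,
            "pct_dup_genes": 100.0 * dup_genes / total if total else float("nan"),
            "orth_genes": orth_genes,
            "orth_dup_genes": orth_dup_genes,
            "pct_orth_dup_genes": (100.0 * orth_dup_genes / orth_genes
                                   if orth_genes else float("nan")),
            "n_orthogroups": n_og,
            "n_dup_orthogroups": n_dup_og,
            "pct_dup_orthogroups": 100.0 * n_dup_og / n_og if n_og else float("nan"),
            "mean_genes_per_dup_orthogroup": mean,
        })
    return pd.DataFrame(rows).set_index("species_id")


def lineage_specific_overlap(table: OrthogroupTable, cfg: LineageConfig,
                             lineage: str | None = None) -> dict[frozenset, int]:
    """Count lineage-specific orthogroups partitioned by the species subset
    that contains them (Venn-style cells).

    Only orthogroups with all genes confined to ``lineage`` (default: the
    first focal lineage) are counted.
    """
    if lineage is None:
        lineage = cfg.focal_pair[0]
    other = cfg.focal_pair[1] if lineage == cfg.focal_pair[0] else cfg.focal_pair[0]
    sp_lineage = set(cfg.lineage_species(lineage))
    sp_other = set(cfg.lineage_species(other))
    out: dict[frozenset, int] = {
        frozenset(c): 0
        for r in range(1, len(sp_lineage) + 1)
        for c in itertools.combinations(sorted(sp_lineage), r)
    }
    for og in table:
        row = table[og]
        present = {sp for sp, genes in row.items() if genes}
        if not present or present & sp_other:
            continue
        if present <= sp_lineage:
            out[frozenset(present)] += 1
    return out
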
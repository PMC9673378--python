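"""Synteny and genome organization of duplicates.

One-to-one ortholog dotplots (midpoint coordinates), classification of
within-species paralog pairs as tandem (strictly consecutive genes on a
chromosome), distant intra-chromosomal, or inter-chromosomal, and
chromosome-level homology with fusion/fission calls from the distribution
of one-to-one orthologs across partner chromosomes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import ChorddupError, GeneRecord, OrthogroupTable

logger = logging.getLogger(__name__)

TANDEM = "tandem"
INTRA_DISTANT = "intra_distant"
INTER = "inter_chromosomal"
LOCATION_CLASSES = (TANDEM, INTRA_DISTANT, INTER)


def one_to_one_pairs(table: OrthogroupTable, species_a: str,
                     species_b: str) -> pd.DataFrame:
    """Gene pairs from orthogroups with exactly one member in each species
    (counts in other species are ignored)."""
    rows = [
        {"orthogroup_id": og, "gene_a": ga[0], "gene_b": gb[0]}
        for og in table
        if len(ga := table.genes(og, species_a)) == 1
        and len(gb := table.genes(og, species_b)) == 1
    ]
    return pd.DataFrame(rows, columns=["orthogroup_id", "gene_a", "gene_b"])


def _index(ann: Iterable[GeneRecord]) -> dict[str, GeneRecord]:
    return {r.gene_id: r for r in ann}


def dotplot(pairs: pd.DataFrame, ann_a: Iterable[GeneRecord],
            ann_b: Iterable[GeneRecord]) -> pd.DataFrame:
    """Dotplot points: each one-to-one pair at its midpoint coordinates in
    the two genomes.  Pairs with a missing coordinate are skipped with a log
    message."""
    ia, ib = _index(ann_a), _index(ann_b)
    rows = []
    skipped = 0
    for row in pairs.itertuples(index=False):
        ra, rb = ia.get(row.gene_a), ib.get(row.gene_b)
        if ra is None or rb is None:
            skipped += 1
            continue
        rows.append({
            "gene_a": row.gene_a, "gene_b": row.gene_b,
            "chrom_a": ra.chrom, "chrom_b": rb.chrom,
            "mid_a": ra.midpoint, "mid_b": rb.midpoint,
            "rank_a": ra.rank, "rank_b": rb.rank,
        })
    if skipped:
        logger.info("dotplot: skipped %d pair(s) with missing coordinates", skipped)
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "chrom_a", "chrom_b",
                                       "mid_a", "mid_b", "rank_a", "rank_b"])


def classify_duplicate_locations(table: OrthogroupTable,
                                 ann: Iterable[GeneRecord], species: str,
                                 max_gap: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify within-species paralog pairs and orthogroups by location.

    A pair is *tandem* when both genes sit on the same chromosome at
    consecutive ranks (|rank difference| - 1 <= ``max_gap``, default 0:
    strictly adjacent), *intra_distant* on the same chromosome otherwise,
    *inter_chromosomal* across chromosomes.  The orthogroup aggregate is
    tandem if any pair is tandem, else intra_distant if all members share a
    chromosome, else inter_chromosomal.  Returns (pair table, orthogroup
    table); singleton orthogroups are skipped.
    """
    idx = _index(ann)
    pair_rows, og_rows = [], []
    for og in table:
        genes = [g for g in table.genes(og, species) if g in idx]
        if len(genes) < 2:
            continue
        classes = []
        for g1, g2 in itertools.combinations(sorted(genes), 2):
            r1, r2 = idx[g1], idx[g2]
            if r1.chrom != r2.chrom:
                cls = INTER
            elif abs(r1.rank - r2.rank) - 1 <= max_gap:
                cls = TANDEM
            else:
                cls = INTRA_DISTANT
            classes.append(cls)
            pair_rows.append({"orthogroup_id": og, "gene_1": g1, "gene_2": g2,
                              "class": cls})
        chroms = {idx[g].chrom for g in genes}
        if TANDEM in classes:
            og_cls = TANDEM
        elif len(chroms) == 1:
            og_cls = INTRA_DISTANT
        else:
            og_cls = INTER
        og_rows.append({"orthogroup_id": og, "n_members": len(genes),
                        "class": og_cls})
    return (pd.DataFrame(pair_rows, columns=["orthogroup_id", "gene_1", "gene_2", "class"]),
            pd.DataFrame(og_rows, columns=["orthogroup_id", "n_members", "class"]))


@dataclass
class ChromHomologyMap:
    """Per-chromosome ortholog sharing with partner chromosomes plus
    one-to-one / fusion-or-fission calls."""

    fractions: pd.DataFrame  # chrom_a, chrom_b, n_orthologs, fraction
    calls: pd.DataFrame      # chrom_a, partners, call


def chromosome_homology(points: pd.DataFrame, min_fraction: float = 0.2,
                        min_orthologs: int = 5) -> ChromHomologyMap:
    """Chromosome homology from the dotplot's one-to-one orthologs.

    For each A-chromosome, partner B-chromosomes are those receiving at
    least ``min_fraction`` of its orthologs.  A chromosome with one partner
    is called ``one_to_one``; with two or more substantial partners it is
    called ``fusion_or_fission`` (one chromosome in A corresponding to
    several in B, or vice versa).  Chromosomes with fewer than
    ``min_orthologs`` mapped orthologs are not called.
    """
    if points.empty:
        raise ChorddupError("no dotplot points for chromosome homology")
    counts = (points.groupby(["chrom_a", "chrom_b"]).size()
              .rename("n_orthologs").reset_index())
    totals = counts.groupby("chrom_a")["n_orthologs"].transform("sum")
    counts["fraction"] = counts["n_orthologs"] / totals

    call_rows = []
    for chrom_a, sub in counts.groupby("chrom_a"):
        n_total = int(sub["n_orthologs"].sum())
        if n_total < min_orthologs:
            continue
        partners = sorted(sub.loc[sub["fraction"] >= min_fraction, "chrom_b"])
        call = "one_to_one" if len(partners) == 1 else (
            "fusion_or_fission" if len(partners) >= 2 else "unassigned")
        call_rows.append({"chrom_a": chrom_a, "partners": ",".join(partners),
                          "n_orthologs": n_total, "call": call})
    return ChromHomologyMap(
        fractions=counts.sort_values(["chrom_a", "chrom_b"]).reset_index(drop=True),
        calls=pd.DataFrame(call_rows, columns=["chrom_a", "partners",
                                               "n_orthologs", "call"]),
    )


def plot_dotplot(points: pd.DataFrame, path: str,
                 chrom_order_a: Sequence[str] | None = None,
                 chrom_order_b: Sequence[str] | None = None) -> None:
    """Render the dotplot, points colored by A-chromosome (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7))
    chroms = chrom_order_a or sorted(points["chrom_a"].unique())
    cmap = plt.get_cmap("tab20")
    for i, chrom in enumerate(chroms):
        sub = points[points["chrom_a"] == chrom]
        ax.scatter(sub["mid_a"], sub["mid_b"], s=2, color=cmap(i % 20), label=chrom)
    ax.set_xlabel("genome A midpoint (bp)")
    ax.set_ylabel("genome B midpoint (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
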
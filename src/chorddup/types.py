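"""Shared data model for the duplication-profiling pipeline.

The central container is :class:`OrthogroupTable` (orthogroup -> species ->
member genes); everything downstream — copy-number matrices, lineage
duplication statuses, enrichment universes, synteny pairs — is derived from
it plus gene coordinates, ohnolog lists and expression matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

# Per-lineage duplication statuses.
ABSENT = "absent"
SINGLE_COPY = "single_copy"
SMALL_SCALE_DUP = "small_scale_dup"
OHNOLOG = "ohnolog"
STATUSES = (ABSENT, SINGLE_COPY, SMALL_SCALE_DUP, OHNOLOG)
DUPLICATED_STATUSES = frozenset({SMALL_SCALE_DUP, OHNOLOG})

# Joint (two-lineage) orthogroup classes.
BOTH_SINGLE = "both_single"
A_SPECIFIC_DUP = "A_specific_dup"
B_SPECIFIC_DUP = "B_specific_dup"
PARALLEL_DUP = "parallel_dup"
A_ONLY = "A_only_orthogroup"
B_ONLY = "B_only_orthogroup"
JOINT_CLASSES = (BOTH_SINGLE, A_SPECIFIC_DUP, B_SPECIFIC_DUP, PARALLEL_DUP, A_ONLY, B_ONLY)

WGD_ROUNDS = ("2R", "3R")


class ChorddupError(Exception):
    """Base error for domain-rule violations."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene's location in its genome.

    Coordinates are 1-based inclusive (GFF3 convention); readers convert at
    the boundary.  ``rank`` is the 0-based position of the gene among the
    genes of its chromosome ordered by ascending start (ties broken by end,
    then gene id).  Strand is stored but never used downstream.
    """

    gene_id: str
    species_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ChorddupError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ChorddupError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def assign_ranks(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Return records with ``rank`` assigned per (species, chrom).

    Ordering is by ascending start, ties broken by end then gene_id.
    """
    by_chrom: dict[tuple[str, str], list[GeneRecord]] = {}
    for r in records:
        by_chrom.setdefault((r.species_id, r.chrom), []).append(r)
    out: list[GeneRecord] = []
    for recs in by_chrom.values():
        recs.sort(key=lambda r: (r.start, r.end, r.gene_id))
        for i, r in enumerate(recs):
            out.append(GeneRecord(r.gene_id, r.species_id, r.chrom, r.start, r.end, r.strand, i))
    return out


class OrthogroupTable:
    """Orthogroup membership: orthogroup id -> species id -> member gene ids.

    Invariants enforced at construction: every gene id appears in at most one
    orthogroup, and no orthogroup is empty overall.  Species lists may be
    empty.
    """

    def __init__(self, entries: Mapping[str, Mapping[str, Sequence[str]]]):
        self._entries: dict[str, dict[str, list[str]]] = {}
        gene_to_og: dict[str, str] = {}
        for og, by_sp in entries.items():
            row = {sp: list(genes) for sp, genes in by_sp.items()}
            total = sum(len(g) for g in row.values())
            if total == 0:
                raise ChorddupError(f"orthogroup {og} has no genes")
            for sp, genes in row.items():
                for g in genes:
                    if g in gene_to_og:
                        raise ChorddupError(
                            f"gene {g} appears in orthogroups {gene_to_og[g]} and {og}"
                        )
                    gene_to_og[g] = og
            self._entries[og] = row
        self._gene_to_og = gene_to_og

    @property
    def entries(self) -> dict[str, dict[str, list[str]]]:
        return self._entries

    @property
    def gene_to_orthogroup(self) -> dict[str, str]:
        return self._gene_to_og

    @property
    def species(self) -> list[str]:
        seen: set[str] = set()
        for row in self._entries.values():
            seen.update(row)
        return sorted(seen)

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self._entries)

    def genes(self, og: str, species: str | None = None) -> list[str]:
        row = self._entries[og]
        if species is not None:
            return list(row.get(species, []))
        return [g for genes in row.values() for g in genes]

    def count(self, og: str, species: str) -> int:
        return len(self._entries[og].get(species, ()))

    def n_genes(self, species: str | None = None) -> int:
        if species is None:
            return len(self._gene_to_og)
        return sum(len(row.get(species, ())) for row in self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __getitem__(self, og: str) -> dict[str, list[str]]:
        return self._entries[og]

    def __contains__(self, og: str) -> bool:
        return og in self._entries

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthogroupTable):
            return NotImplemented
        if set(self._entries) != set(other._entries):
            return False
        for og, row in self._entries.items():
            orow = other._entries[og]
            keys = {sp for sp in row if row[sp]} | {sp for sp in orow if orow[sp]}
            for sp in keys:
                if sorted(row.get(sp, [])) != sorted(orow.get(sp, [])):
                    return False
        return True


@dataclass
class OhnologList:
    """Genes retained from a whole-genome duplication, labelled by round.

    Rounds are restricted to 2R (the two WGDs at the origin of vertebrates)
    and 3R (the teleost-specific WGD).  Duplicate records collapse.
    """

    _members: set[tuple[str, str, str]] = field(default_factory=set)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "OhnologList":
        members: set[tuple[str, str, str]] = set()
        for sp, gene, rnd in records:
            rnd = str(rnd).strip().upper()
            if rnd not in WGD_ROUNDS:
                raise ChorddupError(f"WGD round {rnd!r} not in {WGD_ROUNDS}")
            members.add((sp, gene, rnd))
        return cls(members)

    @property
    def records(self) -> list[tuple[str, str, str]]:
        return sorted(self._members)

    def contains(self, species: str, gene: str, wgd_round: str | None = None) -> bool:
        if wgd_round is None:
            return any((species, gene, r) in self._members for r in WGD_ROUNDS)
        return (species, gene, wgd_round) in self._members

    def genes(self, wgd_round: str, species: str | None = None) -> set[str]:
        return {
            g for sp, g, r in self._members
            if r == wgd_round and (species is None or sp == species)
        }

    def __len__(self) -> int:
        return len(self._members)


@dataclass(frozen=True)
class LineageConfig:
    """Assignment of species to lineages and the focal lineage pair.

    ``focal_pair`` orders the comparison: (A, B) = (amphioxus, vertebrate)
    in the default panel.  ``wgd_lineage`` is the lineage that may carry
    ohnolog orthogroups (structurally forbidden elsewhere — all amphioxus
    duplications are small-scale).  ``wgd_3r_species`` are the species whose
    private duplications may be 3R-demoted (the teleost).
    """

    species_to_lineage: Mapping[str, str]
    focal_pair: tuple[str, str]
    wgd_3r_species: frozenset[str] = frozenset()
    wgd_lineage: str | None = None

    def __post_init__(self) -> None:
        a, b = self.focal_pair
        if a == b:
            raise ChorddupError("focal lineages must be distinct")
        if not self.lineage_species(a) or not self.lineage_species(b):
            raise ChorddupError("both focal lineages need at least one species")
        if self.wgd_lineage is None:
            object.__setattr__(self, "wgd_lineage", b)

    def lineage_species(self, lineage: str) -> list[str]:
        return sorted(sp for sp, ln in self.species_to_lineage.items() if ln == lineage)

    def lineage_of(self, species: str) -> str:
        try:
            return self.species_to_lineage[species]
        except KeyError:
            raise ChorddupError(f"species {species} missing from lineage config") from None


def default_lineage_config() -> LineageConfig:
    """The 3-amphioxus + 4-vertebrate chordate panel used throughout."""
    mapping = {
        "Blan": "amphioxus", "Bflo": "amphioxus", "Bbel": "amphioxus",
        "Drer": "vertebrate", "Ggal": "vertebrate", "Mmus": "vertebrate",
        "Hsap": "vertebrate",
    }
    return LineageConfig(
        species_to_lineage=mapping,
        focal_pair=("amphioxus", "vertebrate"),
        wgd_3r_species=frozenset({"Drer"}),
    )


@dataclass
class ExpressionMatrix:
    """TPM by gene x sample plus sample -> condition metadata.

    ``values``: DataFrame indexed by gene id, columns sample ids, TPM >= 0.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``condition_id`` and ``condition_class`` (adult_tissue | dev_stage).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ChorddupError("negative TPM value in expression matrix")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ChorddupError(f"samples without metadata: {missing}")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.sample_meta["condition_id"].unique())

    def samples_for(self, condition: str) -> list[str]:
        m = self.sample_meta
        return [s for s in self.values.columns if m.loc[s, "condition_id"] == condition]


@dataclass(frozen=True)
class GeneTreeRec:
    """A gene tree as newick text plus the tip -> species map."""

    newick: str
    tip_species: Mapping[str, str]
    orthogroup_id: str | None = None


@dataclass
class LineageProfile:
    """Per-orthogroup duplication status of the two focal lineages.

    ``table`` is indexed by orthogroup id with columns ``status_a``,
    ``status_b``, ``mean_copies_a``, ``mean_copies_b``, ``joint_class``,
    where a/b follow ``lineages`` = cfg.focal_pair.
    """

    table: pd.DataFrame
    lineages: tuple[str, str]

    def status(self, og: str, lineage: str) -> str:
        col = "status_a" if lineage == self.lineages[0] else "status_b"
        return self.table.loc[og, col]

    def duplicated(self, og: str, lineage: str) -> bool:
        return self.status(og, lineage) in DUPLICATED_STATUSES

    def __len__(self) -> int:
        return len(self.table)
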
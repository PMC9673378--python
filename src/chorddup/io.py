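"""Readers and writers for the external formats the pipeline touches.

Everything is normalized at this boundary to the shared data model:
coordinates become 1-based inclusive, orthogroup rows become an
:class:`~chorddup.types.OrthogroupTable`, newick trees become
:class:`~chorddup.types.GeneTreeRec` with an explicit tip -> species map.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .types import (
    ChorddupError,
    ExpressionMatrix,
    GeneRecord,
    GeneTreeRec,
    OhnologList,
    OrthogroupTable,
    assign_ranks,
)

logger = logging.getLogger(__name__)

_MEMBER_SPLIT = re.compile(r"[,\s]+")

# ---------------------------------------------------------------------------
# orthogroups


def read_orthogroups(path: str | Path, dialect: str = "broccoli") -> OrthogroupTable:
    """Read an orthogroup TSV (Broccoli- or OrthoFinder-style).

    Both dialects are tab-separated with the orthogroup id in the first
    column and one column per species; members are comma- or
    space-separated.  A gene id appearing in two orthogroups raises,
    naming the gene.
    """
    if dialect not in ("broccoli", "orthofinder"):
        raise ChorddupError(f"unknown orthogroup dialect {dialect!r}")
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ChorddupError(f"{path}: orthogroup header needs >=2 columns")
        species = header[1:]
        entries: dict[str, dict[str, list[str]]] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ChorddupError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            og = fields[0]
            row: dict[str, list[str]] = {}
            for sp, cell in zip(species, fields[1:]):
                cell = cell.strip()
                row[sp] = [g for g in _MEMBER_SPLIT.split(cell) if g] if cell else []
            entries[og] = row
    return OrthogroupTable(entries)


def write_orthogroups(table: OrthogroupTable, path: str | Path,
                      species: Sequence[str] | None = None) -> None:
    species = list(species) if species is not None else table.species
    with Path(path).open("w") as fh:
        fh.write("\t".join(["orthogroup_id"] + species) + "\n")
        for og in table:
            cells = [",".join(table.genes(og, sp)) for sp in species]
            fh.write("\t".join([og] + cells) + "\n")


# ---------------------------------------------------------------------------
# gene annotation (GFF3 / BED)

_GFF_ATTR_ID = re.compile(r"(?:^|;)\s*(?:ID|gene_id)=([^;]+)")


def read_gene_annotation(path: str | Path, format: str, species_id: str) -> list[GeneRecord]:
    """Read gene coordinates from GFF3 (1-based inclusive) or BED6 (0-based
    half-open), normalizing to 1-based inclusive and assigning per-chromosome
    ranks by ascending start (ties by end then gene id).

    GFF3: only rows of type ``gene`` are used; when a gene id repeats, the
    longest span wins.
    """
    path = Path(path)
    if format == "gff3":
        records = _read_gff3(path, species_id)
    elif format == "bed":
        records = _read_bed(path, species_id)
    else:
        raise ChorddupError(f"unknown annotation format {format!r}")
    return assign_ranks(records)


def _read_gff3(path: Path, species_id: str) -> list[GeneRecord]:
    best: dict[str, GeneRecord] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ChorddupError(f"{path}:{lineno}: malformed GFF3 line")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            m = _GFF_ATTR_ID.search(attrs)
            if not m:
                raise ChorddupError(f"{path}:{lineno}: gene row without ID attribute")
            try:
                rec = GeneRecord(m.group(1), species_id, chrom, int(start), int(end),
                                 strand if strand in "+-" else ".")
            except ValueError:
                raise ChorddupError(f"{path}:{lineno}: non-integer coordinates") from None
            prev = best.get(rec.gene_id)
            if prev is None or (rec.end - rec.start) > (prev.end - prev.start):
                best[rec.gene_id] = rec
    return list(best.values())


def _read_bed(path: Path, species_id: str) -> list[GeneRecord]:
    records = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ChorddupError(f"{path}:{lineno}: malformed BED line (<4 columns)")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            try:
                # BED is 0-based half-open; +1 on start converts to 1-based inclusive.
                records.append(GeneRecord(name, species_id, chrom, int(start) + 1, int(end), strand))
            except ValueError:
                raise ChorddupError(f"{path}:{lineno}: non-integer coordinates") from None
    return records


def write_gene_annotation(records: Iterable[GeneRecord], path: str | Path,
                          format: str = "bed") -> None:
    with Path(path).open("w") as fh:
        for r in records:
            if format == "bed":
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")
            elif format == "gff3":
                fh.write(f"{r.chrom}\t.\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\tID={r.gene_id}\n")
            else:
                raise ChorddupError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# ohnologs


def read_ohnologs(path: str | Path) -> OhnologList:
    """Read a 3-column (species, gene, round) ohnolog table; duplicates collapse."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ChorddupError(f"{path}: ohnolog table needs 3 columns")
    records = [tuple(row[:3]) for row in df.itertuples(index=False)]
    return OhnologList.from_records(records)


def write_ohnologs(ohno: OhnologList, path: str | Path) -> None:
    pd.DataFrame(ohno.records, columns=["species_id", "gene_id", "wgd_round"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TPM matrix plus sample metadata.

    Samples absent from the metadata are dropped with a warning; negative
    values raise.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    if "condition_id" not in meta.columns:
        raise ChorddupError(f"{meta_path}: metadata needs a condition_id column")
    if "condition_class" not in meta.columns:
        meta["condition_class"] = "adult_tissue"
    known = [s for s in values.columns if s in meta.index]
    dropped = [s for s in values.columns if s not in meta.index]
    if dropped:
        logger.warning("dropping %d sample(s) without metadata: %s", len(dropped), dropped)
    values = values[known]
    if (values.values < 0).any():
        raise ChorddupError(f"{path}: negative TPM value")
    return ExpressionMatrix(values=values, sample_meta=meta.loc[known])


def write_expression(m: ExpressionMatrix, path: str | Path, meta_path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")
    m.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# gene trees


def read_gene_trees(path: str | Path,
                    species_map: Mapping[str, str] | None = None,
                    prefix_rule: str = r"^([A-Za-z0-9]+)_") -> list[GeneTreeRec]:
    """Read newick trees (one per line) and map tips to species.

    Tips are mapped through ``species_map`` when given, else through
    ``prefix_rule`` (a regex whose first group is the species id).  Any
    unmappable tip raises, listing the offending tips.
    """
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  preserve_underscores=True)
    pat = re.compile(prefix_rule)
    out = []
    for tree in trees:
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        mapping: dict[str, str] = {}
        bad = []
        for tip in tips:
            if species_map is not None and tip in species_map:
                mapping[tip] = species_map[tip]
            else:
                m = pat.match(tip)
                if m:
                    mapping[tip] = m.group(1)
                else:
                    bad.append(tip)
        if bad:
            raise ChorddupError(f"{path}: unmappable tips {bad}")
        out.append(GeneTreeRec(
            newick=tree.as_string(schema="newick", suppress_rooting=True).strip(),
            tip_species=mapping,
        ))
    return out


def write_gene_trees(trees: Iterable[GeneTreeRec], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in trees:
            nwk = t.newick.strip()
            fh.write(nwk + ("\n" if not nwk.endswith("\n") else ""))


# ---------------------------------------------------------------------------
# ontology + gene -> GO


def read_obo(path: str | Path, edge_types: tuple[str, ...] = ("is_a", "part_of")):
    """Read an OBO ontology into (parents, namespaces).

    ``parents``: term id -> set of parent term ids over ``edge_types``
    (is_a and part_of by default, standard propagation practice).
    ``namespaces``: term id -> namespace.  Uses obonet when available and
    falls back to a minimal stanza parser otherwise.
    """
    try:
        import obonet

        graph = obonet.read_obo(str(path))
        parents: dict[str, set[str]] = {t: set() for t in graph.nodes}
        namespaces = {
            t: data.get("namespace", "") for t, data in graph.nodes(data=True)
        }
        # obonet edges run child -> parent keyed by relation type.
        for child, parent, key in graph.edges(keys=True):
            if key in edge_types:
                parents[child].add(parent)
        return parents, namespaces
    except ImportError:  # pragma: no cover - obonet is a declared dependency
        return _read_obo_minimal(path, edge_types)


def _read_obo_minimal(path: str | Path, edge_types: tuple[str, ...]):
    parents: dict[str, set[str]] = {}
    namespaces: dict[str, str] = {}
    term_id = None
    in_term = False
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                in_term, term_id = True, None
            elif line.startswith("["):
                in_term = False
            elif in_term and line.startswith("id:"):
                term_id = line.split("id:", 1)[1].strip()
                parents.setdefault(term_id, set())
            elif in_term and term_id and line.startswith("namespace:"):
                namespaces[term_id] = line.split("namespace:", 1)[1].strip()
            elif in_term and term_id and line.startswith("is_a:") and "is_a" in edge_types:
                parents[term_id].add(line.split("is_a:", 1)[1].split("!")[0].strip())
            elif in_term and term_id and line.startswith("relationship:"):
                fields = line.split("relationship:", 1)[1].split("!")[0].split()
                if len(fields) >= 2 and fields[0] in edge_types:
                    parents[term_id].add(fields[1])
    return parents, namespaces


def write_obo(parents: Mapping[str, set[str]], path: str | Path,
              namespaces: Mapping[str, str] | None = None) -> None:
    with Path(path).open("w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n\n")
        for term in sorted(parents):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            if namespaces and term in namespaces:
                fh.write(f"namespace: {namespaces[term]}\n")
            for p in sorted(parents[term]):
                fh.write(f"is_a: {p}\n")
            fh.write("\n")


def read_gene_go(path: str | Path, format: str = "tsv") -> dict[str, set[str]]:
    """Read gene -> GO associations from a two-column TSV or a GAF
    (columns 2 and 5)."""
    gomap: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "!")):
                continue
            fields = line.split("\t")
            if format == "tsv":
                if len(fields) < 2:
                    raise ChorddupError(f"{path}:{lineno}: need 2 columns")
                gene, term = fields[0], fields[1]
            elif format == "gaf":
                if len(fields) < 5:
                    raise ChorddupError(f"{path}:{lineno}: GAF needs >=5 columns")
                gene, term = fields[1], fields[4]
            else:
                raise ChorddupError(f"unknown gene-GO format {format!r}")
            gomap.setdefault(gene, set()).add(term)
    return gomap


def write_gene_go(gomap: Mapping[str, set[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene in sorted(gomap):
            for term in sorted(gomap[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# BLAST tabular

BLAST_COLUMNS = ["query_id", "subject_id", "pct_identity", "aln_length",
                 "qlen", "slen", "evalue", "database_tag"]


def read_blast_table(path: str | Path, database_tag: str | None = None) -> pd.DataFrame:
    """Read BLAST outfmt "6 qseqid sseqid pident length qlen slen evalue".

    An eighth column, when present, is the database tag; otherwise
    ``database_tag`` labels every hit.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 7:
        df[7] = database_tag if database_tag is not None else "default"
    if df.shape[1] != 8:
        raise ChorddupError(f"{path}: expected 7 or 8 BLAST columns, got {df.shape[1]}")
    df.columns = BLAST_COLUMNS
    df = df.astype({"pct_identity": float, "aln_length": int, "qlen": int,
                    "slen": int, "evalue": float})
    if (df["aln_length"] < 1).any():
        raise ChorddupError(f"{path}: alignment length < 1")
    if (df["evalue"] < 0).any():
        raise ChorddupError(f"{path}: negative e-value")
    return df


def write_blast_table(df: pd.DataFrame, path: str | Path) -> None:
    df[BLAST_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
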
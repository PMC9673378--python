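"""Gene-model validation from similarity and expression evidence.

Each gene is scored against several similarity databases and one expression
strategy.  Similarity evidence is *strong* when some hit covers more than
75% of both query and subject with e-value below 1e-8 (the coverage reading
of the published length-ratio thresholds — the literal length/alignment
ratio would be >= 1 for ungapped alignments and vacuous), *weak* when some
hit has e-value below 1e-4, else *none*.  Expression evidence is *strong*
when the gene is expressed in more than 3 libraries, *none* at 0, *weak*
otherwise (the unstated exactly-3 case is conservatively weak).  A gene is
retained when at least one strategy is strong.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .types import ChorddupError, ExpressionMatrix

STRONG, WEAK, NONE = "strong", "weak", "none"

STRONG_COVERAGE = 0.75
STRONG_EVALUE = 1e-8
WEAK_EVALUE = 1e-4


def seqsim_evidence(hits: pd.DataFrame) -> pd.DataFrame:
    """Evidence level per (query gene, database): strong / weak / none.

    Returns a table with one row per gene x database combination present in
    the hits.  Genes with no hits simply do not appear (their evidence is
    none).
    """
    if (hits["qlen"] <= 0).any() or (hits["slen"] <= 0).any():
        raise ChorddupError("zero-length query or subject in BLAST hits")
    df = hits.copy()
    df["qcov"] = df["aln_length"] / df["qlen"]
    df["scov"] = df["aln_length"] / df["slen"]
    df["is_strong"] = ((df["qcov"] > STRONG_COVERAGE) & (df["scov"] > STRONG_COVERAGE)
                       & (df["evalue"] < STRONG_EVALUE))
    df["is_weak"] = df["evalue"] < WEAK_EVALUE
    agg = df.groupby(["query_id", "database_tag"])[["is_strong", "is_weak"]].any()
    agg["evidence"] = np.where(agg["is_strong"], STRONG,
                               np.where(agg["is_weak"], WEAK, NONE))
    return agg.reset_index()[["query_id", "database_tag", "evidence"]]


def classify_seqsim(hits: pd.DataFrame, gene: str) -> dict[str, str]:
    """Evidence per database for one gene (none for databases without hits)."""
    sub = hits[hits["query_id"] == gene]
    out: dict[str, str] = {}
    if sub.empty:
        return out
    table = seqsim_evidence(sub)
    for row in table.itertuples(index=False):
        out[row.database_tag] = row.evidence
    return out


def expression_evidence(m: ExpressionMatrix, threshold: float = 1.0) -> pd.DataFrame:
    """Per-gene expression evidence from library-level presence.

    A gene counts as expressed in a library (sample) when its TPM is at or
    above ``threshold``; strong = expressed in more than 3 libraries, none =
    0, weak otherwise.
    """
    n_expr = (m.values >= threshold).sum(axis=1)
    evidence = np.where(n_expr > 3, STRONG, np.where(n_expr == 0, NONE, WEAK))
    return pd.DataFrame({"n_expressed_libraries": n_expr, "evidence": evidence})


def classify_expression(m: ExpressionMatrix, gene: str,
                        threshold: float = 1.0) -> str:
    table = expression_evidence(m, threshold=threshold)
    if gene not in table.index:
        raise ChorddupError(f"gene {gene} not in the expression matrix")
    return str(table.loc[gene, "evidence"])


def retention(evidence: pd.DataFrame) -> tuple[set[str], dict]:
    """Retained gene set plus summary percentages.

    ``evidence``: one row per gene (index = gene id), one column per
    strategy, values in {strong, weak, none}.  A gene is retained iff any
    strategy is strong; the summary reports counts and the retained
    percentage to two decimals.
    """
    is_strong = (evidence == STRONG).any(axis=1)
    retained = set(evidence.index[is_strong])
    n = len(evidence)
    summary = {
        "n_genes": n,
        "n_retained": len(retained),
        "n_dropped": n - len(retained),
        "pct_retained": round(100.0 * len(retained) / n, 2) if n else float("nan"),
    }
    return retained, summary


def evidence_table(seqsim: pd.DataFrame | None,
                   expr: pd.DataFrame | None,
                   genes: Iterable[str]) -> pd.DataFrame:
    """Assemble the per-gene strategy table used by :func:`retention`.

    ``seqsim`` is the output of :func:`seqsim_evidence` (pivoted to one
    column per database), ``expr`` the output of
    :func:`expression_evidence`; genes missing from either get ``none``.
    """
    genes = list(genes)
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    if seqsim is not None and not seqsim.empty:
        pivot = seqsim.pivot(index="query_id", columns="database_tag",
                             values="evidence")
        for db in pivot.columns:
            out[f"seqsim_{db}"] = pivot[db].reindex(genes).fillna(NONE)
    if expr is not None and not expr.empty:
        out["expression"] = expr["evidence"].reindex(genes).fillna(NONE)
    return out.fillna(NONE)


def protein_correspondence(cds: str, protein: str) -> tuple[float, bool]:
    """Fraction of mismatches between the translated CDS and the annotated
    protein; passes at <= 10% mismatches.

    The CDS is translated with the standard code after trimming a trailing
    stop; sequences are compared position by position over the shorter
    length, and any length difference counts as that many mismatches (so the
    denominator is the longer length).  Untranslatable codons translate to X
    and count as mismatches.
    """
    cds = cds.strip().upper().replace("U", "T")
    protein = protein.strip().upper().rstrip("*")
    if len(cds) % 3 != 0:
        raise ChorddupError(f"CDS length {len(cds)} not divisible by 3")
    translated = str(Seq(cds).translate())
    if translated.endswith("*"):
        translated = translated[:-1]
    n_short = min(len(translated), len(protein))
    n_long = max(len(translated), len(protein))
    if n_long == 0:
        raise ChorddupError("empty CDS/protein comparison")
    mismatches = sum(1 for a, b in zip(translated, protein)
                     if a != b or a == "X")
    mismatches += n_long - n_short
    fraction = mismatches / n_long
    return fraction, fraction <= 0.10
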
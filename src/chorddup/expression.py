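"""Expression characterization of duplicate genes.

Per-condition mean TPM, the Tau tissue-specificity index, boxplot-style
group summaries, and the cross-species expression-breadth comparison: for
matched condition pairs between two species, the difference in the number
of expressed conditions per ortholog pair, with the union-of-duplicates
variant that pools the conditions covered by all copies on the duplicated
side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ChorddupError, ExpressionMatrix, OrthogroupTable

logger = logging.getLogger(__name__)

#: Conditions excluded from the cross-species comparison because their
#: expression patterns are too divergent between the species compared.
DEFAULT_EXCLUDED_CONDITIONS = ("blastula", "female_gonads", "epidermis")


@dataclass(frozen=True)
class ConditionMap:
    """Matched condition pairs (species A condition, species B condition)."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        a = [p[0] for p in self.pairs]
        b = [p[1] for p in self.pairs]
        if len(set(a)) != len(a) or len(set(b)) != len(b):
            raise ChorddupError("conditions must be unique on each side of the map")

    def __len__(self) -> int:
        return len(self.pairs)

    def side(self, which: int) -> list[str]:
        return [p[which] for p in self.pairs]


def default_condition_map() -> ConditionMap:
    """The seven homologous amphioxus / zebrafish conditions used for the
    expression-breadth comparison."""
    return ConditionMap(pairs=(
        ("embryo", "embryo"),
        ("male_gonads", "testis"),
        ("muscle", "muscle_tissue"),
        ("neural_tube", "brain"),
        ("gut", "intestine"),
        ("gills", "pharyngeal_gill"),
        ("hepatic_diverticulum", "liver"),
    ))


@dataclass
class PresenceProfile:
    """Boolean expressed/not-expressed calls per gene over an ordered
    condition list."""

    calls: pd.DataFrame  # genes x conditions, bool
    threshold: float

    @property
    def conditions(self) -> list[str]:
        return list(self.calls.columns)

    def n_expressed(self, gene: str) -> int:
        return int(self.calls.loc[gene].sum())


def condition_means(m: ExpressionMatrix, class_filter: str | None = None) -> pd.DataFrame:
    """Arithmetic mean TPM per gene and condition.

    ``class_filter`` restricts to one condition class (``adult_tissue`` or
    ``dev_stage``).
    """
    meta = m.sample_meta
    if class_filter is not None:
        meta = meta[meta["condition_class"] == class_filter]
    groups = meta.groupby("condition_id").groups
    out = {}
    for cond, samples in groups.items():
        cols = [s for s in samples if s in m.values.columns]
        if cols:
            out[cond] = m.values[cols].mean(axis=1)
    return pd.DataFrame(out)


def tau(x: Sequence[float]) -> float:
    """Tau tissue-specificity index of a per-condition expression vector.

    tau = sum_i (1 - x_i / x_max) / (n - 1); 0 for uniform expression, 1 for
    expression confined to a single condition.  Undefined (raises) for
    all-zero vectors; invariant under positive scaling.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ChorddupError("tau needs a 1-D vector of >= 2 conditions")
    if (x < 0).any():
        raise ChorddupError("tau needs non-negative expression values")
    xmax = x.max()
    if xmax == 0:
        raise ChorddupError("tau undefined for an all-zero expression vector")
    return float((1.0 - x / xmax).sum() / (len(x) - 1))


def tau_table(means: pd.DataFrame, log_transform: bool = False) -> pd.DataFrame:
    """Tau per gene from a gene x condition mean table.

    Genes with no expression in any condition get NaN and are flagged.  With
    ``log_transform`` the index is computed on log2(TPM + 1) instead of raw
    means (surfaced because the choice changes the value).
    """
    vals = means.to_numpy(dtype=float)
    if log_transform:
        vals = np.log2(vals + 1.0)
    xmax = vals.max(axis=1)
    n = vals.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (1.0 - vals / xmax[:, None]).sum(axis=1) / (n - 1)
    t = np.where(xmax > 0, t, np.nan)
    return pd.DataFrame({"tau": t, "n_conditions": n,
                         "defined": xmax > 0}, index=means.index)


def presence_profile(means: pd.DataFrame, conditions: Sequence[str],
                     threshold: float = 1.0,
                     excluded: Sequence[str] = DEFAULT_EXCLUDED_CONDITIONS) -> PresenceProfile:
    """Expressed/not-expressed calls: mean TPM >= threshold.

    ``conditions`` fixes the column order (one side of a ConditionMap);
    excluded conditions must not be requested and never appear.
    """
    conditions = list(conditions)
    bad = [c for c in conditions if c in set(excluded)]
    if bad:
        raise ChorddupError(f"conditions {bad} are excluded from the analysis")
    missing = [c for c in conditions if c not in means.columns]
    if missing:
        raise ChorddupError(f"conditions missing from the mean table: {missing}")
    calls = means[conditions] >= threshold
    return PresenceProfile(calls=calls, threshold=threshold)


def _aligned(profile: PresenceProfile, gene: str) -> np.ndarray:
    return profile.calls.loc[gene].to_numpy(dtype=bool)


def expression_delta(table: OrthogroupTable,
                     profile_a: PresenceProfile,
                     profile_b: PresenceProfile,
                     species_a: str, species_b: str,
                     mode: str = "one_to_one") -> pd.DataFrame:
    """Per-orthogroup differences in the number of expressed conditions
    (species A count minus species B count).

    ``one_to_one``: restricted to orthogroups with exactly one gene of each
    species; one record per pair.  ``union_vs_single``: orthogroups with one
    gene on one side and >= 2 on the other; emits one record per duplicate
    copy (``one_to_one`` rows, each copy against the single gene) plus one
    ``union_vs_single`` row where the duplicated side is represented by the
    union of its copies' conditions.  Orthogroups not matching the requested
    configuration are skipped with a log message.
    """
    if mode not in ("one_to_one", "union_vs_single"):
        raise ChorddupError(f"unknown delta mode {mode!r}")
    n_cond_a = len(profile_a.conditions)
    n_cond_b = len(profile_b.conditions)
    if n_cond_a != n_cond_b:
        raise ChorddupError("presence profiles must cover the same matched conditions")

    rows = []
    skipped = 0
    for og in table:
        ga = [g for g in table.genes(og, species_a) if g in profile_a.calls.index]
        gb = [g for g in table.genes(og, species_b) if g in profile_b.calls.index]
        if mode == "one_to_one":
            if len(ga) != 1 or len(gb) != 1:
                skipped += 1
                continue
            ca = int(_aligned(profile_a, ga[0]).sum())
            cb = int(_aligned(profile_b, gb[0]).sum())
            rows.append({"orthogroup_id": og, "mode": "one_to_one",
                         "gene_a": ga[0], "gene_b": gb[0],
                         "count_a": ca, "count_b": cb, "delta": ca - cb})
        else:
            if len(ga) == 1 and len(gb) >= 2:
                single, dups, dup_side = ga[0], gb, "b"
            elif len(gb) == 1 and len(ga) >= 2:
                single, dups, dup_side = gb[0], ga, "a"
            else:
                skipped += 1
                continue
            sp_single = profile_a if dup_side == "b" else profile_b
            sp_dup = profile_b if dup_side == "b" else profile_a
            c_single = int(_aligned(sp_single, single).sum())
            union = np.zeros(n_cond_a, dtype=bool)
            for g in dups:
                v = _aligned(sp_dup, g)
                c_dup = int(v.sum())
                union |= v
                delta = (c_single - c_dup) if dup_side == "b" else (c_dup - c_single)
                rows.append({"orthogroup_id": og, "mode": "one_to_one",
                             "gene_a": single if dup_side == "b" else g,
                             "gene_b": g if dup_side == "b" else single,
                             "count_a": c_single if dup_side == "b" else c_dup,
                             "count_b": c_dup if dup_side == "b" else c_single,
                             "delta": delta})
            c_union = int(union.sum())
            delta_u = (c_single - c_union) if dup_side == "b" else (c_union - c_single)
            rows.append({"orthogroup_id": og, "mode": "union_vs_single",
                         "gene_a": single if dup_side == "b" else "|".join(dups),
                         "gene_b": "|".join(dups) if dup_side == "b" else single,
                         "count_a": c_single if dup_side == "b" else c_union,
                         "count_b": c_union if dup_side == "b" else c_single,
                         "delta": delta_u})
    if skipped:
        logger.info("expression_delta(%s): skipped %d orthogroup(s) not matching "
                    "the requested configuration", mode, skipped)
    return pd.DataFrame(rows, columns=["orthogroup_id", "mode", "gene_a", "gene_b",
                                       "count_a", "count_b", "delta"])


def delta_distribution_stats(deltas: Sequence[int]) -> dict:
    """Median, mean, Fisher-Pearson adjusted sample skewness and an integer
    histogram of a delta distribution."""
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise ChorddupError("no delta records")
    lo, hi = int(d.min()), int(d.max())
    hist = {k: int((d == k).sum()) for k in range(lo, hi + 1)}
    return {
        "n": int(d.size),
        "median": float(np.median(d)),
        "mean": float(d.mean()),
        "skewness": float(stats.skew(d, bias=False)) if d.size >= 3 else float("nan"),
        "histogram": hist,
    }


def group_expression_summary(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Boxplot statistics per gene group.

    Boxes span Q1..Q3 (linear-interpolation quartiles), whiskers extend to
    the most extreme points within 1.5 x IQR beyond the box; points outside
    are outliers and excluded from the summary.
    """
    rows = []
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ChorddupError(f"empty expression group {name!r}")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        rows.append({
            "group": name, "n": int(v.size),
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
            "n_outliers": int(v.size - inside.size),
        })
    return pd.DataFrame(rows).set_index("group")
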
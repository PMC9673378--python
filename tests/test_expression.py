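"""Expression characterization: Tau, presence calls, breadth deltas, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chorddup.expression import (
    ConditionMap,
    condition_means,
    default_condition_map,
    delta_distribution_stats,
    expression_delta,
    group_expression_summary,
    presence_profile,
    tau,
    tau_table,
)
from chorddup.profiles import lineage_status
from chorddup.simulate import SynthParams, simulate_bundle
from chorddup.types import ChorddupError, ExpressionMatrix, OrthogroupTable


def _matrix(values, samples, conds, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    vals = pd.DataFrame(values, index=genes, columns=samples)
    meta = pd.DataFrame({"condition_id": conds,
                         "condition_class": "adult_tissue"},
                        index=pd.Index(samples, name="sample_id"))
    return ExpressionMatrix(values=vals, sample_meta=meta)


class TestConditionMeans:
    def test_replicate_mean(self):
        m = _matrix([[2.0, 4.0]], ["s1", "s2"], ["muscle", "muscle"])
        means = condition_means(m)
        assert means.loc["g0", "muscle"] == 3.0

    def test_single_replicate_identity(self):
        m = _matrix([[5.0]], ["s1"], ["gut"])
        assert condition_means(m).loc["g0", "gut"] == 5.0

    def test_matches_per_cell_recomputation(self):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(8)]
        conds = ["c1", "c1", "c2", "c2", "c2", "c3", "c3", "c3"]
        vals = rng.random((10, 8)) * 50
        m = _matrix(vals, samples, conds)
        means = condition_means(m)
        for gi in range(10):
            for cond in ("c1", "c2", "c3"):
                cols = [i for i, c in enumerate(conds) if c == cond]
                assert means.iloc[gi][cond] == pytest.approx(vals[gi, cols].mean())


class TestTau:
    def test_uniform_is_zero(self):
        assert tau([5, 5, 5, 5]) == 0.0

    def test_single_condition_is_one(self):
        assert tau([0, 0, 9]) == 1.0

    def test_hand_evaluated_example(self):
        assert tau([1, 2, 4]) == pytest.approx(0.625)

    def test_all_zero_flagged(self):
        with pytest.raises(ChorddupError, match="all-zero"):
            tau([0.0, 0.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e4), min_size=2, max_size=10),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, vec, scale):
        if max(vec) == 0:
            return
        assert tau(vec) == pytest.approx(tau([v * scale for v in vec]), abs=1e-9)

    def test_table_flags_undefined_genes(self):
        means = pd.DataFrame({"c1": [1.0, 0.0], "c2": [3.0, 0.0]},
                             index=["g1", "g2"])
        t = tau_table(means)
        assert t.loc["g1", "defined"]
        assert not t.loc["g2", "defined"]
        assert np.isnan(t.loc["g2", "tau"])


class TestPresenceProfile:
    def test_threshold_calls(self):
        means = pd.DataFrame({"c1": [0.0], "c2": [1.2], "c3": [0.4]}, index=["g"])
        p = presence_profile(means, ["c1", "c2", "c3"], threshold=1.0)
        assert list(p.calls.loc["g"]) == [False, True, False]

    def test_zero_threshold_all_present_for_positive(self):
        means = pd.DataFrame({"c1": [0.1], "c2": [7.0]}, index=["g"])
        p = presence_profile(means, ["c1", "c2"], threshold=0.0)
        assert p.calls.loc["g"].all()

    def test_excluded_condition_rejected(self):
        means = pd.DataFrame({"blastula": [1.0]}, index=["g"])
        with pytest.raises(ChorddupError, match="excluded"):
            presence_profile(means, ["blastula"])

    def test_unmapped_condition_rejected(self):
        means = pd.DataFrame({"c1": [1.0]}, index=["g"])
        with pytest.raises(ChorddupError, match="missing"):
            presence_profile(means, ["c1", "c9"])

    def test_counts_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        means = pd.DataFrame(rng.random((30, 5)) * 10,
                             columns=[f"c{i}" for i in range(5)])
        counts = []
        for thr in (0.5, 1.0, 2.0, 5.0):
            p = presence_profile(means, list(means.columns), threshold=thr)
            counts.append(int(p.calls.values.sum()))
        assert counts == sorted(counts, reverse=True)


def _presence(genes_to_vec, conds):
    df = pd.DataFrame.from_dict(genes_to_vec, orient="index", columns=conds)
    from chorddup.expression import PresenceProfile
    return PresenceProfile(calls=df.astype(bool), threshold=1.0)


class TestExpressionDelta:
    conds_a = [f"a{i}" for i in range(7)]
    conds_b = [f"b{i}" for i in range(7)]

    def test_identical_profiles_delta_zero(self):
        table = OrthogroupTable({"OG1": {"Blan": ["x"], "Drer": ["y"]}})
        vec = [1, 1, 0, 0, 1, 0, 1]
        pa = _presence({"x": vec}, self.conds_a)
        pb = _presence({"y": vec}, self.conds_b)
        out = expression_delta(table, pa, pb, "Blan", "Drer", mode="one_to_one")
        assert list(out["delta"]) == [0]

    def test_union_of_duplicates_schematic(self):
        """A single gene expressed in 5 conditions against a duplicate pair
        covering 3 and 4 with union 5: per-copy deltas +2 and +1, union
        delta 0."""
        table = OrthogroupTable({"OG1": {"Blan": ["s"], "Drer": ["d1", "d2"]}})
        pa = _presence({"s": [1, 1, 1, 1, 1, 0, 0]}, self.conds_a)
        pb = _presence({"d1": [1, 1, 1, 0, 0, 0, 0],
                        "d2": [0, 1, 1, 1, 1, 0, 0]}, self.conds_b)
        out = expression_delta(table, pa, pb, "Blan", "Drer", mode="union_vs_single")
        per_copy = out[out["mode"] == "one_to_one"]["delta"].tolist()
        assert sorted(per_copy) == [1, 2]
        union = out[out["mode"] == "union_vs_single"]["delta"].tolist()
        assert union == [0]

    def test_mismatched_configuration_skipped(self):
        table = OrthogroupTable({"OG1": {"Blan": ["x1", "x2"], "Drer": ["y1", "y2"]}})
        pa = _presence({"x1": [1] * 7, "x2": [1] * 7}, self.conds_a)
        pb = _presence({"y1": [1] * 7, "y2": [1] * 7}, self.conds_b)
        assert expression_delta(table, pa, pb, "Blan", "Drer", "one_to_one").empty
        assert expression_delta(table, pa, pb, "Blan", "Drer", "union_vs_single").empty

    def test_union_bounds_on_random_profiles(self):
        rng = np.random.default_rng(9)
        entries, va, vb = {}, {}, {}
        for i in range(300):
            og = f"OG{i}"
            entries[og] = {"Blan": [f"x{i}"], "Drer": [f"y{i}_1", f"y{i}_2"]}
            va[f"x{i}"] = rng.random(7) < 0.5
            vb[f"y{i}_1"] = rng.random(7) < 0.5
            vb[f"y{i}_2"] = rng.random(7) < 0.5
        table = OrthogroupTable(entries)
        pa = _presence(va, self.conds_a)
        pb = _presence(vb, self.conds_b)
        out = expression_delta(table, pa, pb, "Blan", "Drer", "union_vs_single")
        for og, sub in out.groupby("orthogroup_id"):
            copies = sub[sub["mode"] == "one_to_one"]["count_b"]
            union = sub[sub["mode"] == "union_vs_single"]["count_b"].iloc[0]
            assert union >= copies.max()
            assert union <= min(7, copies.sum())


class TestDeltaStats:
    def test_symmetric_zero_skewness(self):
        s = delta_distribution_stats([-1, 0, 1])
        assert s["skewness"] == pytest.approx(0.0)
        assert s["median"] == 0.0

    def test_positive_skew_direction(self):
        assert delta_distribution_stats([0, 0, 0, 3])["skewness"] > 0

    def test_matches_moment_formula(self):
        """Skewness equals the adjusted Fisher-Pearson moment formula
        recomputed directly."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.integers(-5, 6, size=int(rng.integers(5, 40))).astype(float)
            if np.allclose(x, x[0]):
                continue
            n = len(x)
            m = x.mean()
            m2 = ((x - m) ** 2).mean()
            m3 = ((x - m) ** 3).mean()
            g1 = m3 / m2 ** 1.5
            adj = g1 * np.sqrt(n * (n - 1)) / (n - 2)
            assert delta_distribution_stats(x)["skewness"] == pytest.approx(adj)

    def test_histogram_covers_support(self):
        s = delta_distribution_stats([-2, 0, 0, 3])
        assert sum(s["histogram"].values()) == 4
        assert set(s["histogram"]) == set(range(-2, 4))


class TestGroupSummary:
    def test_one_to_nine(self):
        s = group_expression_summary({"g": list(range(1, 10))})
        row = s.loc["g"]
        assert row["median"] == 5
        assert row["q1"] == 3.0 and row["q3"] == 7.0
        assert row["whisker_low"] == 1 and row["whisker_high"] == 9

    def test_outlier_excluded_from_whisker(self):
        values = list(range(1, 10)) + [7.0 + 2 * 4.0]  # Q3 + 2*IQR
        s = group_expression_summary({"g": values})
        assert s.loc["g", "whisker_high"] < 15.0
        assert s.loc["g", "n_outliers"] == 1

    def test_matches_sorting_recomputation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = rng.random(int(rng.integers(5, 60))) * 100
            s = group_expression_summary({"g": v}).loc["g"]
            vs = np.sort(v)
            assert s["median"] == pytest.approx(np.percentile(vs, 50))
            q1, q3 = np.percentile(vs, [25, 75])
            lo = vs[vs >= q1 - 1.5 * (q3 - q1)].min()
            hi = vs[vs <= q3 + 1.5 * (q3 - q1)].max()
            assert s["whisker_low"] == pytest.approx(lo)
            assert s["whisker_high"] == pytest.approx(hi)

    def test_empty_group_raises(self):
        with pytest.raises(ChorddupError, match="empty"):
            group_expression_summary({"g": []})


class TestSubfunctionalizationSignature:
    def test_deltas_skew_toward_single_copy_side(self):
        """With duplicates partitioning an ancestral condition set, per-copy
        deltas shift toward the single-copy species while union deltas stay
        centered at zero (sign tests)."""
        bundle = simulate_bundle(SynthParams(
            seed=41, n_orthogroups=2000, subfunctionalization_prob=0.8,
            dropout=0.0))
        table = bundle.orthogroups
        cmap = bundle.condition_map
        means_a = condition_means(bundle.expression["Blan"])
        means_b = condition_means(bundle.expression["Drer"])
        pa = presence_profile(means_a, cmap.side(0), threshold=1.0)
        pb = presence_profile(means_b, cmap.side(1), threshold=1.0)
        out = expression_delta(table, pa, pb, "Blan", "Drer", "union_vs_single")
        # restrict to single amphioxus gene vs duplicated zebrafish side
        og_single_a = {og for og in table
                       if table.count(og, "Blan") == 1 and table.count(og, "Drer") >= 2}
        sub = out[out["orthogroup_id"].isin(og_single_a)]
        per_copy = sub[sub["mode"] == "one_to_one"]["delta"]
        union = sub[sub["mode"] == "union_vs_single"]["delta"]
        assert len(per_copy) >= 200
        # sign test: duplicates cover fewer conditions than the single ortholog
        pos = int((per_copy > 0).sum())
        neg = int((per_copy < 0).sum())
        assert pos > 2 * neg
        assert per_copy.mean() > 0.3
        # union restores the ancestral breadth
        assert abs(union.mean()) < 0.15
        assert abs(union.median()) <= 1


def test_default_condition_map_has_seven_pairs():
    cmap = default_condition_map()
    assert len(cmap) == 7
    assert ("male_gonads", "testis") in cmap.pairs


def test_condition_map_rejects_duplicates():
    with pytest.raises(ChorddupError):
        ConditionMap(pairs=(("a", "x"), ("a", "y")))
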
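"""Co-duplication enrichment: hypergeometric correctness and fold recovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from chorddup.enrichment import (
    copy_number_association,
    coduplication_report,
    enrichment_test,
    intersection_table,
)
from chorddup.profiles import copy_number_matrix, lineage_status
from chorddup.simulate import SynthParams, simulate_bundle
from chorddup.types import ChorddupError, LineageProfile


def _profile_from_flags(dup_a, dup_b):
    """Build a minimal two-status profile from boolean duplication flags."""
    df = pd.DataFrame({
        "status_a": ["small_scale_dup" if a else "single_copy" for a in dup_a],
        "status_b": ["small_scale_dup" if b else "single_copy" for b in dup_b],
        "mean_copies_a": [2.5 if a else 1.0 for a in dup_a],
        "mean_copies_b": [2.5 if b else 1.0 for b in dup_b],
        "joint_class": "",
    }, index=[f"OG{i}" for i in range(len(dup_a))])
    return LineageProfile(table=df, lineages=("A", "B"))


def _enumerated_upper_tail(N, K, n, k):
    """P[X >= k] for a hypergeometric draw by exhaustive enumeration of all
    C(N, n) subsets of a universe with K marked elements."""
    universe = list(range(N))
    marked = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestEnrichmentTest:
    def test_all_overlap_five_of_ten(self):
        r = enrichment_test(10, 5, 5, 5, n_tests=1)
        assert r.p_raw == pytest.approx(1 / 252)

    def test_null_cell_not_significant(self):
        # observed equals expectation exactly on symmetric margins
        r = enrichment_test(100, 50, 50, 25, n_tests=1)
        assert r.p_raw > 0.3
        assert r.fold == pytest.approx(1.0)

    def test_matches_enumeration_for_small_universes(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k_max = min(K, n)
            k = int(rng.integers(max(0, K + n - N), k_max + 1))
            r = enrichment_test(N, K, n, k, n_tests=1)
            if r.direction == "enriched":
                expected = _enumerated_upper_tail(N, K, n, k)
            else:
                expected = 1.0 - _enumerated_upper_tail(N, K, n, k + 1)
            assert r.p_raw == pytest.approx(expected, abs=1e-12)

    def test_observed_beyond_margins_rejected(self):
        with pytest.raises(ChorddupError, match="exceeds"):
            enrichment_test(10, 3, 4, 5)

    def test_bonferroni_monotone_and_capped(self):
        p1 = enrichment_test(100, 40, 40, 30, n_tests=1).p_bonferroni
        p6 = enrichment_test(100, 40, 40, 30, n_tests=6).p_bonferroni
        assert p6 >= p1
        assert enrichment_test(100, 50, 50, 25, n_tests=10 ** 9).p_bonferroni == 1.0

    def test_printed_worked_example(self):
        """Observed 7.3% vs expected 4.3% of the universe gives a 1.7-fold
        enrichment whose binary logarithm is 0.76."""
        N = 1000
        r = enrichment_test(N, 215, 200, 73, n_tests=6)
        assert r.expected_pct == pytest.approx(4.3)
        assert r.observed_pct == pytest.approx(7.3)
        assert round(r.fold, 1) == 1.7
        assert round(r.log2_fold, 2) == 0.76


class TestIntersectionTable:
    def test_independent_universe_folds_near_one(self):
        rng = np.random.default_rng(0)
        dup_a = rng.random(400) < 0.5
        dup_b = rng.random(400) < 0.5
        profile = _profile_from_flags(dup_a, dup_b)
        cells = intersection_table(profile)
        assert cells["observed"].sum() == 400
        for row in cells.itertuples(index=False):
            if row.category_b == "ohnolog":
                continue
            fold = row.observed / row.expected
            assert abs(fold - 1.0) < 0.25

    def test_observed_counts_equal_set_intersections(self, small_bundle):
        profile = lineage_status(small_bundle.orthogroups, small_bundle.cfg,
                                 small_bundle.ohnologs)
        cells = intersection_table(profile)
        t = profile.table
        shared = t[(t["status_a"] != "absent") & (t["status_b"] != "absent")]
        a_sets = {
            "single": set(shared.index[~shared["status_a"].isin(["small_scale_dup", "ohnolog"])]),
            "ssd": set(shared.index[shared["status_a"].isin(["small_scale_dup", "ohnolog"])]),
        }
        b_sets = {
            "single": set(shared.index[shared["status_b"] == "single_copy"]),
            "ohnolog": set(shared.index[shared["status_b"] == "ohnolog"]),
            "ssd": set(shared.index[shared["status_b"] == "small_scale_dup"]),
        }
        for row in cells.itertuples(index=False):
            assert row.observed == len(a_sets[row.category_a] & b_sets[row.category_b])

    def test_observed_and_expected_both_sum_to_universe(self, small_bundle):
        profile = lineage_status(small_bundle.orthogroups, small_bundle.cfg,
                                 small_bundle.ohnologs)
        cells = intersection_table(profile)
        n = cells["n_universe"].iloc[0]
        assert cells["observed"].sum() == n
        assert cells["expected"].sum() == pytest.approx(n)

    def test_empty_universe_raises(self):
        profile = _profile_from_flags([], [])
        with pytest.raises(ChorddupError, match="universe"):
            intersection_table(profile)


class TestFoldRecovery:
    @pytest.mark.parametrize("f", [1.0, 2.0, 4.0])
    def test_enrichment_factor_recovered(self, f):
        """The generator's co-duplication odds multiplier is recovered from
        the joint duplication fraction within the 95% binomial interval."""
        params = SynthParams(seed=int(10 * f), n_orthogroups=5000,
                             enrichment_factor=f, p_dup={"amphioxus": 0.2, "vertebrate": 0.2},
                             p_lineage_specific=0.0, p_3r_only=0.0)
        bundle = simulate_bundle(params)
        profile = lineage_status(bundle.orthogroups, bundle.cfg, bundle.ohnologs)
        t = profile.table
        shared = t[(t["status_a"] != "absent") & (t["status_b"] != "absent")]
        dup_a = shared["status_a"].isin(["small_scale_dup", "ohnolog"])
        dup_b = shared["status_b"].isin(["small_scale_dup", "ohnolog"])
        n = len(shared)
        k = int((dup_a & dup_b).sum())
        p_joint_true = f * 0.2 * 0.2
        # 95% binomial CI for the joint count at the generative probability
        se = math.sqrt(p_joint_true * (1 - p_joint_true) / n)
        p_hat = k / n
        assert abs(p_hat - p_joint_true) < 1.96 * se + 1e-9
        fold_hat = p_hat / ((dup_a.mean()) * (dup_b.mean()))
        assert fold_hat == pytest.approx(f, rel=0.15)


class TestCopyNumberAssociation:
    def test_perfect_rank_correlation(self):
        means = np.linspace(2, 8, 50)
        df = pd.DataFrame({
            "status_a": "small_scale_dup", "status_b": "small_scale_dup",
            "mean_copies_a": means, "mean_copies_b": means ** 2,
            "joint_class": "parallel_dup",
        }, index=[f"OG{i}" for i in range(50)])
        assoc = copy_number_association(LineageProfile(df, ("A", "B")))
        assert assoc.spearman_rho == pytest.approx(1.0)

    def test_independent_means_near_zero(self):
        rng = np.random.default_rng(123)
        df = pd.DataFrame({
            "status_a": "small_scale_dup", "status_b": "small_scale_dup",
            "mean_copies_a": 2 + rng.random(500) * 4,
            "mean_copies_b": 2 + rng.random(500) * 4,
            "joint_class": "parallel_dup",
        }, index=[f"OG{i}" for i in range(500)])
        assoc = copy_number_association(LineageProfile(df, ("A", "B")))
        assert abs(assoc.spearman_rho) < 0.1
        assert assoc.chi2_p > 0.05

    def test_rho_matches_naive_rank_correlation(self):
        """Spearman's rho equals a from-scratch Pearson-on-midranks."""

        def naive_spearman(x, y):
            def midrank(v):
                order = sorted(range(len(v)), key=lambda i: v[i])
                ranks = [0.0] * len(v)
                i = 0
                while i < len(v):
                    j = i
                    while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                        j += 1
                    r = (i + j) / 2 + 1
                    for k in range(i, j + 1):
                        ranks[order[k]] = r
                    i = j + 1
                return ranks

            rx, ry = midrank(list(x)), midrank(list(y))
            mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
            num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
            den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                            * sum((b - my) ** 2 for b in ry))
            return num / den

        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(5, 30))
            x = rng.integers(1, 6, size=n).astype(float)
            y = x + rng.integers(0, 4, size=n)
            df = pd.DataFrame({
                "status_a": "small_scale_dup", "status_b": "small_scale_dup",
                "mean_copies_a": x, "mean_copies_b": y.astype(float),
                "joint_class": "parallel_dup",
            }, index=[f"OG{i}" for i in range(n)])
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assoc = copy_number_association(LineageProfile(df, ("A", "B")))
            assert assoc.spearman_rho == pytest.approx(naive_spearman(x, y), abs=1e-12)

    def test_too_few_orthogroups(self):
        profile = _profile_from_flags([True, True], [True, True])
        with pytest.raises(ChorddupError, match=">= 3"):
            copy_number_association(profile)

    def test_report_on_bundle(self, small_bundle):
        profile = lineage_status(small_bundle.orthogroups, small_bundle.cfg,
                                 small_bundle.ohnologs)
        report = coduplication_report(profile)
        assert len(report) == 6
        assert (report["p_bonferroni"] <= 1).all()
        assert (report["p_raw"] <= report["p_bonferroni"] + 1e-15).all()
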
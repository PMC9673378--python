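"""Dotplots, duplicate location classes, chromosome homology."""

import numpy as np
import pandas as pd
import pytest

from chorddup.synteny import (
    chromosome_homology,
    classify_duplicate_locations,
    dotplot,
    one_to_one_pairs,
)
from chorddup.simulate import SynthParams, simulate_bundle
from chorddup.types import GeneRecord, OrthogroupTable, assign_ranks


def _ann(genes, species="sp"):
    """genes: list of (gene_id, chrom, start, end)."""
    return assign_ranks(GeneRecord(g, species, c, s, e) for g, c, s, e in genes)


class TestOneToOnePairs:
    def test_basic(self):
        t = OrthogroupTable({
            "OG1": {"A": ["a1"], "B": ["b1"]},
            "OG2": {"A": ["a2", "a3"], "B": ["b2"]},
            "OG3": {"A": ["a4"], "B": ["b3"], "C": ["c1", "c2"]},
        })
        pairs = one_to_one_pairs(t, "A", "B")
        assert set(zip(pairs["gene_a"], pairs["gene_b"])) == {("a1", "b1"), ("a4", "b3")}

    def test_counting_oracle_on_random_tables(self):
        rng = np.random.default_rng(6)
        gid = 0
        entries = {}
        for i in range(200):
            row = {}
            for sp in ("A", "B"):
                n = int(rng.integers(0, 4))
                row[sp] = [f"{sp}g{gid + k}" for k in range(n)]
                gid += n
            if not any(row.values()):
                row["A"] = [f"Ag{gid}"]
                gid += 1
            entries[f"OG{i}"] = row
        t = OrthogroupTable(entries)
        expected = sum(1 for og in entries
                       if len(entries[og].get("A", [])) == 1
                       and len(entries[og].get("B", [])) == 1)
        assert len(one_to_one_pairs(t, "A", "B")) == expected


class TestDotplot:
    def test_midpoints(self):
        pairs = pd.DataFrame({"orthogroup_id": ["OG1"], "gene_a": ["a"],
                              "gene_b": ["b"]})
        pts = dotplot(pairs, _ann([("a", "chr1", 100, 200)], "A"),
                      _ann([("b", "chr3", 10, 19)], "B"))
        assert pts.loc[0, "mid_a"] == 150.0
        assert pts.loc[0, "mid_b"] == 14.5

    def test_missing_coordinates_skipped(self, caplog):
        pairs = pd.DataFrame({"orthogroup_id": ["OG1", "OG2"],
                              "gene_a": ["a", "x"], "gene_b": ["b", "y"]})
        pts = dotplot(pairs, _ann([("a", "chr1", 1, 2)], "A"),
                      _ann([("b", "chr1", 1, 2)], "B"))
        assert len(pts) == 1

    def test_identity_genomes_on_diagonal(self):
        genes = [(f"g{i}", f"chr{1 + i % 3}", 100 * i + 1, 100 * i + 50)
                 for i in range(30)]
        ann_a = _ann(genes, "A")
        ann_b = _ann(genes, "B")
        pairs = pd.DataFrame({"orthogroup_id": [f"OG{i}" for i in range(30)],
                              "gene_a": [g for g, *_ in genes],
                              "gene_b": [g for g, *_ in genes]})
        pts = dotplot(pairs, ann_a, ann_b)
        assert (pts["mid_a"] == pts["mid_b"]).all()
        assert (pts["chrom_a"] == pts["chrom_b"]).all()

    def test_inversion_reverses_local_rank_order(self):
        """A simulated inversion produces a segment with negative rank
        correlation while the untouched segment stays positive."""
        n = 40
        genes_a = [(f"g{i}", "chr1", 100 * i + 1, 100 * i + 50) for i in range(n)]
        coords_b = list(range(n))
        coords_b[10:30] = coords_b[10:30][::-1]
        genes_b = [(f"g{i}", "chr1", 100 * coords_b.index(i) + 1,
                    100 * coords_b.index(i) + 50) for i in range(n)]
        t = OrthogroupTable({f"OG{i}": {"A": [f"g{i}"]} for i in range(n)})
        pairs = pd.DataFrame({"orthogroup_id": [f"OG{i}" for i in range(n)],
                              "gene_a": [f"g{i}" for i in range(n)],
                              "gene_b": [f"g{i}" for i in range(n)]})
        pts = dotplot(pairs, _ann(genes_a, "A"), _ann(genes_b, "B"))
        pts = pts.sort_values("rank_a")
        inside = pts.iloc[10:30]
        outside = pts.iloc[:10]
        assert np.corrcoef(inside["rank_a"], inside["rank_b"])[0, 1] < -0.99
        assert np.corrcoef(outside["rank_a"], outside["rank_b"])[0, 1] > 0.99


class TestDuplicateLocations:
    def _table(self):
        return OrthogroupTable({"OG1": {"sp": ["p", "q"]}})

    def test_adjacent_ranks_tandem(self):
        ann = _ann([("p", "chr2", 700, 750), ("q", "chr2", 800, 850),
                    ("z", "chr2", 100, 150)])
        pairs, ogs = classify_duplicate_locations(self._table(), ann, "sp")
        assert pairs.loc[0, "class"] == "tandem"
        assert ogs.loc[0, "class"] == "tandem"

    def test_gap_of_one_is_distant(self):
        ann = _ann([("p", "chr2", 700, 750), ("z", "chr2", 760, 790),
                    ("q", "chr2", 800, 850)])
        pairs, _ = classify_duplicate_locations(self._table(), ann, "sp")
        assert pairs.loc[0, "class"] == "intra_distant"

    def test_gap_parameter_relaxes_tandem(self):
        ann = _ann([("p", "chr2", 700, 750), ("z", "chr2", 760, 790),
                    ("q", "chr2", 800, 850)])
        pairs, _ = classify_duplicate_locations(self._table(), ann, "sp", max_gap=1)
        assert pairs.loc[0, "class"] == "tandem"

    def test_across_chromosomes(self):
        ann = _ann([("p", "chr1", 1, 50), ("q", "chr2", 1, 50)])
        pairs, ogs = classify_duplicate_locations(self._table(), ann, "sp")
        assert pairs.loc[0, "class"] == "inter_chromosomal"
        assert ogs.loc[0, "class"] == "inter_chromosomal"

    def test_classes_partition_pairs(self, small_bundle):
        pairs, _ = classify_duplicate_locations(
            small_bundle.orthogroups, small_bundle.annotations["Blan"], "Blan")
        assert pairs["class"].isin(["tandem", "intra_distant",
                                    "inter_chromosomal"]).all()

    @pytest.mark.parametrize("t", [0.1, 0.5])
    def test_tandem_fraction_recovered(self, t):
        """Pair-level tandem frequency among two-copy orthogroups recovers
        the generator's tandem fraction within the binomial interval."""
        bundle = simulate_bundle(SynthParams(seed=int(100 * t), n_orthogroups=4000,
                                             tandem_fraction=t))
        table = bundle.orthogroups
        n = 0
        n_tandem = 0
        for sp in table.species:  # placement mechanism is identical per species
            two_copy = {og for og in table if table.count(og, sp) == 2}
            pairs, _ = classify_duplicate_locations(table, bundle.annotations[sp], sp)
            sub = pairs[pairs["orthogroup_id"].isin(two_copy)]
            n += len(sub)
            n_tandem += int((sub["class"] == "tandem").sum())
        assert n > 500
        frac = n_tandem / n
        se = (t * (1 - t) / n) ** 0.5
        assert abs(frac - t) < 1.96 * se + 0.01


class TestChromosomeHomology:
    def _points(self, mapping, n_per=30):
        rows = []
        for i, (ca, cb) in enumerate(mapping):
            rows.append({"gene_a": f"a{i}", "gene_b": f"b{i}", "chrom_a": ca,
                         "chrom_b": cb, "mid_a": 1.0 * i, "mid_b": 1.0 * i,
                         "rank_a": i, "rank_b": i})
        return pd.DataFrame(rows)

    def test_identity_one_to_one(self):
        mapping = [(f"chr{c}", f"chr{c}") for c in (1, 2) for _ in range(20)]
        h = chromosome_homology(self._points(mapping))
        assert (h.calls["call"] == "one_to_one").all()
        assert list(h.calls["partners"]) == ["chr1", "chr2"]

    def test_split_chromosome_called_fusion_or_fission(self):
        """One A chromosome mapping half-and-half to two B chromosomes is a
        fusion/fission call."""
        mapping = ([("chrA1", "chrB9")] * 25 + [("chrA1", "chrB11")] * 25
                   + [("chrA2", "chrB2")] * 30)
        h = chromosome_homology(self._points(mapping))
        row = h.calls.set_index("chrom_a").loc["chrA1"]
        assert row["call"] == "fusion_or_fission"
        assert row["partners"] == "chrB11,chrB9"

    def test_fractions_sum_to_one(self, small_bundle):
        from chorddup.synteny import one_to_one_pairs as o2o
        table = small_bundle.orthogroups
        pairs = o2o(table, "Blan", "Bflo")
        pts = dotplot(pairs, small_bundle.annotations["Blan"],
                      small_bundle.annotations["Bflo"])
        h = chromosome_homology(pts)
        sums = h.fractions.groupby("chrom_a")["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_invariant_to_relabeling(self):
        mapping = [("chrA1", "chrB9")] * 25 + [("chrA1", "chrB11")] * 25
        h1 = chromosome_homology(self._points(mapping))
        relabeled = [("K", {"chrB9": "P", "chrB11": "Q"}[b]) for _, b in mapping]
        h2 = chromosome_homology(self._points(relabeled))
        assert list(h1.calls["call"]) == list(h2.calls["call"])
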
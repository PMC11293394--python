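import numpy as np
import pandas as pd
import pytest

from nfkbdep.config import RunConfig
from nfkbdep.io import PeakRecord
from nfkbdep.peaks import (
    accessibility_overlay,
    cluster_composition,
    filter_reproducible,
    kinetic_kmeans,
    quantify,
    rank_order_matrix,
    union_peaksets,
)
from nfkbdep.simulate import ARCHETYPE_SHAPES

from conftest import random_peak_sets


def brute_force_union(peaksets):
    """O(n^2) oracle: repeatedly merge any two overlapping intervals."""
    items = [
        [p.chrom, p.start, p.end, {name}]
        for name, records in peaksets.items()
        for p in records
    ]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                    a[1], a[2] = min(a[1], b[1]), max(a[2], b[2])
                    a[3] |= b[3]
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((c, s, e, frozenset(t)) for c, s, e, t in items)


def _peak(chrom, start, end, pid="p", score=25.0, rpkm=4.0):
    return PeakRecord(chrom, start, end, pid, score, {"r": rpkm})


class TestFilterReproducible:
    def test_passing_both_replicates_kept(self):
        reps = [[_peak("chr1", 0, 200, "a")], [_peak("chr1", 10, 190, "a")]]
        kept = filter_reproducible({1.0: reps})
        assert len(kept) == 1
        assert (kept[0].start, kept[0].end) == (0, 200)

    def test_score_threshold_is_strict(self):
        reps = [[_peak("chr1", 0, 200, score=19.0)], [_peak("chr1", 0, 200, score=19.0)]]
        assert filter_reproducible({1.0: reps}) == []

    def test_one_of_three_replicates_excluded(self):
        reps = [[_peak("chr1", 0, 200)], [], []]
        assert filter_reproducible({1.0: reps}, min_replicates=2) == []

    def test_two_of_three_replicates_kept(self):
        reps = [[_peak("chr1", 0, 200)], [_peak("chr1", 0, 200)], []]
        assert len(filter_reproducible({1.0: reps}, min_replicates=2)) == 1

    def test_single_passing_timepoint_suffices(self):
        low = [[_peak("chr1", 0, 200, rpkm=0.1)]] * 2
        high = [[_peak("chr1", 0, 200)]] * 2
        kept = filter_reproducible({0.0: low, 2.0: high})
        assert len(kept) == 1

    def test_mismatched_chromosome_sets_rejected(self):
        reps = [[_peak("chr1", 0, 200)], [_peak("chrX", 0, 200)]]
        with pytest.raises(ValueError, match="chromosome"):
            filter_reproducible({1.0: reps})

    def test_monotone_in_score_cutoff(self):
        rng = np.random.default_rng(2)
        reps = [
            [
                _peak("chr1", 1000 * i, 1000 * i + 300, f"p{i}", score=float(s), rpkm=5.0)
                for i, s in enumerate(rng.uniform(0, 60, size=40))
            ]
            for _ in range(2)
        ]
        n_prev = None
        for cut in (5.0, 19.0, 40.0):
            n = len(filter_reproducible({1.0: reps}, RunConfig(ps_cut=cut)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestUnionPeaksets:
    def test_disjoint_sets_concatenate(self):
        a = [_peak("chr1", i * 1000, i * 1000 + 100, f"a{i}") for i in range(3)]
        b = [_peak("chr2", i * 1000, i * 1000 + 100, f"b{i}") for i in range(4)]
        out = union_peaksets({"A": a, "B": b})
        assert len(out) == 7
        assert out["A"].sum() == 3 and out["B"].sum() == 4

    def test_identical_sets_idempotent(self):
        a = [_peak("chr1", i * 1000, i * 1000 + 100, f"a{i}") for i in range(5)]
        out = union_peaksets({"A": a, "B": list(a)})
        assert len(out) == 5
        assert out[["A", "B"]].all().all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            sets = random_peak_sets(rng, n_sets=3, n_peaks=25)
            got = union_peaksets(sets)
            got_tuples = sorted(
                (
                    row.chrom,
                    row.start,
                    row.end,
                    frozenset(n for n in sets if getattr(row, n)),
                )
                for row in got.itertuples()
            )
            assert got_tuples == brute_force_union(sets)


class TestQuantify:
    def test_unit_arithmetic(self):
        merged = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [200], "peak_id": ["p"]}
        )
        counts = pd.DataFrame({"s1": [40], "s2": [0]}, index=["p"])
        out = quantify(merged, counts, {"s1": 10.0, "s2": 10.0})
        assert out.loc["p", "s1"] == pytest.approx(20.0)
        assert out.loc["p", "s2"] == 0.0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(5)
        n = 30
        merged = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * 1000,
                "end": np.arange(n) * 1000 + rng.integers(100, 900, n),
                "peak_id": [f"p{i}" for i in range(n)],
            }
        )
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(n, 3)).astype(float),
            index=merged["peak_id"],
            columns=["a", "b", "c"],
        )
        libs = {"a": 8.0, "b": 12.5, "c": 30.0}
        out = quantify(merged, counts, libs)
        for pid in merged["peak_id"]:
            width_kb = (
                merged.set_index("peak_id").loc[pid, "end"]
                - merged.set_index("peak_id").loc[pid, "start"]
            ) / 1000
            for s in libs:
                assert out.loc[pid, s] == pytest.approx(counts.loc[pid, s] / (width_kb * libs[s]))


class TestKineticKmeans:
    def _matrix(self, profiles, ids=None):
        ids = ids or [f"p{i}" for i in range(len(profiles))]
        return pd.DataFrame(profiles, index=ids, columns=["0h", "0.5h", "1h", "2h"])

    def test_noiseless_archetypes_become_singleton_clusters(self):
        m = self._matrix(ARCHETYPE_SHAPES * 10.0)
        cl = kinetic_kmeans(m, k=6, seed=0)
        assert sorted(cl.assignments) == [1, 2, 3, 4, 5, 6]
        # relabelling follows the kinetic order of the planted shapes
        assert cl.assignments["p0"] == 1 and cl.assignments["p5"] == 6

    def test_late_profile_joins_late_cluster(self):
        cl = kinetic_kmeans(self._matrix(ARCHETYPE_SHAPES * 8.0), k=6, seed=0)
        assert cl.assign([1.0, 1.0, 1.0, 10.0]) == 6

    def test_deterministic_under_seed_and_row_order(self):
        rng = np.random.default_rng(0)
        profiles = ARCHETYPE_SHAPES[rng.integers(0, 6, 120)] * np.exp(
            rng.normal(0, 0.2, size=(120, 4))
        )
        m = self._matrix(profiles)
        a = kinetic_kmeans(m, seed=3).assignments
        b = kinetic_kmeans(m, seed=3).assignments
        pd.testing.assert_series_equal(a, b)
        shuffled = m.sample(frac=1, random_state=1)
        c = kinetic_kmeans(shuffled, seed=3).assignments
        assert (c.reindex(a.index) == a).all()

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kinetic_kmeans(self._matrix(ARCHETYPE_SHAPES[:3]), k=6)


class TestClusterComposition:
    def test_single_cluster_factor(self):
        m = pd.DataFrame(
            ARCHETYPE_SHAPES, index=[f"p{i}" for i in range(6)], columns=["0h", "0.5h", "1h", "2h"]
        )
        cl = kinetic_kmeans(m, seed=0)
        comp = cluster_composition(cl, {"f": ["p5"], "g": [f"p{i}" for i in range(6)]})
        assert comp.loc["f", 6] == 100.0 and comp.loc["f", 1] == 0.0
        assert comp.loc["g"].sum() == pytest.approx(100.0, abs=1e-9)


class TestAccessibilityOverlay:
    def test_contained_peak_is_accessible(self):
        peaks = [_peak("chr1", 100, 200, "q")]
        atac = [_peak("chr1", 0, 500, "a")]
        assert bool(accessibility_overlay(peaks, atac)["q"])

    def test_half_open_boundary(self):
        # ATAC interval [0, 100); a peak starting at 100 shares no base
        peaks = [_peak("chr1", 100, 200, "q")]
        atac = [_peak("chr1", 0, 100, "a")]
        assert not bool(accessibility_overlay(peaks, atac)["q"])
        touching = [_peak("chr1", 99, 200, "q2")]
        assert bool(accessibility_overlay(touching, atac)["q2"])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            sets = random_peak_sets(rng, n_sets=2, n_peaks=30)
            query, subject = sets["set0"], sets["set1"]
            got = accessibility_overlay(query, subject)
            for q in query:
                expected = any(
                    q.chrom == s.chrom and q.start < s.end and s.start < q.end
                    for s in subject
                )
                assert got[q.peak_id] == expected


class TestRankOrderMatrix:
    def test_descending_by_reference(self):
        m = pd.DataFrame({"ref": [3, 9, 1], "x": [0, 1, 2]}, index=["a", "b", "c"])
        out = rank_order_matrix(m, "ref")
        assert list(out.index) == ["b", "a", "c"]

    def test_ties_break_lexicographically(self):
        m = pd.DataFrame({"ref": [5, 5, 5]}, index=["c", "a", "b"])
        assert list(rank_order_matrix(m, "ref").index) == ["a", "b", "c"]

    def test_sorting_is_a_permutation(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(
            rng.random((20, 3)), index=[f"p{i}" for i in range(20)], columns=["ref", "x", "y"]
        )
        out = rank_order_matrix(m, "ref")
        pd.testing.assert_frame_equal(out.sort_index(), m.sort_index())
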
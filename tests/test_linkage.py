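"""Two-point estimation, Haldane mapping, ordering and cleanup."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from durmap import linkage, simdata
from durmap.errors import EmptyResultError, UndefinedEstimateError, ValidationError
from durmap.linkage import (
    MISSING,
    build_component_map,
    correct_singletons,
    estimate_all_pairs,
    estimate_pair,
    filter_markers,
    group_markers,
    haldane_cM,
    haldane_r,
    order_group,
    order_markers,
    ril_expand,
    ril_invert,
    two_point_lod,
)

from conftest import make_seg


class TestHaldane:
    @pytest.mark.parametrize("r,expected", [(0.0, 0.0), (0.1, -50 * np.log(0.8))])
    def test_known_values(self, r, expected):
        assert haldane_cM(r) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(0.0, 0.499))
    def test_round_trip(self, r):
        assert haldane_r(haldane_cM(r)) == pytest.approx(r, abs=1e-12)

    def test_unlinked_is_infinite_distance(self):
        with pytest.raises(ValidationError):
            haldane_cM(0.5)

    @given(st.floats(0.0, 0.5))
    def test_ril_transform_round_trip(self, r):
        assert ril_invert(ril_expand(r)) == pytest.approx(r, abs=1e-12)


class TestFilter:
    def test_missing_and_distortion_rules(self):
        rng = np.random.default_rng(0)
        n = 200
        balanced = rng.integers(0, 2, n)
        gappy = balanced.copy()
        gappy[:40] = MISSING  # 20% missing
        skewed = np.array([0] * 150 + [1] * 50)  # chi2 = 50, P ~ 1.5e-12
        seg = make_seg([balanced, gappy, skewed], markers=["ok", "gap", "skew"])
        kept, report = filter_markers(seg)
        assert kept.markers == ("ok",)
        reasons = dict(zip(report["marker"], report["reason"]))
        assert reasons == {"gap": "missing", "skew": "distortion"}
        p_skew = report.set_index("marker").loc["skew", "distortion_p"]
        assert p_skew == pytest.approx(1.54e-12, rel=0.05)

    def test_balanced_marker_retained(self):
        seg = make_seg([[0, 1] * 100])
        kept, report = filter_markers(seg)
        assert kept.n_markers == 1 and report.empty

    def test_everything_filtered_is_distinct_error(self):
        seg = make_seg([[0] * 200])
        with pytest.raises(EmptyResultError):
            filter_markers(seg)


class TestEstimatePair:
    def test_dh_lod_worked_example(self):
        # k=10, n=100: LOD = -10 - 4.118 + 30.103 = 15.99
        a = np.zeros(100, dtype=np.int8)
        b = a.copy()
        b[:10] = 1
        est = estimate_pair(make_seg([a, b], "DH"), "m1", "m2")
        assert est.r == pytest.approx(0.10)
        assert est.lod == pytest.approx(15.99, abs=0.01)

    def test_ril_inverse_expansion(self):
        a = np.zeros(90, dtype=np.int8)
        b = a.copy()
        b[:30] = 1  # R = 1/3 -> r = 0.25
        est = estimate_pair(make_seg([a, b], "RIL"), "m1", "m2")
        assert est.r == pytest.approx(0.25, abs=1e-9)

    def test_half_recombinant_has_zero_lod(self):
        a = np.zeros(100, dtype=np.int8)
        b = a.copy()
        b[:50] = 1
        est = estimate_pair(make_seg([a, b], "DH"), "m1", "m2")
        assert est.lod == pytest.approx(0.0, abs=1e-12)

    def test_no_informative_meioses(self):
        a = np.array([0, 0, MISSING, MISSING], dtype=np.int8)
        b = np.array([MISSING, MISSING, 1, 1], dtype=np.int8)
        with pytest.raises(UndefinedEstimateError):
            estimate_pair(make_seg([a, b], "DH", lines=list("wxyz")), "m1", "m2")

    def test_lod_invariants(self):
        # LOD at R = 0.5 is 0; grows as R departs from 0.5 at fixed n
        assert two_point_lod(50, 100, 0.5) == pytest.approx(0.0, abs=1e-12)
        lods = [two_point_lod(k, 100, k / 100) for k in (40, 30, 20, 10, 0)]
        assert all(b > a for a, b in zip(lods, lods[1:]))

    def test_matches_vectorized_table(self, ril_seg):
        tab = estimate_all_pairs(ril_seg).set_index(["marker_a", "marker_b"])
        for a, b in [(ril_seg.markers[0], ril_seg.markers[1]),
                     (ril_seg.markers[3], ril_seg.markers[17])]:
            est = estimate_pair(ril_seg, a, b)
            key = (a, b) if (a, b) in tab.index else (b, a)
            row = tab.loc[key]
            assert row["k"] == est.k and row["n"] == est.n
            assert row["lod"] == pytest.approx(est.lod, abs=1e-9)


class TestGrouping:
    def _pairs(self, lods):
        import pandas as pd

        return pd.DataFrame(
            [(a, b, 0.2, 0.2, l) for (a, b), l in lods.items()],
            columns=["marker_a", "marker_b", "R", "r", "lod"],
        )

    def test_transitive_closure(self):
        groups = group_markers(self._pairs({("A", "B"): 8, ("B", "C"): 7, ("A", "C"): 2}))
        assert groups == [["A", "B", "C"]]

    def test_all_unlinked_singletons(self):
        groups = group_markers(self._pairs({("A", "B"): 2, ("B", "C"): 1, ("A", "C"): 0}))
        assert groups == [["A"], ["B"], ["C"]]

    def test_relaxed_threshold_merges(self):
        lods = {("A", "B"): 8, ("B", "C"): 4, ("C", "D"): 8}
        assert len(group_markers(self._pairs(lods), lod_min=6.0)) == 2
        assert len(group_markers(self._pairs(lods), lod_min=3.0, max_r=0.3)) == 1


class TestOrdering:
    def _simulate(self, n_markers, n_lines, seed, length=60.0):
        tm = simdata.simulate_true_map(1, length, n_markers, seed=seed)
        cfg = simdata.SimConfig(pop_type="RIL", n_lines=n_lines, missing_rate=0.0,
                                error_rate=0.0, seed=seed + 1000)
        return tm, simdata.simulate_population(tm, cfg)

    def test_two_marker_group(self):
        _, seg = self._simulate(2, 200, 3)
        lg = order_group(seg, list(seg.markers))
        est = estimate_pair(seg, *seg.markers)
        assert lg.length_cM == pytest.approx(haldane_cM(est.r), abs=1e-9)

    def test_exhaustive_permutation_oracle(self):
        """Heuristic order reaches the brute-force optimum of the same criterion."""
        tm, seg = self._simulate(6, 500, 4)
        pairs = estimate_all_pairs(seg)
        ordered, pos = order_markers(list(seg.markers), pairs)
        dist = {}
        for row in pairs.itertuples(index=False):
            d = haldane_cM(min(row.r, 0.49999))
            dist[(row.marker_a, row.marker_b)] = d
            dist[(row.marker_b, row.marker_a)] = d
        cost = lambda order: sum(dist[(a, b)] for a, b in zip(order, order[1:]))
        best = min(cost(p) for p in itertools.permutations(seg.markers))
        assert cost(ordered) == pytest.approx(best, abs=1e-9)
        # and the optimum equals the true order up to full reversal
        truth = list(tm.groups[0].markers)
        assert ordered in (truth, truth[::-1])

    def test_input_order_invariance(self):
        _, seg = self._simulate(6, 400, 5)
        pairs = estimate_all_pairs(seg)
        base, _ = order_markers(list(seg.markers), pairs)
        shuffled = list(seg.markers)[::-1]
        again, _ = order_markers(shuffled, pairs)
        assert again in (base, base[::-1])

    def test_order_recovery_property(self):
        """20 markers, 200 RILs: rank correlation >= 0.99 in >= 95% of seeds."""
        from scipy import stats

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            tm, seg = self._simulate(20, 200, 50 + seed, length=100.0)
            lg = order_group(seg, list(seg.markers))
            truth = {m: i for i, m in enumerate(tm.groups[0].markers)}
            ranks = [truth[m] for m in lg.markers]
            rho = abs(stats.spearmanr(ranks, range(len(ranks))).statistic)
            if rho >= 0.99:
                hits += 1
        assert hits >= 0.95 * n_seeds


class TestSingletons:
    def _seg_with_gap(self, gaps, calls, pop="RIL"):
        tm = simdata.TrueMap(
            (simdata.TrueGroup("g", ("a", "b", "c"),
                               np.array([0.0, gaps[0], gaps[0] + gaps[1]])),)
        )
        seg = make_seg(np.array(calls, dtype=np.int8).T, pop, markers=["a", "b", "c"])
        lg = linkage.LinkageGroup("g", ("a", "b", "c"), tm.groups[0].positions)
        return seg, lg

    def test_double_crossover_blanked_in_window(self):
        seg, lg = self._seg_with_gap([2, 2], [[0, 1, 0], [0, 0, 0]])
        cleaned, n = correct_singletons(seg, lg, window_cM=5.0)
        assert n == 1
        assert cleaned.calls[1, 0] == MISSING
        assert cleaned.calls[0, 0] == 0 and cleaned.calls[2, 0] == 0  # never flipped
        _, n2 = correct_singletons(cleaned, lg, window_cM=5.0)
        assert n2 == 0  # idempotent

    def test_outside_window_untouched(self):
        seg, lg = self._seg_with_gap([8, 8], [[0, 1, 0]])
        cleaned, n = correct_singletons(seg, lg, window_cM=5.0)
        assert n == 0 and np.array_equal(cleaned.calls, seg.calls)

    def test_dh_wide_window_corrects(self):
        seg, lg = self._seg_with_gap([8, 8], [[0, 1, 0]], pop="DH")
        _, n = correct_singletons(seg, lg, window_cM=10.0)
        assert n == 1


class TestComponentMap:
    def test_recovers_group_structure(self):
        # evenly spaced 10 cM grid: every adjacent pair is well inside the
        # linkable range, so the 3 chromosomes must come back as 3 groups
        tm = simdata.TrueMap(
            tuple(
                simdata.TrueGroup(
                    f"LG{i + 1}",
                    tuple(f"G{i + 1}M{j + 1:03d}" for j in range(8)),
                    np.arange(8) * 10.0,
                )
                for i in range(3)
            )
        )
        cfg = simdata.SimConfig(pop_type="RIL", n_lines=300, missing_rate=0.02,
                                error_rate=0.002, seed=10)
        seg = simdata.simulate_population(tm, cfg)
        result = build_component_map(seg)
        assert len(result.groups) == 3
        recovered = sorted(tuple(sorted(g.markers)) for g in result.groups)
        truth = sorted(tuple(sorted(g.markers)) for g in tm.groups)
        assert recovered == truth
        assert result.cm_per_marker == pytest.approx(result.total_cM / result.n_markers)

    def test_empty_after_filtering_raises(self):
        seg = make_seg([[0] * 200, [1] * 200])
        with pytest.raises(EmptyResultError):
            build_component_map(seg)
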
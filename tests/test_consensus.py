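"""Meiosis pooling, heterogeneity screening, framework and interpolation."""

import numpy as np
import pandas as pd
import pytest

from durmap import consensus, simdata
from durmap.consensus import (
    ConsensusGroup,
    ConsensusMap,
    PopPairCounts,
    add_interpolated,
    build_framework,
    cm_per_marker,
    collinearity,
    interpolate_unique,
    length_excess_pct,
    pool_all_pairs,
    pool_pair,
    summarize_map,
)
from durmap.consensus import test_heterogeneity as heterogeneity_test
from durmap.errors import UndefinedEstimateError, ValidationError
from durmap.linkage import LinkageGroup


class TestHeterogeneity:
    def test_worked_contingency_example(self):
        # 10/100 vs 30/100, pooled p = 0.2 -> chi2 = 12.5, df 1
        chi2, df, p = heterogeneity_test(
            [PopPairCounts("p1", 10, 100, "DH"), PopPairCounts("p2", 30, 100, "DH")]
        )
        assert chi2 == pytest.approx(12.5)
        assert df == 1
        assert p == pytest.approx(4.07e-4, rel=0.01)

    def test_identical_proportions_null(self):
        chi2, _, p = heterogeneity_test(
            [PopPairCounts("p1", 20, 100, "DH"), PopPairCounts("p2", 20, 100, "DH")]
        )
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_three_identical_populations_df(self):
        chi2, df, _ = heterogeneity_test(
            [PopPairCounts(f"p{i}", 15, 100, "DH") for i in range(3)]
        )
        assert df == 2 and chi2 == pytest.approx(0.0, abs=1e-12)

    def test_single_population_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            heterogeneity_test([PopPairCounts("p1", 10, 100, "DH")])

    def test_ril_counts_enter_on_meiotic_scale(self):
        # RIL observed 30/90 (R=1/3) shrinks to r=0.25 -> homogeneous with DH 25/100
        chi2, _, p = heterogeneity_test(
            [PopPairCounts("ril", 30, 90, "RIL"), PopPairCounts("dh", 25, 100, "DH")]
        )
        assert chi2 < 0.1 and p > 0.5


class TestPooling:
    def test_homogeneous_dh_count_pooling(self):
        est = pool_pair(
            "a", "b",
            [PopPairCounts("p1", 10, 100, "DH"), PopPairCounts("p2", 8, 50, "DH")],
        )
        assert est.r == pytest.approx(18 / 150)
        assert est.excluded == ()
        assert est.n == 150

    def test_heterogeneous_population_excluded(self):
        est = pool_pair(
            "a", "b",
            [PopPairCounts("p1", 10, 100, "DH"), PopPairCounts("p2", 45, 100, "DH")],
        )
        assert len(est.excluded) == 1
        kept = est.included[0]
        assert est.r == pytest.approx(kept.k / kept.n)

    def test_single_population_identity(self):
        from durmap.linkage import two_point_lod

        est = pool_pair("a", "b", [PopPairCounts("p1", 12, 80, "DH")])
        assert est.r == pytest.approx(12 / 80)
        assert est.lod == pytest.approx(float(two_point_lod(12, 80, 12 / 80)), abs=1e-9)

    def test_pooled_se_smaller_than_components(self):
        """Pooling 4 homogeneous populations shrinks the sampling SD."""
        rng = np.random.default_rng(17)
        r_true, n = 0.2, 100
        per_pop = [[] for _ in range(4)]
        pooled = []
        for _ in range(300):
            ks = rng.binomial(n, r_true, size=4)
            for i, k in enumerate(ks):
                per_pop[i].append(k / n)
            est = pool_pair(
                "a", "b",
                [PopPairCounts(f"p{i}", int(k), n, "DH") for i, k in enumerate(ks)],
            )
            pooled.append(est.r)
        assert np.std(pooled) < min(np.std(v) for v in per_pop)

    def test_three_fold_rate_difference_rejected(self):
        """A 3x recombination-rate difference trips the P < 0.001 screen."""
        rng = np.random.default_rng(23)
        rejections = 0
        n_rep = 50
        for _ in range(n_rep):
            k1 = int(rng.binomial(200, 0.1))
            k2 = int(rng.binomial(200, 0.3))
            _, _, p = heterogeneity_test(
                [PopPairCounts("p1", k1, 200, "DH"), PopPairCounts("p2", k2, 200, "DH")]
            )
            if p < 0.001:
                rejections += 1
        assert rejections >= 0.9 * n_rep


class TestFramework:
    def _populations(self, n_pops=2, n_lines=200, seed=31, n_markers=6):
        tm = simdata.TrueMap(
            (
                simdata.TrueGroup(
                    "LG1",
                    tuple(f"M{j + 1}" for j in range(n_markers)),
                    np.arange(n_markers) * 12.0,
                ),
            )
        )
        pops = {}
        for i in range(n_pops):
            cfg = simdata.SimConfig(pop_type="RIL", n_lines=n_lines, missing_rate=0.0,
                                    error_rate=0.0, seed=seed + i)
            pops[f"pop{i + 1}"] = simdata.simulate_population(tm, cfg)
        return tm, pops

    def test_framework_order_matches_truth(self):
        import itertools

        tm, pops = self._populations()
        pooled = pool_all_pairs(pops)
        cmap, report = build_framework(pooled)
        assert len(cmap.groups) == 1
        got = list(cmap.groups[0].markers)
        truth = list(tm.groups[0].markers)
        assert got in (truth, truth[::-1])
        # exhaustive oracle on the pooled criterion
        dist = {}
        from durmap.linkage import haldane_cM

        for row in pooled.itertuples(index=False):
            d = haldane_cM(min(row.r, 0.49999))
            dist[(row.marker_a, row.marker_b)] = d
            dist[(row.marker_b, row.marker_a)] = d
        cost = lambda o: sum(dist[(a, b)] for a, b in zip(o, o[1:]))
        best = min(cost(p) for p in itertools.permutations(truth))
        assert cost(got) == pytest.approx(best, abs=1e-9)
        assert set(report.columns) >= {"group", "n_markers", "length_cM", "mean_adj_lod"}

    def test_disconnected_anchors_split_group(self):
        # two marker clusters far apart on one chromosome -> 2 framework groups
        tm = simdata.TrueMap(
            (
                simdata.TrueGroup(
                    "LG1",
                    ("A1", "A2", "A3", "B1", "B2", "B3"),
                    np.array([0.0, 5.0, 10.0, 300.0, 305.0, 310.0]),
                ),
            )
        )
        pops = {}
        for i in range(2):
            cfg = simdata.SimConfig(pop_type="RIL", n_lines=150, missing_rate=0.0,
                                    error_rate=0.0, seed=40 + i)
            pops[f"pop{i + 1}"] = simdata.simulate_population(tm, cfg)
        cmap, _ = build_framework(pool_all_pairs(pops))
        assert len(cmap.groups) == 2

    def test_single_population_framework_is_component_map(self):
        from durmap.linkage import order_group

        tm, pops = self._populations(n_pops=1)
        (seg,) = pops.values()
        cmap, _ = build_framework(pool_all_pairs(pops))
        lg = order_group(seg, list(seg.markers))
        assert tuple(cmap.groups[0].markers) in (lg.markers, lg.markers[::-1])
        assert cmap.groups[0].length_cM == pytest.approx(lg.length_cM, abs=1e-9)

    def test_framework_length_close_to_truth(self):
        """4 homogeneous 200-line populations: length within 5% of the true map."""
        tm, pops = self._populations(n_pops=4, n_lines=200, seed=60, n_markers=8)
        cmap, _ = build_framework(pool_all_pairs(pops))
        truth = float(tm.groups[0].positions[-1])
        assert abs(cmap.groups[0].length_cM - truth) / truth < 0.05


class TestInterpolation:
    FRAME = ConsensusMap(
        (
            ConsensusGroup(
                "LG1", ("a1", "a2"), np.array([12.0, 26.0]),
                ("framework",) * 2, ((), ()),
            ),
        )
    )

    def _component(self, markers, positions):
        return LinkageGroup("c1", tuple(markers), np.asarray(positions, dtype=float))

    def test_linear_interpolation(self):
        comp = self._component(["x0", "a1", "u", "a2"], [0.0, 10.0, 15.0, 20.0])
        proj, unplaced = interpolate_unique(comp, self.FRAME)
        assert not unplaced
        pos = proj.set_index("marker")["cM"]
        assert pos["u"] == pytest.approx(19.0)

    def test_coincident_with_anchor(self):
        comp = self._component(["a1", "u", "a2"], [0.0, 0.0, 10.0])
        proj, _ = interpolate_unique(comp, self.FRAME)
        assert proj.set_index("marker").loc["u", "cM"] == pytest.approx(12.0)

    def test_extension_beyond_terminal_anchor(self):
        comp = self._component(["a1", "a2", "u"], [0.0, 10.0, 15.0])
        proj, _ = interpolate_unique(comp, self.FRAME)
        assert proj.set_index("marker").loc["u", "cM"] == pytest.approx(33.0)

    def test_fewer_than_two_anchors_unplaceable(self):
        frame = ConsensusMap(
            (ConsensusGroup("LG1", ("a1",), np.array([5.0]), ("framework",), ((),)),)
        )
        comp = self._component(["a1", "u"], [0.0, 4.0])
        proj, unplaced = interpolate_unique(comp, frame)
        assert proj.empty and unplaced == ["u"]

    def test_insertion_is_order_preserving_and_exact_at_anchors(self):
        comp = self._component(
            ["a1", "u1", "u2", "a2"], [0.0, 3.0, 7.0, 10.0]
        )
        proj, _ = interpolate_unique(comp, self.FRAME)
        cmap = add_interpolated(self.FRAME, proj)
        g = cmap.groups[0]
        order = list(g.markers)
        assert order.index("a1") < order.index("u1") < order.index("u2") < order.index("a2")
        # anchors keep their (shifted-to-zero) spacing
        assert g.position_of("a2") - g.position_of("a1") == pytest.approx(14.0)


class TestCollinearity:
    GROUP = ConsensusGroup(
        "LG1", tuple(f"m{i}" for i in range(10)), np.arange(10) * 5.0,
        ("framework",) * 10, ((),) * 10,
    )

    def test_identical_order(self):
        comp = LinkageGroup("c", self.GROUP.markers, np.arange(10) * 4.0)
        rho, r2, n = collinearity(comp, self.GROUP)
        assert rho == pytest.approx(1.0) and n == 10

    def test_uniform_stretch_affine_invariance(self):
        comp = LinkageGroup("c", self.GROUP.markers, np.arange(10) * 10.0)
        rho, r2, _ = collinearity(comp, self.GROUP)
        assert rho == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_reversed_orientation_resolved(self):
        comp = LinkageGroup("c", tuple(reversed(self.GROUP.markers)), np.arange(10) * 5.0)
        rho, r2, _ = collinearity(comp, self.GROUP)
        assert rho == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_adjacent_swap_matches_rank_oracle(self):
        from scipy import stats

        markers = list(self.GROUP.markers)
        markers[4], markers[5] = markers[5], markers[4]
        comp = LinkageGroup("c", tuple(markers), np.arange(10) * 5.0)
        rho, _, _ = collinearity(comp, self.GROUP)
        x = [markers.index(m) for m in self.GROUP.markers]
        expected = stats.spearmanr(x, range(10)).statistic
        assert rho == pytest.approx(expected)

    def test_too_few_shared_markers(self):
        comp = LinkageGroup("c", ("m0", "m1"), np.array([0.0, 5.0]))
        with pytest.raises(UndefinedEstimateError):
            collinearity(comp, self.GROUP)


class TestSummaries:
    def test_summary_totals_and_classes(self):
        cmap = ConsensusMap(
            (
                ConsensusGroup(
                    "LG1", ("a", "b", "c"), np.array([0.0, 5.0, 10.0]),
                    ("framework", "interpolated", "framework"), ((),) * 3,
                ),
                ConsensusGroup("LG2", ("d",), np.array([0.0]), ("framework",), ((),)),
            )
        )
        df = summarize_map(cmap)
        total = df[df["group"] == "TOTAL"].iloc[0]
        assert total["n_markers"] == 4
        assert total["n_interpolated"] == 1
        assert total["length_cM"] == pytest.approx(10.0)

    def test_cm_per_marker_division(self):
        assert cm_per_marker(1258.7, 311) == pytest.approx(4.05, abs=0.005)

    def test_length_excess(self):
        assert length_excess_pct(120.0, 100.0) == pytest.approx(20.0)
        with pytest.raises(ValidationError):
            length_excess_pct(1.0, 0.0)
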
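"""Marker coding, kinship, heritability and the Q+K mixed model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from durmap.consensus import ConsensusGroup, ConsensusMap
from durmap.errors import UndefinedEstimateError, ValidationError
from durmap.gwas import (
    adjusted_means,
    biallelify,
    broad_sense_h2,
    declare_qtl_regions,
    ibs_kinship,
    mlm_scan,
    multi_qtl_r2,
    significance_thresholds,
)
from durmap.ld import LDPair

from conftest import make_panel


class TestBiallelify:
    def test_ssr_alleles_one_column_each(self):
        calls = np.array([0] * 50 + [1] * 30 + [2] * 20).reshape(-1, 1)
        panel = make_panel(calls, ["SSR"])
        mat, prov = biallelify(panel, maf_min=0.10)
        assert mat.shape[1] == 3
        assert set(prov.values()) == {"x1"}
        assert mat["x1.0"].mean() == pytest.approx(0.5)

    def test_rare_allele_dropped(self):
        calls = np.array([0] * 95 + [1] * 5).reshape(-1, 1)
        panel = make_panel(calls, ["SSR"])
        with pytest.raises(UndefinedEstimateError):
            biallelify(panel, maf_min=0.10)

    def test_dominant_marker_single_column(self):
        calls = np.array([0, 1] * 40).reshape(-1, 1)
        panel = make_panel(calls, ["DArT"])
        mat, _ = biallelify(panel)
        assert list(mat.columns) == ["x1"]
        assert set(np.unique(mat["x1"])) == {0.0, 1.0}


class TestKinship:
    def test_identity_and_discordance(self):
        mat = pd.DataFrame([[0, 0, 1, 1]] * 2 + [[1, 1, 0, 0]],
                           index=["a", "b", "c"], dtype=float)
        K = ibs_kinship(mat)
        assert K.loc["a", "b"] == 1.0
        assert K.loc["a", "c"] == 0.0
        assert np.allclose(K, K.T)

    def test_half_matching_loci(self):
        x = np.zeros(100)
        y = np.r_[np.zeros(50), np.ones(50)]
        K = ibs_kinship(pd.DataFrame([x, y], index=["a", "b"]))
        assert K.loc["a", "b"] == pytest.approx(0.5)

    def test_disjoint_missingness_is_error(self):
        mat = pd.DataFrame(
            [[0.0, np.nan], [np.nan, 1.0]], index=["a", "b"], columns=["l1", "l2"]
        )
        with pytest.raises(UndefinedEstimateError):
            ibs_kinship(mat)


class TestPhenotypeStages:
    def _long(self, values, envs, areas=None, lats=None):
        rows = []
        for e, env in enumerate(envs):
            for acc, v in values[e].items():
                rows.append(
                    (acc, env, (areas or {}).get(env, "A1"),
                     (lats or {}).get(env, 40.0), v)
                )
        return pd.DataFrame(
            rows, columns=["accession", "environment", "macro_area", "latitude", "value"]
        )

    def test_environment_offsets_removed(self):
        genetic = {"a": 1.0, "b": 2.0, "c": 3.0}
        df = self._long(
            [{k: v + 5 for k, v in genetic.items()},
             {k: v - 5 for k, v in genetic.items()}],
            ["e1", "e2"],
        )
        means = adjusted_means(df)
        centered = {k: v - 2.0 for k, v in genetic.items()}  # grand-centered
        for acc, v in centered.items():
            assert means.loc[acc, "A1"] == pytest.approx(v)

    def test_empty_macro_area_error(self):
        df = self._long([{"a": 1.0}], ["e1"])
        df.loc[0, "macro_area"] = None
        with pytest.raises(ValidationError):
            adjusted_means(df)

    def test_h2_closed_form(self):
        # balanced one-way design built from exact components
        rng = np.random.default_rng(1)
        n_acc, n_env = 400, 4
        g = rng.normal(0, np.sqrt(2.0), n_acc)
        vals = []
        for e in range(n_env):
            noise = rng.normal(0, np.sqrt(2.0), n_acc)
            vals.append({f"a{i}": g[i] + noise[i] for i in range(n_acc)})
        df = self._long(vals, [f"e{e}" for e in range(n_env)])
        assert broad_sense_h2(df) == pytest.approx(0.8, abs=0.05)

    def test_h2_noise_free_is_one(self):
        vals = [{"a": 1.0, "b": 2.0, "c": 5.0}] * 3
        df = self._long(vals, ["e1", "e2", "e3"])
        assert broad_sense_h2(df) == pytest.approx(1.0)

    def test_h2_single_environment_undefined(self):
        df = self._long([{"a": 1.0, "b": 2.0}], ["e1"])
        with pytest.raises(UndefinedEstimateError):
            broad_sense_h2(df)

    def test_h2_recovery_over_replicates(self):
        rng = np.random.default_rng(2)
        n_acc, n_env, target = 200, 10, 0.85
        s2g = 2.0
        s2e = s2g * n_env * (1 - target) / target
        estimates = []
        for _ in range(30):
            g = rng.normal(0, np.sqrt(s2g), n_acc)
            vals = [
                {f"a{i}": g[i] + e for i, e in enumerate(rng.normal(0, np.sqrt(s2e), n_acc))}
                for _ in range(n_env)
            ]
            estimates.append(broad_sense_h2(self._long(vals, [f"e{j}" for j in range(n_env)])))
        assert np.mean(estimates) == pytest.approx(target, abs=0.05)


class TestMLM:
    def _ols_f_p(self, y, x):
        n = len(y)
        X0 = np.ones((n, 1))
        X1 = np.c_[X0, x]
        b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
        b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
        rss0 = np.sum((y - X0 @ b0) ** 2)
        rss1 = np.sum((y - X1 @ b1) ** 2)
        f = (rss0 - rss1) / (rss1 / (n - 2))
        return stats.f.sf(f, 1, n - 2)

    def test_identity_kinship_equals_ols(self):
        rng = np.random.default_rng(3)
        n, m = 60, 25
        X = rng.integers(0, 2, size=(n, m)).astype(float)
        y = rng.normal(size=n) + X[:, 0]
        idx = [f"a{i}" for i in range(n)]
        res = mlm_scan(
            pd.Series(y, index=idx),
            pd.DataFrame(X, index=idx, columns=[f"m{j}" for j in range(m)]),
            Q=None, K=None,
        ).set_index("marker")
        for j in range(m):
            expected = self._ols_f_p(y, X[:, j])
            assert res.loc[f"m{j}", "p"] == pytest.approx(expected, rel=1e-8)

    def test_causal_covariate_conditioning(self):
        rng = np.random.default_rng(4)
        n = 120
        idx = [f"a{i}" for i in range(n)]
        causal = rng.integers(0, 2, n).astype(float)
        linked = causal.copy()
        flip = rng.random(n) < 0.1
        linked[flip] = 1 - linked[flip]
        y = pd.Series(2.0 * causal + rng.normal(0, 1, n), index=idx)
        markers = pd.DataFrame({"causal": causal, "linked": linked}, index=idx)
        free = mlm_scan(y, markers).set_index("marker")
        cond = mlm_scan(y, markers, covariate_markers=["causal"]).set_index("marker")
        assert cond.loc["causal", "p"] == pytest.approx(1.0)  # self-conditioning
        assert cond.loc["causal", "note"] == "collinear-with-null"
        assert cond.loc["linked", "p"] > free.loc["linked", "p"]  # attenuated

    def test_structured_power_ranks_causal_first(self, clean_panel):
        _, panel = clean_panel
        markers, _ = biallelify(panel)
        K = ibs_kinship(markers)
        rng = np.random.default_rng(5)
        causal = markers.columns[3]
        x = markers[causal].fillna(markers[causal].mean())
        y = 2.5 * x + pd.Series(rng.normal(0, 1, len(x)), index=x.index)
        res = mlm_scan(y, markers, Q=panel.q_matrix, K=K).set_index("marker")
        assert res["p"].idxmin() == causal


class TestThresholdsAndRegions:
    def test_bonferroni_over_blocks(self):
        assert significance_thresholds(500).experiment_wise == pytest.approx(1e-4)
        assert significance_thresholds(1).experiment_wise == pytest.approx(0.05)
        assert significance_thresholds(50).experiment_wise == pytest.approx(1e-3)
        with pytest.raises(ValidationError):
            significance_thresholds(0)

    def _cmap(self):
        loci = ("m1", "m2", "m3", "m4")
        return ConsensusMap(
            (
                ConsensusGroup("LG1", loci, np.array([3.0, 5.0, 6.0, 50.0]),
                               ("framework",) * 4, ((),) * 4),
            )
        )

    def _results(self, pvals):
        return pd.DataFrame(
            {
                "scope": ["area1"] * len(pvals),
                "marker": list(pvals),
                "p": list(pvals.values()),
                "r2": [0.1] * len(pvals),
            }
        )

    def test_singleton_ci_is_4_4_cm(self):
        regions = declare_qtl_regions(
            self._results({"m4": 0.001}), self._cmap(), [], alpha_marker=0.01
        )
        (r,) = regions
        assert r.ci_cM == (pytest.approx(47.8), pytest.approx(52.2))
        assert r.ci_width == pytest.approx(4.4)

    def test_block_ci_pads_span(self):
        pairs = [
            LDPair("m1", "m2", True, 2.0, 0.8, 0.9, 100),
            LDPair("m2", "m3", True, 1.0, 0.6, 0.9, 100),
        ]
        regions = declare_qtl_regions(
            self._results({"m1": 1e-4, "m2": 5e-3, "m3": 2e-3}),
            self._cmap(), pairs, alpha_marker=0.01,
        )
        (r,) = regions
        assert r.members == ("m1", "m2", "m3")
        assert r.interval_cM == (pytest.approx(3.0), pytest.approx(6.0))
        assert r.ci_cM == (pytest.approx(0.8), pytest.approx(8.2))
        assert r.representative == "m1"

    def test_low_ld_neighbours_split(self):
        pairs = [LDPair("m1", "m2", True, 2.0, 0.1, 0.2, 100)]
        regions = declare_qtl_regions(
            self._results({"m1": 1e-4, "m2": 5e-3}), self._cmap(), pairs
        )
        assert len(regions) == 2

    def test_no_significant_markers(self):
        assert declare_qtl_regions(self._results({"m1": 0.5}), self._cmap(), []) == []

    def test_region_count_monotone_in_alpha(self):
        res = self._results({"m1": 1e-4, "m2": 5e-3, "m4": 9e-3})
        counts = [
            len(declare_qtl_regions(res, self._cmap(), [], alpha_marker=a))
            for a in (1e-5, 1e-3, 1e-2)
        ]
        assert counts == sorted(counts)

    def test_ci_always_contains_interval(self):
        res = self._results({"m1": 1e-4, "m3": 5e-3, "m4": 2e-3})
        for r in declare_qtl_regions(res, self._cmap(), []):
            assert r.ci_cM[0] <= r.interval_cM[0] <= r.interval_cM[1] <= r.ci_cM[1]


class TestJointR2:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(6)
        idx = [f"a{i}" for i in range(50)]
        X = pd.DataFrame(rng.integers(0, 2, (50, 3)).astype(float), index=idx)
        y = pd.Series(X @ np.array([1.0, -2.0, 0.5]), index=idx)
        assert multi_qtl_r2(y, X) == pytest.approx(1.0)

    def test_unrelated_markers_near_zero(self):
        rng = np.random.default_rng(7)
        idx = [f"a{i}" for i in range(500)]
        X = pd.DataFrame(rng.integers(0, 2, (500, 3)).astype(float), index=idx)
        y = pd.Series(rng.normal(size=500), index=idx)
        assert multi_qtl_r2(y, X) < 0.05

    def test_collinear_columns_tolerated(self):
        rng = np.random.default_rng(8)
        idx = [f"a{i}" for i in range(40)]
        x = rng.integers(0, 2, 40).astype(float)
        X = pd.DataFrame({"a": x, "b": x, "c": 1 - x}, index=idx)
        y = pd.Series(3 * x + rng.normal(0, 0.1, 40), index=idx)
        assert 0.9 < multi_qtl_r2(y, X) <= 1.0
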
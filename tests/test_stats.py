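"""GLM, cluster correction plumbing, and cohort-level statistics."""

import numpy as np
import pandas as pd
import pytest

from ficd import stats as st
from ficd.mapping import FiCDMap


def _maps_from_matrix(y):
    return [FiCDMap(cu_values=np.zeros(1), vertex_values=row) for row in y]


class TestVertexwiseGLM:
    def test_identical_groups_give_zero_t(self):
        y = np.tile(np.linspace(1, 2, 10), (8, 1))
        x = np.column_stack([np.ones(8), [0, 0, 0, 0, 1, 1, 1, 1]])
        t, p, df = st.vertexwise_glm(_maps_from_matrix(y),
                                     st.GLMDesign(x, [0, 1]))
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_single_vertex_matches_statsmodels_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        n = 24
        group = np.repeat([0.0, 1.0], n // 2)
        age = rng.normal(64, 7, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = 1.0 + 0.4 * group + 0.01 * age + rng.normal(0, 0.3, n)
        x = np.column_stack([np.ones(n), group, age, sex])
        t, p, df = st.vertexwise_glm(_maps_from_matrix(y[:, None]),
                                     st.GLMDesign(x, [0, 1, 0, 0]))
        fit = sm.OLS(y, x).fit()
        ref = fit.t_test(np.array([0.0, 1, 0, 0]))
        assert t[0] == pytest.approx(float(np.squeeze(ref.tvalue)),
                                     abs=1e-8)
        assert p[0] == pytest.approx(float(np.squeeze(ref.pvalue)),
                                     abs=1e-8)
        assert df == int(fit.df_resid)

    def test_constant_shift_absorbed_by_intercept(self):
        rng = np.random.default_rng(1)
        y = rng.random((12, 6))
        x = np.column_stack([np.ones(12), np.repeat([0.0, 1.0], 6)])
        d = st.GLMDesign(x, [0, 1])
        t1, _, _ = st.vertexwise_glm(_maps_from_matrix(y), d)
        t2, _, _ = st.vertexwise_glm(_maps_from_matrix(y + 7.3), d)
        np.testing.assert_allclose(t1, t2, atol=1e-9)

    def test_rank_deficient_design_names_columns(self):
        x = np.column_stack([np.ones(8), np.arange(8.0),
                             2.0 * np.arange(8.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            st.GLMDesign(x, [0, 1, 0], ("intercept", "a", "a_twice"))


class TestClusterCorrection:
    def test_threshold_one_makes_whole_mesh_one_cluster(self, sphere642):
        rng = np.random.default_rng(2)
        t_map = rng.normal(size=sphere642.n_vertices)
        res = st.monte_carlo_cluster_correction(
            t_map, df=38, mesh=sphere642, cluster_p=1.0, n_iter=100,
            fwhm_mm=10.0, seed=0)
        assert len(res) == 1
        assert len(res[0].member_vertices) == sphere642.n_vertices
        assert res[0].size_mm2 == pytest.approx(sphere642.area(), rel=1e-6)

    def test_no_suprathreshold_vertices_gives_no_clusters(self, sphere642):
        res = st.monte_carlo_cluster_correction(
            np.zeros(sphere642.n_vertices), df=38, mesh=sphere642,
            cluster_p=0.01, n_iter=100, fwhm_mm=10.0, seed=0)
        assert res == []

    def test_nonpositive_fwhm_rejected(self, sphere642):
        with pytest.raises(ValueError, match="fwhm"):
            st.monte_carlo_cluster_correction(
                np.zeros(sphere642.n_vertices), df=38, mesh=sphere642,
                cluster_p=0.01, n_iter=100, fwhm_mm=0.0, seed=0)

    def test_members_are_contiguous(self, sphere642):
        # two antipodal hot caps must come out as separate clusters
        z = sphere642.vertices[:, 2]
        t_map = np.zeros(sphere642.n_vertices)
        t_map[z > 45] = 8.0
        t_map[z < -45] = 8.0
        res = st.monte_carlo_cluster_correction(
            t_map, df=38, mesh=sphere642, cluster_p=0.01, n_iter=100,
            fwhm_mm=10.0, seed=0)
        assert len(res) == 2
        adj = sphere642.adjacency()
        for c in res:
            sub = adj[c.member_vertices][:, c.member_vertices]
            from scipy.sparse.csgraph import connected_components
            assert connected_components(sub, directed=False)[0] == 1


class TestReductionRatio:
    def test_equal_means_give_zero(self):
        assert st.reduction_ratio(1.3, 1.3) == 0.0

    def test_percent_scale_inverse_examples(self):
        assert st.reduction_ratio(1.0, 0.9209) == pytest.approx(7.91)
        assert st.reduction_ratio(1.0, 0.9694) == pytest.approx(3.06)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            st.reduction_ratio(0.0, 1.0)


class TestRegionalFicd:
    def test_constant_roi(self):
        m = FiCDMap(cu_values=np.full(10, 0.7))
        assert st.regional_ficd(m, {1, 5, 7}) == pytest.approx(0.7)

    def test_two_cu_mean(self):
        m = FiCDMap(cu_values=np.array([0.4, 0.8, 5.0]))
        assert st.regional_ficd(m, {0, 1}) == pytest.approx(0.6)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        vals = rng.random(50)
        roi = set(rng.choice(50, 17, replace=False).tolist())
        m = FiCDMap(cu_values=vals)
        assert st.regional_ficd(m, roi) == pytest.approx(
            sum(vals[i] for i in roi) / len(roi), abs=1e-12)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            st.regional_ficd(FiCDMap(cu_values=np.ones(5)), set())


class TestZscoreScores:
    def _table(self):
        rng = np.random.default_rng(4)
        return pd.DataFrame({"mmse": rng.normal(27, 2, 40),
                             "tmt_a": rng.normal(70, 25, 40)})

    def test_pooled_mean_zero_sd_one(self):
        out = st.zscore_scores(self._table(), ["mmse", "tmt_a"])
        for c in ("mmse", "tmt_a"):
            assert out[c].mean() == pytest.approx(0.0, abs=1e-10)
            assert out[c].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self):
        t = self._table()
        t2 = t.copy()
        t2["mmse"] = 3.0 * t2["mmse"] - 11.0
        a = st.zscore_scores(t, ["mmse"])
        b = st.zscore_scores(t2, ["mmse"])
        np.testing.assert_allclose(a["mmse"], b["mmse"], atol=1e-10)

    def test_constant_column_named_in_error(self):
        t = self._table()
        t["cdt"] = 4.0
        with pytest.raises(ValueError, match="cdt"):
            st.zscore_scores(t, ["cdt"])


class TestPartialPearson:
    def test_identity_without_covariate_effect(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        cov = rng.normal(size=(50, 2))
        r, p = st.partial_pearson(x, x.copy(), cov)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_conditional_independence_gives_small_r(self):
        rng = np.random.default_rng(6)
        n = 5000
        z = rng.normal(size=n)
        x = 2.0 * z + rng.normal(size=n)
        y = -1.5 * z + rng.normal(size=n)
        r, p = st.partial_pearson(x, y, z[:, None])
        assert abs(r) < 0.05

    def test_matches_precision_matrix_oracle_and_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(7)
        n = 60
        cov = rng.normal(size=(n, 3))
        x = cov @ [0.5, -0.2, 0.1] + rng.normal(size=n)
        y = cov @ [-0.3, 0.4, 0.2] + 0.6 * x + rng.normal(size=n)
        r, p = st.partial_pearson(x, y, cov)
        # oracle 1: partial correlation from the precision matrix
        m = np.corrcoef(np.column_stack([x, y, cov]).T)
        prec = np.linalg.inv(m)
        r_oracle = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert r == pytest.approx(r_oracle, abs=1e-8)
        # oracle 2: pingouin
        df = pd.DataFrame(np.column_stack([x, y, cov]),
                          columns=["x", "y", "c1", "c2", "c3"])
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2", "c3"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match="need n"):
            st.partial_pearson([1, 2, 3], [1, 2, 3],
                               np.ones((3, 2)))


class TestGlobalRegressions:
    def _table(self, n=60, seed=8):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "lacune_volume_ml": rng.gamma(1.2, 0.4, n),
            "wmh_volume_ml": rng.lognormal(1.0, 0.8, n),
            "relative_brain_volume": rng.normal(0.79, 0.02, n),
            "age": rng.normal(64, 7, n),
            "sex": rng.integers(0, 2, n).astype(float)})

    def test_collinear_predictor_gives_unit_r(self):
        t = self._table()
        g = 0.2 - 0.01 * t["lacune_volume_ml"].to_numpy()
        out = st.global_regressions(t, g)
        row = out[out.predictor == "lacune_volume_ml"].iloc[0]
        assert row.r == pytest.approx(-1.0, abs=1e-10)

    def test_r_matches_closed_form_correlation(self):
        t = self._table()
        rng = np.random.default_rng(9)
        g = 0.2 - 0.003 * t["age"].to_numpy() + rng.normal(0, 0.01, len(t))
        out = st.global_regressions(t, g)
        row = out[out.predictor == "age"].iloc[0]
        x = t["age"].to_numpy()
        r_oracle = (np.mean(x * g) - x.mean() * g.mean()) \
            / (x.std() * g.std())
        assert row.r == pytest.approx(r_oracle, abs=1e-10)

    def test_wmh_is_log_transformed(self):
        t = self._table()
        g = -np.log(t["wmh_volume_ml"].to_numpy())
        out = st.global_regressions(t, g)
        row = out[out.predictor == "log_wmh_volume"].iloc[0]
        assert row.r == pytest.approx(-1.0, abs=1e-10)

    def test_missing_column_rejected(self):
        t = self._table().drop(columns=["age"])
        with pytest.raises(ValueError, match="age"):
            st.global_regressions(t, np.zeros(len(t)))


class TestGroupAnova:
    def test_identical_groups_give_f_near_zero(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 3)
        groups = np.repeat(["a", "b", "c"], 4)
        out = st.group_anova(vals, groups)
        assert out["F"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] > 0.99

    def test_matches_brute_force_f_statistic(self):
        rng = np.random.default_rng(10)
        vals = np.concatenate([rng.normal(0, 1, 12),
                               rng.normal(0.5, 1, 15),
                               rng.normal(1.0, 1, 9)])
        groups = np.repeat(["a", "b", "c"], [12, 15, 9])
        out = st.group_anova(vals, groups)
        # brute-force between/within decomposition
        gm = vals.mean()
        ssb = sum(len(vals[groups == g]) * (vals[groups == g].mean() - gm)
                  ** 2 for g in "abc")
        ssw = sum(((vals[groups == g] - vals[groups == g].mean()) ** 2
                   ).sum() for g in "abc")
        f_oracle = (ssb / 2) / (ssw / (len(vals) - 3))
        assert out["F"] == pytest.approx(f_oracle, abs=1e-8)

    def test_bonferroni_is_m_times_raw(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        out = st.group_anova(vals, groups)
        for pw in out["pairwise"]:
            assert pw["p_bonferroni"] == pytest.approx(
                min(1.0, 3 * pw["p_raw"]), abs=1e-12)
            # Tamhane T2 (Sidak-adjusted Welch) is never below raw Welch
            assert pw["p_tamhane_t2"] >= pw["p_raw"] - 1e-12

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            st.group_anova([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestResidualFwhm:
    def test_recovers_applied_kernel_on_vertex_noise(self, sphere2562):
        from ficd.mapping import smooth_columns
        rng = np.random.default_rng(12)
        noise = rng.standard_normal((sphere2562.n_vertices, 60))
        sm = smooth_columns(sphere2562, noise, 12.0)
        resid = (sm - sm.mean(axis=1, keepdims=True)).T
        got = st.estimate_residual_fwhm(resid, sphere2562)
        assert got == pytest.approx(12.0, rel=0.15)
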
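import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from wetareas import inference as inf


class TestAicc:
    def test_arithmetic_example(self):
        assert inf.aicc(-47, 3, 20) == pytest.approx(101.5)

    def test_converges_to_aic_for_large_n(self):
        aic = -2 * (-100.0) + 2 * 1
        assert abs(inf.aicc(-100.0, 1, 10 ** 7) - aic) < 1e-6

    def test_zero_parameters_edge(self):
        assert inf.aicc(-10.0, 0, 5) == pytest.approx(20.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            inf.aicc(-10.0, 4, 5)


class TestFitDtwModel:
    def test_exact_linear_relationship_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 4, 30)
        g = np.repeat([0, 1, 2], 10)
        f = inf.fit_dtw_model(1.0 + 0.5 * x, x, g)
        assert f.intercept == pytest.approx(1.0, abs=1e-8)
        assert f.dtw_coef == pytest.approx(0.5, abs=1e-8)

    def test_sqrt_transform_linearizes_squared_response(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 4, 30)
        g = np.repeat([0, 1, 2], 10)
        f = inf.fit_dtw_model((2.0 - 0.3 * x) ** 2, x, g, transform="sqrt")
        assert abs(abs(f.dtw_coef) - 0.3) < 1e-6

    def test_log_fit_excludes_nonpositive_with_count(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 4, 40)
        g = np.repeat([0, 1], 20)
        y = np.exp(0.2 * x + rng.normal(0, 0.1, 40))
        y[:5] = 0.0
        f = inf.fit_dtw_model(y, x, g, transform="log")
        assert f.n_excluded == 5
        assert f.n == 35

    def test_r2_ordering_and_bounds(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 4, 60)
        g = np.repeat(np.arange(6), 10)
        y = 1 + 0.4 * x + rng.normal(0, 0.5, 6)[g] + rng.normal(0, 1, 60)
        f = inf.fit_dtw_model(y, x, g)
        assert 0 <= f.marginal_r2 <= f.conditional_r2 <= 1

    def test_constant_dtw_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            inf.fit_dtw_model(np.arange(10.0), np.ones(10),
                              np.repeat([0, 1], 5))

    def test_single_compartment_rejected(self):
        with pytest.raises(ValueError, match="compartments"):
            inf.fit_dtw_model(np.arange(10.0), np.arange(10.0),
                              np.zeros(10))

    def test_poisson_glmm_matches_reference_fit(self):
        # frozen reference: lme4::glmer(y ~ x + (1|g), family=poisson,
        # nAGQ=25) on this exact dataset
        rng = np.random.default_rng(42)
        n = 111
        g = np.repeat(np.arange(9), [12, 12, 13, 12, 12, 13, 12, 12, 13])
        x = rng.uniform(0, 4, n)
        b = rng.normal(0, 0.3, 9)
        y = rng.poisson(np.exp(2.17 + 0.07 * x + b[g]))
        f = inf.fit_dtw_model(y, x, g, family="poisson-log")
        assert f.intercept == pytest.approx(1.9444631, abs=2e-5)
        assert f.dtw_coef == pytest.approx(0.1052519, abs=2e-5)
        assert f.dtw_se == pytest.approx(0.03051303, abs=2e-4)
        assert np.sqrt(f.var_compartment) == pytest.approx(0.1590469,
                                                           abs=2e-4)

    def test_gaussian_fit_matches_lme4_reference(self):
        # frozen reference: lme4::lmer(y ~ x + (1|g)) REML on this dataset
        rng = np.random.default_rng(7)
        n = 111
        g = np.repeat(np.arange(9), [12, 12, 13, 12, 12, 13, 12, 12, 13])
        x = rng.normal(2, 1, n)
        y = 1 + 0.5 * x + rng.normal(0, .5, 9)[g] + rng.normal(0, 1, n)
        f = inf.fit_dtw_model(y, x, g)
        assert f.intercept == pytest.approx(0.7156056, abs=1e-4)
        assert f.dtw_coef == pytest.approx(0.5361545, abs=1e-4)
        assert f.dtw_se == pytest.approx(0.09887069, abs=1e-3)
        assert f.var_compartment == pytest.approx(0.06224242, abs=1e-3)
        assert f.var_residual == pytest.approx(0.77933138, abs=1e-3)
        assert f.loglik == pytest.approx(-145.7129, abs=1e-3)

    def test_slope_bias_shrinks_with_plots_per_compartment(self):
        rng = np.random.default_rng(10)
        for n_per in (5, 10, 20):
            est = []
            for _ in range(30):
                g = np.repeat(np.arange(6), n_per)
                x = rng.uniform(0, 4, 6 * n_per)
                y = (1 + 0.5 * x + rng.normal(0, 0.4, 6)[g]
                     + rng.normal(0, 1, 6 * n_per))
                est.append(inf.fit_dtw_model(y, x, g).dtw_coef)
            est = np.asarray(est)
            mcse = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - 0.5) < 3 * mcse


class TestSelectThreshold:
    def _fit(self, a, n=50):
        return inf.ModelFit("y", "none", "gaussian", 0, 0, 1, 0, 1, 0, 1,
                            0, 4, n, a, 0.1, 0.2)

    def test_delta_and_supported_set(self):
        fits = {0.5: self._fit(100.0), 1.0: self._fit(99.0),
                2.0: self._fit(104.0)}
        sel = inf.select_threshold(fits)
        np.testing.assert_allclose(sel.table["delta"], [1.0, 0.0, 5.0])
        assert sel.supported == [0.5, 1.0]
        assert sel.best_lambda == 1.0
        assert sel.table["support"].tolist() == [
            "substantial", "substantial", "considerably less"]

    def test_ties_all_supported_in_lambda_order(self):
        fits = {l: self._fit(88.0) for l in (0.5, 4.0, 16.0)}
        sel = inf.select_threshold(fits)
        assert sel.supported == [0.5, 4.0, 16.0]
        assert sel.best_lambda == 0.5

    def test_differing_n_rejected(self):
        fits = {0.5: self._fit(100.0, n=50), 1.0: self._fit(99.0, n=40)}
        with pytest.raises(ValueError, match="differ in n"):
            inf.select_threshold(fits)


class TestCompareForestTypes:
    def test_identical_groups_share_a_letter(self):
        df = pd.DataFrame({
            "forest_type": np.repeat(["a", "b", "c"], 10),
            "total_cover": np.tile(np.arange(10.0), 3),
        })
        res = inf.compare_forest_types(df, responses=["total_cover"])
        assert res.anova.loc[0, "F"] == pytest.approx(0.0, abs=1e-12)
        letters = res.letters.iloc[0]
        assert letters["a"] == letters["b"] == letters["c"]

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(1.5, 1, 12)
        df = pd.DataFrame({"forest_type": ["a"] * 12 + ["b"] * 12,
                           "total_cover": np.r_[a, b]})
        res = inf.compare_forest_types(df, responses=["total_cover"])
        from scipy.stats import ttest_ind
        t, _ = ttest_ind(a, b)
        assert res.anova.loc[0, "F"] == pytest.approx(t ** 2)

    def test_f_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(5)
        groups = np.repeat(["a", "b", "c"], [8, 10, 12])
        y = rng.normal(0, 1, 30) + np.repeat([0.0, 0.5, 2.0], [8, 10, 12])
        df = pd.DataFrame({"forest_type": groups, "total_cover": y})
        res = inf.compare_forest_types(df, responses=["total_cover"])
        grand = y.mean()
        ss_b = sum(len(y[groups == g]) * (y[groups == g].mean() - grand) ** 2
                   for g in "abc")
        ss_w = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum()
                   for g in "abc")
        F = (ss_b / 2) / (ss_w / 27)
        assert res.anova.loc[0, "F"] == pytest.approx(F)

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "forest_type": np.repeat(["a", "b"], 15),
            "total_cover": np.r_[rng.normal(0, 0.3, 15),
                                 rng.normal(10, 0.3, 15)],
        })
        res = inf.compare_forest_types(df, responses=["total_cover"])
        letters = res.letters.iloc[0]
        assert letters["a"] != letters["b"]


class TestBrayCurtis:
    def test_identical_plots_distance_zero(self):
        df = pd.DataFrame({"s0": [3.0, 3.0], "s1": [1.0, 1.0]})
        D, _ = inf.bray_curtis(df, ["s0", "s1"])
        assert D.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_plots_distance_one(self):
        df = pd.DataFrame({"s0": [3.0, 0.0], "s1": [0.0, 5.0]})
        D, _ = inf.bray_curtis(df, ["s0", "s1"])
        assert D.iloc[0, 1] == pytest.approx(1.0)

    def test_arithmetic_example(self):
        df = pd.DataFrame({"s0": [3.0, 1.0], "s1": [1.0, 3.0]})
        D, _ = inf.bray_curtis(df, ["s0", "s1"])
        assert D.iloc[0, 1] == pytest.approx(0.5)

    def test_zero_cover_plots_excluded(self):
        df = pd.DataFrame({"plot_id": ["a", "b", "c"],
                           "s0": [3.0, 0.0, 1.0], "s1": [1.0, 0.0, 3.0]})
        D, excluded = inf.bray_curtis(df, ["s0", "s1"])
        assert excluded == ["b"]
        assert list(D.index) == ["a", "c"]


def permanova_oracle_exhaustive(D, x):
    """Independent brute force: explicit projection matrices per permutation."""
    n = len(x)
    A = -0.5 * D ** 2
    J = np.eye(n) - 1.0 / n
    G = J @ A @ J

    def f(xv):
        xc = (xv - xv.mean())[:, None]
        H = xc @ xc.T / (xc.T @ xc).item()
        num = np.trace(H @ G @ H)
        den = np.trace((np.eye(n) - H) @ G @ (np.eye(n) - H)) / (n - 2)
        return num / den

    f_obs = f(x)
    fs = [f(x[list(p)]) for p in itertools.permutations(range(n))]
    return f_obs, np.mean(np.asarray(fs) >= f_obs - 1e-12)


class TestPermanova:
    def _toy(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        comp = rng.lognormal(0, 1, (n, 4))
        D = squareform(pdist(comp, "braycurtis"))
        x = rng.uniform(0, 4, n)
        return D, x

    def test_exhaustive_matches_independent_oracle(self):
        D, x = self._toy()
        res = inf.permanova(D, x, exhaustive=True)
        f_obs, p = permanova_oracle_exhaustive(D, x)
        assert res.pseudo_F == pytest.approx(f_obs, rel=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_perfect_gradient_gives_high_r2_and_floor_p(self):
        x = np.linspace(0, 10, 12)
        D = np.abs(x[:, None] - x[None, :]) / 10.0
        res = inf.permanova(D, x, n_perm=199, seed=0)
        assert res.r2 > 0.95
        assert res.p_value == pytest.approx(1 / 200)

    def test_r2_bounds_and_p_range(self):
        for seed in range(5):
            D, x = self._toy(n=10, seed=seed)
            res = inf.permanova(D, x, n_perm=99, seed=seed)
            assert 0 <= res.r2 <= 1
            assert 0 < res.p_value <= 1

    def test_constant_covariate_rejected(self):
        D, _ = self._toy()
        with pytest.raises(ValueError, match="constant"):
            inf.permanova(D, np.ones(6), n_perm=9, seed=0)

    def test_matches_vegan_adonis2(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(12)
        comp = rng.lognormal(0, 1, (15, 6))
        x = rng.uniform(0, 4, 15)
        D = squareform(pdist(comp, "braycurtis"))
        res = inf.permanova(D, x, n_perm=199, seed=0)
        np.savetxt(tmp_path / "comp.csv", comp, delimiter=",")
        np.savetxt(tmp_path / "x.csv", x, delimiter=",")
        script = (
            f'comp <- as.matrix(read.csv("{tmp_path}/comp.csv", header=FALSE));'
            f'x <- scan("{tmp_path}/x.csv");'
            'suppressMessages(library(vegan));'
            'a <- adonis2(comp ~ x, method="bray", permutations=99);'
            'cat(a$F[1], a$R2[1], "\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        f_ref, r2_ref = map(float, out.stdout.split())
        assert res.pseudo_F == pytest.approx(f_ref, rel=1e-6)
        assert res.r2 == pytest.approx(r2_ref, rel=1e-6)


class TestNmds:
    def test_three_equidistant_points_embed_exactly(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = inf.nmds(D, k=2, n_restarts=4, seed=0)
        assert res.stress < 1e-3

    def test_euclidean_configuration_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        D = squareform(pdist(pts))
        res = inf.nmds(D, k=2, n_restarts=8, seed=0)
        assert res.stress < 1e-3

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(2)
        comp = rng.lognormal(0, 1, (20, 8))
        D = squareform(pdist(comp, "braycurtis"))
        multi = inf.nmds(D, k=2, n_restarts=10, seed=3)
        single = inf.nmds(D, k=2, n_restarts=1, seed=3)
        assert multi.stress <= single.stress + 1e-12

    def test_coordinates_centered_and_principal_rotated(self):
        rng = np.random.default_rng(4)
        comp = rng.lognormal(0, 1, (15, 6))
        D = squareform(pdist(comp, "braycurtis"))
        res = inf.nmds(D, k=2, n_restarts=4, seed=0)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0,
                                   atol=1e-9)
        cov = res.coordinates.T @ res.coordinates
        assert abs(cov[0, 1]) < 1e-8
        assert cov[0, 0] >= cov[1, 1]

    def test_k_not_smaller_than_n_rejected(self):
        D = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError, match="smaller"):
            inf.nmds(D, k=3, n_restarts=2, seed=0)
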
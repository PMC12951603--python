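"""Scaled PCA, sequential MANOVA (Pillai), morphospace permutation tests
and Spearman shrinkage correlations."""

import numpy as np
import pytest
from scipy import stats

from jawstrength import (
    DegenerateInputError,
    manova_pillai,
    pairwise_method_distance,
    scaled_pca,
    spearman,
)
from jawstrength.rrpp import design_blocks, rrpp_anova


def _random_measurements(rng, n=40, v=5):
    base = rng.normal(size=(n, v))
    return 10 + np.cumsum(np.abs(base), axis=1)


class TestScaledPCA:
    def test_constant_variable_is_degenerate(self, rng):
        X = _random_measurements(rng)
        X[:, 2] = 4.2
        with pytest.raises(DegenerateInputError):
            scaled_pca(X)

    def test_variance_fractions_match_dense_eigensolve_oracle(self, rng):
        # two perfectly correlated variables + three independent
        z = rng.normal(size=40)
        X = np.column_stack(
            [z, 2 * z + 1, rng.normal(size=40), rng.normal(size=40),
             rng.normal(size=40)]
        )
        res = scaled_pca(X)
        # oracle: eigendecomposition of the 5x5 correlation matrix
        evals = np.sort(np.linalg.eigvalsh(np.corrcoef(X.T)))[::-1]
        np.testing.assert_allclose(
            res.variance_fraction, evals / evals.sum(), atol=1e-10
        )
        assert res.variance_fraction[0] >= res.variance_fraction[-1]

    def test_reconstruction_and_orthonormal_loadings(self, rng):
        X = _random_measurements(rng)
        res = scaled_pca(X)
        np.testing.assert_allclose(res.reconstruct(), X, atol=1e-8)
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(5), atol=1e-8
        )
        assert abs(res.variance_fraction.sum() - 1.0) < 1e-10

    def test_sign_convention_first_variable_nonnegative(self, rng):
        X = _random_measurements(rng)
        res = scaled_pca(X)
        assert np.all(res.loadings[0] >= -1e-12)


class TestManovaPillai:
    def _design(self, rng, n=60):
        method = rng.choice(["fieldwork", "alcohol"], size=n)
        loc = rng.choice(list("ABCD"), size=n)
        # ensure all cells present
        method[:8] = np.repeat(["fieldwork", "alcohol"], 4)
        loc[:8] = list("ABCD") * 2
        return method, loc

    def test_single_response_pillai_equals_sequential_r2_step(self, rng):
        n = 60
        method, loc = self._design(rng, n)
        y = rng.normal(size=n) + (method == "alcohol") * 1.5
        table = manova_pillai(y[:, None], method, loc, scale=False)
        # oracle: sequential univariate ANOVA R^2 of each step, computed from
        # incremental residual sums of squares of nested OLS fits
        blocks = design_blocks(
            factors={"Method": method, "Location": loc},
            interactions=[("Method", "Location")],
            order=["Method", "Location", "Method:Location"],
        )
        yc = y - y.mean()
        prev_rss = float(yc @ yc)
        X = np.ones((n, 1))
        total = prev_rss
        for name, B in blocks:
            X = np.hstack([X, B])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            # for one response Pillai of the sequential step is SS_step/(SS_step+SS_resid_full)
            ss_step = prev_rss - rss
            prev_rss = rss
            # full-model residual SS:
        rss_full = prev_rss
        # recompute per-term Pillai expectations
        X = np.ones((n, 1))
        prev_rss = total
        for name, B in blocks:
            X = np.hstack([X, B])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            ss_step = prev_rss - rss
            prev_rss = rss
            expected = ss_step / (ss_step + rss_full)
            assert table.loc[name, "Pillai"] == pytest.approx(expected, abs=1e-10)

    def test_invariance_under_nonsingular_linear_map(self, rng):
        n, p = 80, 5
        method, loc = self._design(rng, n)
        Y = rng.normal(size=(n, p))
        Y[method == "alcohol"] += [1, 0, 0.5, 0, 0]
        A = rng.normal(size=(p, p)) + 3 * np.eye(p)
        t1 = manova_pillai(Y, method, loc, scale=False)
        t2 = manova_pillai(Y @ A, method, loc, scale=False)
        terms = ["Method", "Location", "Method:Location"]
        np.testing.assert_allclose(
            t1.loc[terms, "Pillai"], t2.loc[terms, "Pillai"], atol=1e-8
        )

    def test_s_equals_one_f_identity(self, rng):
        # for a 1-df term, F = (V/(1-V)) * den_df/num_df exactly
        n = 60
        method, loc = self._design(rng, n)
        Y = rng.normal(size=(n, 5))
        t = manova_pillai(Y, method, loc)
        V = t.loc["Method", "Pillai"]
        F = t.loc["Method", "approx_F"]
        assert F == pytest.approx(
            V / (1 - V) * t.loc["Method", "den_df"] / t.loc["Method", "num_df"],
            rel=1e-10,
        )

    def test_sequential_pillai_matches_r_manova(self, rng, tmp_path):
        # independent oracle: R's stats::manova (sequential type-I) on the
        # same two-factor-with-interaction model
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        n = 60
        method, loc = self._design(rng, n)
        Y = rng.normal(size=(n, 4))
        Y[method == "alcohol", 0] += 1.2
        import pandas as pd

        df = pd.DataFrame(Y, columns=["y1", "y2", "y3", "y4"])
        df["method"] = method
        df["loc"] = loc
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "m.R"
        script.write_text(
            f"d <- read.csv('{csv}')\n"
            "d$method <- factor(d$method, levels=sort(unique(d$method)))\n"
            "d$loc <- factor(d$loc)\n"
            "fit <- manova(cbind(y1,y2,y3,y4) ~ method + loc + method:loc, data=d)\n"
            "s <- summary(fit, test='Pillai')$stats\n"
            "cat(sprintf('%.12f %.12f %.12f\\n', s[1,2], s[2,2], s[3,2]))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        r_pillai = [float(t) for t in out.stdout.split()]
        ours = manova_pillai(Y, method, loc, scale=False)
        terms = ["Method", "Location", "Method:Location"]
        np.testing.assert_allclose(
            ours.loc[terms, "Pillai"].to_numpy(), r_pillai, atol=1e-8
        )


class TestPairwiseMethodDistance:
    def test_identical_groups_distance_zero_p_high(self, rng):
        S = rng.normal(size=(10, 5))
        scores = np.vstack([S, S])
        method = np.array(["fieldwork"] * 10 + ["alcohol"] * 10)
        pop = np.array(["A"] * 20)
        d, p = pairwise_method_distance(scores, method, pop, "A", 999, rng)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_large_offset_hits_p_floor(self, rng):
        S = rng.normal(size=(20, 5)) * 0.01
        S[10:] += 50.0
        method = np.array(["fieldwork"] * 10 + ["alcohol"] * 10)
        pop = np.array(["A"] * 20)
        d, p = pairwise_method_distance(S, method, pop, "A", 999, rng)
        assert p == pytest.approx(1 / 1000)

    def test_small_group_skipped_with_warning(self, rng, caplog):
        S = rng.normal(size=(11, 3))
        method = np.array(["fieldwork"] * 10 + ["alcohol"])
        pop = np.array(["A"] * 11)
        assert pairwise_method_distance(S, method, pop, "A", 99, rng) is None


class TestSpearman:
    def test_monotone_metric_gives_rho_one(self):
        age = np.array([10, 20, 30, 40, 50, 60, 70, 81], dtype=float)
        rho, p, approx = spearman(age, age**2)
        assert rho == pytest.approx(1.0)
        assert not approx

    def test_matches_rank_pearson_oracle(self, rng):
        for _ in range(25):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            rho, _, _ = spearman(x, y)
            rx = np.argsort(np.argsort(x)) + 1.0
            ry = np.argsort(np.argsort(y)) + 1.0
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_ties_fall_back_to_approximation(self):
        x = np.array([1.0, 1.0, 2, 3, 4, 5, 6, 7])
        y = np.array([2.0, 1, 3, 4, 6, 5, 7, 8])
        _, _, approx = spearman(x, y)
        assert approx

    def test_null_p_uniformity(self, rng):
        # independent metric: p should be roughly uniform
        ps = []
        for _ in range(400):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            ps.append(spearman(x, y)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestRrppEngine:
    def test_ss_additivity_and_p_floor(self, rng):
        n = 30
        y = rng.normal(size=n)
        g = np.array(["a", "b"] * 15)
        y[g == "b"] += 100.0
        blocks = design_blocks(factors={"G": g})
        t = rrpp_anova(y, blocks, n_perm=999, rng=rng)
        assert t.loc["G", "SS"] + t.loc["Residuals", "SS"] == pytest.approx(
            t.loc["Total", "SS"], rel=1e-10
        )
        assert t.loc["G", "p"] == pytest.approx(1 / 1000)

    def test_determinism_under_fixed_seed(self, rng):
        n = 24
        y = np.random.default_rng(5).normal(size=n)
        x = np.random.default_rng(6).normal(size=n)
        blocks = design_blocks(covariates={"x": x})
        t1 = rrpp_anova(y, blocks, 199, np.random.default_rng(42))
        t2 = rrpp_anova(y, blocks, 199, np.random.default_rng(42))
        assert (t1.fillna(0) == t2.fillna(0)).all().all()

    def test_aliased_term_rejected(self, rng):
        n = 20
        x = rng.normal(size=n)
        blocks = design_blocks(covariates={"x": x, "x2": 2 * x})
        with pytest.raises(DegenerateInputError, match="aliased"):
            rrpp_anova(rng.normal(size=n), blocks, 99, rng)
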
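"""Curve resampling, GPA, sliding semilandmarks, shape PCA and
Procrustes ANOVA."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from jawstrength import (
    DegenerateInputError,
    LandmarkSet,
    ValidationError,
    centroid_size,
    gpa,
    mean_shape,
    procrustes_anova,
    resample_curve,
    shape_pca,
    slide_semilandmarks,
)


def _random_rotation(rng):
    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()


class TestResampleCurve:
    def test_straight_segment_equal_spacing(self):
        curve = np.array([[0, 0, 0], [1, 0, 0]], dtype=float)
        out = resample_curve(curve, 5)
        np.testing.assert_allclose(out[:, 0], [0, 0.25, 0.5, 0.75, 1.0], atol=1e-12)

    def test_semicircle_equal_arc_lengths(self):
        t = np.linspace(0, np.pi, 400)
        curve = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        out = resample_curve(curve, 13)
        # equal arc spacing on a circle implies equal chords
        seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
        np.testing.assert_allclose(seg, seg.mean(), atol=1e-6)
        np.testing.assert_allclose(out[0], curve[0])
        np.testing.assert_allclose(out[-1], curve[-1])

    def test_identity_on_already_equidistant_input(self):
        curve = np.column_stack(
            [np.linspace(0, 3, 7), np.zeros(7), np.linspace(0, 4, 7)]
        )
        out = resample_curve(curve, 7)
        np.testing.assert_allclose(out, curve, atol=1e-12)

    def test_too_few_targets_rejected(self):
        with pytest.raises(ValidationError):
            resample_curve(np.zeros((10, 3)), 2)


class TestGPA:
    def test_rigid_motion_invariance(self, rng):
        C = rng.normal(size=(9, 3))
        R = _random_rotation(rng)
        moved = C @ R.T + np.array([5.0, -3.0, 11.0])
        fit = gpa(np.stack([C, moved]))
        d = np.linalg.norm(fit.aligned[0] - fit.aligned[1])
        assert d < 1e-10

    def test_aligned_configs_centred_and_unit_size(self, rng):
        X = rng.normal(size=(6, 8, 3))
        fit = gpa(X)
        for a in fit.aligned:
            assert np.abs(a.mean(axis=0)).max() < 1e-10
            assert centroid_size(a) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(
            fit.consensus, fit.aligned.mean(axis=0), atol=1e-12
        )

    def test_scaling_doubles_centroid_size_not_shape(self, rng):
        X = rng.normal(size=(4, 7, 3))
        X2 = X.copy()
        X2[1] = 2.0 * X2[1]
        f1, f2 = gpa(X), gpa(X2)
        assert f2.centroid_sizes[1] == pytest.approx(2 * f1.centroid_sizes[1])
        np.testing.assert_allclose(f2.aligned[1], f1.aligned[1], atol=1e-10)

    def test_two_triangle_residual_matches_quaternion_grid_oracle(self, rng):
        A = rng.normal(size=(3, 3))
        B = rng.normal(size=(3, 3))
        fit = gpa(np.stack([A, B]))
        ours = float(np.sum((fit.aligned[0] - fit.aligned[1]) ** 2))

        # brute-force: minimise ||a R - b||^2 over rotations, coarse
        # quaternion grid then local polish
        def pre(X):
            c = X - X.mean(axis=0)
            return c / np.sqrt(np.sum(c * c))

        a, b = pre(A), pre(B)

        def cost(q):
            q = q / np.linalg.norm(q)
            R = Rotation.from_quat(q).as_matrix()
            return np.sum((a @ R.T - b) ** 2)

        best = np.inf
        g = np.random.default_rng(0).normal(size=(4000, 4))
        for q in g:
            c = cost(q)
            if c < best:
                best, bq = c, q
        res = minimize(cost, bq, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        # for two configurations GPA converges to the mutually optimal
        # superimposition, so the pairwise aligned residual must equal the
        # brute-force minimum over rotations
        assert ours == pytest.approx(res.fun, rel=1e-6, abs=1e-10)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            gpa(rng.normal(size=(2, 2, 3)))  # too few landmarks
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateInputError):
            gpa(np.stack([line, line + 1]))


class TestSliding:
    def _sets(self, rng, n=6, noise=0.0, bunch_first=False):
        t = np.linspace(0, np.pi, 600)
        base_curves = [
            np.column_stack([np.cos(t) * s, np.sin(t) * s, 0.1 * t * s])
            for s in (1.0, 1.3, 1.6, 2.0)
        ]
        fixed_base = rng.normal(size=(7, 3)) * 2
        sets = []
        for i in range(n):
            curves = []
            for c in base_curves:
                # the bunched specimen keeps a noise-free smooth curve so
                # equidistance is measurable through chord lengths
                cc = c + (0.0 if bunch_first and i == 0 else noise) * rng.normal(
                    size=c.shape
                )
                if bunch_first and i == 0:
                    # bunch vertex spacing toward the start of the curve by
                    # arc-length reparameterisation (same geometric support)
                    seg = np.linalg.norm(np.diff(cc, axis=0), axis=1)
                    s = np.concatenate([[0.0], np.cumsum(seg)])
                    u = np.linspace(0, 1, len(cc)) ** 3 * s[-1]
                    cc = np.column_stack(
                        [np.interp(u, s, cc[:, d]) for d in range(3)]
                    )
                curves.append(cc)
            sets.append(
                LandmarkSet(f"s{i}", "dentary_curves",
                            fixed_base + noise * rng.normal(size=(7, 3)),
                            tuple(curves))
            )
        return sets

    def test_identical_specimens_slide_is_noop(self, rng):
        sets = self._sets(rng, n=4, noise=0.0)
        configs, fit, deltas = slide_semilandmarks(sets, n_iterations=10)
        assert np.all(np.abs(deltas) < 1e-12)
        assert float(np.sum((fit.aligned - fit.consensus) ** 2)) < 1e-20

    def test_bunched_semilandmarks_become_equidistant(self, rng):
        sets = self._sets(rng, n=5, noise=0.005, bunch_first=True)
        configs, fit, deltas = slide_semilandmarks(sets, n_iterations=10)
        # semilandmark block of specimen 0: spacing equal along each curve
        k_fixed = 7
        pos = k_fixed
        for c in range(4):
            m = (configs.shape[1] - k_fixed) // 4
            pts = configs[0][pos : pos + m]
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            assert np.ptp(seg) / seg.mean() < 1e-4
            pos += m

    def test_total_variance_never_increases_after_first_iteration(self, rng):
        sets = self._sets(rng, n=6, noise=0.01)
        _, _, deltas = slide_semilandmarks(sets, n_iterations=10)
        # deltas = drop in summed Procrustes distance per iteration
        assert np.all(deltas >= -1e-8)

    def test_degenerate_curve_names_specimen(self, rng):
        sets = self._sets(rng, n=3)
        bad = LandmarkSet(
            "bad", "dentary_curves", sets[0].fixed,
            tuple(np.zeros_like(c) for c in sets[0].curves),
        )
        with pytest.raises(DegenerateInputError, match="bad"):
            slide_semilandmarks(sets + [bad])


class TestShapePCA:
    def test_rank_one_variation_concentrates_on_pc1(self, rng):
        # aligned specimens lying exactly on consensus + t*v: PC1 carries
        # all variance
        from jawstrength.gmm import ProcrustesFit

        base = rng.normal(size=(10, 3))
        base -= base.mean(axis=0)
        v = rng.normal(size=(10, 3))
        v -= v.mean(axis=0)
        aligned = np.stack(
            [base + t * 0.01 * v for t in np.linspace(-1, 1, 9)]
        )
        fit = ProcrustesFit(
            aligned, np.ones(9), aligned.mean(axis=0), 1, True
        )
        space = shape_pca(fit)
        assert space.variance_fraction[0] > 1 - 1e-10

    def test_variance_fractions_match_dense_eigensolver(self, rng):
        X = rng.normal(size=(12, 6, 3))
        fit = gpa(X)
        space = shape_pca(fit)
        Y = fit.flattened
        C = np.cov(Y.T, bias=False)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        evals = evals[: space.n_axes]
        np.testing.assert_allclose(
            space.variance_fraction,
            evals / np.linalg.eigvalsh(C).sum(),
            atol=1e-8,
        )


class TestProcrustesAnova:
    def test_ss_additivity(self, rng):
        X = rng.normal(size=(20, 6, 3))
        fit = gpa(X)
        loc = np.repeat(list("abcd"), 5)
        t = procrustes_anova(fit, loc, n_perm=99, rng=rng)
        terms = ["Size", "Location", "Size:Location"]
        assert t.loc[terms, "SS"].sum() + t.loc["Residuals", "SS"] == pytest.approx(
            t.loc["Total", "SS"], rel=1e-8
        )

    def test_strong_location_effect_hits_p_floor(self, rng):
        base = rng.normal(size=(6, 3))
        X = []
        loc = np.repeat(list("ab"), 10)
        for i, l in enumerate(loc):
            off = np.zeros(3) if l == "a" else np.array([0, 1.0, 0])
            X.append(base + off * np.linspace(0, 1, 6)[:, None] + 1e-3 * rng.normal(size=(6, 3)))
        fit = gpa(np.stack(X))
        t = procrustes_anova(fit, loc, n_perm=999, rng=rng)
        assert t.loc["Location", "p"] == pytest.approx(1 / 1000)

    def test_null_location_rejection_rate_calibrated(self):
        # i.i.d. shape noise, random labels: rejection rate near alpha
        rej = 0
        n_rep = 500
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            X = rng.normal(size=(16, 5, 3)) + 10 * np.eye(5, 3)[None]
            fit = gpa(X)
            loc = rng.permutation(np.repeat(["a", "b"], 8))
            t = procrustes_anova(fit, loc, n_perm=199, rng=rng)
            rej += t.loc["Location", "p"] <= 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_single_specimen_group_rejected(self, rng):
        X = rng.normal(size=(5, 6, 3))
        with pytest.raises(DegenerateInputError):
            procrustes_anova(fit=gpa(X), location=np.array(list("aabbc")), n_perm=9, rng=rng)


class TestMeanShape:
    def test_group_of_one_and_midpoint(self, rng):
        X = rng.normal(size=(4, 5, 3))
        fit = gpa(X)
        np.testing.assert_allclose(mean_shape(fit, [2]), fit.aligned[2])
        np.testing.assert_allclose(
            mean_shape(fit, [0, 1]), 0.5 * (fit.aligned[0] + fit.aligned[1])
        )
        with pytest.raises(DegenerateInputError):
            mean_shape(fit, [])

    def test_population_means_recover_generator_means(self, small_bundle):
        # population mean shapes from GPA should rank-correlate with the
        # injected depth ordering through jaw depth
        from jawstrength.gmm import gpa as run_gpa

        meta = small_bundle.specimen_meta
        X = np.stack([ls.fixed for ls in small_bundle.mandible_sets])
        fit = run_gpa(X)
        pops = sorted(meta["population"].unique())
        depths = []
        for pop in pops:
            idx = np.where((meta["population"] == pop).to_numpy())[0]
            m = mean_shape(fit, idx)
            depths.append(np.ptp(m[:, 1]))  # dorsoventral depth of the mean
        true = small_bundle.truth["depth_effects"]
        # deeper injected effect -> deeper mean shape (allow GPA scaling slack)
        assert np.corrcoef(np.argsort(np.argsort(true)), np.argsort(np.argsort(depths)))[0, 1] > 0.5
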
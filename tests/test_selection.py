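"""Selection differentials: relative fitness, doubling convention, mode policy."""

import numpy as np
import pytest

from selsurf import (
    SelectionDifferentials,
    SurfaceResult,
    classify_mode,
    estimate_differentials,
    morph_index,
    relative_fitness,
)

from conftest import make_records


def fake_surface(interior_min: bool, interior_max: bool) -> SurfaceResult:
    grid = np.linspace(-1, 1, 5)
    flat = np.ones(5)
    return SurfaceResult(
        grid=grid,
        fit=flat,
        ci_lo=flat,
        ci_hi=flat,
        lam=1.0,
        interior_min=interior_min,
        interior_max=interior_max,
        argext=0.0 if (interior_min or interior_max) else float("nan"),
    )


def differentials(beta, p_beta, gamma, p_gamma) -> SelectionDifferentials:
    return SelectionDifferentials(
        beta=beta,
        se_beta=0.01,
        t_beta=beta / 0.01,
        p_beta=p_beta,
        gamma=gamma,
        se_gamma=0.01,
        t_gamma=gamma / 0.01,
        p_gamma=p_gamma,
        n=100,
    )


class TestRelativeFitness:
    def test_equal_sizes_give_unit_fitness(self):
        assert np.allclose(relative_fitness(np.full(7, 30.0)), 1.0)

    def test_two_point_arithmetic(self):
        w = relative_fitness(np.array([np.e, np.e**3]))
        assert np.allclose(w, [0.5, 1.5])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mean_is_one_by_construction(self, seed):
        rec = make_records(n=50, seed=seed)
        assert relative_fitness(rec).mean() == pytest.approx(1.0, abs=1e-12)

    def test_sub_millimeter_sizes_break_the_ratio_convention(self):
        with pytest.raises(ValueError, match="mean ln SVL"):
            relative_fitness(np.array([0.5, 0.6, 0.7]))

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            relative_fitness(np.array([-1.0, 20.0]))


class TestEstimateDifferentials:
    def test_exact_linear_fitness(self):
        z = np.array([-1.5, -0.5, 0.0, 0.7, 1.3, 2.0])
        w = 1 + 0.1 * z
        est = estimate_differentials(z, w)
        assert est.beta == pytest.approx(0.1, abs=1e-12)
        assert est.gamma == pytest.approx(0.0, abs=1e-10)

    def test_exact_quadratic_on_symmetric_design(self):
        z = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        w = 1 + z**2
        est = estimate_differentials(z, w)
        assert est.gamma == pytest.approx(2.0, abs=1e-10)  # doubled raw c = 1
        assert est.beta == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_normal_equation_oracle(self, rng):
        z = rng.normal(size=40)
        w = 1 + 0.05 * z + 0.03 * z**2 + rng.normal(0, 0.1, size=40)

        def ols(X, y):
            XtX_inv = np.linalg.inv(X.T @ X)
            coef = XtX_inv @ X.T @ y
            resid = y - X @ coef
            sigma2 = resid @ resid / (len(y) - X.shape[1])
            return coef, np.sqrt(np.diag(sigma2 * XtX_inv))

        ones = np.ones_like(z)
        coef_lin, se_lin = ols(np.column_stack([ones, z]), w)
        coef_quad, se_quad = ols(np.column_stack([ones, z, z**2]), w)

        est = estimate_differentials(z, w)
        assert est.beta == pytest.approx(coef_lin[1], abs=1e-10)
        assert est.se_beta == pytest.approx(se_lin[1], abs=1e-10)
        assert est.gamma == pytest.approx(2 * coef_quad[2], abs=1e-10)
        assert est.se_gamma == pytest.approx(2 * se_quad[2], abs=1e-10)
        # doubling cancels in the t ratio
        assert est.t_gamma == pytest.approx(coef_quad[2] / se_quad[2], abs=1e-10)

    def test_beta_comes_from_the_linear_only_model(self, rng):
        # on an asymmetric design the quadratic model's linear term differs
        z = np.abs(rng.normal(size=60)) + 0.2
        w = 1 + 0.05 * z + 0.04 * z**2 + rng.normal(0, 0.05, size=60)
        est = estimate_differentials(z, w)
        assert est.beta != pytest.approx(est.linear_term_quadratic_model, abs=1e-6)

    def test_constant_trait_is_singular(self):
        with pytest.raises(ValueError, match="singular|constant"):
            estimate_differentials(np.ones(10), np.ones(10))

    def test_recovers_positive_curvature_from_generator(self):
        rec = make_records(n=200, seed=8, gamma_true=0.1)
        est = estimate_differentials(morph_index(rec).scores, relative_fitness(rec))
        assert est.gamma > 0
        assert est.p_gamma < 0.05


class TestClassifyMode:
    def test_disruptive_with_interior_minimum(self):
        est = differentials(beta=0.031, p_beta=0.0006, gamma=0.126, p_gamma=1e-4)
        cls = classify_mode(est, fake_surface(interior_min=True, interior_max=False))
        assert cls.mode == "disruptive"
        assert cls.directional == 1

    def test_stabilizing_with_interior_maximum(self):
        est = differentials(beta=0.076, p_beta=1e-4, gamma=-0.060, p_gamma=0.002)
        cls = classify_mode(est, fake_surface(interior_min=False, interior_max=True))
        assert cls.mode == "stabilizing"

    def test_nonsignificant_gamma_is_none(self):
        est = differentials(beta=0.020, p_beta=0.105, gamma=0.001, p_gamma=0.929)
        cls = classify_mode(est, fake_surface(interior_min=True, interior_max=True))
        assert cls.mode == "none"
        assert cls.directional == 0

    def test_significant_gamma_without_interior_extremum_is_none(self):
        est = differentials(beta=0.0, p_beta=0.9, gamma=0.05, p_gamma=0.001)
        cls = classify_mode(est, fake_surface(interior_min=False, interior_max=False))
        assert cls.mode == "none"

    def test_surface_none_falls_back_to_sign_and_significance(self):
        est = differentials(beta=0.0, p_beta=0.9, gamma=0.05, p_gamma=0.001)
        assert classify_mode(est, None).mode == "disruptive"

    def test_invalid_alpha_rejected(self):
        est = differentials(beta=0.0, p_beta=0.9, gamma=0.0, p_gamma=0.9)
        with pytest.raises(ValueError):
            classify_mode(est, None, alpha=1.5)


class TestTypeOneErrorCalibration:
    def test_null_gamma_rejection_rate_near_nominal(self):
        # flat true surface: the quadratic t-test should reject at ~alpha
        rejections = 0
        reps = 1000
        for seed in range(reps):
            rec = make_records(
                n=100, seed=20_000 + seed, gamma_true=0.0, beta_true=0.0
            )
            est = estimate_differentials(
                morph_index(rec).scores, relative_fitness(rec)
            )
            rejections += est.p_gamma < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 0.02  # ~3 binomial SEs
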
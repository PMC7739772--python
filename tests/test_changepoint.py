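"""Linear-plateau fit, AIC comparison, bootstrap CI and LOOCV stability."""

import numpy as np
import pytest

from sprintcp import (
    DegenerateDataError,
    bootstrap_ci,
    compare_models,
    fit_cprm,
    fit_linear,
    generate_cohort,
    loocv_stability,
    profile_curve,
    ta_config,
)


def brute_force_hinge(x, y, grid_points):
    """Independent oracle: per-candidate OLS via numpy.linalg.lstsq."""
    grid = np.linspace(x.min(), x.max(), grid_points)
    best = (np.inf, None)
    for tau in grid:
        A = np.column_stack([np.ones_like(x), np.minimum(x, tau)])
        coef, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(np.sum((y - A @ coef) ** 2))
        if sse < best[0] - 1e-15:
            best = (sse, float(tau))
    return best[1], best[0]


def random_hinge_cohort(rng):
    n = int(rng.integers(8, 21))
    x = rng.uniform(1.0, 6.0, size=n)
    tau = rng.uniform(np.quantile(x, 0.3), np.quantile(x, 0.8))
    beta1 = -rng.uniform(0.3, 1.5)
    y = 12.0 + beta1 * np.minimum(x, tau) + rng.normal(0.0, 0.2, size=n)
    return x, y


class TestFitLinear:
    def test_hand_computed_normal_equations(self, toy_hinge):
        x, y = toy_hinge
        f = fit_linear(x, y)
        assert f.beta1 == pytest.approx(-44.0 / 35.0, rel=1e-12)
        assert f.beta0 == pytest.approx(52.0 / 5.0, rel=1e-12)
        assert f.sse == pytest.approx(152.0 / 35.0, rel=1e-12)
        assert f.aic == pytest.approx(f.n * np.log(f.sse / f.n) + 6.0)

    def test_exact_line_flags_degenerate_perfect_fit(self):
        x = np.arange(1.0, 6.0)
        f = fit_linear(x, 2.0 * x + 1.0)
        assert f.beta0 == pytest.approx(1.0)
        assert f.beta1 == pytest.approx(2.0)
        assert f.sse == 0.0
        assert f.aic == -np.inf and f.perfect_fit

    def test_y_shift_equivariance(self, toy_hinge):
        x, y = toy_hinge
        a, b = fit_linear(x, y), fit_linear(x, y + 7.5)
        assert b.beta0 == pytest.approx(a.beta0 + 7.5)
        assert b.beta1 == pytest.approx(a.beta1)
        assert b.sse == pytest.approx(a.sse)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_linear([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestFitCprm:
    def test_exact_hinge_toy(self, toy_hinge):
        x, y = toy_hinge
        f = fit_cprm(x, y)
        step = (x.max() - x.min()) / (f.grid[2] - 1)
        assert abs(f.tau - 4.0) <= step
        assert f.beta0 == pytest.approx(12.0, abs=1e-9)
        assert f.beta1 == pytest.approx(-2.0, abs=1e-9)
        assert f.sse < 1e-18
        assert f.plateau_level == pytest.approx(4.0, abs=1e-9)
        assert f.changepoint_present

    def test_noiseless_linear_data_pick_upper_endpoint(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = 9.0 - 0.5 * x
        f = fit_cprm(x, y)
        assert f.tau == pytest.approx(x.max())
        assert f.sse == pytest.approx(f.linear_fit.sse, abs=1e-18)
        assert not f.changepoint_present  # equal SSE: no hinge evidence

    def test_x_scale_and_y_shift_equivariance(self, toy_hinge):
        x, y = toy_hinge
        base = fit_cprm(x, y)
        scaled = fit_cprm(3.0 * x, y)
        assert scaled.tau == pytest.approx(3.0 * base.tau)
        shifted = fit_cprm(x, y + 2.0)
        assert shifted.tau == pytest.approx(base.tau)
        assert shifted.plateau_level == pytest.approx(base.plateau_level + 2.0)

    def test_nesting_on_random_cohorts(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(8, 21))
            x = rng.uniform(0.0, 10.0, size=n)
            y = rng.normal(size=n)
            f = fit_cprm(x, y)
            assert f.sse <= f.linear_fit.sse + 1e-12
            assert f.grid[0] <= f.tau <= f.grid[1]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x, y = random_hinge_cohort(rng)
            f = fit_cprm(x, y, grid_points=201)
            tau_o, sse_o = brute_force_hinge(x, y, grid_points=2001)
            step = (x.max() - x.min()) / 200
            assert abs(f.tau - tau_o) <= step
            assert f.sse >= sse_o - 1e-9 * max(sse_o, 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_cprm([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])


class TestCompareModels:
    def test_equal_sse_gives_penalty_of_two(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = 9.0 - 0.5 * x + np.array([0.1, -0.1, 0.1, -0.1, 0.1, -0.1])
        f = fit_cprm(x, y)
        if f.sse == pytest.approx(f.linear_fit.sse):
            assert f.delta_aic == pytest.approx(2.0)
            choice = compare_models(f)
            assert choice.preferred == "linear" and not choice.by_sse

    def test_zero_sse_hinge_beats_positive_sse_line(self, toy_hinge):
        f = fit_cprm(*toy_hinge)
        choice = compare_models(f)
        assert choice.preferred == "changepoint"
        assert choice.by_sse  # AIC degenerate at SSE ~ 0
        assert f.delta_aic == -np.inf

    def test_delta_aic_invariant_to_y_rescaling(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(1, 6, 14)
        y = 14.3 - 0.7 * np.minimum(x, 4.7) + rng.normal(0, 0.2, 14)
        a = fit_cprm(x, y)
        b = fit_cprm(x, 10.0 * y)
        assert b.delta_aic == pytest.approx(a.delta_aic, abs=1e-9)


class TestBootstrapCI:
    def test_deterministic_under_fixed_seed(self, ta_cohort):
        x = ta_cohort.column("ta_thickness_mm")
        y = ta_cohort.column("sprint_time_s")
        a = bootstrap_ci(x, y, B=100, seed=13)
        b = bootstrap_ci(x, y, B=100, seed=13)
        assert a.lower == b.lower and a.upper == b.upper
        np.testing.assert_array_equal(a.tau_draws, b.tau_draws)

    def test_draws_within_range_and_ordered(self, toy_hinge):
        x, y = toy_hinge
        ci = bootstrap_ci(x, y, B=200, seed=1)
        assert ci.lower <= ci.upper
        assert ci.tau_draws.min() >= x.min() and ci.tau_draws.max() <= x.max()
        assert ci.tau_draws.size == 200

    def test_percentile_endpoints_are_quantiles_of_draws(self, ta_cohort):
        x = ta_cohort.column("ta_thickness_mm")
        y = ta_cohort.column("sprint_time_s")
        ci = bootstrap_ci(x, y, B=300, seed=5, level=0.90)
        lo, hi = np.quantile(ci.tau_draws, [0.05, 0.95])
        assert ci.lower == pytest.approx(lo) and ci.upper == pytest.approx(hi)

    def test_degenerate_resamples_are_redrawn_not_dropped(self):
        # Only 5 distinct x values: resamples frequently collapse below 4
        # distinct values and must be redrawn.
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([5.0, 4.0, 3.0, 3.0, 3.0])
        ci = bootstrap_ci(x, y, B=100, seed=2)
        assert ci.tau_draws.size == 100
        assert ci.n_redrawn > 0

    def test_exhausted_resampling_raises(self):
        # Hypothetical duplicate-heavy measurements: only 2 distinct x.
        x = np.array([1.0, 1.0, 2.0, 2.0, 1.0, 2.0])
        y = np.array([3.0, 3.1, 2.0, 2.1, 3.2, 1.9])
        with pytest.raises(DegenerateDataError):
            bootstrap_ci(x, y, B=50, seed=3)


class TestLoocvStability:
    def test_noiseless_toy_is_perfectly_stable(self, toy_hinge):
        x, y = toy_hinge
        res = loocv_stability(x, y, ids=[f"P{i}" for i in range(6)])
        assert len(res.tau_by_left_out) == 6
        for tau in res.tau_by_left_out.values():
            assert tau == pytest.approx(4.0, abs=(x.max() - x.min()) / 1000)
        assert res.tau_range == pytest.approx(0.0, abs=1e-2)
        assert res.all_present
        assert res.flagged_folds == ()

    def test_one_fold_per_participant(self, ta_cohort):
        res = loocv_stability(
            ta_cohort.column("ta_thickness_mm"),
            ta_cohort.column("sprint_time_s"),
            ta_cohort.ids, grid_points=201)
        assert set(res.tau_by_left_out) == set(ta_cohort.ids)
        assert res.tau_range >= 0

    def test_duplicated_cohort_is_weight_insensitive(self, toy_hinge):
        x, y = toy_hinge
        full = fit_cprm(x, y)
        x2 = np.concatenate([x, x])
        y2 = np.concatenate([y, y])
        ids = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
        res = loocv_stability(x2, y2, ids)
        # Removing one copy of a duplicated point never moves the optimum.
        for tau in res.tau_by_left_out.values():
            assert tau == pytest.approx(full.tau, abs=1e-9)


def test_profile_curve_reproduces_hinge(toy_hinge):
    f = fit_cprm(*toy_hinge)
    gx, gy = profile_curve(f, points=11)
    np.testing.assert_allclose(gy, f.beta0 + f.beta1 * np.minimum(gx, f.tau))
    assert gy[-1] == pytest.approx(f.plateau_level)
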
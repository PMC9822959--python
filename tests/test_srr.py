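import numpy as np
import pytest
from scipy.optimize import curve_fit

from stockshift.exceptions import InputError
from stockshift.io import SRRDataset
from stockshift.srr import (
    choose_glm_family,
    fit_beverton_holt,
    fit_linear,
    fit_ricker,
    fit_segmented_glm,
    fit_srr_breakpoint_regression,
    loocv_compare,
    segmented_psi_grid_oracle,
)
from stockshift.simulate import simulate_srr_regimes


def make_srr(s, r, start=1950):
    s = np.asarray(s, float)
    return SRRDataset(np.arange(start, start + s.size), s, np.asarray(r, float))


class TestBevertonHolt:
    def test_noiseless_recovery_to_1e6(self):
        s = np.linspace(100, 2000, 50)
        fit = fit_beverton_holt(make_srr(s, 2 * s / (1 + 0.001 * s)))
        assert fit.params["alpha"] == pytest.approx(2.0, rel=1e-6)
        assert fit.params["beta"] == pytest.approx(0.001, rel=1e-6)

    def test_beta_zero_reduces_to_proportional(self):
        s = np.linspace(100, 2000, 50)
        fit = fit_beverton_holt(make_srr(s, 2.5 * s))
        assert fit.params["alpha"] == pytest.approx(2.5, rel=1e-8)
        assert abs(fit.params["beta"]) < 1e-10

    def test_matches_reference_optimizer_on_noisy_replicates(self):
        """Median alpha estimate over seeded lognormal-noise replicates agrees
        with an independent reference optimizer (scipy curve_fit on the same
        log-scale objective)."""
        ours, ref = [], []
        for rep in range(20):
            rng = np.random.default_rng(rep)
            s = rng.uniform(100, 2000, 50)
            r = 2 * s / (1 + 0.001 * s) * np.exp(0.3 * rng.standard_normal(50))
            d = make_srr(s, r)
            ours.append(fit_beverton_holt(d).params["alpha"])

            def logbh(s_, la, b):
                return la + np.log(s_) - np.log1p(b * s_)

            popt, _ = curve_fit(logbh, s, np.log(r), p0=[np.log(2.0), 0.001], maxfev=10000)
            ref.append(np.exp(popt[0]))
        assert np.median(ours) == pytest.approx(np.median(ref), rel=1e-4)

    def test_negative_beta_is_flagged_not_fatal(self):
        s = np.linspace(100, 1000, 30)
        r = s * np.exp(0.5 + 0.0005 * s)  # accelerating: pulls beta negative
        fit = fit_beverton_holt(make_srr(s, r))
        assert fit.params["beta"] < 0
        assert "negative_beta" in fit.flags


class TestRicker:
    def test_noiseless_machine_precision(self):
        s = np.linspace(100, 2000, 50)
        fit = fit_ricker(make_srr(s, s * np.exp(1 - 0.002 * s)))
        assert fit.params["alpha"] == pytest.approx(1.0, abs=1e-12)
        assert fit.params["beta"] == pytest.approx(0.002, abs=1e-15)

    def test_equals_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(100, 1500, 40)
        r = s * np.exp(0.8 - 0.001 * s) * np.exp(0.2 * rng.standard_normal(40))
        fit = fit_ricker(make_srr(s, r))
        # independent closed-form solution of the normal equations
        X = np.vstack([np.ones_like(s), s]).T
        y = np.log(r / s)
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.params["alpha"] == pytest.approx(coef[0], rel=1e-10)
        assert fit.params["beta"] == pytest.approx(-coef[1], rel=1e-10)

    def test_increasing_ratio_flags_non_dome(self):
        s = np.linspace(100, 1000, 30)
        fit = fit_ricker(make_srr(s, s * np.exp(0.1 + 0.001 * s)))
        assert fit.params["beta"] < 0
        assert "negative_beta_non_dome" in fit.flags

    def test_degenerate_design_rejected(self):
        with pytest.raises(InputError):
            fit_ricker(make_srr([100, 100, 100, 100, 100], [50, 60, 70, 80, 90]))


class TestLinear:
    def test_exact_line(self):
        s = np.linspace(10, 100, 20)
        fit = fit_linear(make_srr(s, 3 * s))
        assert fit.params["slope"] == pytest.approx(3.0)
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_loglog_power_law(self):
        s = np.linspace(10, 100, 20)
        fit = fit_linear(make_srr(s, 2 * np.sqrt(s)), log_scale=True)
        assert fit.params["slope"] == pytest.approx(0.5)
        assert fit.params["intercept"] == pytest.approx(np.log(2))
        np.testing.assert_allclose(fit.fitted, 2 * np.sqrt(s), rtol=1e-9)

    def test_rmse_matches_independent_ols(self, ricker_srr):
        fit = fit_linear(ricker_srr)
        slope, icpt = np.polyfit(ricker_srr.s, ricker_srr.r, 1)
        resid = ricker_srr.r - (icpt + slope * ricker_srr.s)
        assert fit.sse == pytest.approx(float(resid @ resid), rel=1e-10)


class TestFamilyChoice:
    def test_hand_computed_dispersion_small_table(self):
        # 10 equidispersed rows; phi recomputed by the Pearson formula by hand
        s = np.arange(10.0) + 1
        r = np.array([4.0, 6, 5, 7, 6, 8, 7, 9, 8, 10])
        choice = choose_glm_family(make_srr(s, r))
        import statsmodels.api as sm

        res = sm.GLM(r, sm.add_constant(s), family=sm.families.Poisson()).fit()
        phi_hand = float(np.sum((r - res.mu) ** 2 / res.mu) / (10 - 2))
        assert choice.dispersion == pytest.approx(phi_hand, rel=1e-10)

    def test_poisson_counts_detected(self):
        rng = np.random.default_rng(7)
        d = make_srr(rng.uniform(10, 100, 100), rng.poisson(20, 100) + 1e-9, start=1900)
        assert choose_glm_family(d).family == "poisson"

    def test_negative_binomial_counts_detected(self):
        rng = np.random.default_rng(2)
        mu, size = 20.0, 0.5
        r = rng.negative_binomial(size, size / (size + mu), 100) + 1.0
        d = make_srr(rng.uniform(10, 100, 100), r, start=1900)
        assert choose_glm_family(d).family == "negative_binomial"

    def test_non_count_data_uses_gaussian(self, ricker_srr):
        assert choose_glm_family(ricker_srr, assume_counts=False).family == "gaussian"


class TestSegmented:
    def test_noiseless_breakpoint_to_1e3(self):
        s = np.linspace(10, 990, 60)
        r = np.where(s <= 500, 100 + s, 600 - 0.5 * (s - 500))
        fit = fit_segmented_glm(make_srr(s, r))
        assert fit.psi == pytest.approx(500.0, abs=1e-3)
        assert fit.params["slope_below"] == pytest.approx(1.0, abs=1e-8)
        assert fit.params["slope_above"] == pytest.approx(-0.5, abs=1e-8)
        assert fit.params["slope_diff_p"] < 1e-6

    @pytest.mark.parametrize("seed", [4, 9, 23])
    def test_noisy_psi_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = np.sort(rng.uniform(10, 990, 60))
        r = np.maximum(
            np.where(s <= 500, 100 + s, 600 - 0.5 * (s - 500)) + rng.normal(0, 30, 60), 1
        )
        d = make_srr(s, r)
        fit = fit_segmented_glm(d)
        psi_oracle = segmented_psi_grid_oracle(d, 1000)
        step = (np.quantile(s, 0.98) - np.quantile(s, 0.02)) / 999
        assert abs(fit.psi - psi_oracle) <= step + 1e-9

    def test_straight_line_flags_no_supported_break(self):
        rng = np.random.default_rng(4)
        s = np.linspace(10, 990, 60)
        fit = fit_segmented_glm(make_srr(s, np.maximum(2 * s + rng.normal(0, 20, 60), 1)))
        assert "no supported break" in fit.flags
        assert fit.params["slope_diff_p"] >= 0.05

    def test_psi0_outside_range_rejected(self, ricker_srr):
        with pytest.raises(InputError):
            fit_segmented_glm(ricker_srr, psi0=1e9)


class TestBreakpointRegression:
    def test_two_break_noiseless_exact_positions(self):
        rng = np.random.default_rng(1)
        sp = rng.uniform(100, 900, 45)
        d, truth = simulate_srr_regimes(
            [1.8, 1.0, 1.5], [0.002, 0.002, 0.001], [1960, 1975, 1990], sp, 0.0, seed=1
        )
        fit = fit_srr_breakpoint_regression(d, max_breaks=2)
        assert fit.params["n_breaks"] == 2
        assert list(fit.break_years) == [1975, 1990]

    def test_stationary_ricker_selects_zero_breaks(self):
        rng = np.random.default_rng(3)
        sp = rng.uniform(100, 900, 45)
        d, _ = simulate_srr_regimes([1.2], [0.002], [1960], sp, 0.3, seed=3)
        fit = fit_srr_breakpoint_regression(d, max_breaks=2)
        assert fit.params["n_breaks"] == 0

    def test_alpha_halving_break_recovered(self):
        rng = np.random.default_rng(8)
        sp = rng.uniform(100, 900, 45)
        d, truth = simulate_srr_regimes([1.6, 0.8], [0.002, 0.002], [1960, 1984], sp, 0.15, seed=8)
        fit = fit_srr_breakpoint_regression(d, max_breaks=2)
        assert any(abs(by - 1984) <= 2 for by in fit.break_years)


class TestLoocv:
    def test_noiseless_linear_gives_zero_errors(self):
        s = np.linspace(10, 100, 15)
        cmp = loocv_compare(make_srr(s, 3 * s + 5), candidates=("linear",))
        assert cmp.results["linear"]["rmse_train"] == pytest.approx(0.0, abs=1e-8)
        assert cmp.results["linear"]["rmse_test"] == pytest.approx(0.0, abs=1e-8)

    def test_linear_loocv_matches_hat_matrix_identity(self):
        """LOOCV test errors of OLS equal e_i / (1 - h_ii); checked on n = 9."""
        rng = np.random.default_rng(6)
        s = rng.uniform(10, 100, 10)
        r = 2 * s + rng.normal(0, 5, 10)
        d = make_srr(s, r)
        cmp = loocv_compare(d, candidates=("linear",))
        X = np.vstack([np.ones_like(s), s]).T
        H = X @ np.linalg.solve(X.T @ X, X.T)
        resid = r - H @ r
        loo = resid / (1 - np.diag(H))
        assert cmp.results["linear"]["rmse_test"] == pytest.approx(
            float(np.sqrt(np.mean(loo**2))), rel=1e-9
        )

    def test_segmented_wins_on_broken_stick(self):
        rng = np.random.default_rng(9)
        s = rng.uniform(50, 1000, 40)
        r = np.maximum(np.where(s <= 500, 50 + 1.2 * s, 650 - 0.6 * (s - 500)) + rng.normal(0, 60, 40), 1)
        cmp = loocv_compare(make_srr(s, r), candidates=("linear", "ricker", "segmented_glm"))
        assert cmp.winner == "segmented_glm"

    def test_winner_has_minimal_train_rmse(self, ricker_srr):
        cmp = loocv_compare(ricker_srr, candidates=("linear", "ricker", "loglog_linear"))
        best = min(cmp.results.values(), key=lambda v: v["rmse_train"])
        assert cmp.results[cmp.winner]["rmse_train"] == best["rmse_train"]

    def test_too_few_pairs_rejected(self):
        s = np.linspace(10, 100, 8)
        with pytest.raises(InputError):
            loocv_compare(make_srr(s, 2 * s), candidates=("linear",))
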
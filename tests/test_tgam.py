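import numpy as np
import pytest

from stockshift.exceptions import InputError, ThresholdSearchError
from stockshift.io import EnvironmentalSeries, SRRDataset
from stockshift.simulate import simulate_sst_threshold_srr
from stockshift.tgam import (
    ThresholdGamFit,
    GamFit,
    decide_tgam,
    evaluate_threshold_criteria,
    fit_pspline_gam,
    fit_threshold_gam,
    loocv_tgam_vs_gam,
)


class TestPsplineGam:
    def test_linear_data_gives_edf_one_and_ols_line(self):
        x = np.linspace(0, 10, 50)
        y = 2 * x + 1
        fit = fit_pspline_gam(x, y, k=3)
        assert abs(fit.edf - 1.0) < 0.1
        np.testing.assert_allclose(fit.fitted[5:-5], y[5:-5], atol=1e-6)

    def test_gcv_identity_holds_exactly(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 10, 50)
        y = np.sin(x) + rng.normal(0, 0.3, 50)
        fit = fit_pspline_gam(x, y, k=10)
        rss = float(np.sum((y - fit.fitted) ** 2))
        assert fit.gcv == pytest.approx(50 * rss / (50 - fit.trace) ** 2, rel=1e-8)

    def test_lambda_matches_denser_grid_oracle(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 10, 60)
        y = np.sin(x) + rng.normal(0, 0.3, 60)
        coarse = fit_pspline_gam(x, y, k=10)
        dense = fit_pspline_gam(x, y, k=10, lambda_grid=np.logspace(-6, 8, 561))
        # the dense-grid minimum can't be meaningfully below the coarse choice
        assert coarse.gcv <= dense.gcv * 1.01

    def test_heavy_penalty_limit_is_least_squares_line(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 10, 50)
        y = 3 * x + 2 + rng.normal(0, 0.5, 50)
        fit = fit_pspline_gam(x, y, k=6, lambda_grid=np.array([1e12]))
        assert abs(fit.edf - 1.0) < 0.1
        slope, icpt = np.polyfit(x, y, 1)
        np.testing.assert_allclose(fit.fitted, icpt + slope * x, atol=0.1)

    def test_contract_violations(self):
        with pytest.raises(InputError):
            fit_pspline_gam(np.arange(4.0), np.arange(4.0), k=3)
        with pytest.raises(InputError):
            fit_pspline_gam(np.full(20, 1.0), np.arange(20.0), k=3)

    def test_prediction_interpolates_fit(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 10, 40)
        y = np.cos(x) + rng.normal(0, 0.1, 40)
        fit = fit_pspline_gam(x, y, k=8)
        np.testing.assert_allclose(fit.predict(x), fit.fitted, atol=1e-9)


class TestThresholdGam:
    def test_threshold_recovered_within_grid_step(self):
        srr, env, truth = simulate_sst_threshold_srr(threshold=12.0, seed=5)
        fit = fit_threshold_gam(srr, env)
        step = (np.quantile(env.sst, 0.8) - np.quantile(env.sst, 0.2)) / 19
        assert abs(fit.threshold - 12.0) <= step + 1e-9

    def test_reported_gcv_is_profile_minimum(self):
        srr, env, _ = simulate_sst_threshold_srr(threshold=12.0, seed=7)
        fit = fit_threshold_gam(srr, env)
        assert fit.gcv == pytest.approx(float(np.min(fit.gcv_profile[:, 1])), rel=1e-12)

    def test_regime_sizes_respected(self):
        srr, env, _ = simulate_sst_threshold_srr(threshold=12.0, seed=3)
        fit = fit_threshold_gam(srr, env, min_regime=5)
        assert fit.n_below >= 5 and fit.n_above >= 5

    def test_no_effect_profile_leads_to_rejection(self):
        srr, env, _ = simulate_sst_threshold_srr(
            threshold=12.0, slope_below=1.25, slope_above=1.25, seed=11
        )
        dec = decide_tgam(srr, env, lazy_loocv=False)
        assert dec.verdict == "rejected"

    def test_too_little_overlap_rejected(self):
        srr, env, _ = simulate_sst_threshold_srr(threshold=12.0, n=30, seed=0)
        short_env = EnvironmentalSeries(env.years[:15], env.sst[:15])
        with pytest.raises(InputError):
            fit_threshold_gam(srr, short_env)

    def test_linear_regimes_have_edf_near_one(self):
        srr, env, _ = simulate_sst_threshold_srr(threshold=12.0, noise_sd=0.0, seed=2)
        fit = fit_threshold_gam(srr, env)
        assert abs(fit.edf_below - 1.0) < 0.1
        assert abs(fit.edf_above - 1.0) < 0.1


class TestLoocvCompetition:
    def test_two_regime_data_prefers_tgam(self):
        srr, env, _ = simulate_sst_threshold_srr(threshold=12.0, seed=4)
        out = loocv_tgam_vs_gam(srr, env)
        assert out["prefers_tgam"]
        assert out["rmse_tgam"] < out["rmse_gam"]

    def test_single_regime_data_prefers_plain_gam(self):
        srr, env, _ = simulate_sst_threshold_srr(
            threshold=12.0, slope_below=1.25, slope_above=1.25, seed=4
        )
        out = loocv_tgam_vs_gam(srr, env)
        assert not out["prefers_tgam"]


def _mk_fit(edf_below, edf_above, p_below, p_above, profile):
    dummy = GamFit(
        basis_dim=4,
        coefficients=np.zeros(4),
        lambda_=1.0,
        edf=edf_below,
        gcv=1.0,
        fitted=np.zeros(5),
        trace=edf_below + 1,
        rss=1.0,
        knots=np.linspace(0, 1, 8),
        degree=3,
    )
    return ThresholdGamFit(
        threshold=12.0,
        below_smooth=dummy,
        above_smooth=dummy,
        gcv_profile=np.column_stack([np.linspace(10, 14, len(profile)), profile]),
        edf_below=edf_below,
        edf_above=edf_above,
        slope_p_below=p_below,
        slope_p_above=p_above,
        gcv=float(np.min(profile)),
        n_below=10,
        n_above=10,
    )


class TestDecisionRules:
    def test_null_case_rejects_all_three(self):
        fit = _mk_fit(1.0, 1.0, 0.4, 0.4, np.full(20, 100.0))
        dec = evaluate_threshold_criteria(fit, loocv_prefers_tgam=True)
        assert dec.verdict == "rejected"
        assert not any(dec.criteria.values())

    def test_textbook_acceptance(self):
        profile = np.concatenate([np.full(9, 100.0), [60.0], np.full(10, 100.0)])
        fit = _mk_fit(1.2, 2.6, 0.001, 0.3, profile)
        dec = evaluate_threshold_criteria(fit, loocv_prefers_tgam=True)
        assert dec.verdict == "accepted"
        assert dec.threshold == 12.0
        assert dec.details["edf_band_above"] == "strongly non-linear"

    def test_loocv_flag_gates_acceptance(self):
        profile = np.concatenate([np.full(9, 100.0), [60.0], np.full(10, 100.0)])
        fit = _mk_fit(1.2, 2.6, 0.001, 0.3, profile)
        dec = evaluate_threshold_criteria(fit, loocv_prefers_tgam=False)
        assert dec.verdict == "rejected"
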
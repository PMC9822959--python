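import numpy as np
import pytest

from stockshift.exceptions import InputError
from stockshift.hysteresis import (
    baiperron_breakpoints,
    classify_hysteresis,
    enumerate_breakpoints,
    fit_fssb_breakpoints,
    select_lag,
)
from stockshift.io import StockAssessmentSeries
from stockshift.simulate import (
    _default_immigration,
    equilibrium_continuation,
    simulate_hysteretic_stock,
)

K, R_GROWTH, ALLEE = 1000.0, 0.5, 200.0


def allee_fold():
    iota = _default_immigration(R_GROWTH, K, ALLEE)
    collapse_F, recovery_F, *_ = equilibrium_continuation(R_GROWTH, K, ALLEE, iota, 1e-6 * K)
    return collapse_F, recovery_F


def loop_stock(f_floor, seed, allee=ALLEE, process_sd=0.05):
    collapse_F, _ = allee_fold()
    f = np.concatenate(
        [
            np.linspace(0, 1.2 * collapse_F, 40),
            np.linspace(1.2 * collapse_F, f_floor, 40),
            np.full(40, f_floor),
        ]
    )
    series, truth = simulate_hysteretic_stock(R_GROWTH, K, allee, f, process_sd=process_sd, seed=seed)
    return series, truth


class TestSelectLag:
    def test_contemporaneous_anticorrelation(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0.1, 0.9, 30)
        sel = select_lag(f, -f, max_lag=5)
        assert sel.lag == 0
        assert sel.correlation == pytest.approx(-1.0)

    def test_constructed_lag_three(self):
        rng = np.random.default_rng(1)
        f = np.empty(40)
        f[0] = 0.5
        for t in range(1, 40):
            f[t] = 0.5 + 0.8 * (f[t - 1] - 0.5) + rng.normal(0, 0.05)
        ssb = np.empty(40)
        ssb[3:] = 1000 - 500 * f[:-3]
        ssb[:3] = ssb[3]
        sel = select_lag(f, ssb, max_lag=8)
        assert sel.lag == 3

    def test_noisy_lag_five_recovery(self):
        rng = np.random.default_rng(11)
        f = np.empty(55)
        f[0] = 0.5
        for t in range(1, 55):
            f[t] = 0.5 + 0.8 * (f[t - 1] - 0.5) + rng.normal(0, 0.08)
        ssb = np.empty(55)
        ssb[5:] = 1000 - 500 * f[:-5]
        ssb[:5] = ssb[5]
        ssb = ssb + rng.normal(0, 0.05 * np.ptp(ssb), 55)
        assert select_lag(f, ssb, max_lag=10).lag == 5

    def test_zero_variance_errors(self):
        with pytest.raises(InputError):
            select_lag(np.full(30, 0.3), np.arange(30.0), max_lag=3)

    def test_correlogram_covers_all_lags(self):
        rng = np.random.default_rng(2)
        sel = select_lag(rng.uniform(0, 1, 30), rng.uniform(0, 1, 30), max_lag=6)
        assert sel.correlogram.shape == (7,)
        assert abs(sel.correlation) == pytest.approx(np.max(np.abs(sel.correlogram)))


class TestBaiPerron:
    def test_pure_line_selects_zero_breaks(self):
        x = np.linspace(0, 10, 30)
        bp = baiperron_breakpoints(x, 2 * x + 1, max_breaks=3)
        assert bp.n_breaks == 0
        icpt, slope = bp.segment_coefficients[0]
        assert slope == pytest.approx(2.0)
        assert icpt == pytest.approx(1.0)

    def test_exact_piecewise_slopes(self):
        x = np.concatenate([np.linspace(0, 5, 15), np.linspace(0, 5, 15)])
        y = np.concatenate([2 * x[:15], 10 - 2 * x[15:]])
        bp = baiperron_breakpoints(x, y, max_breaks=2)
        assert bp.n_breaks == 1
        assert list(bp.break_indices) == [15]
        slopes = bp.segment_slopes
        assert slopes[0] == pytest.approx(2.0, abs=1e-10)
        assert slopes[1] == pytest.approx(-2.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_dp_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, 24)
        y = np.where(np.arange(24) < 12, 2 * x + 1, -x + 30) + rng.normal(0, 1, 24)
        bp = baiperron_breakpoints(x, y, max_breaks=2)
        for m, rss in bp.rss_by_m.items():
            _, rss_bf = enumerate_breakpoints(x, y, m)
            assert rss == pytest.approx(rss_bf, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_rss_monotone_in_breaks(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.uniform(0, 10, 40)
        y = 3 * x + rng.normal(0, 5, 40)
        bp = baiperron_breakpoints(x, y, max_breaks=3)
        vals = [bp.rss_by_m[m] for m in sorted(bp.rss_by_m)]
        assert all(b <= a + 1e-9 for a, b in zip(vals[:-1], vals[1:]))

    def test_degenerate_predictor_falls_back_to_intercept(self):
        rng = np.random.default_rng(3)
        x = np.full(20, 0.4)
        y = rng.normal(100, 10, 20)
        bp = baiperron_breakpoints(x, y, max_breaks=1)
        assert bp.degenerate_segments
        assert bp.segment_coefficients[0][1] is None


class TestClassifyHysteresis:
    def test_reversible_stock_is_none(self):
        f = np.concatenate([np.linspace(0, 0.45, 40), np.linspace(0.45, 0, 40)])
        series, _ = simulate_hysteretic_stock(R_GROWTH, K, 0.0, f, process_sd=0.05, seed=7)
        lag = select_lag(series.fmort, series.ssb, 10)
        out = classify_hysteresis(series, lag)
        assert out.classification == "none"

    def test_noiseless_reversible_equilibria_coincide(self):
        """Without an Allee term the equilibrium SSB(F) map is single-valued:
        holding each F level to equilibrium, the up- and down-sweep branches
        coincide to numerical precision."""
        levels = np.linspace(0.0, 0.3, 6)
        hold = 120
        f = np.concatenate([np.repeat(levels, hold), np.repeat(levels[::-1], hold)])
        series, _ = simulate_hysteretic_stock(R_GROWTH, K, 0.0, f, process_sd=0.0, seed=0)
        up = series.ssb[hold - 1 :: hold][: levels.size]
        down = series.ssb[hold - 1 :: hold][levels.size :][::-1]
        np.testing.assert_allclose(up, down, atol=1e-8)

    def test_full_release_gives_closed_loop(self):
        series, _ = loop_stock(0.0, seed=5)
        lag = select_lag(series.fmort, series.ssb, 10)
        breaks = fit_fssb_breakpoints(series, lag)
        out = classify_hysteresis(series, lag, breaks)
        assert out.classification == "closed_loop"
        assert out.p_value < 0.05

    def test_floor_above_recovery_gives_open_loop(self):
        _, recovery_F = allee_fold()
        series, _ = loop_stock(recovery_F + 0.08, seed=5)
        lag = select_lag(series.fmort, series.ssb, 10)
        breaks = fit_fssb_breakpoints(series, lag)
        out = classify_hysteresis(series, lag, breaks)
        assert out.classification == "open_loop"

    def test_monotone_pressure_returns_none_with_reason(self):
        rng = np.random.default_rng(4)
        years = np.arange(1960, 2010)
        f = np.linspace(0.05, 0.6, 50)
        ssb = 1000 - 1200 * f + rng.normal(0, 10, 50)
        series = StockAssessmentSeries("mono", years, ssb, np.full(50, 100.0), f, 1)
        lag = select_lag(series.fmort, series.ssb, 10)
        out = classify_hysteresis(series, lag)
        assert out.classification == "none"
        assert "monotone" in out.reason

    def test_fssb_breakpoints_flags_decoupled_phase(self):
        series, _ = loop_stock(0.0, seed=3)
        lag = select_lag(series.fmort, series.ssb, 10)
        bp = fit_fssb_breakpoints(series, lag, max_breaks=3)
        assert bp.n_breaks >= 1
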
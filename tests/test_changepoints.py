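import numpy as np
import pytest

from stockshift.changepoints import (
    ChangePointResult,
    bcp_posterior,
    binseg_mean_changepoints,
    consensus_changepoints,
    exhaustive_min_sse_segmentation,
)
from stockshift.exceptions import InputError


def stepped(means, lengths, sd, seed):
    rng = np.random.default_rng(seed)
    x = np.repeat(np.asarray(means, float), lengths)
    return x + rng.normal(0, sd, x.size)


class TestBinseg:
    def test_constant_series_has_no_changes(self):
        r = binseg_mean_changepoints(np.full(20, 7.0))
        assert r.candidate_years.size == 0

    def test_single_noiseless_step(self):
        x = np.array([100.0] * 10 + [200.0] * 10)
        r = binseg_mean_changepoints(x, min_segment=5)
        assert list(r.candidate_years) == [10]  # first index of the new segment

    def test_two_noiseless_steps_match_bruteforce(self):
        x = np.array([100.0] * 10 + [200.0] * 10 + [50.0] * 10)
        r = binseg_mean_changepoints(x, max_changes=3, min_segment=5)
        best, _ = exhaustive_min_sse_segmentation(x, 2, 5)
        assert list(r.candidate_years) == [10, 20] == list(best)

    @pytest.mark.parametrize("seed", range(6))
    def test_single_change_equals_global_sse_argmax(self, seed):
        """Greedy binseg with one allowed change equals the exhaustive
        single-split SSE minimizer on arbitrary noisy series."""
        rng = np.random.default_rng(seed)
        x = stepped([50, 80], [15, 15], 6.0, seed) + rng.normal(0, 1, 30)
        r = binseg_mean_changepoints(x, max_changes=1, min_segment=5, penalty=-1e12)
        best, _ = exhaustive_min_sse_segmentation(x, 1, 5)
        assert list(r.candidate_years) == list(best)

    @pytest.mark.parametrize("shift,scale", [(1000.0, 1.0), (0.0, 250.0), (-3.0, 0.01)])
    def test_location_scale_equivariance(self, shift, scale):
        x = stepped([100, 180, 90], [10, 10, 10], 8.0, 3)
        base = binseg_mean_changepoints(x)
        trans = binseg_mean_changepoints(shift + scale * x)
        np.testing.assert_array_equal(base.candidate_years, trans.candidate_years)

    def test_short_series_rejected(self):
        with pytest.raises(InputError):
            binseg_mean_changepoints(np.arange(8.0), min_segment=5)

    def test_year_axis_labels_candidates(self):
        x = np.array([10.0] * 8 + [30.0] * 8)
        r = binseg_mean_changepoints(x, years=np.arange(1990, 2006))
        assert list(r.candidate_years) == [1998]


class TestBcpPosterior:
    def test_constant_series_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            r = bcp_posterior(np.full(30, 5.0), seed=0)
        assert np.max(r.posterior_trace) < 0.5
        assert r.candidate_years.size == 0

    def test_clear_step_gets_dominant_posterior(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([np.full(15, 100.0), np.full(15, 200.0)]) + rng.normal(0, 5, 30)
        r = bcp_posterior(x, seed=3)
        tr = r.posterior_trace
        assert tr[15] >= 0.9
        others = np.delete(tr, [14, 15, 16])
        assert tr[15] >= 5 * np.max(others)

    def test_seeded_runs_are_bit_identical(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([np.full(12, 10.0), np.full(12, 14.0)]) + rng.normal(0, 1, 24)
        a = bcp_posterior(x, seed=11)
        b = bcp_posterior(x, seed=11)
        np.testing.assert_array_equal(a.posterior_trace, b.posterior_trace)

    def test_posterior_matches_long_run_oracle(self):
        """Default-length chain agrees with a 10x longer run of the same
        sampler (the long-run MCMC oracle) at the step position."""
        rng = np.random.default_rng(4)
        x = np.concatenate([np.full(15, 100.0), np.full(15, 200.0)]) + rng.normal(0, 5, 30)
        short = bcp_posterior(x, seed=5)
        long = bcp_posterior(x, iterations=50000, burnin=5000, seed=6)
        assert abs(short.posterior_trace[15] - long.posterior_trace[15]) < 0.05

    def test_contract_violations(self):
        with pytest.raises(InputError):
            bcp_posterior(np.arange(4.0))
        with pytest.raises(InputError):
            bcp_posterior(np.arange(10.0), iterations=100, burnin=100)
        with pytest.raises(InputError):
            bcp_posterior(np.arange(10.0), prior_p0=1.5)


def _res(method, years, scores, yrange=(1965, 2021)):
    return ChangePointResult(
        method=method,
        candidate_years=np.asarray(years, int),
        scores=np.asarray(scores, float),
        years=np.arange(yrange[0], yrange[1] + 1),
    )


class TestConsensus:
    def test_exact_agreement_two_periods(self):
        c = consensus_changepoints(
            _res("bayesian", [2002], [0.9]),
            _res("binseg", [2002], [30.0]),
            year_range=(1965, 2021),
        )
        assert list(c.change_years) == [2002]
        assert c.periods == [(1965, 2001), (2002, 2021)]

    def test_within_tolerance_reports_binseg_year(self):
        c = consensus_changepoints(
            _res("bayesian", [2003], [0.8]),
            _res("binseg", [2002], [30.0]),
            tolerance=1,
            year_range=(1965, 2021),
        )
        assert list(c.change_years) == [2002]

    def test_min_gap_keeps_higher_posterior(self):
        """Enumerating both retention choices for two changes 3 years apart:
        keeping the higher-posterior one is the stated rule."""
        c = consensus_changepoints(
            _res("bayesian", [1990, 1993], [0.9, 0.6]),
            _res("binseg", [1990, 1993], [20.0, 25.0]),
            min_gap=5,
            year_range=(1980, 2000),
        )
        assert list(c.change_years) == [1990]

    def test_unmatched_candidates_are_discarded(self):
        c = consensus_changepoints(
            _res("bayesian", [1990], [0.9]),
            _res("binseg", [1990, 2005], [20.0, 22.0]),
            year_range=(1980, 2015),
        )
        assert list(c.change_years) == [1990]

    def test_empty_candidates_give_single_period(self):
        c = consensus_changepoints(
            _res("bayesian", [], []), _res("binseg", [], []), year_range=(1950, 2000)
        )
        assert c.change_years.size == 0
        assert c.periods == [(1950, 2000)]

    def test_periods_partition_year_range(self):
        c = consensus_changepoints(
            _res("bayesian", [1975, 1990, 2005], [0.7, 0.8, 0.9]),
            _res("binseg", [1974, 1990, 2006], [5.0, 6.0, 7.0]),
            year_range=(1960, 2020),
        )
        total = sum(e - s + 1 for s, e in c.periods)
        assert total == 2020 - 1960 + 1
        for (s1, e1), (s2, e2) in zip(c.periods[:-1], c.periods[1:]):
            assert s2 == e1 + 1
        assert np.all(np.diff(c.change_years) >= 5)
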
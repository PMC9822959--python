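"""Synthetic stock generators with known ground truth.

Every generator returns its data together with a :class:`SimulationTruth`
recording the planted structure (change years, fold bifurcation levels, SRR
regime parameters, temperature threshold), so each pipeline stage can be
tested by parameter recovery without any external assessment data.

The hysteretic stock is a discrete-time harvested population with a strong
Allee effect,

    B_{t+1} = B_t + r*B_t*(B_t/A - 1)*(1 - B_t/K) + iota - f_t*B_t,

multiplied by lognormal process noise and floored at a small extinction
threshold.  With ``allee_A = 0`` the Allee factor is replaced by the plain
logistic ``(1 - B/K)`` and the dynamics are reversible (a single-valued
equilibrium SSB(F) map).  With ``allee_A > 0`` a small immigration/refuge
inflow ``iota`` (default: 1.2x the maximum low-biomass decline rate, so the
collapsed state loses stability at a positive F) creates a genuine fold: the
stock collapses when F exceeds ``collapse_F`` and recovers only once F drops
below ``recovery_F < collapse_F``.  Both bifurcation levels are measured by
numerical equilibrium continuation (forward iteration of the noise-free map
over an F grid), not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError, InputError
from .io import EnvironmentalSeries, SRRDataset, StockAssessmentSeries

__all__ = [
    "SimulationTruth",
    "simulate_stepped_series",
    "simulate_hysteretic_stock",
    "simulate_srr_regimes",
    "simulate_sst_threshold_srr",
    "equilibrium_continuation",
]


@dataclass
class SimulationTruth:
    seed: int
    true_change_years: Optional[np.ndarray] = None
    collapse_F: Optional[float] = None
    recovery_F: Optional[float] = None
    true_srr_params: Optional[list] = None
    true_sst_threshold: Optional[float] = None
    extras: dict = field(default_factory=dict)


def simulate_stepped_series(
    segment_means: Sequence[float],
    segment_lengths: Sequence[int],
    noise_sd: float,
    ar1_rho: float = 0.0,
    seed: int = 0,
    start_year: int = 1960,
):
    """Piecewise-constant mean plus stationary AR(1) Gaussian noise.

    Returns ``(years, values, truth)``; the truth records the first year of
    each new segment.  Noise has marginal standard deviation ``noise_sd`` and
    lag-1 autocorrelation ``ar1_rho``.
    """
    means = np.asarray(segment_means, dtype=float)
    lengths = np.asarray(segment_lengths, dtype=int)
    if means.size != lengths.size or means.size == 0:
        raise InputError("segment_means and segment_lengths must be equal-length, non-empty")
    if np.any(lengths < 5):
        raise InputError("every segment must span at least 5 years")
    if not abs(ar1_rho) < 1:
        raise InputError("|ar1_rho| must be < 1")
    rng = np.random.default_rng(seed)
    n = int(np.sum(lengths))
    signal = np.repeat(means, lengths)
    e = np.empty(n)
    z = rng.standard_normal(n)
    e[0] = noise_sd * z[0]
    innov_sd = noise_sd * np.sqrt(1.0 - ar1_rho**2)
    for t in range(1, n):
        e[t] = ar1_rho * e[t - 1] + innov_sd * z[t]
    years = start_year + np.arange(n)
    change_years = start_year + np.cumsum(lengths)[:-1]
    truth = SimulationTruth(seed=seed, true_change_years=np.asarray(change_years, dtype=int))
    return years, signal + e, truth


def _growth(B, r, K, A, iota):
    if A > 0:
        return r * B * (B / A - 1.0) * (1.0 - B / K) + iota
    return r * B * (1.0 - B / K) + iota


def _default_immigration(r: float, K: float, A: float) -> float:
    if A <= 0:
        return 0.0
    # 1.2x the worst-case decline rate below the Allee threshold, so the
    # collapsed branch loses stability at a positive F (a genuine fold)
    b = np.linspace(1e-6 * K, A, 512)
    decline = r * b * (1.0 - b / A) * (1.0 - b / K)
    return 1.2 * float(np.max(decline))


_CONTINUATION_CACHE: dict = {}


def equilibrium_continuation(
    r: float,
    K: float,
    allee_A: float,
    immigration: float,
    floor: float,
    f_resolution: float = 1e-3,
    n_iter: int = 3000,
):
    """Numerically locate collapse_F and recovery_F of the noise-free map.

    For every F on a grid of step ``f_resolution`` the map is iterated from the
    carrying capacity (upper branch) and from the extinction floor (lower
    branch); a branch counts as 'high' when it settles above the Allee
    threshold (above K/2 for the reversible logistic).  collapse_F is the
    largest F keeping the upper branch high; recovery_F the largest F at which
    the lower start still reaches the high state.
    """
    key = (round(r, 12), round(K, 12), round(allee_A, 12), round(immigration, 12), round(floor, 15), f_resolution, n_iter)
    if key in _CONTINUATION_CACHE:
        return _CONTINUATION_CACHE[key]
    f_max = 1.5 * r + 0.1
    fgrid = np.arange(0.0, f_max + f_resolution, f_resolution)
    ref = allee_A if allee_A > 0 else 0.5 * K

    def settle(B0):
        B = np.full(fgrid.size, B0)
        for _ in range(n_iter):
            B = B + _growth(B, r, K, allee_A, immigration) - fgrid * B
            B = np.clip(B, floor, 5.0 * K)
        return B

    b_up = settle(float(K))
    b_low = settle(float(floor))
    high_up = b_up > ref
    high_low = b_low > ref
    collapse_F = float(fgrid[high_up][-1]) if np.any(high_up) else 0.0
    recovery_F = float(fgrid[high_low][-1]) if np.any(high_low) else 0.0
    result = (collapse_F, recovery_F, fgrid, b_up, b_low)
    _CONTINUATION_CACHE[key] = result
    return result


def simulate_hysteretic_stock(
    r_growth: float,
    K: float,
    allee_A: float,
    f_path: Sequence[float],
    process_sd: float = 0.0,
    seed: int = 0,
    B0: Optional[float] = None,
    immigration: Optional[float] = None,
    ricker_alpha: float = 1.0,
    ricker_beta: Optional[float] = None,
    recruitment_sd: float = 0.0,
    recruitment_age: int = 1,
    start_year: int = 1960,
    extinction_floor_frac: float = 1e-6,
    stock_id: str = "synthetic-allee",
    f_resolution: float = 1e-3,
):
    """Simulate a harvested stock with (optional) Allee-driven hysteresis.

    Recruitment is emitted through a Ricker SRR applied to the biomass in the
    spawn year and reported, assessment-style, at ``recruitment_age`` years
    later.  Returns ``(StockAssessmentSeries, SimulationTruth)``.
    """
    f_path = np.asarray(f_path, dtype=float)
    if np.any(f_path < 0):
        raise InputError("f_path must be non-negative")
    if not 0 <= allee_A < K:
        raise InputError("need 0 <= allee_A < K")
    floor = extinction_floor_frac * K
    iota = _default_immigration(r_growth, K, allee_A) if immigration is None else float(immigration)
    B0 = float(K) if B0 is None else float(B0)
    if not (allee_A < B0 <= K):
        raise InputError("B0 must lie in (allee_A, K]")
    collapse_F, recovery_F, *_ = equilibrium_continuation(
        r_growth, K, allee_A, iota, floor, f_resolution=f_resolution
    )
    if collapse_F <= 0:
        raise ConfigurationError("no positive high-biomass equilibrium at F = 0")
    rng = np.random.default_rng(seed)
    n = f_path.size
    B = np.empty(n)
    B[0] = B0
    noise = np.exp(process_sd * rng.standard_normal(n)) if process_sd > 0 else np.ones(n)
    for t in range(n - 1):
        nxt = B[t] + _growth(B[t], r_growth, K, allee_A, iota) - f_path[t] * B[t]
        B[t + 1] = max(floor, nxt * noise[t + 1])
    beta = 1.0 / K if ricker_beta is None else float(ricker_beta)
    r_noise = (
        np.exp(recruitment_sd * rng.standard_normal(n)) if recruitment_sd > 0 else np.ones(n)
    )
    recruits_spawn = B * np.exp(ricker_alpha - beta * B) * r_noise
    a = int(recruitment_age)
    recruitment = np.full(n, np.nan)
    if a == 0:
        recruitment[:] = recruits_spawn
    else:
        recruitment[a:] = recruits_spawn[: n - a]
    years = start_year + np.arange(n)
    series = StockAssessmentSeries(
        stock_id=stock_id,
        years=years,
        ssb=B,
        recruitment=recruitment,
        fmort=f_path,
        recruitment_age=a,
    )
    truth = SimulationTruth(
        seed=seed,
        collapse_F=collapse_F,
        recovery_F=recovery_F,
        true_srr_params=[(ricker_alpha, beta, None)],
        extras={
            "immigration": iota,
            "extinction_floor": floor,
            "f_grid_resolution": f_resolution,
            "allee_A": allee_A,
            "K": K,
            "r_growth": r_growth,
        },
    )
    return series, truth


def simulate_srr_regimes(
    alphas: Sequence[float],
    betas: Sequence[float],
    regime_years: Sequence[int],
    s_path: Sequence[float],
    lognorm_sd: float = 0.0,
    seed: int = 0,
):
    """Recruitment from regime-dependent Ricker SRRs with lognormal noise.

    ``regime_years`` gives the first year of each regime (the first entry is
    the start of the span); ``s_path`` supplies the parent biomass for every
    year of the span.  Returns ``(SRRDataset, SimulationTruth)``.
    """
    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    starts = np.asarray(regime_years, dtype=int)
    s = np.asarray(s_path, dtype=float)
    if not (alphas.size == betas.size == starts.size) or alphas.size == 0:
        raise InputError("alphas, betas and regime_years must be equal-length, non-empty")
    if np.any(alphas <= 0):
        raise InputError("Ricker alpha must be positive in every regime")
    if np.any(np.diff(starts) <= 0):
        raise InputError("regime start years must be strictly increasing")
    years = starts[0] + np.arange(s.size)
    if starts[-1] > years[-1]:
        raise InputError("last regime starts after the simulated span ends")
    rng = np.random.default_rng(seed)
    regime = np.searchsorted(starts, years, side="right") - 1
    noise = np.exp(lognorm_sd * rng.standard_normal(s.size)) if lognorm_sd > 0 else 1.0
    r = s * np.exp(alphas[regime] - betas[regime] * s) * noise
    truth = SimulationTruth(
        seed=seed,
        true_change_years=starts[1:].copy(),
        true_srr_params=[
            (float(a), float(b), int(yr)) for a, b, yr in zip(alphas, betas, starts)
        ],
    )
    return SRRDataset(spawn_years=years, s=s, r=r), truth


def simulate_diagnostic_stock(seed: int = 0, with_effects: bool = True):
    """Canonical end-to-end scenario for the four-flag pipeline.

    ``with_effects=True`` plants every diagnostic signature at once: a strong
    Allee effect with an F ramp over the fold (abrupt SSB changes + a closed
    hysteresis loop), and recruitment from an SST-switched SRR (dome-shaped
    Ricker below the 12 degC threshold, flat and weak above it) driven by a
    warming SST trend that crosses the threshold mid-series -- so the SRR is
    also non-stationary in time.  ``with_effects=False`` is the matched null:
    reversible logistic dynamics under gently varying F, a single stationary
    Ricker SRR, and SST with no effect.

    Returns ``(StockAssessmentSeries, EnvironmentalSeries, SimulationTruth)``.
    """
    K = 1000.0
    r_growth = 0.5
    n_pre, n_up, n_down, n_hold = 20, 40, 40, 40
    n = n_pre + n_up + n_down + n_hold
    start_year = 1920
    rng = np.random.default_rng([int(seed), 77])
    if with_effects:
        A = 0.2 * K
        iota = _default_immigration(r_growth, K, A)
        collapse_F, _, *_ = equilibrium_continuation(r_growth, K, A, iota, 1e-6 * K)
        f_path = np.concatenate(
            [
                np.zeros(n_pre),
                np.linspace(0.0, 1.2 * collapse_F, n_up),
                np.linspace(1.2 * collapse_F, 0.0, n_down),
                np.zeros(n_hold),
            ]
        )
        series, truth = simulate_hysteretic_stock(
            r_growth,
            K,
            A,
            f_path,
            process_sd=0.05,
            seed=seed,
            recruitment_age=1,
            start_year=start_year,
            stock_id="synthetic-all-effects",
        )
        # warming trend crossing the 12 degC threshold around year 40, i.e.
        # while the stock is still on the (densely sampled) upper branch: the
        # cold regime is then a strong linear SSB->R relationship over the
        # pre-collapse biomass cluster, the warm regime a weak dome over the
        # full collapse-and-recovery biomass range -- regimes that differ in
        # slope, shape (edf) and level, as a genuine temperature threshold
        # the two regime curves intersect at the biomass level the stock holds
        # when SST crosses the threshold (~750 t), so the inevitable boundary
        # years carry no information either way; they diverge strongly over the
        # rest of the biomass range
        sst_threshold = 12.0
        sst = np.linspace(10.0, 17.0, n) + rng.normal(0.0, 0.15, n)
        below = sst <= sst_threshold
        alpha = np.where(below, -0.45, 1.8)
        beta = np.where(below, 0.0, 3.0 / K)
        # additive (homoscedastic) recruitment error: GCV-based smoothing, which
        # assumes constant error variance, is what the temperature flag runs on
        spawn_r = series.ssb * np.exp(alpha - beta * series.ssb)
        spawn_r = np.maximum(spawn_r + 60.0 * rng.standard_normal(n), 5.0)
        recruitment = np.full(n, np.nan)
        recruitment[1:] = spawn_r[:-1]
        series = series.with_values(recruitment=recruitment)
        truth.true_sst_threshold = sst_threshold
        truth.true_srr_params = [
            (-0.45, 0.0, "sst<=threshold"),
            (1.8, 3.0 / K, "sst>threshold"),
        ]
        truth.extras["sst_trend"] = (10.0, 17.0)
    else:
        # gently varying pressure: enough F variance for the lag search, too
        # little to move the equilibrium detectably relative to process noise
        e = np.empty(n)
        z = rng.standard_normal(n)
        e[0] = z[0]
        for t in range(1, n):
            e[t] = 0.6 * e[t - 1] + 0.8 * z[t]
        f_path = np.clip(0.15 + 0.01 * e, 0.0, None)
        series, truth = simulate_hysteretic_stock(
            r_growth,
            K,
            0.0,
            f_path,
            process_sd=0.02,
            seed=seed,
            ricker_alpha=1.2,
            ricker_beta=1.0 / K,
            recruitment_sd=0.10,
            recruitment_age=1,
            start_year=start_year,
            stock_id="synthetic-null",
        )
        # survey/assessment observation error: white on top of the (slow,
        # autocorrelated) population dynamics, as in real assessment output
        series = series.with_values(
            ssb=series.ssb * np.exp(0.05 * rng.standard_normal(n))
        )
        sst = rng.uniform(10.0, 14.0, n)
    env = EnvironmentalSeries(years=series.years, sst=sst)
    return series, env, truth


def simulate_sst_threshold_srr(
    threshold: float = 12.0,
    slope_below: float = 2.0,
    slope_above: float = 0.5,
    sst_range: tuple = (8.0, 16.0),
    n: int = 60,
    noise_sd: float = 50.0,
    seed: int = 0,
    s_range: tuple = (200.0, 2000.0),
    start_year: int = 1960,
):
    """SRR whose slope switches at an SST threshold: r = slope(regime)*s + noise.

    SST is uniform over ``sst_range`` and parent biomass uniform over
    ``s_range``; recruitment is floored just above zero (the linear-plus-noise
    construction can otherwise stray negative at the smallest biomasses).
    Returns ``(SRRDataset, EnvironmentalSeries, SimulationTruth)``.
    """
    if not sst_range[0] < threshold < sst_range[1]:
        raise InputError("threshold must lie strictly inside sst_range")
    if n < 30:
        raise InputError("need n >= 30")
    rng = np.random.default_rng(seed)
    sst = rng.uniform(sst_range[0], sst_range[1], size=n)
    s = rng.uniform(s_range[0], s_range[1], size=n)
    slope = np.where(sst <= threshold, slope_below, slope_above)
    r = slope * s + (noise_sd * rng.standard_normal(n) if noise_sd > 0 else 0.0)
    r = np.maximum(r, 1e-6)
    years = start_year + np.arange(n)
    truth = SimulationTruth(
        seed=seed,
        true_sst_threshold=float(threshold),
        extras={"slope_below": slope_below, "slope_above": slope_above},
    )
    return (
        SRRDataset(spawn_years=years, s=s, r=r),
        EnvironmentalSeries(years=years, sst=sst),
        truth,
    )
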
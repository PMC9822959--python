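"""Hysteresis diagnosis in the lagged F -> SSB relationship (regime-shift flag 2).

Workflow: (1) choose the lag at which fishing mortality best explains SSB by
cross-correlation; (2) locate structural breaks in the temporal sequence of
(F_{t-n}, SSB_t) pairs by an exact dynamic-programming multiple-break
regression (Bai-Perron style, break count by BIC); (3) classify the trajectory
as showing no hysteresis, a closed loop (recovery along a different path) or
an open loop (no recovery although pressure returned to historical levels).

The loop classifier splits the trajectory at the year of maximum smoothed F
into an ascending-pressure and a descending-pressure branch, matches the
branches over their shared F range in equal-width F bins, and requires both a
Welch-test significant branch difference and a practically large branch gap
(>= ``gap_min_frac`` of the SSB range) before calling a loop, so sampling noise
alone cannot trigger a hysteresis call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import InputError
from .io import StockAssessmentSeries

__all__ = [
    "LagSelection",
    "BreakpointModel",
    "HysteresisAssessment",
    "select_lag",
    "baiperron_breakpoints",
    "enumerate_breakpoints",
    "fit_fssb_breakpoints",
    "classify_hysteresis",
]


@dataclass
class LagSelection:
    """Lag n (years) pairing F_{t-n} with SSB_t, chosen by cross-correlation."""

    lag: int
    correlation: float
    correlogram: np.ndarray  # correlation at lags 0..max_lag


@dataclass
class BreakpointModel:
    """Piecewise linear regression with m breaks in observation order."""

    n_breaks: int
    break_indices: np.ndarray  # first observation index of each new segment
    segment_coefficients: list  # (intercept, slope) per segment; slope None if degenerate
    rss: float
    information_criterion: dict  # m -> BIC value
    rss_by_m: dict = field(default_factory=dict)
    degenerate_segments: list = field(default_factory=list)
    break_years: Optional[np.ndarray] = None

    @property
    def segment_slopes(self):
        return [c[1] for c in self.segment_coefficients]


@dataclass
class HysteresisAssessment:
    classification: str  # none | closed_loop | open_loop | indeterminate
    branch_gap: float
    segments_sign_pattern: list
    p_value: Optional[float] = None
    reason: str = ""
    peak_year: Optional[int] = None
    n_matched_bins: int = 0


def select_lag(fmort: Sequence[float], ssb: Sequence[float], max_lag: int = 10) -> LagSelection:
    """Cross-correlation of F leading SSB at lags 0..max_lag.

    For lag n the pairs are (F_{t-n}, SSB_t); each lag's correlation is the
    Pearson correlation over the overlap.  The lag with maximal |correlation|
    wins; ties break toward the smaller lag.
    """
    f = np.asarray(fmort, dtype=float)
    b = np.asarray(ssb, dtype=float)
    if f.size != b.size:
        raise InputError("fmort and ssb must have equal length")
    if max_lag < 0:
        raise InputError("max_lag must be >= 0")
    if f.size - max_lag < 10:
        raise InputError("overlap after lagging must be at least 10 observations")
    cors = np.empty(max_lag + 1)
    for n in range(max_lag + 1):
        x = f[: f.size - n] if n > 0 else f
        y = b[n:]
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 10:
            raise InputError(f"overlap at lag {n} has fewer than 10 complete pairs")
        if np.std(x) == 0 or np.std(y) == 0:
            raise InputError("zero-variance input in cross-correlation")
        cors[n] = np.corrcoef(x, y)[0, 1]
    lag = int(np.argmax(np.abs(cors)))  # argmax returns the first (smallest) maximizer
    return LagSelection(lag=lag, correlation=float(cors[lag]), correlogram=cors)


def _segment_cost_matrix(x: np.ndarray, y: np.ndarray, min_seg: int):
    """cost[a, b] = OLS RSS of y on x over observations a..b inclusive.

    Computed from prefix sums in O(n^2); degenerate segments (no predictor
    variance) fall back to intercept-only RSS and are flagged.
    """
    n = x.size
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    cost = np.full((n, n), np.inf)
    degen = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + min_seg - 1, n):
            m = b - a + 1
            sx = cx[b + 1] - cx[a]
            sy = cy[b + 1] - cy[a]
            sxx = cxx[b + 1] - cxx[a] - sx * sx / m
            syy = cyy[b + 1] - cyy[a] - sy * sy / m
            sxy = cxy[b + 1] - cxy[a] - sx * sy / m
            if sxx <= 1e-12 * max(cxx[b + 1] - cxx[a], 1.0):
                cost[a, b] = max(syy, 0.0)
                degen[a, b] = True
            else:
                cost[a, b] = max(syy - sxy * sxy / sxx, 0.0)
    return cost, degen


def _ols_segment(x, y):
    if x.size >= 2 and np.ptp(x) > 1e-12 * max(np.max(np.abs(x)), 1.0):
        slope, intercept = np.polyfit(x, y, 1)
        return float(intercept), float(slope)
    return float(np.mean(y)), None


def baiperron_breakpoints(
    x: Sequence[float],
    y: Sequence[float],
    max_breaks: int = 3,
    min_segment_fraction: float = 0.15,
    years: Optional[Sequence[int]] = None,
) -> BreakpointModel:
    """Exact multiple-structural-break regression of y on x in observation order.

    Dynamic programming finds, for each m <= max_breaks, the segmentation
    minimizing total per-segment OLS RSS (each segment at least
    ``max(3, ceil(min_segment_fraction * n))`` observations); m is then chosen
    by BIC with ``2(m+1) + m`` parameters.  Deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise InputError("x and y must have equal length")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise InputError("non-finite values in breakpoint regression input")
    min_seg = max(3, int(np.ceil(min_segment_fraction * n)))
    if n < (max_breaks + 1) * min_seg:
        max_breaks = n // min_seg - 1
        if max_breaks < 0:
            raise InputError(f"series of length {n} too short for one segment of {min_seg}")

    cost, degen = _segment_cost_matrix(x, y, min_seg)
    # dp[m][b] = min total RSS over obs 0..b using m breaks; b is last index
    dp = np.full((max_breaks + 1, n), np.inf)
    arg = np.full((max_breaks + 1, n), -1, dtype=int)
    dp[0] = cost[0]
    for m in range(1, max_breaks + 1):
        for b in range((m + 1) * min_seg - 1, n):
            # last segment starts at j; previous part ends at j-1
            best, bestj = np.inf, -1
            for j in range(m * min_seg, b - min_seg + 2):
                v = dp[m - 1][j - 1] + cost[j, b]
                if v < best - 1e-12:
                    best, bestj = v, j
            dp[m][b] = best
            arg[m][b] = bestj

    rss_by_m, bic_by_m = {}, {}
    for m in range(max_breaks + 1):
        rss = dp[m][n - 1]
        if not np.isfinite(rss):
            continue
        rss_by_m[m] = float(rss)
        p = 2 * (m + 1) + m
        bic_by_m[m] = float(n * np.log(max(rss, 1e-300) / n) + p * np.log(n))
    m_star = min(bic_by_m, key=lambda m: (bic_by_m[m], m))

    # backtrack break positions for m_star
    breaks = []
    b = n - 1
    for m in range(m_star, 0, -1):
        j = arg[m][b]
        breaks.append(j)
        b = j - 1
    breaks = sorted(breaks)

    bounds = [0] + breaks + [n]
    coefs, degs = [], []
    for k, (a, bnd) in enumerate(zip(bounds[:-1], bounds[1:])):
        icpt, slope = _ols_segment(x[a:bnd], y[a:bnd])
        coefs.append((icpt, slope))
        if slope is None:
            degs.append(k)
    yrs = None if years is None else np.asarray(years, dtype=int)
    return BreakpointModel(
        n_breaks=m_star,
        break_indices=np.array(breaks, dtype=int),
        segment_coefficients=coefs,
        rss=rss_by_m[m_star],
        information_criterion=bic_by_m,
        rss_by_m=rss_by_m,
        degenerate_segments=degs,
        break_years=None if yrs is None else yrs[np.array(breaks, dtype=int)]
        if breaks
        else np.array([], dtype=int),
    )


def enumerate_breakpoints(x, y, n_breaks, min_segment_fraction=0.15):
    """Brute-force oracle: exhaustive search over all admissible placements of
    exactly ``n_breaks`` breaks, returning (positions, total RSS)."""
    import itertools

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    min_seg = max(3, int(np.ceil(min_segment_fraction * n)))
    cost, _ = _segment_cost_matrix(x, y, min_seg)
    if n_breaks == 0:
        return (), float(cost[0, n - 1])
    best = None
    for combo in itertools.combinations(range(min_seg, n - min_seg + 1), n_breaks):
        bounds = (0,) + combo + (n,)
        if any(b - a < min_seg for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        rss = sum(cost[a, b - 1] for a, b in zip(bounds[:-1], bounds[1:]))
        if best is None or rss < best[1] - 1e-12:
            best = (combo, float(rss))
    if best is None:
        raise InputError("no admissible segmentation")
    return best


def _lagged_pairs(series: StockAssessmentSeries, lag: int):
    f = series.fmort
    b = series.ssb
    n = len(series)
    x = f[: n - lag] if lag > 0 else f
    y = b[lag:]
    yrs = series.years[lag:]
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok], yrs[ok]


def fit_fssb_breakpoints(
    series: StockAssessmentSeries, lag: LagSelection, max_breaks: int = 3
) -> BreakpointModel:
    """Structural breaks of SSB_t on F_{t-n} in temporal order.

    Breaks mark temporal phase changes of the pressure-state relationship, not
    thresholds on the F axis.
    """
    x, y, yrs = _lagged_pairs(series, lag.lag)
    if x.size < 15:
        raise InputError("need at least 15 lagged (F, SSB) pairs")
    return baiperron_breakpoints(x, y, max_breaks=max_breaks, years=yrs)


def _smooth(values: np.ndarray, window: int = 5) -> np.ndarray:
    half = window // 2
    out = np.empty_like(values)
    for i in range(values.size):
        lo, hi = max(0, i - half), min(values.size, i + half + 1)
        seg = values[lo:hi]
        out[i] = np.nanmean(seg) if np.any(np.isfinite(seg)) else np.nan
    return out


def classify_hysteresis(
    series: StockAssessmentSeries,
    lag: LagSelection,
    breaks: Optional[BreakpointModel] = None,
    alpha: float = 0.05,
    n_bins: int = 5,
    gap_min_frac: float = 0.10,
    final_window: int = 5,
) -> HysteresisAssessment:
    """Classify the lagged F-SSB trajectory as none / closed_loop / open_loop.

    The trajectory splits at the year of maximum smoothed F into an
    ascending-pressure branch (path to depletion) and a descending-pressure
    branch (recovery path).  Over their shared F range (``n_bins`` equal-width
    bins, only bins populated by both branches) a loop requires the branch SSB
    difference to be Welch-significant at ``alpha`` *and* at least
    ``gap_min_frac`` of the observed SSB range.  A significant loop is *closed*
    if the final ``final_window`` years' mean SSB re-enters the pre-collapse SSB
    range, *open* if it stays below the pre-collapse minimum although F has
    returned to (or below) the level that previously sustained that biomass.
    """
    sign_pattern = []
    if breaks is not None:
        sign_pattern = [
            0 if c[1] is None else int(np.sign(c[1])) for c in breaks.segment_coefficients
        ]

    x, y, yrs = _lagged_pairs(series, lag.lag)
    if x.size < 12:
        raise InputError("too few lagged pairs to classify hysteresis")

    f_smooth = _smooth(x)
    peak = int(np.argmax(f_smooth))
    asc = slice(0, peak + 1)
    desc = slice(peak + 1, x.size)
    if x[desc].size < 5 or x[asc].size < 5:
        return HysteresisAssessment(
            classification="none",
            branch_gap=0.0,
            segments_sign_pattern=sign_pattern,
            reason="monotone pressure",
            peak_year=int(yrs[peak]),
        )

    f_lo = max(np.min(x[asc]), np.min(x[desc]))
    f_hi = min(np.max(x[asc]), np.max(x[desc]))
    if not f_hi > f_lo:
        return HysteresisAssessment(
            classification="indeterminate",
            branch_gap=0.0,
            segments_sign_pattern=sign_pattern,
            reason="no shared F range between branches",
            peak_year=int(yrs[peak]),
        )
    edges = np.linspace(f_lo, f_hi, n_bins + 1)
    asc_vals, desc_vals, gaps = [], [], []
    matched = 0
    for k in range(n_bins):
        lo, hi = edges[k], edges[k + 1]

        def sel(xx, lo=lo, hi=hi, last=(k == n_bins - 1)):
            return (xx >= lo) & ((xx <= hi) if last else (xx < hi))

        a_v = y[asc][sel(x[asc])]
        d_v = y[desc][sel(x[desc])]
        if a_v.size and d_v.size:
            matched += 1
            asc_vals.append(a_v)
            desc_vals.append(d_v)
            gaps.append(np.mean(a_v) - np.mean(d_v))
    if matched < n_bins:
        return HysteresisAssessment(
            classification="indeterminate",
            branch_gap=float(np.mean(gaps)) if gaps else 0.0,
            segments_sign_pattern=sign_pattern,
            reason=f"branches overlap in only {matched} of {n_bins} F bins",
            peak_year=int(yrs[peak]),
            n_matched_bins=matched,
        )

    a_all = np.concatenate(asc_vals)
    d_all = np.concatenate(desc_vals)
    branch_gap = float(np.mean(gaps))
    tt = stats.ttest_ind(a_all, d_all, equal_var=False)
    p = float(tt.pvalue)
    ssb_range = float(np.nanmax(series.ssb) - np.nanmin(series.ssb))

    significant = p < alpha and abs(branch_gap) >= gap_min_frac * ssb_range
    if not significant:
        return HysteresisAssessment(
            classification="none",
            branch_gap=branch_gap,
            segments_sign_pattern=sign_pattern,
            p_value=p,
            reason="branch difference not significant" if p >= alpha else "branch gap below practical threshold",
            peak_year=int(yrs[peak]),
            n_matched_bins=matched,
        )

    # pre-collapse period: the ascending branch until SSB first falls below
    # half of its running maximum (the collapse itself happens on the way up
    # once F crosses the fold, and must not contaminate the reference range)
    y_asc = y[asc]
    x_asc = x[asc]
    run_max = np.maximum.accumulate(y_asc)
    collapsed = np.nonzero(y_asc < 0.5 * run_max)[0]
    cut = int(collapsed[0]) if collapsed.size else y_asc.size
    cut = max(cut, 2)
    pre_y, pre_x = y_asc[:cut], x_asc[:cut]
    pre_min = float(np.min(pre_y))
    w = min(final_window, y.size)
    final_ssb = float(np.mean(y[-w:]))
    final_f = float(np.mean(x[-w:]))
    if final_ssb >= pre_min:
        cls, reason = "closed_loop", "final SSB re-entered the pre-collapse range"
    else:
        sustained = pre_x[pre_y >= final_ssb]
        f_ref = float(np.max(sustained)) if sustained.size else float(np.min(pre_x))
        if final_f <= f_ref:
            cls, reason = "open_loop", (
                "final SSB below the pre-collapse minimum although F returned to a level "
                "that previously sustained higher biomass"
            )
        else:
            cls, reason = "none", "final SSB low but pressure never returned to historical levels"
    return HysteresisAssessment(
        classification=cls,
        branch_gap=branch_gap,
        segments_sign_pattern=sign_pattern,
        p_value=p,
        reason=reason,
        peak_year=int(yrs[peak]),
        n_matched_bins=matched,
    )
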
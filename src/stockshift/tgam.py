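"""Penalized-spline GAMs and threshold-GAMs for temperature effects on the SRR.

The smooth is a P-spline: uniform (unclamped) cubic B-spline basis of dimension
``k`` with a second-difference penalty on the coefficients, the smoothing
parameter chosen by minimizing GCV = n*RSS/(n - tr(S))^2 over a log-spaced
grid (ties resolve to the smoothest fit).  Because the knots are uniform, the
penalty null space is exactly the linear functions, so the heavily penalized
limit is the least-squares line.  Reported ``edf`` follows the convention that
1 means a linear relationship: edf = tr(S) - 1 (the GCV denominator uses the
full trace).

A threshold GAM (tGAM) splits the recruitment-on-SSB smooth into two regimes
according to whether annual SST is below or above a candidate threshold; the
threshold is chosen by minimizing the joint GCV over a grid of candidates
between the lower and upper SST quantiles (defaults 0.2 and 0.8).  The tGAM is
accepted as evidence of a temperature threshold only if it beats the plain GAM
under leave-one-out cross-validation (threshold re-selected in every fold) and
three further criteria hold: the regime edfs differ, at least one regime slope
is significant, and the GCV profile shows a deep valley at the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

from .exceptions import DecisionError, InputError, ThresholdSearchError
from .io import EnvironmentalSeries, SRRDataset

__all__ = [
    "GamFit",
    "ThresholdGamFit",
    "TGamDecision",
    "fit_pspline_gam",
    "fit_threshold_gam",
    "loocv_tgam_vs_gam",
    "evaluate_threshold_criteria",
    "decide_tgam",
]

DEFAULT_LAMBDA_GRID = np.logspace(-6.0, 8.0, 57)


def _uniform_knots(x_lo: float, x_hi: float, k: int, degree: int) -> np.ndarray:
    """Uniform B-spline knots giving exactly k basis functions over [x_lo, x_hi]."""
    nseg = k - degree
    if nseg < 1:
        raise InputError(f"basis dimension {k} too small for degree {degree}")
    h = (x_hi - x_lo) / nseg
    return x_lo + h * np.arange(-degree, nseg + degree + 1)


def _design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    eps = 1e-9 * max(knots[-1] - knots[0], 1.0)
    xc = np.clip(x, knots[degree] + 0 * eps, knots[-degree - 1] - eps)
    return BSpline.design_matrix(xc, knots, degree).toarray()


def _second_diff(k: int) -> np.ndarray:
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D


def _penalized_profile(B: np.ndarray, y: np.ndarray, D: np.ndarray, lam_grid: np.ndarray):
    """Per-lambda (trace, RSS, GCV) for the penalized LS fit, via a generalized
    eigendecomposition so the whole grid costs one k x k eigenproblem."""
    n, k = B.shape
    A = B.T @ B
    A_r = A + (1e-10 * np.trace(A) / k + 1e-300) * np.eye(k)
    L = np.linalg.cholesky(A_r)
    Linv = np.linalg.inv(L)
    M = Linv @ (D.T @ D) @ Linv.T
    mu, U = np.linalg.eigh((M + M.T) / 2.0)
    mu = np.clip(mu, 0.0, None)
    c = U.T @ (Linv @ (B.T @ y))
    yty = float(y @ y)
    denom = 1.0 + lam_grid[:, None] * mu[None, :]
    trace = np.sum(1.0 / denom, axis=1)
    bty = np.sum(c**2 / denom, axis=1)
    quad = np.sum(c**2 / denom**2, axis=1)
    rss = np.clip(yty - 2.0 * bty + quad, 0.0, None)
    gcv = n * rss / (n - trace) ** 2
    return trace, rss, gcv, (L, U, mu, c)


GCV_FLAT_TOL = 5e-3


def _select_lambda(gcv: np.ndarray, yty: float, n: int) -> int:
    """Index of the selected smoothing parameter.

    GCV profiles are typically flat near their minimum; among the grid points
    whose GCV lies within ``GCV_FLAT_TOL`` (0.5%) of the minimum the smoothest
    fit (largest lambda) is taken.  This also resolves exact ties (e.g. data
    in the penalty null space, where every lambda fits perfectly).
    """
    best = float(np.min(gcv))
    tol = GCV_FLAT_TOL * best + 1e-12 * (yty + 1.0) / max(n, 1)
    idx = np.nonzero(gcv <= best + tol)[0]
    return int(idx[-1])


@dataclass
class GamFit:
    """A fitted penalized-spline smooth of one predictor."""

    basis_dim: int
    coefficients: np.ndarray
    lambda_: float
    edf: float  # trace(S) - 1; 1 = linear
    gcv: float
    fitted: np.ndarray
    trace: float
    rss: float
    knots: np.ndarray = field(repr=False, default=None)
    degree: int = 3
    n_obs: int = 0

    def predict(self, x_new) -> np.ndarray:
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        return _design(x_new, self.knots, self.degree) @ self.coefficients


def _fit_gam_basis(
    B: np.ndarray,
    y: np.ndarray,
    knots: np.ndarray,
    degree: int,
    lam_grid: np.ndarray,
) -> GamFit:
    n, k = B.shape
    trace, rss, gcv, (L, U, mu, c) = _penalized_profile(B, y, _second_diff(k), lam_grid)
    j = _select_lambda(gcv, float(y @ y), n)
    beta = np.linalg.solve(L.T, U @ (c / (1.0 + lam_grid[j] * mu)))
    fitted = B @ beta
    return GamFit(
        basis_dim=k,
        coefficients=beta,
        lambda_=float(lam_grid[j]),
        edf=float(trace[j] - 1.0),
        gcv=float(gcv[j]),
        fitted=fitted,
        trace=float(trace[j]),
        rss=float(rss[j]),
        knots=knots,
        degree=degree,
        n_obs=n,
    )


def fit_pspline_gam(
    x: Sequence[float],
    y: Sequence[float],
    k: int = 3,
    lambda_grid: Optional[np.ndarray] = None,
) -> GamFit:
    """Penalized B-spline smooth of y on x with GCV-selected smoothing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    n = x.size
    if k < 3:
        raise InputError("basis dimension k must be >= 3")
    if n < k + 2:
        raise InputError(f"need at least k + 2 = {k + 2} observations, got {n}")
    if np.ptp(x) <= 0:
        raise InputError("all x values are equal: degenerate smooth")
    lam = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    degree = 3 if k >= 4 else k - 1
    knots = _uniform_knots(float(np.min(x)), float(np.max(x)), k, degree)
    B = _design(x, knots, degree)
    return _fit_gam_basis(B, y, knots, degree, lam)


@dataclass
class ThresholdGamFit:
    threshold: float
    below_smooth: GamFit
    above_smooth: GamFit
    gcv_profile: np.ndarray  # columns: candidate threshold, joint GCV
    edf_below: float
    edf_above: float
    slope_p_below: float
    slope_p_above: float
    gcv: float
    n_below: int
    n_above: int
    resid_acf1: float = float("nan")
    years: Optional[np.ndarray] = None


def _trend_p(s: np.ndarray, pred: np.ndarray) -> float:
    """Wald p of the linear trend through a regime's smooth predictions.

    Degenerate residuals (an exactly linear smooth) give p = 0 for a nonzero
    trend and p = 1 for an exactly flat one.
    """
    n = s.size
    sbar = np.mean(s)
    sxx = float(np.sum((s - sbar) ** 2))
    if sxx <= 0 or n < 3:
        return 1.0
    slope = float(np.sum((s - sbar) * (pred - np.mean(pred))) / sxx)
    resid = pred - (np.mean(pred) + slope * (s - sbar))
    sigma2 = float(resid @ resid) / (n - 2)
    scale = float(np.mean(pred**2)) + 1.0
    if sigma2 <= 1e-14 * scale:
        return 0.0 if abs(slope) * np.sqrt(sxx) > 1e-7 * np.sqrt(scale) else 1.0
    se = np.sqrt(sigma2 / sxx)
    return float(2 * stats.t.sf(abs(slope) / se, n - 2))


def _join(srr: SRRDataset, env: EnvironmentalSeries):
    common, ia, ib = np.intersect1d(srr.spawn_years, env.years, return_indices=True)
    return common, srr.s[ia], srr.r[ia], env.sst[ib]


def fit_threshold_gam(
    srr: SRRDataset,
    env: EnvironmentalSeries,
    k: int = 4,
    lower_q: float = 0.2,
    upper_q: float = 0.8,
    grid_size: int = 20,
    min_regime: int = 5,
    lambda_grid: Optional[np.ndarray] = None,
) -> ThresholdGamFit:
    """Two-regime SSB->R smooth split by an SST threshold chosen by GCV.

    For each of ``grid_size`` evenly spaced candidate thresholds between the
    ``lower_q`` and ``upper_q`` SST quantiles, the observations are partitioned
    by SST <=/> candidate and a separate k-dimensional smooth of R on SSB is
    fitted per regime (each smoothing parameter by GCV); the joint GCV
    ``n*RSS_total/(n - edf_total)^2`` is profiled and the minimizing candidate
    returned.  Candidates leaving a regime below ``min_regime`` observations
    are skipped.
    """
    if not lower_q < upper_q:
        raise InputError("lower_q must be below upper_q")
    years, s, r, sst = _join(srr, env)
    n = years.size
    if n < 20:
        raise InputError(f"SRR and SST series overlap on only {n} years; need >= 20")
    lam = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    degree = 3 if k >= 4 else k - 1
    knots = _uniform_knots(float(np.min(s)), float(np.max(s)), k, degree)
    B = _design(s, knots, degree)
    D = _second_diff(k)

    qlo, qhi = np.quantile(sst, [lower_q, upper_q])
    candidates = np.linspace(qlo, qhi, grid_size)
    min_fit = max(min_regime, k + 1)

    profile = []
    entries = []  # (cand, gcv, fb, fa, below, partition_id)
    partitions = {}
    for cand in candidates:
        below = sst <= cand
        nb, na = int(np.sum(below)), int(np.sum(~below))
        if nb < min_fit or na < min_fit:
            continue
        key = below.tobytes()
        if key in partitions:
            gcv, fb, fa = partitions[key]
        else:
            fb = _fit_gam_basis(B[below], r[below], knots, degree, lam)
            fa = _fit_gam_basis(B[~below], r[~below], knots, degree, lam)
            edf_total = fb.trace + fa.trace - 1.0  # shared intercept counts once
            gcv = n * (fb.rss + fa.rss) / (n - edf_total) ** 2
            partitions[key] = (gcv, fb, fa)
        profile.append((cand, gcv))
        entries.append((cand, gcv, fb, fa, below, key))
    if not entries:
        raise ThresholdSearchError(
            "no candidate threshold leaves both regimes with enough observations"
        )
    # candidates between the same two observed SST values induce the same
    # partition, hence an identical fit: the GCV profile is piecewise constant.
    # Report the central candidate of the minimizing plateau, not its edge.
    gcvs = np.array([e[1] for e in entries])
    j_best = int(np.argmin(gcvs))
    best_key = entries[j_best][5]
    plateau = [j for j in range(len(entries)) if entries[j][5] == best_key]
    j_mid = plateau[(len(plateau) - 1) // 2]
    cand, gcv, fb, fa, below, _ = entries[j_mid]
    fitted = np.empty(n)
    fitted[below] = fb.fitted
    fitted[~below] = fa.fitted
    resid = r - fitted
    acf1 = float("nan")
    if n > 3 and np.std(resid) > 0:
        acf1 = float(np.corrcoef(resid[:-1], resid[1:])[0, 1])
    return ThresholdGamFit(
        threshold=float(cand),
        below_smooth=fb,
        above_smooth=fa,
        gcv_profile=np.array(profile),
        edf_below=fb.edf,
        edf_above=fa.edf,
        slope_p_below=_trend_p(s[below], fb.fitted),
        slope_p_above=_trend_p(s[~below], fa.fitted),
        gcv=float(gcv),
        n_below=int(np.sum(below)),
        n_above=int(np.sum(~below)),
        resid_acf1=acf1,
        years=years,
    )


def loocv_tgam_vs_gam(
    srr: SRRDataset,
    env: EnvironmentalSeries,
    k_gam: int = 3,
    k_tgam: int = 4,
    lower_q: float = 0.2,
    upper_q: float = 0.8,
    grid_size: int = 20,
    min_regime: int = 5,
    lambda_grid: Optional[np.ndarray] = None,
    max_fold_failures: float = 0.1,
) -> dict:
    """Leave-one-out competition: plain GAM (R ~ s(SSB, k=3)) vs the tGAM with
    its threshold re-selected inside every fold.  Returns both LOOCV RMSEs and
    the preference flag ``tgam_rmse < gam_rmse``."""
    years, s, r, sst = _join(srr, env)
    n = years.size
    if n < 20:
        raise InputError(f"SRR and SST series overlap on only {n} years; need >= 20")
    lam = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, dtype=float)

    deg_g = 3 if k_gam >= 4 else k_gam - 1
    knots_g = _uniform_knots(float(np.min(s)), float(np.max(s)), k_gam, deg_g)
    Bg = _design(s, knots_g, deg_g)
    deg_t = 3 if k_tgam >= 4 else k_tgam - 1
    knots_t = _uniform_knots(float(np.min(s)), float(np.max(s)), k_tgam, deg_t)
    Bt = _design(s, knots_t, deg_t)
    min_fit = max(min_regime, k_tgam + 1)

    err_gam, err_tgam = [], []
    failures = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            fg = _fit_gam_basis(Bg[mask], r[mask], knots_g, deg_g, lam)
            pred_g = float(Bg[i] @ fg.coefficients)

            sst_f = sst[mask]
            qlo, qhi = np.quantile(sst_f, [lower_q, upper_q])
            cands = np.linspace(qlo, qhi, grid_size)
            best = None
            for cand in cands:
                below = sst_f <= cand
                if int(np.sum(below)) < min_fit or int(np.sum(~below)) < min_fit:
                    continue
                Bm = Bt[mask]
                fb = _fit_gam_basis(Bm[below], r[mask][below], knots_t, deg_t, lam)
                fa = _fit_gam_basis(Bm[~below], r[mask][~below], knots_t, deg_t, lam)
                edf_total = fb.trace + fa.trace - 1.0
                gcv = (n - 1) * (fb.rss + fa.rss) / ((n - 1) - edf_total) ** 2
                if best is None or gcv < best[0] - 1e-15:
                    best = (gcv, cand, fb, fa)
            if best is None:
                raise ThresholdSearchError("no admissible threshold in fold")
            _, cand, fb, fa = best
            regime_fit = fb if sst[i] <= cand else fa
            pred_t = float(Bt[i] @ regime_fit.coefficients)
        except Exception:  # noqa: BLE001 - fold failures are counted, then bounded
            failures += 1
            continue
        err_gam.append(r[i] - pred_g)
        err_tgam.append(r[i] - pred_t)
    if failures > max_fold_failures * n:
        raise DecisionError(f"{failures} of {n} LOOCV folds failed")
    rmse_gam = float(np.sqrt(np.mean(np.square(err_gam))))
    rmse_tgam = float(np.sqrt(np.mean(np.square(err_tgam))))
    return {
        "rmse_gam": rmse_gam,
        "rmse_tgam": rmse_tgam,
        "prefers_tgam": bool(rmse_tgam < rmse_gam),
        "n_folds": n - failures,
        "failures": failures,
    }


@dataclass
class TGamDecision:
    loocv_prefers_tgam: Optional[bool]
    criteria: dict  # edf_differ, any_slope_significant, gcv_valley -> bool
    verdict: str  # accepted | rejected
    threshold: Optional[float] = None
    details: dict = field(default_factory=dict)


def _edf_band(edf: float) -> str:
    if edf > 2.0:
        return "strongly non-linear"
    if edf > 1.0:
        return "weakly non-linear"
    return "linear"


def evaluate_threshold_criteria(
    fit: ThresholdGamFit,
    loocv_prefers_tgam: Optional[bool],
    edf_min_gap: float = 0.5,
    alpha: float = 0.05,
    valley_depth: float = 0.05,
) -> TGamDecision:
    """Apply the three printed acceptance criteria to a fitted threshold GAM.

    (1) the regime edfs differ by at least ``edf_min_gap``; (2) at least one
    regime slope is significant at ``alpha``; (3) the GCV profile has a deep
    valley: its minimum lies at least ``valley_depth`` (fraction) below the
    profile median.  The verdict is *accepted* only if the LOOCV flag and all
    three criteria hold.
    """
    profile = fit.gcv_profile[:, 1]
    criteria = {
        "edf_differ": bool(abs(fit.edf_below - fit.edf_above) >= edf_min_gap),
        "any_slope_significant": bool(min(fit.slope_p_below, fit.slope_p_above) < alpha),
        "gcv_valley": bool(np.min(profile) <= (1.0 - valley_depth) * np.median(profile)),
    }
    accepted = bool(loocv_prefers_tgam) and all(criteria.values())
    return TGamDecision(
        loocv_prefers_tgam=loocv_prefers_tgam,
        criteria=criteria,
        verdict="accepted" if accepted else "rejected",
        threshold=fit.threshold if accepted else None,
        details={
            "edf_below": fit.edf_below,
            "edf_above": fit.edf_above,
            "edf_band_below": _edf_band(fit.edf_below),
            "edf_band_above": _edf_band(fit.edf_above),
            "slope_p_below": fit.slope_p_below,
            "slope_p_above": fit.slope_p_above,
            "gcv_min": float(np.min(profile)),
            "gcv_median": float(np.median(profile)),
            "resid_acf1": fit.resid_acf1,
        },
    )


def decide_tgam(
    srr: SRRDataset,
    env: EnvironmentalSeries,
    k_gam: int = 3,
    k_tgam: int = 4,
    lower_q: float = 0.2,
    upper_q: float = 0.8,
    grid_size: int = 20,
    edf_min_gap: float = 0.5,
    alpha: float = 0.05,
    valley_depth: float = 0.05,
    lazy_loocv: bool = True,
) -> TGamDecision:
    """Full temperature-threshold decision: fit the tGAM, check the three
    criteria, and (unless all three already fail and ``lazy_loocv`` is on) run
    the LOOCV competition against the plain GAM.  The verdict is a conjunction,
    so skipping the LOOCV for an already-rejected fit cannot change it."""
    fit = fit_threshold_gam(
        srr, env, k=k_tgam, lower_q=lower_q, upper_q=upper_q, grid_size=grid_size
    )
    pre = evaluate_threshold_criteria(
        fit, loocv_prefers_tgam=True, edf_min_gap=edf_min_gap, alpha=alpha, valley_depth=valley_depth
    )
    loocv_flag: Optional[bool] = None
    loocv_info = {}
    if not lazy_loocv or all(pre.criteria.values()):
        loocv_info = loocv_tgam_vs_gam(
            srr,
            env,
            k_gam=k_gam,
            k_tgam=k_tgam,
            lower_q=lower_q,
            upper_q=upper_q,
            grid_size=grid_size,
        )
        loocv_flag = loocv_info["prefers_tgam"]
    decision = evaluate_threshold_criteria(
        fit,
        loocv_prefers_tgam=loocv_flag,
        edf_min_gap=edf_min_gap,
        alpha=alpha,
        valley_depth=valley_depth,
    )
    decision.details.update(loocv_info)
    decision.details["fit"] = fit
    return decision
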
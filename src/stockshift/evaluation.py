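"""Self-contained benchmark routines: parameter recovery on synthetic stocks.

Each routine regenerates its synthetic data from a seed, runs the relevant
pipeline stage, and measures recovery against the generator's ground truth or
against an independent oracle (brute-force enumeration, dense grid search,
equilibrium continuation).  They are used by the acceptance test suite and by
``scripts/acceptance.py``; the default problem sizes are the package's study
conditions and are documented in the methods note.
"""

from __future__ import annotations

import numpy as np

from .changepoints import (
    bcp_posterior,
    binseg_mean_changepoints,
    consensus_changepoints,
    exhaustive_min_sse_segmentation,
)
from .hysteresis import (
    baiperron_breakpoints,
    classify_hysteresis,
    enumerate_breakpoints,
    fit_fssb_breakpoints,
    select_lag,
)
from .io import SRRDataset, align_srr
from .pipeline import PipelineConfig, run_three_flags
from .simulate import (
    _default_immigration,
    equilibrium_continuation,
    simulate_diagnostic_stock,
    simulate_hysteretic_stock,
    simulate_sst_threshold_srr,
    simulate_stepped_series,
)
from .srr import (
    fit_beverton_holt,
    fit_ricker,
    fit_segmented_glm,
    loocv_compare,
    segmented_psi_grid_oracle,
)
from .tgam import decide_tgam, fit_threshold_gam

__all__ = [
    "child_seeds",
    "binseg_vs_bruteforce",
    "consensus_recovery",
    "baiperron_vs_enumeration",
    "hysteresis_classification_rates",
    "srr_parameter_recovery",
    "loocv_competition_rates",
    "tgam_threshold_rates",
    "pipeline_flag_counts",
]

ALLEE_SCENARIO = {"K": 1000.0, "r_growth": 0.5, "allee_frac": 0.2, "process_sd": 0.05}


def child_seeds(seed: int, n: int, stream: int) -> np.ndarray:
    """n reproducible sub-seeds (< 2^31) for one benchmark stream."""
    return np.random.default_rng([int(seed), int(stream)]).integers(0, 2**31 - 1, size=n)


def binseg_vs_bruteforce(seed: int = 0, n_series: int = 50) -> dict:
    """Fraction of short stepped series (length <= 30, <= 3 changes) on which
    greedy binary segmentation returns exactly the brute-force optimal
    (minimum total within-segment SSE) segmentation."""
    seeds = child_seeds(seed, n_series, 1)
    match = 0
    for rep, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        k = rep % 4
        lengths = [int(v) for v in rng.integers(5, 8, k + 1)]
        while sum(lengths) > 30:
            lengths[int(np.argmax(lengths))] -= 1
        while sum(lengths) < max(10, (k + 1) * 5):
            lengths[0] += 1
        means = np.cumsum(rng.choice([-1.0, 1.0], k + 1) * rng.uniform(40, 80, k + 1)) + 300
        _, x, _ = simulate_stepped_series(means, lengths, noise_sd=5.0, seed=int(s))
        res = binseg_mean_changepoints(x, max_changes=3, min_segment=5)
        m = len(res.candidate_years)
        best, _ = exhaustive_min_sse_segmentation(x, m, 5)
        match += list(res.candidate_years) == list(best)
    return {"match_fraction": match / n_series, "n": n_series}


def consensus_recovery(seed: int = 0, n_reps: int = 100) -> dict:
    """Consensus change-point recovery on stepped series with three planted
    changes (segment means 5 noise-sd apart, segments >= 10 years)."""
    seeds = child_seeds(seed, n_reps, 2)
    means, lengths, sd = [100.0, 150.0, 100.0, 150.0], [12, 10, 12, 10], 10.0
    recovered = 0
    low_spurious = 0
    for s in seeds:
        years, x, truth = simulate_stepped_series(means, lengths, noise_sd=sd, seed=int(s))
        bs = binseg_mean_changepoints(x, max_changes=5, min_segment=5, years=years)
        by = bcp_posterior(x, seed=int(s), years=years)
        cons = consensus_changepoints(
            by, bs, tolerance=1, min_gap=5, year_range=(int(years[0]), int(years[-1]))
        )
        truths = truth.true_change_years
        recovered += all(
            any(abs(int(cy) - int(t)) <= 1 for cy in cons.change_years) for t in truths
        )
        spurious = sum(
            1 for cy in cons.change_years if all(abs(int(cy) - int(t)) > 1 for t in truths)
        )
        low_spurious += spurious <= 1
    return {
        "recovery_fraction": recovered / n_reps,
        "low_spurious_fraction": low_spurious / n_reps,
        "n": n_reps,
    }


def baiperron_vs_enumeration(seed: int = 0, n_reps: int = 10) -> dict:
    """Exact-DP multiple-break regression vs exhaustive enumeration (n = 24,
    up to 2 breaks): fraction of (replicate, m) cells with equal minimal RSS."""
    seeds = child_seeds(seed, n_reps, 3)
    cells = ok = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        x = rng.uniform(0, 10, 24)
        y = np.where(np.arange(24) < 12, 2 * x + 1, -x + 30) + rng.normal(0, 1, 24)
        bp = baiperron_breakpoints(x, y, max_breaks=2)
        for m, rss in bp.rss_by_m.items():
            _, rss_bf = enumerate_breakpoints(x, y, m)
            cells += 1
            ok += abs(rss - rss_bf) <= 1e-9 * (1 + rss_bf)
    return {"match_fraction": ok / cells, "n": cells}


def _allee_fold():
    K = ALLEE_SCENARIO["K"]
    r = ALLEE_SCENARIO["r_growth"]
    A = ALLEE_SCENARIO["allee_frac"] * K
    iota = _default_immigration(r, K, A)
    cF, rF, *_ = equilibrium_continuation(r, K, A, iota, 1e-6 * K)
    return K, r, A, cF, rF


def _classify_loop(f_path, seed, allee):
    K = ALLEE_SCENARIO["K"]
    r = ALLEE_SCENARIO["r_growth"]
    series, _ = simulate_hysteretic_stock(
        r, K, allee, f_path, process_sd=ALLEE_SCENARIO["process_sd"], seed=int(seed)
    )
    lag = select_lag(series.fmort, series.ssb, 10)
    breaks = fit_fssb_breakpoints(series, lag)
    return classify_hysteresis(series, lag, breaks).classification


def hysteresis_classification_rates(seed: int = 0, n_reps: int = 100) -> dict:
    """Loop classification on reversible (no-Allee) stocks and on Allee stocks
    with the pressure floor on either side of the continuation oracle's
    recovery point."""
    K, r, A, cF, rF = _allee_fold()
    up = np.linspace(0, 1.2 * cF, 40)
    down0 = np.linspace(1.2 * cF, 0.0, 40)

    seeds = child_seeds(seed, n_reps, 4)
    false_loops = 0
    rev_path = np.concatenate([np.linspace(0, 0.9 * r, 40), np.linspace(0.9 * r, 0.0, 40)])
    for s in seeds:
        cls = _classify_loop(rev_path, s, allee=0.0)
        false_loops += cls in ("closed_loop", "open_loop")

    closed_ok = 0
    closed_path = np.concatenate([up, down0, np.zeros(40)])
    for s in child_seeds(seed, n_reps, 5):
        closed_ok += _classify_loop(closed_path, s, allee=A) == "closed_loop"

    open_ok = 0
    floor = rF + 0.08
    open_path = np.concatenate([up, np.linspace(1.2 * cF, floor, 40), np.full(40, floor)])
    for s in child_seeds(seed, n_reps, 6):
        open_ok += _classify_loop(open_path, s, allee=A) == "open_loop"

    return {
        "false_loop_count": false_loops,
        "closed_correct_fraction": closed_ok / n_reps,
        "open_correct_fraction": open_ok / n_reps,
        "n": n_reps,
        "collapse_F": cF,
        "recovery_F": rF,
    }


def srr_parameter_recovery(seed: int = 0, n_reps: int = 50) -> dict:
    """Noiseless Ricker / Beverton-Holt recovery error and agreement of the
    segmented breakpoint with a 1000-point grid-search oracle on noisy data."""
    s = np.linspace(100, 2000, 50)
    years = np.arange(1950, 2000)
    bh = fit_beverton_holt(SRRDataset(years, s, 2 * s / (1 + 0.001 * s)))
    rk = fit_ricker(SRRDataset(years, s, s * np.exp(1 - 0.002 * s)))
    bh_err = max(abs(bh.params["alpha"] - 2) / 2, abs(bh.params["beta"] - 0.001) / 0.001)
    rk_err = max(abs(rk.params["alpha"] - 1), abs(rk.params["beta"] - 0.002) / 0.002)

    seeds = child_seeds(seed, n_reps, 7)
    agree = 0
    for sd_ in seeds:
        rng = np.random.default_rng(int(sd_))
        sv = np.sort(rng.uniform(10, 990, 60))
        rv = np.maximum(
            np.where(sv <= 500, 100 + sv, 600 - 0.5 * (sv - 500)) + rng.normal(0, 30, 60), 1
        )
        d = SRRDataset(np.arange(1950, 2010), sv, rv)
        fit = fit_segmented_glm(d)
        psi_oracle = segmented_psi_grid_oracle(d, 1000)
        step = (np.quantile(sv, 0.98) - np.quantile(sv, 0.02)) / 999
        agree += abs(fit.psi - psi_oracle) <= step + 1e-9
    return {
        "bh_noiseless_max_rel_error": bh_err,
        "ricker_noiseless_max_rel_error": rk_err,
        "psi_grid_agreement_fraction": agree / n_reps,
        "n": n_reps,
    }


def loocv_competition_rates(seed: int = 0, n_reps: int = 100) -> dict:
    """Model-competition win rates: the segmented model on broken-stick data
    and the Ricker model (vs linear, train RMSE) on Ricker-generated data."""
    seg_wins = 0
    for s in child_seeds(seed, n_reps, 8):
        rng = np.random.default_rng(int(s))
        sv = rng.uniform(50, 1000, 40)
        rv = np.maximum(
            np.where(sv <= 500, 50 + 1.2 * sv, 650 - 0.6 * (sv - 500)) + rng.normal(0, 65, 40), 1
        )
        cmp = loocv_compare(
            SRRDataset(np.arange(1960, 2000), sv, rv),
            candidates=("linear", "ricker", "segmented_glm"),
        )
        seg_wins += cmp.winner == "segmented_glm"

    ricker_wins = 0
    for s in child_seeds(seed, n_reps, 9):
        rng = np.random.default_rng(int(s))
        sv = rng.uniform(100, 1000, 40)
        rv = sv * np.exp(1.2 - 0.002 * sv) * np.exp(0.3 * rng.standard_normal(40))
        cmp = loocv_compare(
            SRRDataset(np.arange(1960, 2000), sv, rv), candidates=("linear", "ricker")
        )
        ricker_wins += (
            cmp.results["ricker"]["rmse_train"] < cmp.results["linear"]["rmse_train"]
        )
    return {
        "segmented_win_fraction": seg_wins / n_reps,
        "ricker_beats_linear_fraction": ricker_wins / n_reps,
        "n": n_reps,
    }


def tgam_threshold_rates(seed: int = 0, n_recovery: int = 50, n_null: int = 100) -> dict:
    """Threshold recovery within one grid step of the planted 12 degC (slope
    ratio 4, n = 60) and the acceptance rate on matched no-effect nulls."""
    rec = 0
    for s in child_seeds(seed, n_recovery, 10):
        srr, env, _ = simulate_sst_threshold_srr(threshold=12.0, seed=int(s))
        fit = fit_threshold_gam(srr, env)
        step = (np.quantile(env.sst, 0.8) - np.quantile(env.sst, 0.2)) / 19
        rec += abs(fit.threshold - 12.0) <= step + 1e-9

    acc = 0
    for s in child_seeds(seed, n_null, 11):
        srr, env, _ = simulate_sst_threshold_srr(
            threshold=12.0, slope_below=1.25, slope_above=1.25, seed=int(s)
        )
        acc += decide_tgam(srr, env).verdict == "accepted"
    return {
        "threshold_recovery_fraction": rec / n_recovery,
        "null_acceptance_fraction": acc / n_null,
        "n_recovery": n_recovery,
        "n_null": n_null,
    }


def pipeline_flag_counts(seed: int = 0) -> dict:
    """Number of flags raised by the full pipeline on the all-effects stock
    and on the matched null stock."""
    series, env, _ = simulate_diagnostic_stock(seed=seed, with_effects=True)
    rep = run_three_flags(series, env=env, config=PipelineConfig(seed=seed))
    series0, env0, _ = simulate_diagnostic_stock(seed=seed, with_effects=False)
    rep0 = run_three_flags(series0, env=env0, config=PipelineConfig(seed=seed))
    return {
        "effects_flags_raised": rep.overall["n_flags_raised"],
        "null_flags_raised": rep0.overall["n_flags_raised"],
        "effects_detail": {k: rep.overall[k] for k in ("abrupt", "hysteresis", "nonstationary", "temperature")},
        "null_detail": {k: rep0.overall[k] for k in ("abrupt", "hysteresis", "nonstationary", "temperature")},
        "n": len(series),
    }
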
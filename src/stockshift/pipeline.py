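"""Orchestration of the three-flag regime-shift diagnosis for one stock.

The three flags (plus the optional temperature flag) are evaluated
independently -- no flag gates another -- and collected in a
:class:`RegimeShiftReport`:

* **abrupt**: the consensus change-point procedure found at least one abrupt
  change in SSB;
* **hysteresis**: the lagged F-SSB trajectory is classified as a closed or
  open loop;
* **nonstationary**: the LOOCV stock-recruitment competition is won by a
  discontinuous model (segmented or breakpoint regression);
* **temperature**: the threshold-GAM decision accepted an SST threshold.

A failure inside one flag is recorded in the report without aborting the
others.  Reports serialize to JSON with stable key order, so identical inputs,
configuration and seed produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import changepoints as cpt
from . import hysteresis as hyst
from . import srr as srrmod
from . import tgam as tgammod
from .exceptions import ConfigurationError
from .io import EnvironmentalSeries, StockAssessmentSeries, align_srr

__all__ = ["PipelineConfig", "RegimeShiftReport", "run_three_flags", "write_report", "read_report"]

logger = logging.getLogger("stockshift")

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Every tunable of the four flags, with the package defaults."""

    seed: int = 0
    # change points
    binseg_max_changes: int = 5
    binseg_min_segment: int = 5
    binseg_penalty: Optional[float] = None  # None -> 3 log n
    bcp_prior_p0: float = 0.2
    bcp_prior_w0: float = 0.2
    bcp_iterations: int = 5000
    bcp_burnin: int = 500
    bcp_declare_threshold: float = 0.5
    consensus_tolerance: int = 1
    consensus_min_gap: int = 5
    # hysteresis
    max_lag: int = 10
    hysteresis_max_breaks: int = 3
    hysteresis_alpha: float = 0.05
    hysteresis_bins: int = 5
    hysteresis_gap_min_frac: float = 0.10
    # SRR competition
    srr_candidates: tuple = srrmod.DEFAULT_CANDIDATES
    srr_max_breaks: int = 2
    # threshold GAM
    tgam_k_gam: int = 3
    tgam_k_tgam: int = 4
    tgam_lower_q: float = 0.2
    tgam_upper_q: float = 0.8
    tgam_grid_size: int = 20
    tgam_edf_min_gap: float = 0.5
    tgam_alpha: float = 0.05
    tgam_valley_depth: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["srr_candidates"] = list(d["srr_candidates"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "srr_candidates" in d:
            d["srr_candidates"] = tuple(d["srr_candidates"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))


@dataclass
class RegimeShiftReport:
    stock_id: str
    flag_abrupt: Optional[dict] = None
    flag_hysteresis: Optional[dict] = None
    flag_nonstationary: Optional[dict] = None
    flag_temperature: Optional[dict] = None
    overall: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)
    version: str = VERSION
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "stock_id": self.stock_id,
            "flag_abrupt": self.flag_abrupt,
            "flag_hysteresis": self.flag_hysteresis,
            "flag_nonstationary": self.flag_nonstationary,
            "flag_temperature": self.flag_temperature,
            "overall": self.overall,
            "errors": self.errors,
            "config_echo": self.config_echo,
            "version": self.version,
            "seed": self.seed,
        }


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def overall_flags(report: RegimeShiftReport) -> dict:
    """Recompute the per-flag booleans from the serialized component results.

    Pure function of the report contents, used both to populate ``overall`` and
    to verify a round-tripped report.
    """
    flags = {}
    fa = report.flag_abrupt
    flags["abrupt"] = bool(fa and len(fa.get("change_years", [])) >= 1)
    fh = report.flag_hysteresis
    flags["hysteresis"] = bool(
        fh and fh.get("classification") in ("closed_loop", "open_loop")
    )
    fn = report.flag_nonstationary
    flags["nonstationary"] = bool(
        fn
        and fn.get("winner") in ("segmented_glm", "breakpoint_regression")
        and fn.get("winner_supported", True)
    )
    ft = report.flag_temperature
    flags["temperature"] = bool(ft and ft.get("verdict") == "accepted")
    flags["n_flags_raised"] = int(sum(flags[k] for k in ("abrupt", "hysteresis", "nonstationary", "temperature")))
    return flags


def run_three_flags(
    stock: StockAssessmentSeries,
    env: Optional[EnvironmentalSeries] = None,
    config: Optional[PipelineConfig] = None,
    enable_temperature: Optional[bool] = None,
) -> RegimeShiftReport:
    """Run the full diagnosis on one stock.

    The temperature flag runs when ``env`` is provided (or when explicitly
    enabled, in which case a missing ``env`` is a configuration error).
    Partial failure of one flag is recorded without aborting the others.
    """
    cfg = config or PipelineConfig()
    if enable_temperature is None:
        enable_temperature = env is not None
    if enable_temperature and env is None:
        raise ConfigurationError(
            "temperature flag enabled but no environmental (SST) series provided"
        )
    report = RegimeShiftReport(
        stock_id=stock.stock_id, config_echo=cfg.to_dict(), seed=cfg.seed
    )

    t0 = time.perf_counter()
    try:
        ssb_ok = np.isfinite(stock.ssb)
        vals = stock.ssb[ssb_ok]
        yrs = stock.years[ssb_ok]
        binseg = cpt.binseg_mean_changepoints(
            vals,
            max_changes=cfg.binseg_max_changes,
            min_segment=cfg.binseg_min_segment,
            penalty=cfg.binseg_penalty,
            years=yrs,
        )
        bayes = cpt.bcp_posterior(
            vals,
            prior_p0=cfg.bcp_prior_p0,
            prior_w0=cfg.bcp_prior_w0,
            iterations=cfg.bcp_iterations,
            burnin=cfg.bcp_burnin,
            seed=cfg.seed,
            declare_threshold=cfg.bcp_declare_threshold,
            years=yrs,
        )
        consensus = cpt.consensus_changepoints(
            bayes,
            binseg,
            tolerance=cfg.consensus_tolerance,
            min_gap=cfg.consensus_min_gap,
            year_range=(int(yrs[0]), int(yrs[-1])),
        )
        report.flag_abrupt = _jsonify(
            {
                "change_years": consensus.change_years,
                "periods": consensus.periods,
                "provenance": consensus.provenance,
                "binseg_candidates": binseg.candidate_years,
                "bayes_candidates": bayes.candidate_years,
                "bayes_posterior_trace": bayes.posterior_trace,
            }
        )
    except Exception as exc:  # noqa: BLE001 - flag isolation is the contract
        report.errors["abrupt"] = f"{type(exc).__name__}: {exc}"
    logger.info("change-point stage: %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    try:
        lag = hyst.select_lag(stock.fmort, stock.ssb, max_lag=cfg.max_lag)
        breaks = hyst.fit_fssb_breakpoints(stock, lag, max_breaks=cfg.hysteresis_max_breaks)
        assessment = hyst.classify_hysteresis(
            stock,
            lag,
            breaks,
            alpha=cfg.hysteresis_alpha,
            n_bins=cfg.hysteresis_bins,
            gap_min_frac=cfg.hysteresis_gap_min_frac,
        )
        report.flag_hysteresis = _jsonify(
            {
                "lag": lag.lag,
                "correlation": lag.correlation,
                "correlogram": lag.correlogram,
                "break_years": breaks.break_years,
                "segment_slopes": breaks.segment_slopes,
                "classification": assessment.classification,
                "branch_gap": assessment.branch_gap,
                "p_value": assessment.p_value,
                "reason": assessment.reason,
                "peak_year": assessment.peak_year,
            }
        )
    except Exception as exc:  # noqa: BLE001
        report.errors["hysteresis"] = f"{type(exc).__name__}: {exc}"
    logger.info("hysteresis stage: %.2fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    try:
        srr_data = align_srr(stock)
        comparison = srrmod.loocv_compare(srr_data, candidates=cfg.srr_candidates)
        bp_fit = srrmod.fit_srr_breakpoint_regression(srr_data, max_breaks=cfg.srr_max_breaks)
        # a discontinuous winner only evidences non-stationarity if its break
        # is supported: breakpoint regression must have retained >= 1 break
        # under BIC, and the segmented model must both have a significant
        # slope difference and beat the plain linear model on BIC (the Wald
        # test alone is anti-conservative because psi is estimated)
        wres = comparison.results[comparison.winner]
        if comparison.winner == "segmented_glm":
            seg = srrmod.fit_segmented_glm(srr_data)
            lin = srrmod.fit_linear(srr_data)
            n_obs = len(srr_data)
            bic_seg = n_obs * np.log(max(seg.sse, 1e-300) / n_obs) + 4 * np.log(n_obs)
            bic_lin = n_obs * np.log(max(lin.sse, 1e-300) / n_obs) + 2 * np.log(n_obs)
            winner_supported = (
                wres["params"].get("slope_diff_p", 1.0) < 0.05 and bic_seg < bic_lin
            )
        elif comparison.winner == "breakpoint_regression":
            winner_supported = wres["params"].get("n_breaks", 0) >= 1
        else:
            winner_supported = True
        report.flag_nonstationary = _jsonify(
            {
                "winner": comparison.winner,
                "winner_is_discontinuous": comparison.winner_is_discontinuous,
                "winner_supported": winner_supported,
                "results": comparison.results,
                "excluded": comparison.excluded,
                "srr_break_years": bp_fit.break_years,
                "srr_segments": bp_fit.segment_params,
            }
        )
    except Exception as exc:  # noqa: BLE001
        report.errors["nonstationary"] = f"{type(exc).__name__}: {exc}"
    logger.info("SRR stage: %.2fs", time.perf_counter() - t0)

    if enable_temperature:
        t0 = time.perf_counter()
        try:
            srr_data = align_srr(stock)
            decision = tgammod.decide_tgam(
                srr_data,
                env,
                k_gam=cfg.tgam_k_gam,
                k_tgam=cfg.tgam_k_tgam,
                lower_q=cfg.tgam_lower_q,
                upper_q=cfg.tgam_upper_q,
                grid_size=cfg.tgam_grid_size,
                edf_min_gap=cfg.tgam_edf_min_gap,
                alpha=cfg.tgam_alpha,
                valley_depth=cfg.tgam_valley_depth,
            )
            details = {k: v for k, v in decision.details.items() if k != "fit"}
            report.flag_temperature = _jsonify(
                {
                    "verdict": decision.verdict,
                    "threshold": decision.threshold,
                    "criteria": decision.criteria,
                    "loocv_prefers_tgam": decision.loocv_prefers_tgam,
                    "details": details,
                }
            )
        except Exception as exc:  # noqa: BLE001
            report.errors["temperature"] = f"{type(exc).__name__}: {exc}"
        logger.info("threshold-GAM stage: %.2fs", time.perf_counter() - t0)

    report.overall = overall_flags(report)
    return report


def write_report(report: RegimeShiftReport, path, companion_csv: bool = True) -> None:
    """Write the report as stable-key-order JSON (+ companion CSV tables)."""
    path = Path(path)
    payload = _jsonify(report.to_dict())
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    if not companion_csv:
        return
    import pandas as pd

    stem = path.with_suffix("")
    if report.flag_abrupt and report.flag_abrupt.get("periods"):
        pd.DataFrame(
            report.flag_abrupt["periods"], columns=["start_year", "end_year"]
        ).to_csv(f"{stem}_periods.csv", index=False)
    if report.flag_hysteresis and report.flag_hysteresis.get("segment_slopes") is not None:
        pd.DataFrame(
            {
                "segment": range(len(report.flag_hysteresis["segment_slopes"])),
                "slope": report.flag_hysteresis["segment_slopes"],
            }
        ).to_csv(f"{stem}_segments.csv", index=False)
    if report.flag_nonstationary and report.flag_nonstationary.get("results"):
        rows = [
            {"model": m, "rmse_train": v["rmse_train"], "rmse_test": v["rmse_test"]}
            for m, v in sorted(report.flag_nonstationary["results"].items())
        ]
        pd.DataFrame(rows).to_csv(f"{stem}_model_comparison.csv", index=False)


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
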
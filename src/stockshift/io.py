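"""Data model and CSV I/O for stock-assessment time series.

The central container is :class:`StockAssessmentSeries`: aligned annual series of
spawning stock biomass (SSB, tonnes), recruitment (R, thousands, indexed at a
stated age) and fishing mortality (F, per year), on a gap-free calendar-year
axis. Missing observations are carried as NaN and excluded pairwise by each
analysis; they are never imputed or silently dropped.

Recruitment in assessment outputs is reported in the year the cohort reaches
its recruitment age.  :func:`align_srr` shifts it back to the spawn year, so a
stock-recruitment pair ``(s_t, r_t)`` relates the parent biomass in year ``t``
to the offspring that biomass produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import EmptyDatasetError, FormatError, ValidationError

__all__ = [
    "StockAssessmentSeries",
    "ReferencePoints",
    "SRRDataset",
    "EnvironmentalSeries",
    "read_stock_csv",
    "write_stock_csv",
    "read_sst_csv",
    "write_sst_csv",
    "align_srr",
    "DEFAULT_STOCK_COLUMNS",
    "DEFAULT_SST_COLUMNS",
]

DEFAULT_STOCK_COLUMNS: Mapping[str, str] = {
    "year": "Year",
    "ssb": "SSB",
    "recruitment": "R",
    "fmort": "F",
}

DEFAULT_SST_COLUMNS: Mapping[str, str] = {"year": "Year", "sst": "SST"}


def _as_float(values) -> np.ndarray:
    return np.asarray(values, dtype=float)


def _check_years(years: np.ndarray) -> None:
    if years.ndim != 1 or years.size == 0:
        raise ValidationError("year axis must be a non-empty 1-d array")
    diffs = np.diff(years)
    if np.any(diffs <= 0):
        dup = years[1:][diffs <= 0]
        raise ValidationError(f"years must be strictly increasing; offending years: {dup.tolist()}")
    gaps = years[1:][diffs > 1]
    if gaps.size:
        missing = []
        for i, d in enumerate(diffs):
            if d > 1:
                missing.extend(range(int(years[i]) + 1, int(years[i + 1])))
        raise ValidationError(f"years must be consecutive; missing years: {missing}")


@dataclass(frozen=True)
class StockAssessmentSeries:
    """Aligned annual SSB / recruitment / fishing-mortality series for one stock."""

    stock_id: str
    years: np.ndarray
    ssb: np.ndarray
    recruitment: np.ndarray
    fmort: np.ndarray
    recruitment_age: int = 0

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        _check_years(years)
        object.__setattr__(self, "years", years)
        for name in ("ssb", "recruitment", "fmort"):
            arr = _as_float(getattr(self, name))
            if arr.shape != years.shape:
                raise ValidationError(
                    f"{name} has length {arr.size}, expected {years.size} to match years"
                )
            object.__setattr__(self, name, arr)
        if int(self.recruitment_age) < 0:
            raise ValidationError("recruitment_age must be >= 0")
        object.__setattr__(self, "recruitment_age", int(self.recruitment_age))
        with np.errstate(invalid="ignore"):
            if np.any(self.ssb[np.isfinite(self.ssb)] <= 0):
                raise ValidationError("ssb must be positive where present")
            if np.any(self.recruitment[np.isfinite(self.recruitment)] <= 0):
                raise ValidationError("recruitment must be positive where present")
            if np.any(self.fmort[np.isfinite(self.fmort)] < 0):
                raise ValidationError("fishing mortality must be non-negative where present")

    def __len__(self) -> int:
        return self.years.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Year": self.years, "SSB": self.ssb, "R": self.recruitment, "F": self.fmort}
        )

    def with_values(self, **kwargs) -> "StockAssessmentSeries":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ReferencePoints:
    """ICES-style management reference points; annotation only, never inference."""

    f_msy: Optional[float] = None
    f_pa: Optional[float] = None
    f_lim: Optional[float] = None
    msy_btrigger: Optional[float] = None
    b_pa: Optional[float] = None
    b_lim: Optional[float] = None

    def __post_init__(self):
        for name in ("f_msy", "f_pa", "f_lim", "msy_btrigger", "b_pa", "b_lim"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"reference point {name} must be non-negative")
        if self.b_lim is not None and self.b_pa is not None and self.b_lim > self.b_pa:
            raise ValidationError("b_lim must not exceed b_pa")


@dataclass(frozen=True)
class SRRDataset:
    """Stock-recruitment pairs indexed by spawn year (r_t spawned by s_t)."""

    spawn_years: np.ndarray
    s: np.ndarray
    r: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.spawn_years, dtype=int)
        s = _as_float(self.s)
        r = _as_float(self.r)
        if not (years.shape == s.shape == r.shape):
            raise ValidationError("spawn_years, s and r must have equal length")
        if years.size == 0:
            raise EmptyDatasetError("stock-recruitment dataset has no pairs")
        if np.any(np.diff(years) <= 0):
            raise ValidationError("spawn_years must be strictly increasing")
        if np.any(~np.isfinite(s)) or np.any(~np.isfinite(r)):
            raise ValidationError("SRR pairs must be complete; drop incomplete pairs first")
        if np.any(s <= 0) or np.any(r <= 0):
            raise ValidationError("SRR pairs require s > 0 and r > 0")
        object.__setattr__(self, "spawn_years", years)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "r", r)

    def __len__(self) -> int:
        return self.spawn_years.size

    def subset(self, mask) -> "SRRDataset":
        mask = np.asarray(mask, dtype=bool)
        return SRRDataset(self.spawn_years[mask], self.s[mask], self.r[mask])


@dataclass(frozen=True)
class EnvironmentalSeries:
    """Annual environmental covariate series (here: mean SST in deg C)."""

    years: np.ndarray
    sst: np.ndarray

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        sst = _as_float(self.sst)
        if years.shape != sst.shape:
            raise ValidationError("years and sst must have equal length")
        if years.size and np.any(np.diff(years) <= 0):
            raise ValidationError("environmental years must be strictly increasing")
        if np.any(~np.isfinite(sst)):
            raise ValidationError("sst values must be finite")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "sst", sst)

    def __len__(self) -> int:
        return self.years.size


def read_stock_csv(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    recruitment_age: int = 0,
    stock_id: Optional[str] = None,
) -> StockAssessmentSeries:
    """Read a stock assessment CSV (ICES standard-graphs layout) into a series.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    column_map : mapping, optional
        Maps the logical names ``year``, ``ssb``, ``recruitment``, ``fmort`` to
        the column names in the file.  Defaults to ``Year, SSB, R, F``.
    recruitment_age : int
        Age at which recruitment is indexed in the assessment.
    stock_id : str, optional
        Label for the stock; defaults to the file stem.

    Unparseable numeric cells become explicit missing values (NaN); a missing
    mapped column raises :class:`FormatError` naming it, and non-contiguous
    years raise :class:`ValidationError` listing the gaps.
    """
    path = Path(path)
    cmap = dict(DEFAULT_STOCK_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    for logical, col in cmap.items():
        if col not in df.columns:
            raise FormatError(f"column '{col}' (mapped from '{logical}') not found in {path.name}")
    year_raw = pd.to_numeric(df[cmap["year"]], errors="coerce")
    if year_raw.isna().any():
        bad = df.index[year_raw.isna()].tolist()
        raise FormatError(f"year column '{cmap['year']}' not parseable as integers at rows {bad}")
    if np.any(year_raw.to_numpy() % 1 != 0):
        raise FormatError(f"year column '{cmap['year']}' contains non-integer values")
    df = df.assign(_year=year_raw.astype(int)).sort_values("_year", kind="stable")
    years = df["_year"].to_numpy()
    if np.any(np.diff(years) == 0):
        dup = years[1:][np.diff(years) == 0]
        raise ValidationError(f"duplicate years in {path.name}: {sorted(set(dup.tolist()))}")
    return StockAssessmentSeries(
        stock_id=stock_id or path.stem,
        years=years,
        ssb=pd.to_numeric(df[cmap["ssb"]], errors="coerce").to_numpy(),
        recruitment=pd.to_numeric(df[cmap["recruitment"]], errors="coerce").to_numpy(),
        fmort=pd.to_numeric(df[cmap["fmort"]], errors="coerce").to_numpy(),
        recruitment_age=recruitment_age,
    )


def write_stock_csv(series: StockAssessmentSeries, path) -> None:
    """Write a series back to the default CSV dialect (round-trips bit-exactly)."""
    series.to_frame().to_csv(path, index=False)


def read_sst_csv(path, column_map: Optional[Mapping[str, str]] = None) -> EnvironmentalSeries:
    """Read an annual SST CSV with columns ``Year, SST`` (configurable)."""
    path = Path(path)
    cmap = dict(DEFAULT_SST_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    for logical, col in cmap.items():
        if col not in df.columns:
            raise FormatError(f"column '{col}' (mapped from '{logical}') not found in {path.name}")
    sst = pd.to_numeric(df[cmap["sst"]], errors="coerce")
    if sst.isna().any():
        bad = df.index[sst.isna()].tolist()
        raise FormatError(f"non-numeric SST value(s) at row(s) {bad} in {path.name}")
    years = pd.to_numeric(df[cmap["year"]], errors="coerce")
    if years.isna().any():
        raise FormatError(f"non-numeric Year value(s) in {path.name}")
    order = np.argsort(years.to_numpy(), kind="stable")
    years = years.to_numpy().astype(int)[order]
    if np.any(np.diff(years) == 0):
        dup = years[1:][np.diff(years) == 0]
        raise ValidationError(f"duplicate years in {path.name}: {sorted(set(dup.tolist()))}")
    return EnvironmentalSeries(years=years, sst=sst.to_numpy()[order])


def write_sst_csv(env: EnvironmentalSeries, path) -> None:
    pd.DataFrame({"Year": env.years, "SST": env.sst}).to_csv(path, index=False)


def align_srr(series: StockAssessmentSeries) -> SRRDataset:
    """Build spawn-year stock-recruitment pairs from an assessment series.

    Recruitment reported at age ``a`` in assessment year ``y`` is attributed to
    spawn year ``y - a``; the pair for spawn year ``t`` is ``(SSB_t, R_{t+a})``.
    Pairs with either member missing are dropped.
    """
    a = series.recruitment_age
    n = len(series)
    if n <= a:
        raise EmptyDatasetError(
            f"series of length {n} too short for recruitment age {a}: no complete pairs"
        )
    s = series.ssb[: n - a] if a > 0 else series.ssb
    r = series.recruitment[a:]
    years = series.years[: n - a] if a > 0 else series.years
    ok = np.isfinite(s) & np.isfinite(r)
    if not np.any(ok):
        raise EmptyDatasetError("no complete (SSB, R) pairs after alignment")
    return SRRDataset(spawn_years=years[ok], s=s[ok], r=r[ok])
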
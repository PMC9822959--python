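"""Abrupt-change detection in SSB time series (regime-shift flag 1).

Two independent detectors are combined: greedy binary segmentation for changes
in mean (deterministic) and a Bayesian product-partition sampler returning a
per-year posterior change probability.  A *consensus* change is declared where
both methods agree within a small year tolerance, and consecutive consensus
changes must be separated by a minimum gap (the quasi-stability rule: at least
five years between changes by default, so the resulting periods can be read as
quasi-stable SSB regimes).

Change years follow the period-start convention: a change reported at year
``y`` means the new quasi-stable period begins in ``y``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._bcp import GL_LOGW, GL_NODES, gibbs_mean_change
from .exceptions import InputError

__all__ = [
    "ChangePointResult",
    "ConsensusChangePoints",
    "binseg_mean_changepoints",
    "bcp_posterior",
    "consensus_changepoints",
    "exhaustive_min_sse_segmentation",
]


@dataclass
class ChangePointResult:
    """Candidate change years from one detector.

    ``candidate_years`` are first years of new periods; ``scores`` are
    posterior probabilities (bayesian) or penalized log-likelihood gains
    (binseg), one per candidate.
    """

    method: str
    candidate_years: np.ndarray
    scores: np.ndarray
    posterior_trace: Optional[np.ndarray] = None
    years: Optional[np.ndarray] = None

    def __post_init__(self):
        self.candidate_years = np.asarray(self.candidate_years, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.candidate_years.size != self.scores.size:
            raise InputError("one score per candidate required")
        if self.candidate_years.size > 1 and np.any(np.diff(self.candidate_years) <= 0):
            raise InputError("candidate_years must be strictly increasing")


@dataclass
class ConsensusChangePoints:
    """Consensus change years and the quasi-stable periods they delimit."""

    change_years: np.ndarray
    periods: list
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.change_years = np.asarray(self.change_years, dtype=int)


def _prefix_sums(values: np.ndarray):
    s = np.concatenate([[0.0], np.cumsum(values)])
    s2 = np.concatenate([[0.0], np.cumsum(values * values)])
    return s, s2


def _seg_sse(s, s2, a, b):
    """SSE of values[a:b] about its mean (b exclusive)."""
    n = b - a
    tot = s[b] - s[a]
    return (s2[b] - s2[a]) - tot * tot / n


def binseg_mean_changepoints(
    values: Sequence[float],
    max_changes: int = 5,
    min_segment: int = 5,
    penalty: Optional[float] = None,
    years: Optional[Sequence[int]] = None,
) -> ChangePointResult:
    """Greedy binary segmentation for changes in mean.

    At each step the split maximizing the within-segment SSE reduction is
    proposed; it is accepted only if its Gaussian log-likelihood gain (variance
    re-estimated per segment, hence location/scale invariant) exceeds
    ``penalty`` (default: an MBIC-style ``3 log n``) and both child segments
    have at least ``min_segment`` observations.  Candidates are reported as the
    index/year of the first observation of the new segment.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if np.any(~np.isfinite(x)):
        raise InputError("series contains non-finite values")
    if n < 2 * min_segment:
        raise InputError(f"series length {n} < 2*min_segment = {2 * min_segment}")
    if max_changes < 1:
        raise InputError("max_changes must be >= 1")
    yrs = np.arange(n) if years is None else np.asarray(years, dtype=int)
    if yrs.size != n:
        raise InputError("years must match series length")
    if penalty is None:
        penalty = 3.0 * np.log(n)

    s, s2 = _prefix_sums(x)
    total_var = _seg_sse(s, s2, 0, n) / n
    floor = 1e-12 * total_var if total_var > 0 else None

    def ll_cost(a, b):
        sse = _seg_sse(s, s2, a, b)
        m = b - a
        return m * np.log(max(sse / m, floor))

    accepted = []  # (split_index, gain_ll)
    segments = [(0, n)]
    if floor is not None:
        for _ in range(max_changes):
            best = None  # (gain_sse, seg_idx, split)
            for si, (a, b) in enumerate(segments):
                if b - a < 2 * min_segment:
                    continue
                sse_p = _seg_sse(s, s2, a, b)
                for j in range(a + min_segment, b - min_segment + 1):
                    gain = sse_p - _seg_sse(s, s2, a, j) - _seg_sse(s, s2, j, b)
                    if best is None or gain > best[0] + 1e-12 * max(abs(best[0]), 1.0):
                        best = (gain, si, j)
            if best is None:
                break
            _, si, j = best
            a, b = segments[si]
            gain_ll = ll_cost(a, b) - ll_cost(a, j) - ll_cost(j, b)
            if gain_ll <= penalty:
                break
            accepted.append((j, gain_ll))
            segments[si] = (a, j)
            segments.insert(si + 1, (j, b))

    accepted.sort(key=lambda t: t[0])
    idx = np.array([t[0] for t in accepted], dtype=int)
    gains = np.array([t[1] for t in accepted], dtype=float)
    return ChangePointResult(
        method="binseg", candidate_years=yrs[idx] if idx.size else idx, scores=gains, years=yrs
    )


def exhaustive_min_sse_segmentation(
    values: Sequence[float], n_changes: int, min_segment: int = 5
) -> tuple:
    """Brute-force optimal segmentation: enumerate all admissible placements of
    ``n_changes`` change points and return (positions, total SSE) minimizing the
    total within-segment SSE.  Positions are first indices of new segments.

    Intended as an independent oracle for the greedy search on short series.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    s, s2 = _prefix_sums(x)
    if n_changes == 0:
        return (), _seg_sse(s, s2, 0, n)
    best = None
    positions = range(min_segment, n - min_segment + 1)
    for combo in itertools.combinations(positions, n_changes):
        bounds = (0,) + combo + (n,)
        if any(b - a < min_segment for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        sse = sum(_seg_sse(s, s2, a, b) for a, b in zip(bounds[:-1], bounds[1:]))
        if best is None or sse < best[1] - 1e-12:
            best = (combo, sse)
    if best is None:
        raise InputError("no admissible segmentation with the requested spacing")
    return best


def bcp_posterior(
    values: Sequence[float],
    prior_p0: float = 0.2,
    prior_w0: float = 0.2,
    iterations: int = 5000,
    burnin: int = 500,
    seed: int = 0,
    declare_threshold: float = 0.5,
    years: Optional[Sequence[int]] = None,
) -> ChangePointResult:
    """Posterior change probabilities under the Barry-Hartigan partition model.

    Returns a per-year posterior probability that a new period starts in that
    year (``posterior_trace``; position 0 is always 0) and, as candidates, the
    local posterior maxima of runs exceeding ``declare_threshold``.
    Deterministic given ``seed``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 5:
        raise InputError("series must have length >= 5")
    if iterations <= burnin:
        raise InputError("iterations must exceed burnin")
    if not (0 < prior_p0 < 1 and 0 < prior_w0 < 1):
        raise InputError("priors must lie in (0, 1)")
    if np.any(~np.isfinite(x)):
        raise InputError("series contains non-finite values")
    yrs = np.arange(n) if years is None else np.asarray(years, dtype=int)

    trace = np.zeros(n)
    if np.var(x) == 0:
        warnings.warn("zero-variance series: returning all-zero posterior", stacklevel=2)
        return ChangePointResult(
            method="bayesian",
            candidate_years=np.array([], dtype=int),
            scores=np.array([]),
            posterior_trace=trace,
            years=yrs,
        )

    probs = gibbs_mean_change(
        x,
        float(prior_p0),
        float(prior_w0),
        int(iterations),
        int(burnin),
        int(seed),
        GL_NODES,
        GL_LOGW,
    )
    trace[1:] = probs  # boundary i -> new period starts at index i+1

    # local maxima within runs of consecutive positions above the threshold
    cands = []
    i = 1
    while i < n:
        if trace[i] >= declare_threshold:
            j = i
            while j + 1 < n and trace[j + 1] >= declare_threshold:
                j += 1
            k = i + int(np.argmax(trace[i : j + 1]))
            cands.append(k)
            i = j + 1
        else:
            i += 1
    idx = np.array(cands, dtype=int)
    return ChangePointResult(
        method="bayesian",
        candidate_years=yrs[idx] if idx.size else idx,
        scores=trace[idx] if idx.size else np.array([]),
        posterior_trace=trace,
        years=yrs,
    )


def consensus_changepoints(
    bayes: ChangePointResult,
    binseg: ChangePointResult,
    tolerance: int = 1,
    min_gap: int = 5,
    year_range: Optional[tuple] = None,
) -> ConsensusChangePoints:
    """Combine the two detectors with the agreement and minimum-gap rules.

    A consensus change exists where a bayesian and a binseg candidate differ by
    at most ``tolerance`` years (each candidate matches at most once, greedy in
    year order); the binseg year is reported.  Consensus years closer than
    ``min_gap`` are thinned by keeping the one with the higher bayesian
    posterior.  Periods tile ``year_range`` inclusively.
    """
    if tolerance < 0 or min_gap < 1:
        raise InputError("tolerance must be >= 0 and min_gap >= 1")
    if year_range is None:
        if binseg.years is None:
            raise InputError("year_range required when the results carry no year axis")
        year_range = (int(binseg.years[0]), int(binseg.years[-1]))
    y0, y1 = int(year_range[0]), int(year_range[1])

    bayes_years = list(map(int, bayes.candidate_years))
    bayes_scores = list(map(float, bayes.scores))
    matches = []  # (consensus_year, bayes_year, posterior)
    used = [False] * len(bayes_years)
    for by in map(int, binseg.candidate_years):
        best = None
        for k, cy in enumerate(bayes_years):
            if used[k] or abs(cy - by) > tolerance:
                continue
            if best is None or abs(cy - by) < abs(bayes_years[best] - by):
                best = k
        if best is not None:
            used[best] = True
            matches.append((by, bayes_years[best], bayes_scores[best]))

    matches.sort(key=lambda t: t[0])
    # enforce the minimum-gap (quasi-stability) rule
    while True:
        gaps = [
            (m2[0] - m1[0], i) for i, (m1, m2) in enumerate(zip(matches[:-1], matches[1:]))
        ]
        offending = [(g, i) for g, i in gaps if g < min_gap]
        if not offending:
            break
        _, i = min(offending)
        drop = i if matches[i][2] < matches[i + 1][2] else i + 1
        matches.pop(drop)

    change_years = [m[0] for m in matches if y0 < m[0] <= y1]
    matches = [m for m in matches if y0 < m[0] <= y1]
    starts = [y0] + change_years
    ends = [cy - 1 for cy in change_years] + [y1]
    periods = list(zip(starts, ends))
    provenance = [
        {"year": m[0], "binseg_year": m[0], "bayes_year": m[1], "posterior": m[2]}
        for m in matches
    ]
    return ConsensusChangePoints(
        change_years=np.array(change_years, dtype=int), periods=periods, provenance=provenance
    )
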
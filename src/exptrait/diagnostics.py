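"""Distribution-shape diagnostics for total scores.

The qualitative claims about score distributions — right-skew shrinking as
threshold noise grows, right tails straightening on a semi-log plot, the
uniform-threshold condition being log-linear over the whole range — are
quantified here as sample skewness and ordinary least-squares fits of
log frequency on score.  An exponential-shaped total-score distribution
appears as a straight line of slope -lambda-like magnitude on that scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoreHistogram",
    "TailFit",
    "InsufficientTailError",
    "score_histogram",
    "fit_log_linear",
    "sample_skewness",
]

# An OLS line through fewer bins than this says nothing about linearity.
_MIN_BINS = 8


class InsufficientTailError(ValueError):
    """Raised when too few usable bins remain for a meaningful line fit."""


@dataclass(frozen=True)
class ScoreHistogram:
    """Counts over total scores 0..max_score.

    Counts may be non-integer: an analytic pmf scaled by a notional sample
    size is a valid (noise-free) histogram for fitting purposes.
    """

    counts: np.ndarray
    n: float

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def scores(self) -> np.ndarray:
        return np.arange(len(self.counts))

    @property
    def modal_score(self) -> int:
        return int(np.argmax(self.counts))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"score": self.scores, "count": self.counts}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class TailFit:
    """OLS fit of ln(count) on score over a selected score range."""

    slope: float
    intercept: float
    r_squared: float
    scores_used: tuple[int, ...]
    n_bins_used: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_bins_used", len(self.scores_used))
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "slope": self.slope,
                "intercept": self.intercept,
                "r_squared": self.r_squared,
                "scores_used": list(self.scores_used),
                "n_bins_used": self.n_bins_used,
            },
            indent=2,
        )


def score_histogram(totals: np.ndarray, max_score: int) -> ScoreHistogram:
    """Tabulate counts[k] = #{totals == k} for k = 0..max_score."""
    totals = np.asarray(totals)
    if totals.size and (totals.min() < 0 or totals.max() > max_score):
        raise ValueError(
            f"totals outside [0, {max_score}]: range "
            f"[{totals.min()}, {totals.max()}]"
        )
    counts = np.bincount(totals.astype(np.int64), minlength=max_score + 1).astype(
        float
    )
    return ScoreHistogram(counts=counts, n=float(totals.size))


def fit_log_linear(
    hist: ScoreHistogram,
    range_policy: str = "right_tail",
    min_count: float = 5.0,
) -> TailFit:
    """OLS of ln(count) on score over the selected range.

    ``right_tail`` starts at the modal score (the low-score region is where
    real and simulated score distributions deviate from the exponential
    pattern); ``full_range`` starts at 0.  Bins with count below
    ``min_count`` are excluded — log of a zero or near-empty bin is
    noise-dominated, not evidence about the tail.  The top (ceiling) bin is
    also excluded: under a bounded threshold family every respondent whose
    latent severity exceeds the whole threshold range piles up at the
    maximum score, a censoring atom rather than part of the distribution's
    shape.  Fewer than 8 usable bins raises
    :class:`InsufficientTailError` rather than fitting silently.
    """
    if range_policy not in ("right_tail", "full_range"):
        raise ValueError(f"unknown range_policy {range_policy!r}")
    counts = hist.counts
    start = hist.modal_score if range_policy == "right_tail" else 0
    scores = hist.scores
    usable = (scores >= start) & (counts >= min_count) & (scores < len(counts) - 1)
    if usable.sum() < _MIN_BINS:
        raise InsufficientTailError(
            f"only {int(usable.sum())} usable bins (need {_MIN_BINS}) in "
            f"{range_policy} starting at score {start}"
        )
    x = scores[usable].astype(float)
    y = np.log(counts[usable])
    res = stats.linregress(x, y)
    return TailFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        scores_used=tuple(int(s) for s in scores[usable]),
    )


def sample_skewness(totals: np.ndarray) -> float:
    """Adjusted Fisher-Pearson skewness, g1 * sqrt(n(n-1))/(n-2).

    Requires n >= 3 and nonzero variance; this is the bias-adjusted
    standardized third moment conventionally reported for survey score
    distributions.
    """
    totals = np.asarray(totals, dtype=float)
    if totals.size < 3:
        raise ValueError(f"need at least 3 observations, got {totals.size}")
    if np.var(totals) == 0:
        raise ValueError("skewness undefined for zero-variance input")
    return float(stats.skew(totals, bias=False))
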
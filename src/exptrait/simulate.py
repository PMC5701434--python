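"""Monte-Carlo engine for the binary comparison scoring model.

Each simulated respondent gets one exponential latent-severity draw and an
independent threshold draw per question; a question scores 1 exactly when
the latent value strictly exceeds its threshold, and the total score is
the row sum.  Thresholds are drawn fresh per respondent and per question
(items are locally independent, and nothing couples a respondent's
thresholds across questions), and negative normal draws are kept: a
below-zero threshold is always exceeded by the nonnegative latent trait,
which is part of the large-sigma behaviour the model studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import LatentModel, ThresholdSpec, calibrate_thresholds
from .instrument import InstrumentSpec
from .prevalence import PrevalenceTable

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "draw_latent",
    "draw_thresholds",
    "score_binary",
    "simulate_condition",
]


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation condition: latent model, threshold spec, size, seed.

    ``n`` defaults to 10,000 respondents, the scale of the population
    surveys the model is benchmarked against.
    """

    latent: LatentModel
    thresholds: ThresholdSpec
    n: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    def to_json(self) -> str:
        d: dict = {
            "lambda": self.latent.rate,
            "n": self.n,
            "seed": self.seed,
            "threshold_family": self.thresholds.family,
        }
        if self.thresholds.family == "normal":
            d["threshold_sd"] = self.thresholds.sd
            if self.thresholds.means is not None:
                d["threshold_means"] = list(map(float, self.thresholds.means))
        else:
            d["threshold_bounds"] = list(self.thresholds.bounds)
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class SimulationResult:
    """Scores and totals for one simulated condition.

    ``scores`` is the n x Q binary matrix, ``totals`` its row sums,
    ``empirical_prevalence`` its column means.
    """

    totals: np.ndarray
    scores: np.ndarray
    config: SimulationConfig
    empirical_prevalence: np.ndarray

    def totals_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"respondent": np.arange(1, len(self.totals) + 1), "total": self.totals}
        ).to_csv(path, index=False)


def draw_latent(n: int, latent: LatentModel, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. Exp(rate) latent-severity draws (mean and SD both 1/rate)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return rng.exponential(scale=1.0 / latent.rate, size=n)


def draw_thresholds(
    n: int,
    spec: ThresholdSpec,
    rng: np.random.Generator,
    n_questions: int | None = None,
) -> np.ndarray:
    """n x Q matrix of threshold draws, independent over cells.

    Normal family: row r, column q ~ Normal(means[q], sd**2); no truncation
    of negative values.  Uniform family: all cells ~ Uniform(a, b), with Q
    given by ``n_questions``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if spec.family == "normal":
        if spec.means is None:
            raise ValueError("normal spec has no means; calibrate it first")
        q = len(spec.means)
        return rng.normal(loc=spec.means, scale=spec.sd, size=(n, q))
    if n_questions is None:
        raise ValueError("uniform family needs n_questions")
    a, b = spec.bounds
    return rng.uniform(a, b, size=(n, n_questions))


def score_binary(latent: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Binary score matrix: 1 where latent strictly exceeds the threshold.

    Ties score 0 — they have probability zero under the continuous model,
    so the choice only matters for degenerate inputs.
    """
    latent = np.asarray(latent, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 2 or thresholds.shape[0] != latent.shape[0]:
        raise ValueError(
            f"shape mismatch: latent {latent.shape} vs thresholds {thresholds.shape}"
        )
    return (latent[:, None] > thresholds).astype(np.int8)


def simulate_condition(
    config: SimulationConfig,
    instrument: InstrumentSpec,
    prevalence: PrevalenceTable | None = None,
) -> SimulationResult:
    """Run one full condition: calibrate, draw, score, aggregate.

    If the config's normal-family spec has no means yet they are calibrated
    from ``prevalence``.  A single seeded generator drives the latent and
    threshold draws, so results are bit-reproducible from the seed.
    """
    spec = config.thresholds
    if spec.family == "normal" and spec.means is None:
        if prevalence is None:
            raise ValueError("uncalibrated normal spec requires a prevalence table")
        if not prevalence.matches(instrument):
            raise ValueError("prevalence table does not match instrument questions")
        spec = calibrate_thresholds(prevalence, config.latent, spec.sd)
    if spec.family == "normal" and len(spec.means) != instrument.n_questions:
        raise ValueError(
            f"spec covers {len(spec.means)} questions, instrument has "
            f"{instrument.n_questions}"
        )
    rng = np.random.default_rng(config.seed)
    latent = draw_latent(config.n, config.latent, rng)
    thresholds = draw_thresholds(config.n, spec, rng, instrument.n_questions)
    scores = score_binary(latent, thresholds)
    totals = scores.sum(axis=1).astype(np.int64)
    return SimulationResult(
        totals=totals,
        scores=scores,
        config=config,
        empirical_prevalence=scores.mean(axis=0),
    )
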
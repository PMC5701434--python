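"""Semi-analytic total-score distribution (Poisson-binomial mixture).

Conditional on a latent value x, the Q question scores are independent
Bernoulli variables with probabilities P(T_q < x), so the conditional
total is Poisson-binomial; marginalising over the exponential latent
density by adaptive quadrature yields the exact total-score pmf.  This is
the sampling-noise-free counterpart of the Monte-Carlo engine and the
reference the simulator is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .calibration import LatentModel, ThresholdSpec
from .instrument import InstrumentSpec

__all__ = [
    "TotalPmf",
    "item_prob_given_latent",
    "poisson_binomial_pmf",
    "total_pmf",
    "tv_distance",
]

# Latent mass beyond the quadrature cutoff; folded back in by evaluating
# the conditional pmf at the cutoff.
_TAIL_MASS = 1e-10


@dataclass(frozen=True)
class TotalPmf:
    """Exact pmf over total scores 0..Q with its quadrature tolerance."""

    probabilities: np.ndarray
    tol: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0):
            raise ValueError("pmf entries must be nonnegative")
        if abs(p.sum() - 1.0) > 10 * self.tol:
            raise ValueError(
                f"pmf sums to {p.sum():.3e}, outside 1 +/- {10 * self.tol:.1e}"
            )
        object.__setattr__(self, "probabilities", p)

    @property
    def scores(self) -> np.ndarray:
        return np.arange(len(self.probabilities))

    @property
    def modal_score(self) -> int:
        return int(np.argmax(self.probabilities))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"score": self.scores, "probability": self.probabilities}
        ).to_csv(path, index=False)


def item_prob_given_latent(x: float, spec: ThresholdSpec, q: int) -> float:
    """Probability question q is endorsed given latent value x.

    Normal family: Phi((x - mu_q)/sigma), degenerating to a step at mu_q
    when sigma = 0.  Uniform(a, b): (x - a)/(b - a) clamped to [0, 1].
    """
    if spec.family == "normal":
        mu = float(spec.means[q])
        if spec.sd == 0:
            return float(x > mu)
        return float(stats.norm.cdf((x - mu) / spec.sd))
    a, b = spec.bounds
    return float(np.clip((x - a) / (b - a), 0.0, 1.0))


def poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(probs[q]) variables.

    Iterative convolution (dynamic programming), O(Q^2) — exact and cheap
    at the question counts involved here (Q <= 57).
    """
    probs = np.asarray(probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return _pb_pmf(probs)


def _pb_pmf(probs: np.ndarray) -> np.ndarray:
    pmf = np.array([1.0])
    for p in probs:
        nxt = np.empty(len(pmf) + 1)
        nxt[:-1] = pmf * (1.0 - p)
        nxt[-1] = 0.0
        nxt[1:] += pmf * p
        pmf = nxt
    return pmf


def total_pmf(
    instrument: InstrumentSpec,
    spec: ThresholdSpec,
    latent: LatentModel,
    tol: float = 1e-8,
) -> TotalPmf:
    """Marginal total-score pmf: integrate the conditional Poisson-binomial
    over the exponential latent density.

    probabilities[k] = int_0^inf rate*exp(-rate*x) * PB(k; probs(x)) dx,
    computed by adaptive vector quadrature to absolute tolerance ``tol`` on
    [0, U] with U the latent quantile of 1 - 1e-10; the residual tail mass
    is assigned by evaluating the conditional pmf at U.
    """
    if not tol > 0:
        raise ValueError("tol must be positive")
    q_count = instrument.n_questions
    if spec.family == "normal" and len(spec.means) != q_count:
        raise ValueError("spec does not cover all instrument questions")
    rate = latent.rate
    upper = stats.expon.isf(_TAIL_MASS, scale=1.0 / rate)

    if spec.family == "normal":
        mu, sd = spec.means, spec.sd

        def probs_at(x: float) -> np.ndarray:
            if sd == 0:
                return (x > mu).astype(float)
            return stats.norm.cdf((x - mu) / sd)

    else:
        a, b = spec.bounds

        def probs_at(x: float) -> np.ndarray:
            return np.full(q_count, np.clip((x - a) / (b - a), 0.0, 1.0))

    def integrand(x: float) -> np.ndarray:
        return rate * np.exp(-rate * x) * _pb_pmf(probs_at(x))

    res = integrate.quad_vec(integrand, 0.0, upper, epsabs=tol, epsrel=1e-12)
    probs, err = res[0], res[1]
    if err > 10 * tol:
        raise RuntimeError(
            f"quadrature did not converge: achieved error {err:.3e} > {10 * tol:.1e}"
        )
    probs = probs + _TAIL_MASS * _pb_pmf(probs_at(upper))
    probs = np.clip(probs, 0.0, None)
    return TotalPmf(probabilities=probs, tol=tol)


def tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two pmfs on the same score range."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    return float(0.5 * np.abs(p - q).sum())
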
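"""Conjugate Gaussian beliefs over the cause of sensory data.

The stimulus source emits samples x ~ N(μ, σ²); the perceiver holds a
Gaussian prior N(η, s_p) over the cause μ and an observation model with
sensory variance s_l (assumed to estimate σ²).  With known sensory
variance the posterior after n samples is again Gaussian, with

    mean     (n s_p x̄ + s_l η) / (n s_p + s_l)
    variance  s_p s_l / (n s_p + s_l)

Sample variance uses the maximum-likelihood divisor n: the quadratic
expansion of the joint log-likelihood, n(μ − x̄)² + nS, is an identity
only under that convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GaussianBelief",
    "SensoryModel",
    "SampleSummary",
    "summarize_samples",
    "neg_log_likelihood",
    "posterior_update",
    "gaussian_kl",
    "gaussian_entropy",
    "read_samples_csv",
    "sensory_model_from_summary",
]


@dataclass(frozen=True)
class GaussianBelief:
    """Mean/variance pair standing for a prior, posterior, or staged posterior."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not (self.variance > 0 and math.isfinite(self.variance)):
            raise ValueError(f"belief variance must be positive, got {self.variance}")


@dataclass(frozen=True)
class SensoryModel:
    """Observation-noise model: sensory variance s_l estimating σ²."""

    sensory_variance: float

    def __post_init__(self) -> None:
        if not (self.sensory_variance > 0 and math.isfinite(self.sensory_variance)):
            raise ValueError(
                f"sensory variance must be positive, got {self.sensory_variance}"
            )


@dataclass(frozen=True)
class SampleSummary:
    """Sufficient statistics (n, x̄, S) of a sensory sample; S has divisor n.

    With n = 0 the mean and variance fields are ignored.
    """

    n: int
    sample_mean: float = 0.0
    sample_variance: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("sample count must be non-negative")
        if self.n >= 1 and self.sample_variance < 0:
            raise ValueError("sample variance must be non-negative")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "sample_mean": self.sample_mean,
            "sample_variance": self.sample_variance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def summarize_samples(samples: Sequence[float] | np.ndarray) -> SampleSummary:
    """Reduce raw samples to (n, x̄, S) with the MLE variance convention."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("at least one sample is required")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples contain non-finite values")
    mean = float(x.mean())
    return SampleSummary(n=int(x.size), sample_mean=mean, sample_variance=float(np.mean((x - mean) ** 2)))


def neg_log_likelihood(summary: SampleSummary, mu: float, sensory: SensoryModel) -> float:
    """−ln p(x^n | μ) = (n/2) ln 2π s_l + [n(μ − x̄)² + nS] / (2 s_l)."""
    if summary.n < 1:
        raise ValueError("negative log-likelihood needs at least one sample")
    n, sl = summary.n, sensory.sensory_variance
    quad = n * (mu - summary.sample_mean) ** 2 + n * summary.sample_variance
    return 0.5 * n * math.log(2.0 * math.pi * sl) + quad / (2.0 * sl)


def posterior_update(
    prior: GaussianBelief, summary: SampleSummary, sensory: SensoryModel
) -> GaussianBelief:
    """Conjugate posterior over the cause μ given n samples; n = 0 is a no-op."""
    if summary.n == 0:
        return prior
    n, sp, sl = summary.n, prior.variance, sensory.sensory_variance
    denom = n * sp + sl
    return GaussianBelief(
        mean=(n * sp * summary.sample_mean + sl * prior.mean) / denom,
        variance=sp * sl / denom,
    )


def gaussian_kl(a: GaussianBelief, b: GaussianBelief) -> float:
    """KL(N(a) ‖ N(b)) in nats; zero iff the beliefs coincide."""
    va, vb = a.variance, b.variance
    return 0.5 * (math.log(vb / va) + (va + (a.mean - b.mean) ** 2) / vb - 1.0)


def gaussian_entropy(variance: float) -> float:
    """Differential entropy ½(ln 2πσ² + 1) of a Gaussian, in nats."""
    if not (variance > 0 and math.isfinite(variance)):
        raise ValueError(f"variance must be positive, got {variance}")
    return 0.5 * (math.log(2.0 * math.pi * variance) + 1.0)


def sensory_model_from_summary(summary: SampleSummary) -> SensoryModel:
    """Optional helper setting s_l to the sample variance S."""
    return SensoryModel(sensory_variance=summary.sample_variance)


def read_samples_csv(path) -> np.ndarray:
    """Read a raw sample vector from a single-column CSV (header optional)."""
    df = pd.read_csv(path, header=None)
    if df.shape[1] != 1:
        raise ValueError(f"expected a single numeric column, found {df.shape[1]}")
    col = df.iloc[:, 0]
    try:
        float(col.iloc[0])
    except (TypeError, ValueError):
        col = col.iloc[1:]
    if col.empty:
        raise ValueError("no numeric samples found")
    return col.astype(float).to_numpy()
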
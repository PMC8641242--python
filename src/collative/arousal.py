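"""Closed-form arousal quantities under the Gaussian generative model.

With a Gaussian prior N(η, s_p), sensory variance s_l, and n samples of
mean x̄ and (MLE) variance S, each of the three arousal quantities is an
exact quadratic in the prediction error δ = x̄ − η:

    information gain  G_n = A_G δ² + B_G   (KL from posterior to prior)
    uncertainty       U_n = A_U δ² + B_U   (⟨−ln p(x^n|μ)⟩ over the posterior)
    free energy       F_n = G_n + U_n = A_F δ² + B_F

with, writing X = n s_p + s_l,

    A_G = n² s_p / (2X²)          B_G = −½[ln(s_l/X) + n s_p/X]
    A_U = n s_l / (2X²)           B_U = (n/2)[s_p/X + ln 2π s_l + S/s_l]
    A_F = n / (2X)                B_F = ½[ln X + (n−1) ln s_l + n ln 2π + nS/s_l]

The additivity A_F = A_G + A_U, B_F = B_G + B_U holds exactly.  The staged
(two-batch) forms treat the belief after n samples as the prior for m
further samples from the same source; as n grows the gain vanishes and the
uncertainty converges to m times the entropy of the source, which is the
sense in which uncertainty becomes perceived complexity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .gaussian import gaussian_entropy

__all__ = [
    "QuadraticArousalForm",
    "StagedMeasures",
    "AsymptoticLimits",
    "information_gain_quadratic",
    "uncertainty_quadratic",
    "free_energy_quadratic",
    "staged_measures",
    "asymptotic_limits",
    "coefficients_to_json",
]

GAIN = "gain"
UNCERTAINTY = "uncertainty"
FREE_ENERGY = "free_energy"
QUANTITIES = (GAIN, UNCERTAINTY, FREE_ENERGY)


def _check_params(n: int, s_p: float, s_l: float, S: float | None = None, min_n: int = 1) -> None:
    if int(n) != n or n < min_n:
        raise ValueError(f"sample count n must be an integer >= {min_n}, got {n}")
    if not (s_p > 0 and math.isfinite(s_p)):
        raise ValueError(f"prior variance must be positive, got {s_p}")
    if not (s_l > 0 and math.isfinite(s_l)):
        raise ValueError(f"sensory variance must be positive, got {s_l}")
    if S is not None and not (S >= 0 and math.isfinite(S)):
        raise ValueError(f"sample variance must be non-negative, got {S}")


@dataclass(frozen=True)
class QuadraticArousalForm:
    """An arousal quantity as A·δ² + B with its generating parameters."""

    gradient_coeff: float
    intercept: float
    quantity: str
    n: int
    s_p: float
    s_l: float
    S: float | None = None

    def __call__(self, delta):
        return self.gradient_coeff * delta**2 + self.intercept

    def to_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "n": self.n,
            "s_p": self.s_p,
            "s_l": self.s_l,
            "S": self.S,
            "A": self.gradient_coeff,
            "B": self.intercept,
        }


def coefficients_to_json(*forms: QuadraticArousalForm, indent: int | None = 2) -> str:
    records = [f.to_dict() for f in forms]
    return json.dumps(records[0] if len(records) == 1 else records, indent=indent)


def information_gain_quadratic(n: int, s_p: float, s_l: float) -> QuadraticArousalForm:
    """Information gain (Bayesian surprise) KL(posterior ‖ prior) as A_G δ² + B_G."""
    _check_params(n, s_p, s_l)
    x = n * s_p + s_l
    a = n * n * s_p / (2.0 * x * x)
    b = -0.5 * (math.log(s_l / x) + n * s_p / x)
    return QuadraticArousalForm(a, b, GAIN, n, s_p, s_l)


def uncertainty_quadratic(n: int, s_p: float, s_l: float, S: float) -> QuadraticArousalForm:
    """Uncertainty ⟨−ln p(x^n|μ)⟩ over the posterior as A_U δ² + B_U."""
    _check_params(n, s_p, s_l, S)
    x = n * s_p + s_l
    a = n * s_l / (2.0 * x * x)
    b = 0.5 * n * (s_p / x + math.log(2.0 * math.pi * s_l) + S / s_l)
    return QuadraticArousalForm(a, b, UNCERTAINTY, n, s_p, s_l, S)


def free_energy_quadratic(n: int, s_p: float, s_l: float, S: float) -> QuadraticArousalForm:
    """Minimised free energy G + U as A_F δ² + B_F."""
    _check_params(n, s_p, s_l, S)
    x = n * s_p + s_l
    a = 0.5 * n / x
    b = 0.5 * (
        math.log(x) + (n - 1) * math.log(s_l) + n * math.log(2.0 * math.pi) + n * S / s_l
    )
    return QuadraticArousalForm(a, b, FREE_ENERGY, n, s_p, s_l, S)


@dataclass(frozen=True)
class StagedMeasures:
    """Gain, uncertainty and free energy of m further samples after n."""

    gain: float
    uncertainty: float
    free_energy: float


def staged_measures(
    n: int, m: int, s_p: float, s_l: float, S: float, delta: float
) -> StagedMeasures:
    """Two-batch arousal measures: belief after n samples faces m more.

    The belief after n samples, N(η_n, s_n), plays the prior; the
    posterior incorporates n + m samples.  x̄ and S describe the common
    stimulus source, so δ = x̄ − η is still measured against the original
    prior mean.  At n = 0 the forms reduce exactly to the single-stage
    quadratics at count m.
    """
    _check_params(m, s_p, s_l, S)
    if int(n) != n or n < 0:
        raise ValueError(f"first-stage count n must be a non-negative integer, got {n}")
    x = n * s_p + s_l
    y = (n + m) * s_p + s_l
    # -ln(X/Y) + X/Y - 1 evaluated stably for X/Y -> 1 (large n)
    t = -m * s_p / y
    gain = 0.5 * (m * m * s_p * s_l * delta * delta / (x * y * y) + t - math.log1p(t))
    uncertainty = 0.5 * m * (
        s_l * delta * delta / (y * y)
        + s_p / y
        + math.log(2.0 * math.pi * s_l)
        + S / s_l
    )
    return StagedMeasures(gain=gain, uncertainty=uncertainty, free_energy=gain + uncertainty)


@dataclass(frozen=True)
class AsymptoticLimits:
    """n → ∞ limits: gain vanishes, uncertainty reaches m·H(source)."""

    gain_limit: float
    uncertainty_limit: float


def asymptotic_limits(m: int, s_l: float) -> AsymptoticLimits:
    """Infinite-experience limits of the staged measures (S → s_l)."""
    if int(m) != m or m < 1:
        raise ValueError(f"batch size m must be a positive integer, got {m}")
    return AsymptoticLimits(gain_limit=0.0, uncertainty_limit=m * gaussian_entropy(s_l))
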
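"""Sensitivity of the quadratic arousal coefficients to the two variances.

Each arousal quantity is A·δ² + B in the prediction error δ, so the effect
of prior variance s_p or sensory variance s_l splits into an effect on the
gradient A (sensitivity to prediction error) and on the intercept B (the
level at δ = 0).  All ten non-trivial derivatives have closed forms; the
qualitative picture, writing X = n s_p + s_l:

    ∂A_U/∂s_p < 0      ∂B_U/∂s_p ≥ 0      ∂A_F/∂s_p < 0      ∂B_F/∂s_p > 0
    ∂A_G/∂s_l ≤ 0      ∂B_G/∂s_l < 0      ∂A_F/∂s_l < 0      ∂B_F/∂s_l > 0
    ∂A_U/∂s_l has the sign of (n s_p − s_l);   ∂B_U/∂s_l > 0

Because A falls while B rises (for s_p always; for s_l in free energy),
curves for low and high variance cross at a positive prediction error δ*:
the setting that arouses more under small prediction errors arouses less
under large ones.  ``crossover_prediction_error`` locates δ*.

Sensory-variance derivatives are taken, by default, with the sample
variance coupled to the sensory variance at a fixed ratio S/s_l (the model
treats s_l as an estimate of the source variance, so S ≃ s_l moves with
it).  Set ``couple_sample_variance=False`` for the plain partial at
constant S; the coupled convention is what makes ∂B_U/∂s_l and ∂B_F/∂s_l
unconditionally positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .arousal import FREE_ENERGY, GAIN, UNCERTAINTY, QuadraticArousalForm

__all__ = [
    "PRIOR_VARIANCE",
    "SENSORY_VARIANCE",
    "GradientRecord",
    "CrossoverResult",
    "coefficient_gradients",
    "gradients_table",
    "sign_classification",
    "crossover_prediction_error",
    "has_interaction",
]

PRIOR_VARIANCE = "prior_variance"
SENSORY_VARIANCE = "sensory_variance"

NEGATIVE = "negative"
POSITIVE = "positive"
CONDITIONAL = "conditional"


@dataclass(frozen=True)
class GradientRecord:
    """Derivatives of one quantity's (A, B) pair w.r.t. one variance."""

    quantity: str
    parameter: str
    d_gradient_coeff: float
    d_intercept: float
    gradient_sign: str
    intercept_sign: str
    condition: str | None = None
    condition_holds: bool | None = None


def _check(n: int, s_p: float, s_l: float, S: float) -> None:
    if int(n) != n or n < 1:
        raise ValueError(f"sample count n must be a positive integer, got {n}")
    for name, v in (("prior variance", s_p), ("sensory variance", s_l)):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{name} must be positive, got {v}")
    if not (S >= 0 and math.isfinite(S)):
        raise ValueError(f"sample variance must be non-negative, got {S}")


def coefficient_gradients(
    n: int,
    s_p: float,
    s_l: float,
    S: float,
    couple_sample_variance: bool = True,
) -> list[GradientRecord]:
    """All six (quantity × parameter) derivative pairs at the given point."""
    _check(n, s_p, s_l, S)
    x = n * s_p + s_l
    x2, x3 = x * x, x * x * x

    records = [
        GradientRecord(
            GAIN,
            PRIOR_VARIANCE,
            d_gradient_coeff=n * n * (s_l - n * s_p) / (2.0 * x3),
            d_intercept=n * n * s_p / (2.0 * x2),
            gradient_sign=CONDITIONAL,
            intercept_sign=POSITIVE,
            condition="s_l > n*s_p",
            condition_holds=s_l > n * s_p,
        ),
        GradientRecord(
            UNCERTAINTY,
            PRIOR_VARIANCE,
            d_gradient_coeff=-n * n * s_l / x3,
            d_intercept=n * s_l / (2.0 * x2),
            gradient_sign=NEGATIVE,
            intercept_sign=POSITIVE,
        ),
        GradientRecord(
            FREE_ENERGY,
            PRIOR_VARIANCE,
            d_gradient_coeff=-n * n / (2.0 * x2),
            d_intercept=n / (2.0 * x),
            gradient_sign=NEGATIVE,
            intercept_sign=POSITIVE,
        ),
        GradientRecord(
            GAIN,
            SENSORY_VARIANCE,
            d_gradient_coeff=-n * n * s_p / x3,
            d_intercept=-n * n * s_p * s_p / (2.0 * s_l * x2),
            gradient_sign=NEGATIVE,
            intercept_sign=NEGATIVE,
        ),
    ]

    # Sensory-variance derivatives of the S-bearing intercepts.
    if couple_sample_variance:
        db_u = 0.5 * n * (1.0 / s_l - s_p / x2)
        db_f = 0.5 * (1.0 / x + (n - 1) / s_l)
        b_u_sign = POSITIVE
        b_f_sign = POSITIVE
        b_cond = None
        b_holds = None
    else:
        db_u = 0.5 * n * (1.0 / s_l - S / (s_l * s_l) - s_p / x2)
        db_f = 0.5 * (1.0 / x + (n - 1) / s_l - n * S / (s_l * s_l))
        b_u_sign = CONDITIONAL
        b_f_sign = CONDITIONAL
        b_cond = "(s_l - S)/s_l**2 > s_p/(n*s_p + s_l)**2"
        b_holds = (s_l - S) / (s_l * s_l) > s_p / x2

    records.append(
        GradientRecord(
            UNCERTAINTY,
            SENSORY_VARIANCE,
            d_gradient_coeff=0.5 * n * (n * s_p - s_l) / x3,
            d_intercept=db_u,
            gradient_sign=CONDITIONAL,
            intercept_sign=b_u_sign,
            condition="n*s_p > s_l" if b_cond is None else f"n*s_p > s_l; intercept: {b_cond}",
            condition_holds=(n * s_p > s_l) if b_holds is None else b_holds,
        )
    )
    records.append(
        GradientRecord(
            FREE_ENERGY,
            SENSORY_VARIANCE,
            d_gradient_coeff=-0.5 * n / x2,
            d_intercept=db_f,
            gradient_sign=NEGATIVE,
            intercept_sign=b_f_sign,
            condition=b_cond,
            condition_holds=b_holds,
        )
    )
    return records


def gradients_table(
    n: int, s_p: float, s_l: float, S: float, couple_sample_variance: bool = True
) -> pd.DataFrame:
    """Gradient records as a flat table (CSV-ready)."""
    recs = coefficient_gradients(n, s_p, s_l, S, couple_sample_variance)
    return pd.DataFrame(
        [
            {
                "quantity": r.quantity,
                "parameter": r.parameter,
                "d_gradient": r.d_gradient_coeff,
                "d_intercept": r.d_intercept,
                "gradient_sign": r.gradient_sign,
                "intercept_sign": r.intercept_sign,
                "condition": r.condition or "",
                "condition_holds": "" if r.condition_holds is None else r.condition_holds,
            }
            for r in recs
        ]
    )


def sign_classification(n: int, s_p: float, s_l: float) -> pd.DataFrame:
    """Qualitative effect of sensory variance on each quantity's A and B.

    The ``effect`` column comes from the exact derivatives (coupled
    convention); ``tabulated_condition`` carries the condition usually
    quoted with the effect, evaluated at the given parameters.
    """
    _check(n, s_p, s_l, 0.0)
    rows = [
        {
            "quantity": UNCERTAINTY,
            "coefficient": "gradient",
            "effect": "increase" if n * s_p > s_l else "decrease",
            "tabulated_condition": "n*s_p > s_l",
            "condition_holds": n * s_p > s_l,
        },
        {
            "quantity": UNCERTAINTY,
            "coefficient": "intercept",
            "effect": "increase",
            "tabulated_condition": "n*s_p + s_l >= 1",
            "condition_holds": n * s_p + s_l >= 1,
        },
        {
            "quantity": GAIN,
            "coefficient": "gradient",
            "effect": "decrease",
            "tabulated_condition": "",
            "condition_holds": True,
        },
        {
            "quantity": GAIN,
            "coefficient": "intercept",
            "effect": "decrease",
            "tabulated_condition": "s_p > s_l",
            "condition_holds": s_p > s_l,
        },
        {
            "quantity": FREE_ENERGY,
            "coefficient": "gradient",
            "effect": "decrease",
            "tabulated_condition": "",
            "condition_holds": True,
        },
        {
            "quantity": FREE_ENERGY,
            "coefficient": "intercept",
            "effect": "increase",
            "tabulated_condition": "",
            "condition_holds": True,
        },
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CrossoverResult:
    """Where two quadratic forms of the same quantity exchange order.

    ``delta_star`` is the positive prediction error at which the forms
    meet (None when parallel or nested); ``ordering_below`` names the form
    ('a' or 'b') that is larger for δ below the crossing.
    """

    delta_star: float | None
    ordering_below: str | None
    degenerate: bool = False


def crossover_prediction_error(
    form_a: QuadraticArousalForm, form_b: QuadraticArousalForm
) -> CrossoverResult:
    """Positive δ* with A_a δ*² + B_a = A_b δ*² + B_b, if one exists."""
    if form_a.quantity != form_b.quantity:
        raise ValueError(
            f"forms describe different quantities: {form_a.quantity} vs {form_b.quantity}"
        )
    da = form_a.gradient_coeff - form_b.gradient_coeff
    db = form_b.intercept - form_a.intercept
    if da == 0.0 and db == 0.0:
        return CrossoverResult(None, None, degenerate=True)
    if da == 0.0:
        return CrossoverResult(None, "a" if form_a.intercept > form_b.intercept else "b")
    ratio = db / da
    if ratio <= 0.0 or not math.isfinite(ratio):
        return CrossoverResult(None, "a" if form_a.intercept > form_b.intercept else "b")
    return CrossoverResult(
        delta_star=math.sqrt(ratio),
        ordering_below="a" if form_a.intercept > form_b.intercept else "b",
    )


def has_interaction(
    form_a: QuadraticArousalForm,
    form_b: QuadraticArousalForm,
    delta_max: float = 4.0,
) -> bool:
    """True when the two forms cross at some δ* in (0, delta_max]."""
    result = crossover_prediction_error(form_a, form_b)
    return result.delta_star is not None and 0.0 < result.delta_star <= delta_max
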
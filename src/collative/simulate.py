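"""Stimulus sampling, Bayesian-updating trajectories, and parameter sweeps.

A stimulus source emits Gaussian samples N(μ, σ²).  A trajectory
alternates perception (computing the staged gain/uncertainty of the next
batch against the current belief) with learning (conjugate posterior
update), tracking running sufficient statistics instead of storing
samples.  When the sensory variance matches the source variance, the gain
converges to zero and the per-sample uncertainty converges to the entropy
of the source — uncertainty becomes perceived complexity.

Sweeps evaluate the three quadratic arousal forms over a prediction-error
grid for a family of variance settings and flag, per quantity, whether the
extreme settings cross (the interaction signature).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arousal import (
    FREE_ENERGY,
    GAIN,
    UNCERTAINTY,
    free_energy_quadratic,
    information_gain_quadratic,
    staged_measures,
    uncertainty_quadratic,
)
from .gaussian import GaussianBelief, SampleSummary, SensoryModel, posterior_update
from .sensitivity import PRIOR_VARIANCE, SENSORY_VARIANCE, crossover_prediction_error

__all__ = [
    "StimulusSource",
    "TrajectoryRecord",
    "RunConfig",
    "SweepResult",
    "sample_source",
    "bayesian_trajectory",
    "trajectory_frame",
    "sweep_quadratics",
    "load_config",
    "write_csv",
]

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = [
    "step",
    "cumulative_n",
    "gain",
    "uncertainty",
    "free_energy",
    "posterior_mean",
    "posterior_variance",
]
SWEEP_COLUMNS = ["delta", "n", "s_p", "s_l", "S", "gain", "uncertainty", "free_energy"]


@dataclass(frozen=True)
class StimulusSource:
    """Gaussian stimulus source N(μ, σ²) with a mandatory seed."""

    true_mean: float
    true_variance: float
    seed: int

    def __post_init__(self) -> None:
        if not (self.true_variance > 0 and math.isfinite(self.true_variance)):
            raise ValueError(f"source variance must be positive, got {self.true_variance}")


def sample_source(source: StimulusSource, n: int) -> np.ndarray:
    """Draw n samples from the source; identical seed gives identical output."""
    if int(n) != n or n < 1:
        raise ValueError(f"sample count must be a positive integer, got {n}")
    rng = np.random.default_rng(source.seed)
    return rng.normal(source.true_mean, math.sqrt(source.true_variance), int(n))


@dataclass(frozen=True)
class TrajectoryRecord:
    """One perception/learning cycle of a Bayesian-updating run."""

    step: int
    cumulative_n: int
    gain: float
    uncertainty: float
    free_energy: float
    posterior_mean: float
    posterior_variance: float


def bayesian_trajectory(
    prior: GaussianBelief,
    sensory: SensoryModel,
    source: StimulusSource,
    batch_size: int,
    steps: int,
) -> list[TrajectoryRecord]:
    """Alternate perception and learning on batches from the source.

    At each step the staged measures of the incoming batch are computed
    against the belief accumulated so far (via running sufficient
    statistics, so δ and S always refer to the original prior and the full
    sample run), then the posterior is updated.  F = G + U holds at every
    step by construction.
    """
    if int(batch_size) != batch_size or batch_size < 1:
        raise ValueError(f"batch size must be a positive integer, got {batch_size}")
    if int(steps) != steps or steps < 1:
        raise ValueError(f"step count must be a positive integer, got {steps}")
    logger.info(
        "trajectory: seed=%d mu=%g sigma2=%g s_p=%g s_l=%g m=%d steps=%d (collative %s)",
        source.seed, source.true_mean, source.true_variance,
        prior.variance, sensory.sensory_variance, batch_size, steps, __version__,
    )
    rng = np.random.default_rng(source.seed)
    sd = math.sqrt(source.true_variance)
    total_n = 0
    total_sum = 0.0
    total_sq = 0.0
    records: list[TrajectoryRecord] = []
    for step in range(1, int(steps) + 1):
        batch = rng.normal(source.true_mean, sd, int(batch_size))
        n_prev = total_n
        total_n += batch.size
        total_sum += float(batch.sum())
        total_sq += float(np.sum(batch * batch))
        xbar = total_sum / total_n
        s_hat = max(total_sq / total_n - xbar * xbar, 0.0)
        measures = staged_measures(
            n=n_prev,
            m=int(batch_size),
            s_p=prior.variance,
            s_l=sensory.sensory_variance,
            S=s_hat,
            delta=xbar - prior.mean,
        )
        posterior = posterior_update(
            prior, SampleSummary(total_n, xbar, s_hat), sensory
        )
        records.append(
            TrajectoryRecord(
                step=step,
                cumulative_n=total_n,
                gain=measures.gain,
                uncertainty=measures.uncertainty,
                free_energy=measures.free_energy,
                posterior_mean=posterior.mean,
                posterior_variance=posterior.variance,
            )
        )
    return records


def trajectory_frame(records: Sequence[TrajectoryRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=TRAJECTORY_COLUMNS)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for sweeps and simulations (JSON or YAML on disk).

    ``S=None`` couples the sample variance to the sensory variance
    (S = s_l), the figure-reproduction default.
    """

    seed: int
    n: int = 1
    m: int = 1
    s_p: float = 3.0
    s_l: float = 0.5
    S: float | None = None
    delta_grid: tuple[float, ...] = tuple(np.linspace(0.0, 4.0, 401))
    sweep_parameter: str = PRIOR_VARIANCE
    sweep_values: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    mu: float = 0.0
    sigma2: float | None = None
    steps: int = 100


_CONFIG_KEYS = {f.name for f in fields(RunConfig)}
_SWEEP_ALIASES = {"s_p": PRIOR_VARIANCE, "s_l": SENSORY_VARIANCE}


def load_config(path) -> RunConfig:
    """Read a RunConfig from a JSON or YAML file (YAML is a superset)."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ValueError(f"config file {path} does not hold a mapping")
    unknown = set(payload) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in payload:
        raise ValueError("config must set an explicit seed")
    if "delta_grid" in payload:
        payload["delta_grid"] = tuple(float(v) for v in payload["delta_grid"])
    if "sweep_values" in payload:
        payload["sweep_values"] = tuple(float(v) for v in payload["sweep_values"])
    if "sweep_parameter" in payload:
        payload["sweep_parameter"] = _SWEEP_ALIASES.get(
            payload["sweep_parameter"], payload["sweep_parameter"]
        )
    return RunConfig(**payload)


@dataclass(frozen=True)
class SweepResult:
    """Sweep table plus per-quantity interaction flags and crossings."""

    table: pd.DataFrame
    interaction: dict[str, bool]
    crossover: dict[str, float | None]


def _forms_at(n: int, s_p: float, s_l: float, S: float | None):
    s_eff = s_l if S is None else S
    return {
        GAIN: information_gain_quadratic(n, s_p, s_l),
        UNCERTAINTY: uncertainty_quadratic(n, s_p, s_l, s_eff),
        FREE_ENERGY: free_energy_quadratic(n, s_p, s_l, s_eff),
    }


def sweep_quadratics(config: RunConfig) -> SweepResult:
    """Evaluate the three arousal forms over δ × swept-variance grids."""
    if config.sweep_parameter not in (PRIOR_VARIANCE, SENSORY_VARIANCE):
        raise ValueError(f"unknown sweep parameter {config.sweep_parameter!r}")
    deltas = np.asarray(config.delta_grid, dtype=float)
    values = tuple(config.sweep_values)
    if deltas.size == 0 or len(values) == 0:
        raise ValueError("delta grid and sweep values must be non-empty")
    logger.info(
        "sweep: parameter=%s values=%s n=%d seed=%d (collative %s)",
        config.sweep_parameter, values, config.n, config.seed, __version__,
    )

    rows = []
    for value in values:
        s_p = value if config.sweep_parameter == PRIOR_VARIANCE else config.s_p
        s_l = value if config.sweep_parameter == SENSORY_VARIANCE else config.s_l
        forms = _forms_at(config.n, s_p, s_l, config.S)
        s_eff = s_l if config.S is None else config.S
        for delta in deltas:
            rows.append(
                {
                    "delta": delta,
                    "n": config.n,
                    "s_p": s_p,
                    "s_l": s_l,
                    "S": s_eff,
                    "gain": forms[GAIN](delta),
                    "uncertainty": forms[UNCERTAINTY](delta),
                    "free_energy": forms[FREE_ENERGY](delta),
                }
            )
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)

    lo, hi = min(values), max(values)
    delta_max = float(deltas.max())
    interaction: dict[str, bool] = {}
    crossover: dict[str, float | None] = {}
    for quantity in (GAIN, UNCERTAINTY, FREE_ENERGY):
        form_lo = _low_high_form(config, lo)[quantity]
        form_hi = _low_high_form(config, hi)[quantity]
        result = crossover_prediction_error(form_lo, form_hi)
        star = result.delta_star
        crossover[quantity] = star
        interaction[quantity] = star is not None and 0.0 < star <= delta_max
    return SweepResult(table=table, interaction=interaction, crossover=crossover)


def _low_high_form(config: RunConfig, value: float):
    s_p = value if config.sweep_parameter == PRIOR_VARIANCE else config.s_p
    s_l = value if config.sweep_parameter == SENSORY_VARIANCE else config.s_l
    return _forms_at(config.n, s_p, s_l, config.S)


def write_csv(frame: pd.DataFrame, path) -> None:
    """Write a result table with 12 significant digits, fixed column order."""
    frame.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
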
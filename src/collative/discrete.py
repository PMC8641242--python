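"""Exact free-energy accounting on finite generative models.

Perception is modelled as Bayesian inference over a finite set of candidate
causes: a generative model pairs a prior over causes with a likelihood
matrix over a finite sensory alphabet.  On such models every information
quantity of interest — variational free energy, surprisal, Bayesian
surprise (information gain), inverse accuracy (uncertainty) — is an exact
finite sum, so the identities among them hold to machine precision:

    F(q, x) = KL(q ‖ posterior) + surprisal(x)
            = KL(q ‖ prior)     + ⟨−ln p(x|θ)⟩_q

Free energy is bounded below by surprisal, with equality exactly when the
recognition density q equals the Bayesian posterior.  The module also
covers the uncertainty bookkeeping of the learning story: uncertainty
computed under the prior versus under the posterior (their difference is
the symmetrised KL between the two), the predictive-distribution lower
bound, and the cross-entropy decomposition that makes the uncertainty of a
long sample run converge to the entropy of the empirical distribution.

All quantities are in nats.  The convention 0·ln 0 = 0 applies throughout;
recognition mass on outcomes of zero joint probability yields +inf rather
than an exception, so bound properties can be asserted on degenerate
inputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DiscreteDistribution",
    "DiscreteGenerativeModel",
    "DecompositionRecord",
    "UncertaintyRecord",
    "CrossEntropyRecord",
    "SupportMismatchError",
    "ImpossibleObservationError",
    "entropy",
    "kl_divergence",
    "exact_posterior",
    "free_energy",
    "decompose_free_energy",
    "uncertainty_reduction",
    "predictive_cross_entropy",
    "random_distribution",
    "random_model",
    "model_from_json",
    "model_to_json",
    "read_model",
    "write_model",
]

# Input probabilities may carry round-off from user arithmetic; accept a
# small defect and renormalise so downstream identities see exact simplex
# vectors.
_SUM_TOL = 1e-9


class SupportMismatchError(ValueError):
    """A recognition density does not match the model's cause support."""


class ImpossibleObservationError(ValueError):
    """The requested sensory symbol has zero marginal probability."""


def _as_prob_vector(probs: Sequence[float] | np.ndarray, what: str = "distribution") -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError(f"{what} must be a non-empty 1-d vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{what} contains non-finite entries")
    if np.any(p < 0):
        raise ValueError(f"{what} contains negative entries")
    total = float(p.sum())
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"{what} sums to {total:.12g}, expected 1")
    out = p / total
    out.flags.writeable = False
    return out


@dataclass(frozen=True)
class DiscreteDistribution:
    """Probability vector over a finite, optionally labelled support."""

    probs: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        p = _as_prob_vector(self.probs)
        object.__setattr__(self, "probs", p)
        if self.labels is not None:
            labels = tuple(str(c) for c in self.labels)
            if len(labels) != p.size:
                raise ValueError(
                    f"{len(labels)} labels for {p.size} probabilities"
                )
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return int(self.probs.size)

    @classmethod
    def uniform(cls, k: int, labels: Sequence[str] | None = None) -> "DiscreteDistribution":
        return cls(np.full(k, 1.0 / k), tuple(labels) if labels is not None else None)


def entropy(dist: DiscreteDistribution | np.ndarray) -> float:
    """Shannon entropy −Σ p ln p in nats, with 0·ln 0 = 0."""
    p = dist.probs if isinstance(dist, DiscreteDistribution) else _as_prob_vector(dist)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def kl_divergence(
    p: DiscreteDistribution | np.ndarray, q: DiscreteDistribution | np.ndarray
) -> float:
    """KL(p ‖ q) in nats; +inf when p puts mass where q has none."""
    pv = p.probs if isinstance(p, DiscreteDistribution) else _as_prob_vector(p, "p")
    qv = q.probs if isinstance(q, DiscreteDistribution) else _as_prob_vector(q, "q")
    if pv.size != qv.size:
        raise SupportMismatchError(f"supports differ: {pv.size} vs {qv.size}")
    mask = pv > 0
    if np.any(qv[mask] == 0):
        return math.inf
    return float(np.sum(pv[mask] * (np.log(pv[mask]) - np.log(qv[mask]))))


class DiscreteGenerativeModel:
    """Finite generative model p(x, θ) = p(x|θ) p(θ).

    Parameters
    ----------
    prior
        Distribution over causes θ.
    likelihood
        Matrix of conditional probabilities p(x|θ); one row per cause,
        columns over the sensory alphabet.  Every row must sum to one.
    cause_labels, symbol_labels
        Optional names for causes and sensory symbols.  Symbols may then
        be addressed by label anywhere an observation is expected.
    """

    def __init__(
        self,
        prior: DiscreteDistribution | Sequence[float],
        likelihood: Sequence[Sequence[float]] | np.ndarray,
        cause_labels: Sequence[str] | None = None,
        symbol_labels: Sequence[str] | None = None,
    ) -> None:
        if not isinstance(prior, DiscreteDistribution):
            prior = DiscreteDistribution(np.asarray(prior, dtype=float))
        lik = np.asarray(likelihood, dtype=float)
        if lik.ndim != 2:
            raise ValueError(f"likelihood must be a matrix, got shape {lik.shape}")
        if lik.shape[0] != len(prior):
            raise ValueError(
                f"likelihood has {lik.shape[0]} rows for {len(prior)} causes"
            )
        if np.any(lik < 0) or not np.all(np.isfinite(lik)):
            raise ValueError("likelihood entries must be finite and non-negative")
        self.cause_labels = tuple(str(c) for c in cause_labels) if cause_labels else None
        self.symbol_labels = tuple(str(s) for s in symbol_labels) if symbol_labels else None
        if self.cause_labels and len(self.cause_labels) != lik.shape[0]:
            raise ValueError("cause label count does not match likelihood rows")
        if self.symbol_labels and len(self.symbol_labels) != lik.shape[1]:
            raise ValueError("symbol label count does not match likelihood columns")
        row_sums = lik.sum(axis=1)
        for i, total in enumerate(row_sums):
            if abs(total - 1.0) > _SUM_TOL:
                name = self.cause_labels[i] if self.cause_labels else str(i)
                raise ValueError(
                    f"likelihood row {i} (cause {name!r}) sums to {total:.12g}, expected 1"
                )
        lik = lik / row_sums[:, None]
        lik.flags.writeable = False
        self.prior = prior
        self.likelihood = lik

    @property
    def n_causes(self) -> int:
        return self.likelihood.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.likelihood.shape[1]

    def symbol_index(self, x: int | str) -> int:
        if isinstance(x, str):
            if not self.symbol_labels or x not in self.symbol_labels:
                raise KeyError(f"unknown sensory symbol {x!r}")
            return self.symbol_labels.index(x)
        ix = int(x)
        if not 0 <= ix < self.n_symbols:
            raise IndexError(f"symbol index {ix} outside alphabet of size {self.n_symbols}")
        return ix

    def joint(self) -> np.ndarray:
        """Joint matrix p(x, θ), causes on rows, symbols on columns."""
        return self.prior.probs[:, None] * self.likelihood

    def marginal_likelihood(self, x: int | str) -> float:
        """Model evidence p(x) = Σ_θ p(x|θ) p(θ)."""
        ix = self.symbol_index(x)
        return float(self.prior.probs @ self.likelihood[:, ix])


def exact_posterior(model: DiscreteGenerativeModel, x: int | str) -> DiscreteDistribution:
    """Bayes posterior p(θ|x) ∝ p(x|θ) p(θ)."""
    ix = model.symbol_index(x)
    unnorm = model.prior.probs * model.likelihood[:, ix]
    evidence = float(unnorm.sum())
    if evidence <= 0.0:
        raise ImpossibleObservationError(
            f"symbol {x!r} has zero marginal probability under the model"
        )
    return DiscreteDistribution(unnorm / evidence, model.cause_labels)


def _check_recognition(model: DiscreteGenerativeModel, q: DiscreteDistribution | np.ndarray) -> np.ndarray:
    qv = q.probs if isinstance(q, DiscreteDistribution) else _as_prob_vector(q, "recognition density")
    if qv.size != model.n_causes:
        raise SupportMismatchError(
            f"recognition density has {qv.size} entries for {model.n_causes} causes"
        )
    return qv


def free_energy(
    model: DiscreteGenerativeModel, q: DiscreteDistribution | np.ndarray, x: int | str
) -> float:
    """Variational free energy F = ⟨ln q(θ) − ln p(x, θ)⟩_q in nats.

    F ≥ −ln p(x), with equality iff ``q`` equals the exact posterior.
    Recognition mass on causes with zero joint probability gives +inf.
    """
    qv = _check_recognition(model, q)
    ix = model.symbol_index(x)
    joint_col = model.prior.probs * model.likelihood[:, ix]
    mask = qv > 0
    if np.any(joint_col[mask] == 0):
        return math.inf
    return float(np.sum(qv[mask] * (np.log(qv[mask]) - np.log(joint_col[mask]))))


@dataclass(frozen=True)
class DecompositionRecord:
    """The two exact additive decompositions of free energy (nats).

    ``free_energy = kl_to_posterior + surprisal`` (perception reading) and
    ``free_energy = bayesian_surprise + inverse_accuracy`` (arousal
    reading: information gain plus uncertainty).
    """

    free_energy: float
    kl_to_posterior: float
    surprisal: float
    bayesian_surprise: float
    inverse_accuracy: float


def decompose_free_energy(
    model: DiscreteGenerativeModel, q: DiscreteDistribution | np.ndarray, x: int | str
) -> DecompositionRecord:
    """Evaluate free energy together with both of its decompositions."""
    qv = _check_recognition(model, q)
    ix = model.symbol_index(x)
    posterior = exact_posterior(model, x)
    surprisal = -math.log(model.marginal_likelihood(x))
    kl_post = kl_divergence(qv, posterior.probs)
    gain = kl_divergence(qv, model.prior.probs)
    lik_col = model.likelihood[:, ix]
    mask = qv > 0
    if np.any(lik_col[mask] == 0):
        inv_acc = math.inf
    else:
        inv_acc = float(-np.sum(qv[mask] * np.log(lik_col[mask])))
    return DecompositionRecord(
        free_energy=free_energy(model, qv, x),
        kl_to_posterior=kl_post,
        surprisal=surprisal,
        bayesian_surprise=gain,
        inverse_accuracy=inv_acc,
    )


@dataclass(frozen=True)
class UncertaintyRecord:
    """Uncertainty ⟨−ln p(x|θ)⟩ before and after recognition (nats).

    ``u_pri`` averages over the prior, ``u_post`` over the posterior, and
    ``u_star`` is the predictive-distribution lower bound
    −ln⟨p(x|θ)⟩_posterior.  ``reduction = u_pri − u_post`` equals the
    symmetrised KL between prior and posterior, hence is never negative.
    """

    u_pri: float
    u_post: float
    u_star: float
    reduction: float


def _expected_nll(weights: np.ndarray, lik_col: np.ndarray) -> float:
    mask = weights > 0
    if np.any(lik_col[mask] == 0):
        return math.inf
    return float(-np.sum(weights[mask] * np.log(lik_col[mask])))


def uncertainty_reduction(model: DiscreteGenerativeModel, x: int | str) -> UncertaintyRecord:
    """Uncertainty before/after recognising ``x`` plus its lower bound."""
    ix = model.symbol_index(x)
    posterior = exact_posterior(model, x)
    lik_col = model.likelihood[:, ix]
    u_pri = _expected_nll(model.prior.probs, lik_col)
    u_post = _expected_nll(posterior.probs, lik_col)
    u_star = -math.log(float(posterior.probs @ lik_col))
    return UncertaintyRecord(
        u_pri=u_pri, u_post=u_post, u_star=u_star, reduction=u_pri - u_post
    )


@dataclass(frozen=True)
class CrossEntropyRecord:
    """Cross-entropy decomposition of a predictive distribution on count data.

    ``u_star_total`` is the total information of the whole sample run under
    the predictive distribution (n times the cross entropy), and
    ``cross_entropy = kl_to_empirical + empirical_entropy`` with the KL
    term non-negative — the empirical entropy is the attainable floor.
    """

    u_star_total: float
    cross_entropy: float
    kl_to_empirical: float
    empirical_entropy: float


def predictive_cross_entropy(
    predictive: DiscreteDistribution | np.ndarray, counts: Sequence[int] | np.ndarray
) -> CrossEntropyRecord:
    """Decompose the predictive information of an observed count vector."""
    pv = (
        predictive.probs
        if isinstance(predictive, DiscreteDistribution)
        else _as_prob_vector(predictive, "predictive distribution")
    )
    c = np.asarray(counts)
    if c.ndim != 1 or c.size != pv.size:
        raise SupportMismatchError(
            f"counts shape {c.shape} does not match alphabet of size {pv.size}"
        )
    if np.any(c < 0) or not np.all(c == np.round(c)):
        raise ValueError("counts must be non-negative integers")
    n = int(c.sum())
    if n < 1:
        raise ValueError("at least one observation is required")
    f = c.astype(float) / n
    h = entropy(f)
    kl = kl_divergence(f, pv)
    ce = kl + h if math.isfinite(kl) else math.inf
    return CrossEntropyRecord(
        u_star_total=n * ce, cross_entropy=ce, kl_to_empirical=kl, empirical_entropy=h
    )


# ---------------------------------------------------------------------------
# Random instances (flat on the simplex) for property tests and stress runs.


def random_distribution(k: int, rng: np.random.Generator) -> DiscreteDistribution:
    """A probability vector drawn uniformly from the k-simplex."""
    return DiscreteDistribution(rng.dirichlet(np.ones(k)))


def random_model(
    n_causes: int, n_symbols: int, rng: np.random.Generator
) -> DiscreteGenerativeModel:
    """A generative model with flat-simplex prior and likelihood rows."""
    prior = random_distribution(n_causes, rng)
    lik = rng.dirichlet(np.ones(n_symbols), size=n_causes)
    return DiscreteGenerativeModel(prior, lik)


# ---------------------------------------------------------------------------
# JSON round-trip: {"causes": [...], "symbols": [...], "prior": [...],
#                   "likelihood": [[...], ...]}


def model_to_json(model: DiscreteGenerativeModel, indent: int | None = 2) -> str:
    payload = {
        "causes": list(model.cause_labels)
        if model.cause_labels
        else [str(i) for i in range(model.n_causes)],
        "symbols": list(model.symbol_labels)
        if model.symbol_labels
        else [str(i) for i in range(model.n_symbols)],
        "prior": model.prior.probs.tolist(),
        "likelihood": model.likelihood.tolist(),
    }
    return json.dumps(payload, indent=indent)


def model_from_json(text: str) -> DiscreteGenerativeModel:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"model JSON is not valid JSON: {exc}") from exc
    for key in ("prior", "likelihood"):
        if key not in payload:
            raise ValueError(f"model JSON is missing the {key!r} field")
    return DiscreteGenerativeModel(
        prior=np.asarray(payload["prior"], dtype=float),
        likelihood=np.asarray(payload["likelihood"], dtype=float),
        cause_labels=payload.get("causes"),
        symbol_labels=payload.get("symbols"),
    )


def write_model(model: DiscreteGenerativeModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(model_to_json(model))
        fh.write("\n")


def read_model(path) -> DiscreteGenerativeModel:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_json(fh.read())
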
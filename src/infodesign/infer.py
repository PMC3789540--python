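"""Likelihoods, Bayesian posterior over the hypothesis class, realized gain.

Measurements are conditionally independent given the model and its
parameters; parameter uncertainty is marginalized through the predictive
distribution (Gaussian covariance from the unscented transform, or a
particle mixture from Monte Carlo propagation), so every likelihood stays
closed-form.  All internal entropies and log-probabilities are in nats;
conversion to bits happens only at the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp

from .models import DesignSpace
from .propagate import PredictiveDistribution

__all__ = [
    "InferenceError",
    "Experiment",
    "Dataset",
    "BeliefState",
    "log_likelihood",
    "posterior",
    "information_gain",
    "sequential_update",
    "restricted_gaussian",
]

LOG2 = math.log(2.0)


class InferenceError(RuntimeError):
    """Posterior update failure (e.g. data impossible under every model)."""


@dataclass(frozen=True)
class Experiment:
    """Ordered multiset of (time index, readout index) pairs of a design space."""

    pairs: tuple[tuple[int, int], ...]

    def __init__(self, pairs: Sequence[tuple[int, int]]):
        object.__setattr__(self, "pairs", tuple((int(i), int(j)) for i, j in pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def flat_indices(self, space: DesignSpace) -> np.ndarray:
        return np.array([space.flat_index(i, j) for i, j in self.pairs], dtype=int)

    def validate(self, space: DesignSpace) -> None:
        if len(self.pairs) > space.budget:
            raise ValueError(f"experiment has {len(self.pairs)} measurements, budget is {space.budget}")
        if not space.allow_repeats and len(set(self.pairs)) != len(self.pairs):
            raise ValueError("repeated measurements require allow_repeats")
        self.flat_indices(space)  # range check

    def extended(self, pair: tuple[int, int]) -> "Experiment":
        return Experiment(self.pairs + ((int(pair[0]), int(pair[1])),))


@dataclass(frozen=True)
class Dataset:
    """Realized measurement values aligned with an experiment's pairs."""

    experiment: Experiment
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != len(self.experiment):
            raise ValueError("dataset length must match the experiment")
        if not np.all(np.isfinite(v)):
            raise ValueError("dataset values must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BeliefState:
    """Probability vector over the candidate models, stored as natural logs."""

    log_probs: np.ndarray

    def __post_init__(self):
        lp = np.asarray(self.log_probs, dtype=float).ravel()
        total = logsumexp(lp)
        if not np.isfinite(total) or abs(total) > 1e-10:
            raise ValueError("belief state must normalize to 1 (within 1e-10)")
        object.__setattr__(self, "log_probs", lp - total)

    @classmethod
    def from_probs(cls, probs) -> "BeliefState":
        p = np.asarray(probs, dtype=float).ravel()
        with np.errstate(divide="ignore"):
            return cls(np.log(p))

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs)

    def entropy(self) -> float:
        """Shannon entropy in nats."""
        lp = self.log_probs
        finite = lp > -np.inf
        return float(-np.sum(np.exp(lp[finite]) * lp[finite]))

    def entropy_bits(self) -> float:
        return self.entropy() / LOG2

    def map_index(self) -> int:
        return int(np.argmax(self.log_probs))


def restricted_gaussian(
    pred: PredictiveDistribution, space: DesignSpace, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and *noisy* covariance restricted to channels ``idx``.

    Repeated indices (multiset experiments) share the predictive component
    perfectly but receive independent noise on each occurrence, which is
    exactly what duplicating rows/columns and adding a diagonal achieves.
    """
    sd = space.noise_sd(pred.mean)
    mu = pred.mean[idx]
    cov = pred.cov[np.ix_(idx, idx)] + np.diag(sd[idx] ** 2)
    return mu, cov


def log_likelihood(data: Dataset, pred: PredictiveDistribution, space: DesignSpace) -> float:
    """Log density of the data under one model's marginal predictive law.

    Gaussian representation: a dense multivariate normal over the measured
    coordinates with the per-channel noise variances added on the diagonal.
    Particle representation: an equally-weighted mixture over particles, each
    convolved with the independent noise kernel (parameter marginalization
    performed by the particles themselves).
    """
    idx = data.experiment.flat_indices(space)
    k = idx.size
    if k == 0:
        return 0.0
    y = data.values
    sd = space.noise_sd(pred.mean)[idx]
    if pred.kind == "particles" and pred.particles is not None:
        centered = (y - pred.particles[:, idx]) / sd
        comp = -0.5 * np.sum(centered**2, axis=1) - np.sum(np.log(sd)) - 0.5 * k * math.log(2 * math.pi)
        return float(logsumexp(comp) - math.log(pred.particles.shape[0]))
    mu = pred.mean[idx]
    cov = pred.cov[np.ix_(idx, idx)] + np.diag(sd**2)
    try:
        chol = cholesky(cov, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - sd > 0 prevents this
        raise InferenceError("singular total covariance") from exc
    z = solve_triangular(chol, y - mu, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return float(-0.5 * (k * math.log(2 * math.pi) + logdet + z @ z))


def posterior(
    prior: BeliefState,
    data: Dataset,
    preds: Sequence[PredictiveDistribution],
    space: DesignSpace,
) -> BeliefState:
    """Bayes update of the model probabilities, computed stably in log space."""
    if len(preds) != prior.log_probs.size:
        raise ValueError("one predictive distribution per model is required")
    ll = np.array([log_likelihood(data, p, space) for p in preds])
    log_un = prior.log_probs + ll
    norm = logsumexp(log_un)
    if not np.isfinite(norm):
        raise InferenceError("data impossible under every model")
    return BeliefState(log_un - norm)


def information_gain(prior: BeliefState, post: BeliefState) -> float:
    """Realized gain: relative entropy KL(posterior || prior), in nats.

    Zero posterior mass contributes nothing (0 log 0 = 0); posterior mass on
    a model the prior excludes makes the gain infinite, flagged explicitly.
    """
    q, lq = post.probs, post.log_probs
    lp = prior.log_probs
    support = q > 0
    if np.any(support & (lp == -np.inf)):
        return math.inf
    return float(np.sum(q[support] * (lq[support] - lp[support])))


def sequential_update(
    prior: BeliefState,
    datasets: Sequence[Dataset],
    preds: Sequence[PredictiveDistribution],
    space: DesignSpace,
) -> BeliefState:
    """Assimilate datasets one at a time; identical to one batch update.

    Yesterday's posterior is today's prior.  Because parameter
    marginalization correlates measurements across time, each new block is
    conditioned on everything assimilated before it: the update telescopes
    joint likelihoods of the growing concatenated dataset, which makes the
    sequential result equal the batch result to round-off, in any order.
    """
    belief = prior
    pairs: tuple = ()
    values: list[float] = []
    for data in datasets:
        pairs = pairs + data.experiment.pairs
        values.extend(data.values.tolist())
        concat = Dataset(Experiment(pairs), np.array(values))
        belief = posterior(prior, concat, preds, space)
    return belief
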
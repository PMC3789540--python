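"""Expected information gain (mutual information) of a candidate experiment.

The design objective is the mutual information between the model indicator
and the hypothetical measurement outcome, written in the discrete-model form

    I(F; Y_pi) = H(F) - E_Y[ H(F | Y_pi) ],

which equals the expected Kullback-Leibler gain of a Bayes update and keeps
all entropies discrete (no Gaussian-mixture differential entropies).  Two
estimators are provided: a nested Monte Carlo estimator (sample a model from
the prior, an outcome from its noisy predictive law, score the posterior
entropy) and a deterministic dense-grid quadrature usable for experiments of
one or two measurements, which serves as the oracle for the Monte Carlo
path.

Monte Carlo evaluations within one design sweep share a single common
random-number draw (model indices plus standard-normal innovations indexed
by selection position), so comparisons between candidate experiments are not
corrupted by independent sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .infer import Experiment
from .models import DesignSpace, HypothesisClass
from .propagate import PredictiveDistribution

__all__ = [
    "MIEstimate",
    "CommonRandomNumbers",
    "expected_information_gain",
    "mi_fixed_sample",
    "mi_quadrature",
    "per_timepoint_profile",
]

LOG2 = math.log(2.0)


@dataclass(frozen=True)
class MIEstimate:
    """A mutual-information estimate in nats with its Monte Carlo error.

    ``value`` is the raw estimate (sampling noise can push it slightly below
    zero); ``reported`` floors it at zero for presentation while the raw
    value stays available for diagnostics.
    """

    value: float
    std_error: float
    estimator: str
    n_samples: int
    seed: Optional[int] = None

    @property
    def reported(self) -> float:
        return max(self.value, 0.0)

    @property
    def value_bits(self) -> float:
        return self.reported / LOG2


@dataclass(frozen=True)
class CommonRandomNumbers:
    """Shared outer sample: model draws plus positional noise innovations.

    ``normals[n, :k]`` are the standard-normal innovations used for the
    ``k``-th measurement of any candidate experiment, so two experiments that
    share a prefix also share its simulated outcomes.
    """

    model_draws: np.ndarray  # (n_outer,) model indices sampled from the prior
    normals: np.ndarray      # (n_outer, k_max)
    uniforms: np.ndarray     # (n_outer,) for particle-index selection
    seed: int

    @classmethod
    def draw(cls, prior: np.ndarray, n_outer: int, k_max: int, seed: int) -> "CommonRandomNumbers":
        if n_outer < 1:
            raise ValueError("n_outer must be >= 1")
        rng = np.random.default_rng(seed)
        draws = rng.choice(prior.size, size=n_outer, p=prior)
        normals = rng.standard_normal((n_outer, max(k_max, 1)))
        uniforms = rng.random(n_outer)
        return cls(draws, normals, uniforms, int(seed))

    @property
    def n_outer(self) -> int:
        return self.model_draws.size


def _channel_laws(preds, space, idx):
    """Per-model (mean, cholesky, logdet) of the noisy law on channels ``idx``."""
    out = []
    for pred in preds:
        sd = space.noise_sd(pred.mean)[idx]
        mu = pred.mean[idx]
        cov = pred.cov[np.ix_(idx, idx)] + np.diag(sd**2)
        chol = cholesky(cov, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        out.append((mu, chol, logdet))
    return out


def mi_fixed_sample(
    hclass: HypothesisClass,
    preds: Sequence[PredictiveDistribution],
    experiment: Experiment,
    space: DesignSpace,
    crn: CommonRandomNumbers,
) -> MIEstimate:
    """Nested Monte Carlo MI on a fixed common-random-number sample.

    Deterministic given the CRN draw; the estimate is an average of
    per-outer-sample contributions, whose spread yields the standard error.
    """
    k = len(experiment)
    if k == 0:
        return MIEstimate(0.0, 0.0, "mc_nested", crn.n_outer, crn.seed)
    if k > crn.normals.shape[1]:
        raise ValueError(f"CRN draw supports at most {crn.normals.shape[1]} measurements")
    idx = experiment.flat_indices(space)
    n = crn.n_outer
    n_models = len(hclass)
    log_prior = np.log(hclass.prior)

    if any(p.kind == "particles" for p in preds):
        return _mi_fixed_sample_particles(hclass, preds, idx, space, crn)

    laws = _channel_laws(preds, space, idx)
    y = np.empty((n, k))
    for f in range(n_models):
        sel = crn.model_draws == f
        if not np.any(sel):
            continue
        mu, chol, _ = laws[f]
        y[sel] = mu + crn.normals[sel, :k] @ chol.T
    ll = np.empty((n, n_models))
    const = -0.5 * k * math.log(2 * math.pi)
    for g in range(n_models):
        mu, chol, logdet = laws[g]
        z = solve_triangular(chol, (y - mu).T, lower=True)
        ll[:, g] = const - 0.5 * logdet - 0.5 * np.sum(z**2, axis=0)
    log_post = log_prior + ll
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)
    h_post = -np.sum(np.where(post > 0, post * log_post, 0.0), axis=1)
    gains = hclass.prior_entropy() - h_post
    value = float(gains.mean())
    se = float(gains.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return MIEstimate(value, se, "mc_nested", n, crn.seed)


def _mi_fixed_sample_particles(hclass, preds, idx, space, crn):
    """Particle-mixture variant of the fixed-sample MI estimator."""
    n = crn.n_outer
    k = idx.size
    n_models = len(hclass)
    log_prior = np.log(hclass.prior)
    sds = [space.noise_sd(p.mean)[idx] for p in preds]
    y = np.empty((n, k))
    for f in range(n_models):
        sel = np.flatnonzero(crn.model_draws == f)
        if sel.size == 0:
            continue
        p = preds[f]
        if p.kind == "particles" and p.particles is not None:
            pick = (crn.uniforms[sel] * p.particles.shape[0]).astype(int)
            base = p.particles[np.ix_(pick, idx)]
        else:
            base = np.tile(p.mean[idx], (sel.size, 1))
        y[sel] = base + crn.normals[sel, :k] * sds[f]
    ll = np.empty((n, n_models))
    const = -0.5 * k * math.log(2 * math.pi)
    for g in range(n_models):
        p = preds[g]
        sd = sds[g]
        if p.kind == "particles" and p.particles is not None:
            part = p.particles[:, idx]
            # (n, n_particles) mixture components
            z2 = ((y[:, None, :] - part[None, :, :]) / sd) ** 2
            comp = const - np.sum(np.log(sd)) - 0.5 * z2.sum(axis=2)
            ll[:, g] = logsumexp(comp, axis=1) - math.log(part.shape[0])
        else:
            mu, chol, logdet = _channel_laws([p], space, idx)[0]
            z = solve_triangular(chol, (y - mu).T, lower=True)
            ll[:, g] = const - 0.5 * logdet - 0.5 * np.sum(z**2, axis=0)
    log_post = log_prior + ll
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    post = np.exp(log_post)
    h_post = -np.sum(np.where(post > 0, post * log_post, 0.0), axis=1)
    gains = hclass.prior_entropy() - h_post
    value = float(gains.mean())
    se = float(gains.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return MIEstimate(value, se, "mc_nested", n, crn.seed)


def expected_information_gain(
    hclass: HypothesisClass,
    preds: Sequence[PredictiveDistribution],
    experiment: Experiment,
    space: DesignSpace,
    n_outer: int = 2000,
    seed: int = 0,
    crn: Optional[CommonRandomNumbers] = None,
) -> MIEstimate:
    """Expected KL gain of the experiment, I(model; Y_pi), in nats.

    Samples a model from the prior and an outcome from its noisy predictive
    law, scores the posterior model entropy, and averages.  Deterministic
    given the seed (or an explicitly shared CRN draw); an empty experiment
    returns exactly zero.
    """
    if len(preds) != len(hclass):
        raise ValueError("one predictive distribution per model is required")
    if crn is None:
        crn = CommonRandomNumbers.draw(hclass.prior, n_outer, max(len(experiment), 1), seed)
    return mi_fixed_sample(hclass, preds, experiment, space, crn)


def _restricted_noisy(preds, space, idx):
    out = []
    for pred in preds:
        sd = space.noise_sd(pred.mean)[idx]
        mu = pred.mean[idx]
        cov = pred.cov[np.ix_(idx, idx)] + np.diag(sd**2)
        out.append((mu, cov))
    return out


def mi_quadrature(
    hclass: HypothesisClass,
    preds: Sequence[PredictiveDistribution],
    experiment: Experiment,
    space: DesignSpace,
    grid_size: int = 401,
) -> float:
    """Deterministic dense-grid MI for experiments of one or two measurements.

    Integrates  sum_f p(f) int p(y|f) log[ p(y|f) / sum_g p(g) p(y|g) ] dy
    on a trapezoid grid spanning every component mean +/- 8.5 sd.  Exact up
    to grid resolution; used as the oracle for the Monte Carlo estimator.
    """
    k = len(experiment)
    if k == 0:
        return 0.0
    if k > 2:
        raise ValueError("mi_quadrature supports at most 2 measurements")
    idx = experiment.flat_indices(space)
    laws = _restricted_noisy(preds, space, idx)
    prior = hclass.prior
    span = 8.5
    if k == 1:
        mus = np.array([mu[0] for mu, _ in laws])
        sds = np.array([math.sqrt(c[0, 0]) for _, c in laws])
        lo = float(np.min(mus - span * sds))
        hi = float(np.max(mus + span * sds))
        # resolve the narrowest mixture component even when means are far apart
        npts = int(np.clip((hi - lo) / (0.2 * float(sds.min())), max(grid_size, 801), 200_001))
        grid = np.linspace(lo, hi, npts)
        ll = np.stack(
            [
                -0.5 * ((grid - m) / s) ** 2 - math.log(s) - 0.5 * math.log(2 * math.pi)
                for m, s in zip(mus, sds)
            ],
            axis=1,
        )
        log_mix = logsumexp(np.log(prior) + ll, axis=1)
        integrand = np.sum(prior * np.exp(ll) * (ll - log_mix[:, None]), axis=1)
        return float(np.trapezoid(integrand, grid))
    # k == 2: correlated 2-D Gaussians on a product grid
    grids = []
    for dim in range(2):
        mus = np.array([mu[dim] for mu, _ in laws])
        sds = np.array([math.sqrt(c[dim, dim]) for _, c in laws])
        lo = float(np.min(mus - span * sds))
        hi = float(np.max(mus + span * sds))
        npts = int(np.clip((hi - lo) / (0.5 * float(sds.min())), max(grid_size, 221), 1501))
        grids.append(np.linspace(lo, hi, npts))
    g0, g1 = grids
    yy0, yy1 = np.meshgrid(g0, g1, indexing="ij")
    pts = np.stack([yy0.ravel(), yy1.ravel()], axis=1)
    ll = np.stack(
        [multivariate_normal(mean=mu, cov=c, allow_singular=True).logpdf(pts) for mu, c in laws],
        axis=1,
    )
    log_mix = logsumexp(np.log(prior) + ll, axis=1)
    integrand = np.sum(prior * np.exp(ll) * (ll - log_mix[:, None]), axis=1).reshape(g0.size, g1.size)
    inner = np.trapezoid(integrand, g1, axis=1)
    return float(np.trapezoid(inner, g0))


def per_timepoint_profile(
    hclass: HypothesisClass,
    preds: Sequence[PredictiveDistribution],
    space: DesignSpace,
    readout: Optional[str] = None,
    n_outer: int = 2000,
    seed: int = 0,
    normalize: bool = False,
) -> pd.DataFrame:
    """MI of every singleton experiment at one readout, along the time grid.

    Returns a frame with columns ``time``, ``mi_nats``, ``mi_bits``,
    ``std_error`` and, when ``normalize`` is set, ``normalized`` (MI divided
    by the prior entropy, hence in [0, 1] up to sampling error).  All
    singletons share one common-random-number draw.
    """
    j = 0 if readout is None else space.readouts.index(readout)
    crn = CommonRandomNumbers.draw(hclass.prior, n_outer, 1, seed)
    rows = []
    h_prior = hclass.prior_entropy()
    for i in range(space.n_times):
        est = mi_fixed_sample(hclass, preds, Experiment([(i, j)]), space, crn)
        row = {
            "time": space.times[i],
            "mi_nats": est.reported,
            "mi_bits": est.value_bits,
            "std_error": est.std_error,
        }
        if normalize:
            row["normalized"] = est.reported / h_prior if h_prior > 0 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
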
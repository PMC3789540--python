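"""IVP solving and uncertainty propagation to predictive measurement laws.

For each candidate model, parameter and initial-condition uncertainty is
pushed through the initial value problem to a joint distribution over every
candidate measurement of a design space (all time points x readouts), before
measurement noise is added.  Two propagation schemes are provided:

* the unscented transform (deterministic sigma points; exact for linear
  dynamics with Gaussian inputs and cheap for the unimodal cases that
  dominate here), and
* plain Monte Carlo sampling, which also serves as the independent reference
  for validating the sigma-point approximation.

The drift of the state distribution is never solved as a PDE; these two
schemes are its operational surrogates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import block_diag

from .models import CandidateModel, DesignSpace

__all__ = [
    "PropagationError",
    "Trajectory",
    "SigmaPointSet",
    "PredictiveDistribution",
    "solve_model",
    "predict_measurements",
    "unscented_propagate",
    "monte_carlo_propagate",
    "repair_psd",
]

logger = logging.getLogger(__name__)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class PropagationError(RuntimeError):
    """IVP integration or uncertainty-propagation failure."""


@dataclass
class Trajectory:
    """IVP solution sampled on a time grid (rows align with the grid)."""

    model_id: str
    times: np.ndarray
    states: np.ndarray  # (n_times, dim_state)


@dataclass
class SigmaPointSet:
    """Deterministic sample of the joint (theta, x0) uncertainty.

    ``points`` has ``2 d + 1`` rows where ``d`` is the number of uncertain
    coordinates; mean weights sum to one.
    """

    points: np.ndarray
    weights_mean: np.ndarray
    weights_cov: np.ndarray


@dataclass
class PredictiveDistribution:
    """Joint law of all candidate measurements for one model (noise-free).

    ``mean`` and ``cov`` are indexed by the design space's flat channel index
    (time-major).  ``kind`` is ``"gaussian"`` (moments only, from the
    unscented transform) or ``"particles"`` (Monte Carlo sample retained in
    ``particles`` alongside its sample moments).
    """

    model_id: str
    mean: np.ndarray
    cov: np.ndarray
    kind: str = "gaussian"
    particles: Optional[np.ndarray] = None

    @property
    def n_channels(self) -> int:
        return self.mean.size


def repair_psd(cov: np.ndarray, rel_floor: float = 1e-12) -> np.ndarray:
    """Symmetrize and clip eigenvalues at ``rel_floor`` of the trace.

    Sigma-point round-off can leave tiny negative eigenvalues; they are
    clipped and the repair is logged when it exceeds numerical dust.
    """
    sym = 0.5 * (cov + cov.T)
    if sym.size == 0:
        return sym
    w, v = np.linalg.eigh(sym)
    floor = rel_floor * max(float(np.trace(sym)), 0.0)
    if w.min() < -1e-6 * max(floor, 1e-30):
        logger.debug("clipping negative covariance eigenvalue %.3e", w.min())
    w = np.clip(w, floor, None) if floor > 0 else np.clip(w, 0.0, None)
    return (v * w) @ v.T


def solve_model(
    model: CandidateModel,
    times: np.ndarray,
    theta: Optional[np.ndarray] = None,
    x0: Optional[np.ndarray] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Solve the IVP from the model's initial time and sample it on ``times``.

    ``LSODA`` switches automatically between stiff and non-stiff modes.
    Deterministic for fixed tolerances.
    """
    times = np.asarray(times, dtype=float).ravel()
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    if times.size and times[0] < model.t0:
        raise PropagationError(f"{model.id}: grid starts before the initial time {model.t0}")
    x_init = model.x0_mean if x0 is None else np.asarray(x0, dtype=float).ravel()
    f = model.rhs_function(theta)
    t_end = float(times[-1]) if times.size else model.t0
    if t_end == model.t0:
        states = np.tile(x_init, (times.size, 1))
        return Trajectory(model.id, times, states)
    def _blowup(t, x):  # terminal guard: stops cleanly instead of stalling near a singularity
        return 1e12 - float(np.max(np.abs(x)))

    _blowup.terminal = True
    sol = solve_ivp(
        f,
        (model.t0, t_end),
        x_init,
        method=method,
        t_eval=times,
        rtol=rtol,
        atol=atol,
        events=[_blowup],
    )
    if sol.status == 1:
        raise PropagationError(f"{model.id}: trajectory blow-up before t={t_end}")
    if not sol.success:
        raise PropagationError(f"{model.id}: IVP integration failed ({sol.message})")
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        raise PropagationError(f"{model.id}: non-finite trajectory values")
    return Trajectory(model.id, times, states)


def predict_measurements(
    model: CandidateModel,
    space: DesignSpace,
    theta: Optional[np.ndarray] = None,
    x0: Optional[np.ndarray] = None,
    **solver_kw,
) -> np.ndarray:
    """Deterministic readout predictions as a flat channel vector."""
    traj = solve_model(model, space.times, theta=theta, x0=x0, **solver_kw)
    h = model.observation_matrix(space.readouts)
    return (traj.states @ h.T).ravel()


def _augmented_moments(model: CandidateModel) -> tuple[np.ndarray, np.ndarray]:
    mean = np.concatenate([model.theta_mean, model.x0_mean])
    cov = block_diag(model.theta_cov, model.x0_cov)
    return mean, cov


def sigma_points(
    mean: np.ndarray,
    cov: np.ndarray,
    alpha: float = 1.0,
    beta: float = 2.0,
    kappa: float = 0.0,
) -> SigmaPointSet:
    """Scaled-unscented sigma points over the uncertain coordinates only.

    Coordinates with zero variance are held at their mean, so ``d`` counts
    only genuinely uncertain coordinates and the set has ``2 d + 1`` points.
    """
    mean = np.asarray(mean, dtype=float).ravel()
    cov = 0.5 * (np.asarray(cov, dtype=float) + np.asarray(cov, dtype=float).T)
    active = np.flatnonzero(np.diag(cov) > 0)
    d = active.size
    if d == 0:
        return SigmaPointSet(mean[None, :], np.array([1.0]), np.array([1.0]))
    sub = cov[np.ix_(active, active)]
    w, v = np.linalg.eigh(sub)
    if w.min() < -1e-9 * max(w.max(), 1.0):
        raise PropagationError("joint (theta, x0) covariance is not PSD")
    sqrt_sub = v * np.sqrt(np.clip(w, 0.0, None))
    lam = alpha**2 * (d + kappa) - d
    scale = np.sqrt(d + lam)
    pts = np.tile(mean, (2 * d + 1, 1))
    for k in range(d):
        delta = np.zeros_like(mean)
        delta[active] = scale * sqrt_sub[:, k]
        pts[1 + k] += delta
        pts[1 + d + k] -= delta
    wm = np.full(2 * d + 1, 1.0 / (2.0 * (d + lam)))
    wc = wm.copy()
    wm[0] = lam / (d + lam)
    wc[0] = lam / (d + lam) + (1.0 - alpha**2 + beta)
    return SigmaPointSet(pts, wm, wc)


def unscented_propagate(
    model: CandidateModel,
    space: DesignSpace,
    alpha: float = 1.0,
    beta: float = 2.0,
    kappa: float = 0.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> PredictiveDistribution:
    """Sigma-point push-forward of joint (theta, x0) uncertainty.

    Each sigma point is solved through the IVP and mapped through the
    observation functionals at every grid time; the returned Gaussian
    surrogate carries the weighted mean and full covariance across all
    candidate measurements.  Measurement noise is *not* included.
    """
    mean, cov = _augmented_moments(model)
    sps = sigma_points(mean, cov, alpha=alpha, beta=beta, kappa=kappa)
    nth = model.dim_theta
    preds = np.empty((sps.points.shape[0], space.n_channels))
    for p, point in enumerate(sps.points):
        try:
            preds[p] = predict_measurements(
                model, space, theta=point[:nth], x0=point[nth:], rtol=rtol, atol=atol
            )
        except PropagationError as exc:
            raise PropagationError(f"{model.id}: sigma point {p} failed: {exc}") from exc
    mu = sps.weights_mean @ preds
    centered = preds - mu
    c = (sps.weights_cov[:, None] * centered).T @ centered
    return PredictiveDistribution(model.id, mu, repair_psd(c), kind="gaussian")


def monte_carlo_propagate(
    model: CandidateModel,
    space: DesignSpace,
    n: int,
    seed: int,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> PredictiveDistribution:
    """Monte Carlo push-forward: ``n`` joint (theta, x0) draws through the IVP.

    Returns the particle representation together with its sample moments;
    deterministic for a fixed seed.
    """
    if n < 2:
        raise ValueError("need n >= 2 Monte Carlo draws")
    rng = np.random.default_rng(seed)
    mean, cov = _augmented_moments(model)
    # factor the input covariance with negatives clipped only at zero: a
    # trace-relative floor would inflate legitimately tiny variances when
    # parameter scales are heterogeneous
    w, v = np.linalg.eigh(0.5 * (cov + cov.T))
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    draws = mean + rng.standard_normal((n, mean.size)) @ factor.T
    nth = model.dim_theta
    particles = np.empty((n, space.n_channels))
    for r in range(n):
        try:
            particles[r] = predict_measurements(
                model, space, theta=draws[r, :nth], x0=draws[r, nth:], rtol=rtol, atol=atol
            )
        except PropagationError as exc:
            raise PropagationError(f"{model.id}: Monte Carlo draw {r} failed: {exc}") from exc
    mu = particles.mean(axis=0)
    centered = particles - mu
    c = centered.T @ centered / (n - 1)
    return PredictiveDistribution(model.id, mu, repair_psd(c), kind="particles", particles=particles)


def propagate_class(
    hclass,
    space: DesignSpace,
    method: str = "unscented",
    n: int = 1000,
    seed: int = 0,
    **kw,
) -> list[PredictiveDistribution]:
    """Propagate every model of a hypothesis class (one predictive per model)."""
    preds = []
    for k, model in enumerate(hclass.models):
        if method == "unscented":
            preds.append(unscented_propagate(model, space, **kw))
        elif method == "monte_carlo":
            preds.append(monte_carlo_propagate(model, space, n=n, seed=seed + k, **kw))
        else:
            raise ValueError(f"unknown propagation method {method!r}")
    return preds
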
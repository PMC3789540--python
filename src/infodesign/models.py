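"""Hypothesis classes of candidate ODE models and the measurement design space.

A *hypothesis class* is a finite, prior-weighted set of candidate dynamical
models (ODE right-hand sides with parameter and initial-condition
uncertainty) that share at least one observable readout.  The *design space*
enumerates every candidate measurement as a (time point, readout) pair with a
per-measurement Gaussian noise model and a budget on how many measurements an
experiment may contain.

Three fixture constructors are bundled:

``make_bergman_class``
    The insulin-dependent glucose minimal-model family (four structurally
    distinct phenomenological models of intravenous glucose tolerance) with a
    documented literature-scale parameterization and a piecewise-linear
    plasma-insulin forcing time course.

``make_linear_gaussian_pair``
    Two one-state linear ODEs ``dx/dt = a_k x`` with Gaussian initial
    condition; every predictive law is exactly Gaussian and available in
    closed form, which makes the pair the analytic test fixture.

``make_synthetic_class``
    A randomized mass-action hypothesis-class generator: a shared core
    reaction network plus per-model elementary extensions (extra reactions
    with log-uniform rate constants), emulating a large benchmark class of
    heterogeneous biochemical hypotheses sharing observable species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "Forcing",
    "CandidateModel",
    "HypothesisClass",
    "FixedNoise",
    "ProportionalNoise",
    "DesignSpace",
    "make_bergman_class",
    "bergman_design_space",
    "make_linear_gaussian_pair",
    "make_synthetic_class",
    "BUILTIN_RHS",
]


class ConfigurationError(ValueError):
    """Invalid model, hypothesis-class or design-space specification."""


_PSD_TOL = 1e-9


def _symmetrize_check_psd(mat: np.ndarray, name: str) -> np.ndarray:
    a = np.atleast_2d(np.asarray(mat, dtype=float))
    if a.shape[0] != a.shape[1]:
        raise ConfigurationError(f"{name} must be square, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-8, rtol=1e-8):
        raise ConfigurationError(f"{name} must be symmetric")
    a = 0.5 * (a + a.T)
    if a.size:
        w = np.linalg.eigvalsh(a)
        scale = max(1.0, float(np.max(np.abs(w), initial=0.0)))
        if float(np.min(w, initial=0.0)) < -_PSD_TOL * scale:
            raise ConfigurationError(f"{name} is not positive semidefinite")
    return a


@dataclass(frozen=True)
class Forcing:
    """Piecewise-linear interpolated input time course, e.g. plasma insulin.

    The forcing is supplied to the models rather than determined by them;
    outside the tabulated range it is held at the boundary values.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ConfigurationError("forcing needs matching 1-d times/values, >= 2 knots")
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("forcing times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t):
        return np.interp(t, self.times, self.values)


# ---------------------------------------------------------------------------
# Built-in right-hand sides (glucose minimal-model family)
# ---------------------------------------------------------------------------
#
# States and units: G [mg/dl] plasma glucose; X [1/min] insulin action in a
# compartment remote from plasma.  Forcing: insulin(t) [uU/ml] plasma insulin.
# Constants: Gb basal glucose [mg/dl], Ib basal insulin [uU/ml].


def _rhs_bergman_i(t, x, theta, const, forcing):
    # insulin-independent glucose turnover toward basal
    (sg,) = theta
    g = x[0]
    return np.array([sg * (const["Gb"] - g)])


def _rhs_bergman_iv(t, x, theta, const, forcing):
    # constant hepatic production; disposal enhanced directly by plasma insulin
    sg, si = theta
    g = x[0]
    ins = forcing["insulin"](t)
    return np.array([sg * (const["Gb"] - g) - si * (ins - const["Ib"]) * g])


def _rhs_bergman_v(t, x, theta, const, forcing):
    # constant production; disposal through a remote insulin-action compartment
    sg, p2, p3 = theta
    g, xr = x
    ins = forcing["insulin"](t)
    return np.array([
        sg * (const["Gb"] - g) - xr * g,
        -p2 * xr + p3 * (ins - const["Ib"]),
    ])


def _rhs_bergman_vi(t, x, theta, const, forcing):
    # insulin-dependent production (suppressed by remote insulin action) plus
    # peripheral, insulin-driven glucose disappearance
    sg, p2, p3, h = theta
    g, xr = x
    ins = forcing["insulin"](t)
    return np.array([
        sg * (const["Gb"] - g) - xr * g - h * xr,
        -p2 * xr + p3 * (ins - const["Ib"]),
    ])


#: name -> (rhs function, total additive term count across equations)
BUILTIN_RHS: dict[str, tuple[Callable, int]] = {
    "bergman_i": (_rhs_bergman_i, 1),
    "bergman_iv": (_rhs_bergman_iv, 2),
    "bergman_v": (_rhs_bergman_v, 4),
    "bergman_vi": (_rhs_bergman_vi, 5),
}


def _compile_mass_action(reactions: Sequence[dict], state_names: Sequence[str]):
    """Compile a mass-action reaction table into per-reaction index arrays."""
    index = {name: i for i, name in enumerate(state_names)}
    nx = len(state_names)
    compiled = []
    for r_i, reac in enumerate(reactions):
        try:
            reactants = dict(reac.get("reactants", {}))
            products = dict(reac.get("products", {}))
        except AttributeError as exc:  # pragma: no cover - config error path
            raise ConfigurationError(f"reaction {r_i} is not a mapping") from exc
        net = np.zeros(nx)
        sp_idx, sp_st = [], []
        for name, st in reactants.items():
            if name not in index:
                raise ConfigurationError(f"reaction {r_i}: unknown species {name!r}")
            sp_idx.append(index[name])
            sp_st.append(int(st))
            net[index[name]] -= st
        for name, st in products.items():
            if name not in index:
                raise ConfigurationError(f"reaction {r_i}: unknown species {name!r}")
            net[index[name]] += st
        compiled.append((np.array(sp_idx, dtype=int), np.array(sp_st, dtype=int), net))
    return compiled


@dataclass
class CandidateModel:
    """One ODE hypothesis: dynamics, uncertainty, observation map, forcing.

    The right-hand side is specified either by a registered built-in name
    (``rhs_builtin``), a mass-action reaction table (``reactions``; the
    parameter vector then holds the rate constants, one per reaction), or a
    raw callable ``rhs_callable(t, x, theta)`` (not serializable).

    Parameter and initial-condition uncertainty are Gaussian with the given
    means and (possibly all-zero) covariances; an all-zero covariance means
    the corresponding quantities are known exactly.
    """

    id: str
    state_names: list[str]
    x0_mean: np.ndarray
    x0_cov: np.ndarray
    theta_mean: np.ndarray
    theta_cov: np.ndarray
    observation_map: dict[str, np.ndarray]
    rhs_builtin: Optional[str] = None
    reactions: Optional[list[dict]] = None
    rhs_callable: Optional[Callable] = None
    constants: dict = field(default_factory=dict)
    forcing: dict[str, Forcing] = field(default_factory=dict)
    t0: float = 0.0

    def __post_init__(self):
        self.x0_mean = np.asarray(self.x0_mean, dtype=float).ravel()
        self.theta_mean = np.asarray(self.theta_mean, dtype=float).ravel()
        self.x0_cov = _symmetrize_check_psd(self.x0_cov, f"{self.id}: x0_cov")
        self.theta_cov = _symmetrize_check_psd(self.theta_cov, f"{self.id}: theta_cov")
        nx, nth = self.x0_mean.size, self.theta_mean.size
        if len(self.state_names) != nx:
            raise ConfigurationError(f"{self.id}: {len(self.state_names)} state names for {nx} states")
        if self.x0_cov.shape != (nx, nx):
            raise ConfigurationError(f"{self.id}: x0_cov shape {self.x0_cov.shape} != ({nx},{nx})")
        if self.theta_cov.shape != (nth, nth):
            raise ConfigurationError(f"{self.id}: theta_cov shape mismatch")
        specs = sum(x is not None for x in (self.rhs_builtin, self.reactions, self.rhs_callable))
        if specs != 1:
            raise ConfigurationError(f"{self.id}: exactly one of rhs_builtin/reactions/rhs_callable required")
        if self.rhs_builtin is not None and self.rhs_builtin not in BUILTIN_RHS:
            raise ConfigurationError(f"{self.id}: unknown built-in rhs {self.rhs_builtin!r}")
        if self.reactions is not None:
            if nth != len(self.reactions):
                raise ConfigurationError(
                    f"{self.id}: mass-action models need one rate parameter per reaction"
                )
            self._compiled = _compile_mass_action(self.reactions, self.state_names)
        obs = {}
        for name, coeffs in self.observation_map.items():
            c = np.asarray(coeffs, dtype=float).ravel()
            if c.size != nx:
                raise ConfigurationError(f"{self.id}: readout {name!r} references {c.size} states, model has {nx}")
            obs[str(name)] = c
        if not obs:
            raise ConfigurationError(f"{self.id}: observation map is empty")
        self.observation_map = obs

    # -- basic geometry -----------------------------------------------------
    @property
    def dim_state(self) -> int:
        return self.x0_mean.size

    @property
    def dim_theta(self) -> int:
        return self.theta_mean.size

    @property
    def n_rhs_terms(self) -> int:
        """Structural size of the dynamics (additive rhs terms / reactions)."""
        if self.rhs_builtin is not None:
            return BUILTIN_RHS[self.rhs_builtin][1]
        if self.reactions is not None:
            return len(self.reactions)
        return -1  # unknown for raw callables

    @property
    def readout_names(self) -> list[str]:
        return list(self.observation_map)

    # -- evaluation ---------------------------------------------------------
    def rhs_function(self, theta: Optional[np.ndarray] = None) -> Callable:
        """Return ``f(t, x) -> dx/dt`` with the parameter vector bound."""
        th = self.theta_mean if theta is None else np.asarray(theta, dtype=float).ravel()
        if th.size != self.dim_theta:
            raise ConfigurationError(f"{self.id}: theta has size {th.size}, expected {self.dim_theta}")
        if self.rhs_builtin is not None:
            fn = BUILTIN_RHS[self.rhs_builtin][0]
            const, forcing = self.constants, self.forcing
            return lambda t, x: fn(t, x, th, const, forcing)
        if self.rhs_callable is not None:
            fn = self.rhs_callable
            return lambda t, x: np.asarray(fn(t, x, th), dtype=float)
        compiled = self._compiled
        nx = self.dim_state

        def f(t, x):
            xp = np.maximum(x, 0.0)  # guards mass-action fluxes against solver round-off
            dx = np.zeros(nx)
            for k, (sp, st, net) in enumerate(compiled):
                flux = th[k]
                for i, s in zip(sp, st):
                    flux *= xp[i] ** s
                dx += flux * net
            return dx

        return f

    def observation_matrix(self, readouts: Sequence[str]) -> np.ndarray:
        """Stack readout functionals into an (n_readouts, dim_state) matrix."""
        rows = []
        for name in readouts:
            if name not in self.observation_map:
                raise ConfigurationError(f"{self.id}: no readout named {name!r}")
            rows.append(self.observation_map[name])
        return np.array(rows)


@dataclass
class HypothesisClass:
    """Prior-weighted finite set of candidate models sharing readouts."""

    models: list[CandidateModel]
    prior: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.prior = np.asarray(self.prior, dtype=float).ravel()
        if len(self.models) < 2:
            raise ConfigurationError("a hypothesis class needs at least 2 models")
        if self.prior.size != len(self.models):
            raise ConfigurationError("prior length must match number of models")
        if np.any(self.prior < 0):
            raise ConfigurationError("prior entries must be nonnegative")
        if abs(self.prior.sum() - 1.0) > 1e-12:
            raise ConfigurationError("prior must sum to 1 (within 1e-12)")
        ids = [m.id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("model ids must be unique")
        if not self.common_readouts:
            raise ConfigurationError("models share no common readout")

    @property
    def common_readouts(self) -> list[str]:
        """Readout names available in every model, in first-model order."""
        common = set(self.models[0].observation_map)
        for m in self.models[1:]:
            common &= set(m.observation_map)
        return [r for r in self.models[0].observation_map if r in common]

    @property
    def model_ids(self) -> list[str]:
        return [m.id for m in self.models]

    def __len__(self) -> int:
        return len(self.models)

    def index_of(self, model_id: str) -> int:
        try:
            return self.model_ids.index(model_id)
        except ValueError as exc:
            raise KeyError(f"no model with id {model_id!r}") from exc

    def prior_entropy(self) -> float:
        """Shannon entropy of the prior over models, in nats."""
        p = self.prior[self.prior > 0]
        return float(-np.sum(p * np.log(p)))

    def prior_entropy_bits(self) -> float:
        return self.prior_entropy() / math.log(2.0)


# ---------------------------------------------------------------------------
# Noise models and design space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedNoise:
    """Known per-measurement noise sd: a scalar or an (n_times, n_readouts) matrix."""

    sd: float | np.ndarray

    def sd_vector(self, n_times: int, n_readouts: int, pred_mean=None) -> np.ndarray:
        sd = np.asarray(self.sd, dtype=float)
        if sd.ndim == 0:
            out = np.full(n_times * n_readouts, float(sd))
        else:
            if sd.shape != (n_times, n_readouts):
                raise ConfigurationError(f"noise sd matrix shape {sd.shape} != ({n_times},{n_readouts})")
            out = sd.ravel()
        if np.any(out <= 0):
            raise ConfigurationError("noise sd must be positive everywhere")
        return out


@dataclass(frozen=True)
class ProportionalNoise:
    """Noise sd proportional to the predicted concentration, with a floor.

    ``factor=0.5`` reproduces the half-of-the-concentration rule; the floor
    keeps the sd positive when a predicted concentration approaches zero.
    """

    factor: float = 0.5
    floor: float = 1e-3

    def sd_vector(self, n_times: int, n_readouts: int, pred_mean=None) -> np.ndarray:
        if self.factor <= 0 or self.floor <= 0:
            raise ConfigurationError("proportional noise needs positive factor and floor")
        if pred_mean is None:
            raise ConfigurationError("proportional noise requires a predicted mean")
        mu = np.asarray(pred_mean, dtype=float).ravel()
        if mu.size != n_times * n_readouts:
            raise ConfigurationError("predicted mean has wrong length for this design space")
        return np.maximum(self.factor * np.abs(mu), self.floor)


@dataclass
class DesignSpace:
    """Candidate measurements: a time grid crossed with a readout list.

    The flat channel index runs time-major: channel ``i * n_readouts + j``
    is time point ``i`` of readout ``j``.
    """

    times: np.ndarray
    readouts: list[str]
    noise: FixedNoise | ProportionalNoise
    budget: int
    allow_repeats: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size < 1:
            raise ConfigurationError("design space needs at least one time point")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("time grid must be strictly increasing")
        self.readouts = list(self.readouts)
        if not self.readouts:
            raise ConfigurationError("design space needs at least one readout")
        self.budget = int(self.budget)
        if self.budget < 1:
            raise ConfigurationError("budget must be a positive integer")
        if not self.allow_repeats and self.budget > self.n_channels:
            raise ConfigurationError(
                f"budget {self.budget} exceeds the {self.n_channels} distinct candidate measurements"
            )

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_readouts(self) -> int:
        return len(self.readouts)

    @property
    def n_channels(self) -> int:
        return self.n_times * self.n_readouts

    def flat_index(self, i: int, j: int) -> int:
        if not (0 <= i < self.n_times and 0 <= j < self.n_readouts):
            raise IndexError(f"(time={i}, readout={j}) outside the design space")
        return i * self.n_readouts + j

    def pair(self, flat: int) -> tuple[int, int]:
        return divmod(int(flat), self.n_readouts)

    def all_pairs(self) -> list[tuple[int, int]]:
        """All candidate (time index, readout index) pairs in lexicographic order."""
        return [(i, j) for i in range(self.n_times) for j in range(self.n_readouts)]

    def noise_sd(self, pred_mean=None) -> np.ndarray:
        """Per-channel noise sd as a flat vector aligned with the channel index."""
        return self.noise.sd_vector(self.n_times, self.n_readouts, pred_mean)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

#: Documented default parameterization of the glucose minimal-model family.
#: Kinetic constants are literature-scale values for a normal-tolerance
#: subject (glucose effectiveness SG ~ 0.028/min; remote-compartment kinetics
#: p2 = 0.025/min, p3 = 1.3e-5 /min^2 per uU/ml); the insulin time course is a
#: synthetic IVGTT-style first-phase peak decaying back to basal.
_BERGMAN_PARAMS: dict[str, dict] = {
    "default": {
        "Gb": 92.0,       # basal glucose [mg/dl]
        "Ib": 11.0,       # basal insulin [uU/ml]
        "G0": 279.0,      # glucose immediately after the injection [mg/dl]
        "sg": 0.028,      # glucose effectiveness [1/min]
        "si": 5.0e-4,     # direct plasma-insulin disposal gain [ml/uU/min]
        "p2": 0.025,      # remote-compartment decay [1/min]
        "p3": 1.3e-5,     # remote-compartment gain [1/min^2 per uU/ml]
        "h": 40.0,        # production suppression / peripheral gain [mg/dl]
        "rel_theta_sd": 0.10,  # 10% sd on every kinetic constant
        "insulin_times": [0.0, 2.0, 5.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0, 180.0],
        "insulin_values": [11.0, 110.0, 75.0, 50.0, 30.0, 22.0, 15.0, 12.0, 11.0, 11.0],
    }
}


def make_bergman_class(parameterization: str = "default") -> HypothesisClass:
    """Four-model glucose-tolerance hypothesis class with uniform prior.

    Models I, IV, V and VI of the minimal-model family: I is
    insulin-independent; IV and V assume a constant hepatic glucose
    production rate (IV with direct plasma-insulin action, V through a remote
    insulin-action compartment); VI adds insulin-dependent production and
    peripheral glucose disappearance.  All four share the ``glucose`` readout.
    """
    if parameterization not in _BERGMAN_PARAMS:
        raise ConfigurationError(
            f"unknown Bergman parameterization {parameterization!r}; "
            f"available: {sorted(_BERGMAN_PARAMS)}"
        )
    p = _BERGMAN_PARAMS[parameterization]
    forcing = {"insulin": Forcing(np.array(p["insulin_times"]), np.array(p["insulin_values"]))}
    const = {"Gb": p["Gb"], "Ib": p["Ib"]}
    rel = p["rel_theta_sd"]

    def cov(theta):
        return np.diag((rel * np.asarray(theta)) ** 2)

    specs = [
        ("I", "bergman_i", ["G"], [p["G0"]], [p["sg"]]),
        ("IV", "bergman_iv", ["G"], [p["G0"]], [p["sg"], p["si"]]),
        ("V", "bergman_v", ["G", "X"], [p["G0"], 0.0], [p["sg"], p["p2"], p["p3"]]),
        ("VI", "bergman_vi", ["G", "X"], [p["G0"], 0.0], [p["sg"], p["p2"], p["p3"], p["h"]]),
    ]
    models = []
    for mid, rhs, states, x0, theta in specs:
        nx = len(states)
        obs = {"glucose": [1.0] + [0.0] * (nx - 1)}
        models.append(
            CandidateModel(
                id=mid,
                state_names=states,
                x0_mean=np.array(x0),
                x0_cov=np.zeros((nx, nx)),
                theta_mean=np.array(theta),
                theta_cov=cov(theta),
                observation_map=obs,
                rhs_builtin=rhs,
                constants=dict(const),
                forcing=dict(forcing),
            )
        )
    prior = np.full(4, 0.25)
    return HypothesisClass(models, prior, metadata={"parameterization": parameterization})


def bergman_design_space(
    n_times: int = 20,
    t_start: float = 9.0,
    t_end: float = 180.0,
    noise_sd: float = 15.0,
    budget: int = 5,
) -> DesignSpace:
    """Default glucose sampling pool: uniform post-injection time grid.

    ``noise_sd`` is the fixed glucose measurement sd in mg/dl (assay plus
    short-term biological variability scale).
    """
    times = np.linspace(t_start, t_end, n_times)
    return DesignSpace(times=times, readouts=["glucose"], noise=FixedNoise(noise_sd), budget=budget)


def make_linear_gaussian_pair(
    separation: float,
    noise_sd: float = 0.1,
    rate: float = -1.0,
    x0_mean: float = 1.0,
    x0_sd: float = 0.1,
) -> HypothesisClass:
    """Two one-state linear ODEs ``dx/dt = a_k x`` with Gaussian x0.

    ``a_1 = rate`` and ``a_2 = rate + separation``; the exact trajectory is
    ``x0 * exp(a_k t)``, so every predictive law is exactly Gaussian with
    mean ``x0_mean * exp(a t)`` and sd ``x0_sd * exp(a t)``.  ``noise_sd`` is
    recorded in the metadata as the suggested measurement noise.
    """
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be positive")
    rates = [rate, rate + separation]
    models = []
    for k, a in enumerate(rates):
        models.append(
            CandidateModel(
                id=f"lin{k + 1}",
                state_names=["x"],
                x0_mean=np.array([x0_mean]),
                x0_cov=np.array([[x0_sd**2]]),
                theta_mean=np.array([a]),
                theta_cov=np.zeros((1, 1)),
                observation_map={"x": [1.0]},
                rhs_callable=lambda t, x, th: th[0] * x,
            )
        )
    return HypothesisClass(
        models,
        np.array([0.5, 0.5]),
        metadata={"noise_sd": float(noise_sd), "rates": [float(a) for a in rates]},
    )


def linear_gaussian_space(times, noise_sd: float = 0.1, budget: int = 1, allow_repeats=False) -> DesignSpace:
    """Companion design space for :func:`make_linear_gaussian_pair`."""
    return DesignSpace(
        times=np.asarray(times, dtype=float),
        readouts=["x"],
        noise=FixedNoise(noise_sd),
        budget=budget,
        allow_repeats=allow_repeats,
    )


def make_synthetic_class(
    n_models: int,
    n_species: int,
    seed: int,
    n_extensions: tuple[int, int] = (1, 3),
    rel_theta_sd: float = 0.10,
) -> HypothesisClass:
    """Randomized mass-action hypothesis class with a shared observable core.

    All models share the same ``n_species`` chemical species (every species
    is a readout) and a common core network — constant inflow into the first
    species, a linear conversion chain, and first-order degradation of every
    species — which keeps total mass bounded on any finite window.  Each
    model appends 1–3 randomized elementary extension reactions (conversion,
    degradation, binding or catalytic conversion) with log-uniform rate
    constants, giving heterogeneous structure across the class.  Output is a
    deterministic function of the seed.
    """
    if n_models < 2 or n_species < 2:
        raise ConfigurationError("need n_models >= 2 and n_species >= 2")
    rng = np.random.default_rng(seed)
    species = [f"s{i}" for i in range(n_species)]

    core: list[dict] = [{"reactants": {}, "products": {species[0]: 1}}]
    core_rates = [float(rng.uniform(0.3, 0.8))]
    for i in range(n_species - 1):
        core.append({"reactants": {species[i]: 1}, "products": {species[i + 1]: 1}})
        core_rates.append(float(10 ** rng.uniform(-0.3, 0.5)))
    for i in range(n_species):
        core.append({"reactants": {species[i]: 1}, "products": {}})
        core_rates.append(float(10 ** rng.uniform(-0.5, 0.3)))

    x0 = rng.uniform(0.4, 1.2, n_species)
    obs = {name: np.eye(n_species)[i] for i, name in enumerate(species)}

    def random_extension() -> dict:
        kind = rng.choice(["conversion", "degradation", "binding", "catalytic"])
        a, b, c = rng.choice(n_species, size=3, replace=False) if n_species >= 3 else (
            *rng.choice(n_species, size=2, replace=False),
            int(rng.integers(n_species)),
        )
        if kind == "conversion":
            return {"reactants": {species[a]: 1}, "products": {species[b]: 1}}
        if kind == "degradation":
            return {"reactants": {species[a]: 1}, "products": {}}
        if kind == "binding":
            return {"reactants": {species[a]: 1, species[b]: 1}, "products": {species[c]: 1}}
        return {"reactants": {species[a]: 1, species[b]: 1}, "products": {species[a]: 1, species[c]: 1}}

    models = []
    for m in range(n_models):
        k = int(rng.integers(n_extensions[0], n_extensions[1] + 1))
        ext = [random_extension() for _ in range(k)]
        ext_rates = [float(10 ** rng.uniform(-0.7, 0.7)) for _ in range(k)]
        theta = np.array(core_rates + ext_rates)
        models.append(
            CandidateModel(
                id=f"m{m}",
                state_names=list(species),
                x0_mean=x0.copy(),
                x0_cov=np.zeros((n_species, n_species)),
                theta_mean=theta,
                theta_cov=np.diag((rel_theta_sd * theta) ** 2),
                observation_map={k_: v.copy() for k_, v in obs.items()},
                reactions=core + ext,
            )
        )
    prior = np.full(n_models, 1.0 / n_models)
    return HypothesisClass(models, prior, metadata={"seed": int(seed)})
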
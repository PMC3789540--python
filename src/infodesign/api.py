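"""High-level modelling interface: ``ExperimentDesign`` -> ``DesignResults``.

Mirrors the model/results split familiar from statistical modelling
libraries: an :class:`ExperimentDesign` is constructed from the data of the
problem (a hypothesis class and a design space), ``fit()`` runs the
selection procedure, and the returned :class:`DesignResults` carries the
chosen experiment, its incremental information gains, the optimality bounds
and a ``summary()`` table.  Information profiling, frequency sweeps and data
simulation hang off the same objects.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import design as _design
from .bench import simulate_dataset
from .infer import BeliefState, Dataset, Experiment, posterior
from .models import DesignSpace, HypothesisClass
from .modelspec import load_hypothesis_class
from .objective import per_timepoint_profile
from .propagate import PredictiveDistribution, propagate_class

__all__ = ["ExperimentDesign", "DesignResults"]


class ExperimentDesign:
    """Budgeted measurement-selection problem for model discrimination.

    Parameters
    ----------
    hclass
        The hypothesis class (candidate ODE models with a prior).
    space
        The design space (time grid x readouts, noise model, budget).
    propagation
        ``"unscented"`` (default) or ``"monte_carlo"`` uncertainty
        propagation for building the predictive distributions.
    n_outer
        Outer-sample count of the Monte Carlo MI estimator.
    estimator
        ``"mc"`` (default) or ``"quadrature"`` (budgets of at most 2).
    """

    def __init__(
        self,
        hclass: HypothesisClass,
        space: DesignSpace,
        propagation: str = "unscented",
        n_particles: int = 1000,
        n_outer: int = 2000,
        estimator: str = "mc",
        propagation_seed: int = 0,
    ):
        self.hclass = hclass
        self.space = space
        self.propagation = propagation
        self.n_particles = n_particles
        self.n_outer = n_outer
        self.estimator = estimator
        self.propagation_seed = propagation_seed
        self._preds: Optional[list[PredictiveDistribution]] = None

    @classmethod
    def from_config(cls, model_spec_path, space: DesignSpace, **kw) -> "ExperimentDesign":
        """Build from a model-spec YAML file and an explicit design space."""
        return cls(load_hypothesis_class(model_spec_path), space, **kw)

    @property
    def preds(self) -> list[PredictiveDistribution]:
        """Per-model predictive distributions (computed once, cached)."""
        if self._preds is None:
            self._preds = propagate_class(
                self.hclass,
                self.space,
                method=self.propagation,
                n=self.n_particles,
                seed=self.propagation_seed,
            )
        return self._preds

    def fit(
        self,
        budget: Optional[int] = None,
        method: str = "greedy",
        seed: int = 0,
        n_outer: Optional[int] = None,
    ) -> "DesignResults":
        """Select the experiment and return the results object.

        ``method`` is ``"greedy"``, ``"lazy"`` or ``"exhaustive"``; the
        exhaustive route is only feasible on small pools and is mainly the
        optimality oracle for the greedy ones.
        """
        n_outer = self.n_outer if n_outer is None else n_outer
        if method == "greedy":
            res = _design.greedy_design(
                self.hclass, self.preds, self.space, budget=budget,
                n_outer=n_outer, seed=seed, estimator=self.estimator,
            )
        elif method == "lazy":
            res = _design.lazy_greedy_design(
                self.hclass, self.preds, self.space, budget=budget,
                n_outer=n_outer, seed=seed, estimator=self.estimator,
            )
        elif method == "exhaustive":
            budget_ = self.space.budget if budget is None else int(budget)
            objective = _design.make_mi_objective(
                self.hclass, self.preds, self.space, k_max=budget_ + 1,
                n_outer=n_outer, seed=seed, estimator=self.estimator,
            )
            selection, value = _design.exhaustive_design(
                self.hclass, self.preds, self.space, budget=budget_, objective=objective
            )
            est = objective(list(selection.pairs))
            res = _design.DesignResult(
                selection=selection,
                incremental_gains=np.array([]),
                total=est,
                offline_bound=max(est.value, 0.0) / _design.APPROX_FACTOR,
                online_bound=np.nan,
                seed=seed,
                evaluations=objective.evaluations,
                settings={"method": "exhaustive", "estimator": self.estimator, "n_outer": n_outer},
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        return DesignResults(self, res)

    def information_profile(self, readout: Optional[str] = None, seed: int = 0,
                            n_outer: Optional[int] = None, normalize: bool = True) -> pd.DataFrame:
        """Per-time-point MI of singleton measurements at one readout."""
        return per_timepoint_profile(
            self.hclass, self.preds, self.space, readout=readout,
            n_outer=self.n_outer if n_outer is None else n_outer,
            seed=seed, normalize=normalize,
        )

    def frequency_sweep(
        self,
        frequencies: Sequence[float],
        window: Optional[tuple[float, float]] = None,
        readout: Optional[str] = None,
        seed: int = 0,
        n_outer: Optional[int] = None,
    ) -> pd.DataFrame:
        """Normalized information of uniform sampling vs sampling frequency."""
        readout = self.space.readouts[0] if readout is None else readout
        if window is None:
            window = (0.0, float(self.space.times[-1]))
        noise = self.space.noise

        def builder(times):
            space_f = DesignSpace(times=times, readouts=[readout], noise=noise,
                                  budget=len(times), allow_repeats=False)
            preds_f = propagate_class(self.hclass, space_f, method="unscented")
            return space_f, preds_f

        return _design.frequency_sweep(
            self.hclass, builder, frequencies, window,
            n_outer=self.n_outer if n_outer is None else n_outer, seed=seed,
        )

    def simulate(self, true_model_id: str, experiment: Experiment, seed: int) -> Dataset:
        """Simulate noisy data from a named candidate at selected coordinates."""
        model = self.hclass.models[self.hclass.index_of(true_model_id)]
        return simulate_dataset(model, experiment, self.space, seed)

    def update(self, data: Dataset, prior: Optional[BeliefState] = None) -> BeliefState:
        """Posterior over the class given realized data."""
        prior = BeliefState.from_probs(self.hclass.prior) if prior is None else prior
        return posterior(prior, data, self.preds, self.space)


class DesignResults:
    """Fitted selection: chosen experiment, gains, bounds, summary table."""

    def __init__(self, model: ExperimentDesign, result: _design.DesignResult):
        self.model = model
        self._result = result

    # pass-through conveniences -------------------------------------------
    @property
    def selection(self) -> Experiment:
        return self._result.selection

    @property
    def incremental_gains(self) -> np.ndarray:
        return self._result.incremental_gains

    @property
    def total(self):
        return self._result.total

    @property
    def offline_bound(self) -> float:
        return self._result.offline_bound

    @property
    def online_bound(self) -> float:
        return self._result.online_bound

    @property
    def evaluations(self) -> int:
        return self._result.evaluations

    @property
    def seed(self):
        return self._result.seed

    def design_table(self) -> pd.DataFrame:
        """Rank / time / readout / incremental and cumulative gain in bits."""
        space = self.model.space
        rows = []
        cum = 0.0
        gains = self._result.incremental_gains
        for rank, (i, j) in enumerate(self.selection.pairs, start=1):
            gain_bits = float(gains[rank - 1]) / np.log(2) if gains.size >= rank else np.nan
            cum += 0.0 if np.isnan(gain_bits) else gain_bits
            rows.append(
                {
                    "rank": rank,
                    "time": space.times[i],
                    "readout": space.readouts[j],
                    "gain_bits": gain_bits,
                    "cumulative_bits": cum,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        r = self._result
        ln2 = float(np.log(2))
        return {
            "selection": [list(p) for p in r.selection.pairs],
            "selection_times": [float(self.model.space.times[i]) for i, _ in r.selection.pairs],
            "selection_readouts": [self.model.space.readouts[j] for _, j in r.selection.pairs],
            "incremental_gains_nats": r.incremental_gains.tolist(),
            "incremental_gains_bits": (r.incremental_gains / ln2).tolist(),
            "total_nats": r.total.value,
            "total_bits": r.total.value_bits,
            "std_error_nats": r.total.std_error,
            "offline_bound_nats": r.offline_bound,
            "offline_bound_bits": r.offline_bound / ln2,
            "online_bound_nats": r.online_bound,
            "online_bound_bits": (r.online_bound / ln2) if np.isfinite(r.online_bound) else None,
            "seed": r.seed,
            "evaluations": r.evaluations,
            "settings": r.settings,
        }

    def summary(self) -> str:
        """Human-readable report of the fitted design."""
        r = self._result
        lines = [
            "          Experiment design for model discrimination",
            "=" * 62,
            f"Models: {len(self.model.hclass)}   candidates: {self.model.space.n_channels}   "
            f"budget: {len(r.selection)}   method: {r.settings.get('method', '?')}",
            f"Prior entropy: {self.model.hclass.prior_entropy_bits():.4f} bits",
            "-" * 62,
            f"{'rank':>4} {'time':>10} {'readout':>12} {'gain [bits]':>12} {'cum [bits]':>11}",
        ]
        for _, row in self.design_table().iterrows():
            lines.append(
                f"{int(row['rank']):>4} {row['time']:>10.3f} {row['readout']:>12} "
                f"{row['gain_bits']:>12.4f} {row['cumulative_bits']:>11.4f}"
            )
        lines += [
            "-" * 62,
            f"Total expected information gain: {r.total.value_bits:.4f} bits "
            f"(se {r.total.std_error / np.log(2):.4f})",
            f"Offline bound on optimum: {r.offline_bound / np.log(2):.4f} bits",
        ]
        if np.isfinite(r.online_bound):
            lines.append(f"Online bound on optimum:  {r.online_bound / np.log(2):.4f} bits")
        lines.append(f"Objective evaluations: {r.evaluations}   seed: {r.seed}")
        return "\n".join(lines)
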
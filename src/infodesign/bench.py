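"""Success-rate benchmark of design criteria for model selection.

Simulates the full design-then-experiment loop: a designer picks a budgeted
set of (time, readout) measurements, synthetic data are generated from a
designated true model with additive independent Gaussian noise (optionally
the half-of-the-concentration rule), the posterior over the hypothesis class
is computed, and the run counts as a success when the maximum-a-posteriori
model is the selection target — the true model in the realizable scenario,
or the candidate closest to the truth in relative entropy when the truth is
outside the class (non-realizable).

Designers: the expected-information-gain greedy design (EIG), a
prior-weighted sum-of-squared-Euclidean-distances score (EUD), a simplified
point-parameter noncentrality criterion (ANC, max-min of noise-normalized
squared mean discrepancies), and a uniformly random selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import greedy_design
from .infer import BeliefState, Dataset, Experiment, posterior
from .models import CandidateModel, DesignSpace, HypothesisClass, ProportionalNoise
from .propagate import PredictiveDistribution, predict_measurements, propagate_class

__all__ = [
    "ScenarioConfig",
    "BenchResult",
    "simulate_dataset",
    "best_model_nonrealizable",
    "baseline_euclidean",
    "baseline_noncentrality",
    "random_design",
    "success_rate",
    "DESIGNERS",
]

DESIGNERS = ("EIG", "EUD", "ANC", "random")


@dataclass
class ScenarioConfig:
    """One benchmark scenario: class, truth, design space, noise, replication."""

    hclass: HypothesisClass
    true_model: CandidateModel
    space: DesignSpace
    n_runs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @property
    def realizable(self) -> bool:
        return self.true_model.id in self.hclass.model_ids


@dataclass
class BenchResult:
    """Aggregate success rate plus the per-run records that produced it."""

    method: str
    success_rate: float
    n_runs: int
    seed: int
    selection: Experiment
    runs: pd.DataFrame = field(repr=False, default=None)


def simulate_dataset(
    true_model: CandidateModel,
    experiment: Experiment,
    space: DesignSpace,
    seed: int,
    truth: Optional[np.ndarray] = None,
) -> Dataset:
    """Noisy synthetic data from the true model at the selected coordinates.

    ``y_ij = prediction(t_i, j) + eps_ij`` with independent Gaussian noise
    whose sd follows the design space's noise model evaluated on the true
    prediction (for the proportional rule: half of the concentration, with a
    small floor near zero).  ``truth`` may supply a precomputed full-grid
    prediction to avoid re-integrating the IVP.  Deterministic given seed.
    """
    if truth is None:
        truth = predict_measurements(true_model, space)
    idx = experiment.flat_indices(space)
    sd = space.noise_sd(truth)[idx]
    rng = np.random.default_rng(seed)
    values = truth[idx] + rng.standard_normal(idx.size) * sd
    return Dataset(experiment, values)


def _gaussian_kl(mu0, cov0, mu1, cov1) -> float:
    """KL( N(mu0, cov0) || N(mu1, cov1) ) in nats."""
    k = mu0.size
    chol1 = np.linalg.cholesky(cov1)
    sol = np.linalg.solve(cov1, cov0)
    diff = mu1 - mu0
    z = np.linalg.solve(chol1, diff)
    _, logdet0 = np.linalg.slogdet(cov0)
    logdet1 = 2.0 * float(np.sum(np.log(np.diag(chol1))))
    return 0.5 * float(np.trace(sol) + z @ z - k + logdet1 - logdet0)


def best_model_nonrealizable(
    hclass: HypothesisClass,
    true_model: CandidateModel,
    space: DesignSpace,
    preds: Optional[Sequence[PredictiveDistribution]] = None,
    true_pred: Optional[PredictiveDistribution] = None,
) -> str:
    """Candidate closest to the truth in predictive relative entropy.

    Minimizes KL(true predictive law || candidate predictive law) over the
    full design-space coordinates with measurement noise included; ties
    within 1e-9 go to the lowest model index.
    """
    from .propagate import unscented_propagate

    if preds is None:
        preds = propagate_class(hclass, space, method="unscented")
    if true_pred is None:
        true_pred = unscented_propagate(true_model, space)
    sd_t = space.noise_sd(true_pred.mean)
    cov_t = true_pred.cov + np.diag(sd_t**2)
    kls = []
    for pred in preds:
        sd_c = space.noise_sd(pred.mean)
        cov_c = pred.cov + np.diag(sd_c**2)
        kls.append(_gaussian_kl(true_pred.mean, cov_t, pred.mean, cov_c))
    kls = np.asarray(kls)
    best = int(np.argmin(kls))
    near = np.flatnonzero(kls <= kls[best] + 1e-9)
    return hclass.models[int(near[0])].id


def _pairwise_sq_diffs(hclass, preds):
    """Prior-weighted squared mean differences per channel, per model pair."""
    n = len(hclass)
    out = []
    for a in range(n):
        for b in range(a + 1, n):
            w = hclass.prior[a] * hclass.prior[b]
            out.append((w, (preds[a].mean - preds[b].mean) ** 2))
    return out


def baseline_euclidean(
    hclass: HypothesisClass,
    preds: Sequence[PredictiveDistribution],
    space: DesignSpace,
    budget: Optional[int] = None,
) -> Experiment:
    """Greedy maximization of prior-weighted summed squared mean distances.

    The score is additive over selected channels (modular), so the greedy
    selection equals the exhaustive optimum of the same score.  Ties break
    lexicographically on (time index, readout index).
    """
    budget = space.budget if budget is None else int(budget)
    score = np.zeros(space.n_channels)
    for w, sq in _pairwise_sq_diffs(hclass, preds):
        score += w * sq
    order = sorted(range(space.n_channels), key=lambda c: (-score[c], space.pair(c)))
    return Experiment([space.pair(c) for c in order[:budget]])


def baseline_noncentrality(
    hclass: HypothesisClass,
    preds: Sequence[PredictiveDistribution],
    space: DesignSpace,
    budget: Optional[int] = None,
) -> Experiment:
    """Simplified noncentrality criterion: greedy max-min discrimination.

    Uses point (plug-in) predictions: the score of a selection is the
    minimum over model pairs of the summed squared mean discrepancies
    normalized by the noise variance, and the greedy step adds the channel
    maximizing that worst-case score.  Noise is evaluated on the
    prior-weighted mean prediction so every pair shares one normalization.
    """
    budget = space.budget if budget is None else int(budget)
    mixture_mean = np.sum([p * pr.mean for p, pr in zip(hclass.prior, preds)], axis=0)
    sd = space.noise_sd(mixture_mean)
    pair_scores = [sq / sd**2 for _, sq in _pairwise_sq_diffs(hclass, preds)]
    selection: list[int] = []
    acc = np.zeros(len(pair_scores))
    for _ in range(budget):
        best_c, best_val = None, -math.inf
        for c in range(space.n_channels):
            if not space.allow_repeats and c in selection:
                continue
            val = min(acc[p] + pair_scores[p][c] for p in range(len(pair_scores)))
            if val > best_val:
                best_c, best_val = c, val
        selection.append(best_c)
        acc += np.array([pair_scores[p][best_c] for p in range(len(pair_scores))])
    return Experiment([space.pair(c) for c in selection])


def random_design(space: DesignSpace, budget: int, seed: int) -> Experiment:
    """Uniformly random budget-sized selection from the candidate pool."""
    rng = np.random.default_rng(seed)
    pool = space.all_pairs()
    idx = rng.choice(len(pool), size=budget, replace=space.allow_repeats)
    return Experiment([pool[i] for i in sorted(idx)])


def design_experiment(
    method: str,
    hclass: HypothesisClass,
    preds: Sequence[PredictiveDistribution],
    space: DesignSpace,
    budget: int,
    seed: int = 0,
    n_outer: int = 1000,
) -> Experiment:
    """Dispatch a designer tag to its selection routine."""
    if method == "EIG":
        return greedy_design(hclass, preds, space, budget=budget, seed=seed, n_outer=n_outer).selection
    if method == "EUD":
        return baseline_euclidean(hclass, preds, space, budget=budget)
    if method == "ANC":
        return baseline_noncentrality(hclass, preds, space, budget=budget)
    if method == "random":
        return random_design(space, budget, seed)
    raise ValueError(f"unknown designer {method!r}; choose from {DESIGNERS}")


def success_rate(
    config: ScenarioConfig,
    designer: str,
    budget: Optional[int] = None,
    preds: Optional[Sequence[PredictiveDistribution]] = None,
    n_outer: int = 1000,
) -> BenchResult:
    """Empirical success rate of one designer on a scenario.

    The design is data-independent, so it is computed once; each run then
    simulates data from the true model with a run-indexed child seed (the
    same innovation sequence across designers, for paired comparisons),
    computes the posterior, and succeeds iff the strict MAP model is the
    target.  A MAP tie counts as a failure (conservative).
    """
    if preds is None:
        preds = propagate_class(config.hclass, config.space, method="unscented")
    budget = config.space.budget if budget is None else int(budget)
    experiment = design_experiment(
        designer, config.hclass, preds, config.space, budget, seed=config.seed, n_outer=n_outer
    )
    truth_mean = predict_measurements(config.true_model, config.space)
    if config.realizable:
        target = config.true_model.id
    else:
        target = best_model_nonrealizable(config.hclass, config.true_model, config.space, preds=preds)
    prior = BeliefState.from_probs(config.hclass.prior)
    records = []
    for r in range(config.n_runs):
        run_seed = (config.seed * 1_000_003 + r) % (2**31 - 1)
        data = simulate_dataset(config.true_model, experiment, config.space, run_seed, truth=truth_mean)
        post = posterior(prior, data, preds, config.space)
        lp = post.log_probs
        top = np.flatnonzero(lp >= lp.max() - 1e-12)
        map_id = config.hclass.models[int(top[0])].id
        success = bool(top.size == 1 and map_id == target)
        records.append(
            {"run": r, "seed": run_seed, "target": target, "map": map_id, "success": success}
        )
    runs = pd.DataFrame(records)
    rate = float(runs["success"].sum()) / config.n_runs
    return BenchResult(
        method=designer,
        success_rate=rate,
        n_runs=config.n_runs,
        seed=config.seed,
        selection=experiment,
        runs=runs,
    )
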
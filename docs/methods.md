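# Methods

## Problem and model

The studied system is assumed to evolve as an ODE initial value problem
ẋ(t) = f(x(t), θ) with known initial condition x(0) = x₀, where each state
component is a concentration or physiological quantity. The researcher holds
a finite hypothesis class ℋ = {f₁, …, f_M} of candidate right-hand sides with
prior probabilities p(f); the data-generating system may (realizable) or may
not (non-realizable) be a member. An individual measurement is a linear
readout of the state at a time point, corrupted by independent Gaussian noise:
y_ij = h_j(x(t_i)) + ε_ij, ε_ij ~ N(0, σ_ij²). An experiment π is a budgeted
multiset of (time index, readout index) pairs; repeated pairs receive
independent noise on each occurrence. After observing the dataset D_π, model
probabilities are revised by Bayes' rule with the likelihood marginalized over
the parameter/initial-condition uncertainty of each model, and the realized
value of the experiment is the relative entropy KL(posterior ‖ prior).

The design objective is the expectation of that gain over hypothetical
outcomes — the mutual information I(F; Y_π) between the model indicator F and
the outcome Y_π — maximized subject to the measurement budget |π| ≤ κ. Since
I(F; Y_π) is monotone and submodular in π, greedy selection achieves at least
(1 − 1/e) of the optimal value (a guarantee inherited from the standard
submodular-maximization results; it is not re-proved here, and the package
additionally reports the tighter data-dependent online bound obtained by
adding the top-κ remaining marginal gains to the achieved value).

## Uncertainty propagation

Parameter and initial-condition uncertainty are treated jointly: the
augmented vector (θ, x₀) carries a block-diagonal Gaussian covariance, and
"alternative parameter values are alternative models" in the sense that the
predictive law of every candidate measurement already integrates over them.
The evolution of state uncertainty is never solved as a density PDE; two
operational surrogates are provided:

- **Unscented transform** (default): 2d + 1 sigma points over the d
  genuinely uncertain coordinates (zero-variance coordinates are held at
  their means), each solved through the IVP and mapped through the readout
  functionals, with scaled-UT weights α = 1, β = 2, κ_ut = 0 (the standard
  Gaussian-optimal choice; the scaling is exposed but there was no reason to
  deviate). Exact for linear dynamics with Gaussian inputs.
- **Monte Carlo**: n i.i.d. draws of (θ, x₀) solved through the IVP,
  retained as particles with their sample moments. It is the independent
  reference for validating the sigma-point approximation, and the particle
  likelihood (an equally weighted mixture convolved with the noise kernel)
  supports multimodal predictive laws where the Gaussian surrogate is crude.

Numerical choices: the IVP solver is LSODA (automatic stiff/non-stiff
switching) at rtol 1e-8 / atol 1e-10 by default; tolerances are exposed
because information estimates should be solver-stable. A terminal event
aborts cleanly when a trajectory exceeds 1e12 in magnitude instead of
stalling near a finite-time singularity. Predictive covariances are
symmetrized and their eigenvalues floored at 1e-12 of the trace to absorb
sigma-point round-off; *input* covariances are factored with negatives
clipped at zero only, because a trace-relative floor would corrupt
legitimately tiny variances when parameter scales are heterogeneous (rate
constants of order 1e-5 next to constants of order 10).

## Information estimation

The MI is computed in its discrete-model form I = H(F) − E_Y[H(F | Y)]:
sample a model from the prior, an outcome from its noisy predictive law on
π, compute the posterior entropy over models, and average. This avoids the
intractable differential entropy of the Gaussian-mixture observation law and
directly expresses posterior concentration. All internal quantities are in
nats; user-facing outputs convert to bits. Estimator details:

- **Common random numbers.** One outer sample (model draws plus
  standard-normal innovations indexed by selection position) is shared by
  every candidate experiment within a sweep, so greedy, lazy, exhaustive and
  bound computations all optimize the same fixed sample-average objective and
  their comparisons are not corrupted by independent sampling noise. The
  guarantees are therefore statements about the estimated objective; the
  reported standard errors quantify its distance to the exact one. Every
  result records its seed.
- **n_outer defaults to 2000** per evaluation, with the standard error of
  the per-sample gains reported alongside. Raw estimates may dip below zero
  by sampling noise; they are floored at zero for reporting and kept raw for
  diagnostics.
- **Quadrature oracle.** For experiments of one or two measurements the MI
  is also computable by deterministic trapezoid integration of the defining
  mixture integral, with the grid refined to resolve the narrowest mixture
  component; it validates the Monte Carlo path in the tests.
- **Sequential updating.** Parameter marginalization correlates
  measurements across time, so a naive product of per-block likelihoods is
  not exact; the sequential update instead conditions each new block on
  everything already assimilated (joint-likelihood telescoping), making
  sequential and batch posteriors identical to round-off in any order.

## Selection and bounds

Greedy selection always spends the full budget (information increments are
nonnegative), with ties broken lexicographically on (time index, readout
index) so the output is independent of enumeration order. The lazy variant
keeps stale marginal gains in a priority queue (valid upper bounds under
diminishing returns) and falls back to a full re-evaluation of the round
whenever a fresh winner leads the next stale priority by less than three
combined standard errors, which keeps it aligned with plain greedy under
Monte Carlo noise at strictly fewer or equal objective evaluations.
Exhaustive search refuses pools beyond 1e5 subsets (the 20-choose-5 = 15 504
reference case sits comfortably inside). The online bound's q parameter
defaults to the budget κ.

## Fixtures and the synthetic benchmark generator

**Glucose-tolerance family.** Four phenomenological models of intravenous
glucose tolerance sharing the plasma-glucose readout G (mg/dl), forced by a
plasma-insulin time course I(t) (µU/ml) that is supplied to, not produced
by, the ODEs (piecewise-linear interpolation; IVGTT-style first-phase peak
of 110 µU/ml at 2 min decaying to the basal 11 µU/ml):

- I: Ġ = s_G (G_b − G) — insulin-independent turnover;
- IV: Ġ = s_G (G_b − G) − s_I (I(t) − I_b) G — constant hepatic production,
  disposal enhanced directly by plasma insulin;
- V: Ġ = s_G (G_b − G) − X G, Ẋ = −p₂ X + p₃ (I(t) − I_b) — constant
  production, disposal through a remote insulin-action compartment;
- VI: Ġ = s_G (G_b − G) − X G − h X, Ẋ as in V — insulin-dependent
  production suppression plus peripheral, insulin-driven disappearance.

Default parameterization (all values in `models.py`): G_b = 92 mg/dl,
I_b = 11 µU/ml, G(0) = 279 mg/dl (known exactly), s_G = 0.028 /min,
s_I = 5·10⁻⁴ ml/µU/min, p₂ = 0.025 /min, p₃ = 1.3·10⁻⁵ /min² per µU/ml,
h = 40 mg/dl, with independent 10% standard deviations on every kinetic
constant. These are literature-scale minimal-model values for a
normal-tolerance subject; the package's qualitative claims (information
profile peaking in the transient toward the steady state, frequency
saturation above 90% by 0.2 samples/min, near-coincidence of greedy and
exhaustive designs) are checked in the acceptance tests and are robust to
moderate changes of this choice. The default design space samples 20
uniform times in 9–180 min with a fixed measurement sd of 15 mg/dl, an
assay-plus-biological-variability scale that keeps the five-measurement
design information in the ~1.0–1.4 bit mid-range rather than saturated at
the 2-bit ceiling.

**Linear-Gaussian pair.** Two one-state linear ODEs ẋ = a_k x with Gaussian
x₀; every predictive law is exactly Gaussian and known in closed form, which
anchors the propagation and estimator tests at machine tolerance.

**Synthetic hypothesis classes.** A seeded generator emulating large
benchmark classes of biochemical hypotheses: all models share n_species
observable species and a core mass-action network (constant inflow, a linear
conversion chain, first-order degradation of every species — which bounds
total mass on any finite window and guarantees integrability), and each
model appends 1–3 randomized elementary extension reactions (conversion,
degradation, binding, catalytic conversion) with log-uniform rate constants
and 10% parameter uncertainty. What it emulates: heterogeneous model
complexity across a class sharing observable species. What it does not:
the curated biochemical realism of a hand-built pathway model, parameter
priors informed by data, or conservation structures beyond mass
boundedness — so passing benchmark tests demonstrates the ranking behavior
of the criteria under controlled conditions, not performance on any
particular real pathway.

## Benchmark protocol

Each scenario fixes the class, a true model (inside the class or not), a
design space and a noise rule; data are simulated as the true model's
deterministic readouts plus independent Gaussian noise, by default with
standard deviation equal to half of the predicted concentration (floored at
1e-3 in readout units near zero concentrations, a case the half-concentration
rule leaves undefined). Designs are data-independent, so each designer's
selection is computed once; runs differ only in the noise seed, and the
run-indexed child seeds are shared across designers so comparisons are
paired. A run succeeds when the strict maximum-a-posteriori model equals the
target — the true model when realizable, otherwise the candidate minimizing
the Gaussian KL divergence to the truth's noisy predictive law over the full
design space. Posterior ties count as failures (conservative). The default
replication is 200 runs per scenario, a desk-scale choice whose binomial
standard error (≈3.5 percentage points at p = 0.25) is adequate for the
directional comparisons the tests make; n_runs is configurable.

Baselines: EUD greedily maximizes the prior-weighted sum over model pairs of
squared differences of predictive means (modular, hence exactly optimized by
greedy); ANC is a deliberately simplified point-parameter noncentrality
criterion — greedy max–min over model pairs of noise-normalized squared mean
discrepancies — replacing the full ensemble version, whose nested nonlinear
parameter fitting per candidate configuration is outside this package's
scope; `random` selects uniformly at random.

## Problem sizes used by the shipped analyses

The acceptance computations use the four-model glucose class with 2000 outer
Monte Carlo samples per MI evaluation, a 20-point pool for the greedy versus
exhaustive comparison (budgets 3–5), a 60-point uniform 3-minute grid for
the information profile, seven frequencies up to 1 sample/min for the
saturation sweep, 10⁴ Monte Carlo draws for the propagation cross-check, and
200-run benchmark scenarios on a 4-model, 3-species synthetic class. These
sizes were chosen so every claim is resolved well beyond its decision
threshold (standard errors of a few thousandths of a bit; binomial errors of
a few percent) while a full reproduction stays a coffee-break computation on
one CPU.

## Known limitations

- Observation maps are linear functionals of the state; nonlinear readouts
  would require extending the sigma-point contract for no gain on the
  shipped case studies.
- The Gaussian predictive surrogate can misrepresent strongly skewed
  push-forwards (visible in the glucose model VI late-time skewness); the
  particle representation is the fallback, at higher cost.
- Greedy guarantees hold for the common-random-number estimate of the
  objective, not the exact MI; standard errors are reported so users can
  judge the gap.
- Model-spec files cover built-in and mass-action right-hand sides only;
  arbitrary black-box rhs callables are code-level objects and cannot be
  serialized. SBML import/export is out of scope.
- Plotting is intentionally left to the user's tooling; all outputs are
  plain DataFrames/CSV/JSON.
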
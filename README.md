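# infodesign

Near-optimal Bayesian experimental design for **model selection among ODE
dynamical systems**. Given a finite hypothesis class of candidate models
ℋ = {f₁, …, f_M} with prior p(f), a grid of candidate sampling times, a set
of measurable readouts and a per-measurement Gaussian noise model, the
package selects the budgeted multiset π of (time point, readout) pairs that
(nearly) maximizes the mutual information between the model indicator and
the hypothetical experimental outcome,

    π̂ = argmax_{|π| ≤ κ}  I(F ; Y_π),
    I(F ; Y_π) = H(F) − E_{Y_π}[ H(F | Y_π) ],

i.e. the expected Kullback–Leibler gain of the Bayes update from prior to
posterior model probabilities. Because this set function is monotone and
submodular, the greedy sweep that repeatedly adds the measurement with the
largest information increment is guaranteed to achieve at least a
(1 − 1/e) ≈ 63.2% fraction of the unattainable optimum, with a polynomial
number of objective evaluations; computable offline and online bounds
sandwich the optimum from above. The package is aimed at systems biologists
and modellers who must decide *when* and *what* to measure before running an
expensive experiment that should discriminate between competing mechanistic
hypotheses.

What's inside:

- **models** — hypothesis classes and design spaces, with three bundled
  fixtures: the four-model insulin-dependent glucose-tolerance family
  (minimal models I, IV, V, VI with a documented parameterization and a
  piecewise-linear plasma-insulin forcing), an exactly solvable
  linear-Gaussian pair, and a seeded generator of large mass-action
  hypothesis classes with shared observable species. Classes round-trip
  through a YAML model-spec format.
- **propagate** — IVP solving plus unscented-transform and Monte Carlo
  propagation of parameter/initial-condition uncertainty into a joint
  predictive law over all candidate measurements.
- **infer** — Gaussian/particle-mixture likelihoods with parameters
  marginalized, log-space Bayes updates over the class, realized
  information gain, sequential (posterior-becomes-prior) updating.
- **objective** — the nested Monte Carlo MI estimator with common random
  numbers, and a dense-grid quadrature oracle for 1–2 measurement designs.
- **design** — greedy, lazy-greedy and exhaustive selection, (1 − 1/e)
  offline and submodular online bounds, sampling-frequency sweeps and
  per-time-point information profiles.
- **bench** — success-rate benchmark (realizable and non-realizable
  scenarios) of the information design against Euclidean-distance and
  simplified noncentrality baselines and random selection.

## Worked example

```python
import infodesign as idn

hclass = idn.make_bergman_class()          # glucose models I, IV, V, VI, uniform prior
space = idn.bergman_design_space()         # 20 sampling times in 9-180 min, sd 15 mg/dl
problem = idn.ExperimentDesign(hclass, space, n_outer=2000)
results = problem.fit(budget=5, seed=7)
print(results.summary())
```

prints

```
          Experiment design for model discrimination
==============================================================
Models: 4   candidates: 20   budget: 5   method: greedy
Prior entropy: 2.0000 bits
--------------------------------------------------------------
rank       time      readout  gain [bits]  cum [bits]
   1     18.000      glucose       0.7585      0.7585
   2     45.000      glucose       0.2534      1.0118
   3      9.000      glucose       0.1556      1.1675
   4     54.000      glucose       0.1177      1.2851
   5     63.000      glucose       0.0700      1.3551
--------------------------------------------------------------
Total expected information gain: 1.3551 bits (se 0.0118)
Offline bound on optimum: 2.1438 bits
Online bound on optimum:  1.5417 bits
Objective evaluations: 105   seed: 7
```

Reading: out of the 2 bits that would identify one of four equally probable
models, five well-placed glucose samples are expected to deliver ≈1.36 bits;
the first sample at 18 min (early in the transition toward the
post-injection steady state) is by far the most informative, and later
additions obey diminishing returns. The optimum over all C(20,5) = 15 504
five-point designs can be no better than the online bound of ≈1.54 bits, so
the greedy design is certifiably close to optimal; running
`problem.fit(budget=5, method="exhaustive")` confirms it is practically
identical.

The same object exposes `problem.information_profile()` (per-time-point MI),
`problem.frequency_sweep([...])` (information versus uniform sampling
frequency), and `problem.simulate()` / `problem.update()` for closing the
loop with data. A `click` CLI wraps these as `infodesign design|profile|bench|validate`
driven by a YAML config (see `infodesign.cli`).

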
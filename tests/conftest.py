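import numpy as np
import pytest

import infodesign as idn


@pytest.fixture(scope="session")
def bergman_class():
    return idn.make_bergman_class()


@pytest.fixture(scope="session")
def bergman_space():
    return idn.bergman_design_space()


@pytest.fixture(scope="session")
def bergman_preds(bergman_class, bergman_space):
    return idn.propagate_class(bergman_class, bergman_space)


@pytest.fixture(scope="session")
def linear_pair():
    return idn.make_linear_gaussian_pair(separation=0.5)


def make_linear_class(rates, x0_sd=0.1, x0_mean=1.0):
    """Hand-built class of one-state linear ODEs dx/dt = a_k x."""
    models = [
        idn.CandidateModel(
            id=f"lin{k}",
            state_names=["x"],
            x0_mean=np.array([x0_mean]),
            x0_cov=np.array([[x0_sd**2]]),
            theta_mean=np.array([a]),
            theta_cov=np.zeros((1, 1)),
            observation_map={"x": [1.0]},
            rhs_callable=lambda t, x, th: th[0] * x,
        )
        for k, a in enumerate(rates)
    ]
    prior = np.full(len(rates), 1.0 / len(rates))
    return idn.HypothesisClass(models, prior)


def gaussian_point_preds(means, model_ids=None):
    """Zero-covariance predictive distributions with prescribed means."""
    means = np.atleast_2d(np.asarray(means, dtype=float))
    out = []
    for k, mu in enumerate(means):
        mid = f"m{k}" if model_ids is None else model_ids[k]
        out.append(idn.PredictiveDistribution(mid, mu, np.zeros((mu.size, mu.size))))
    return out
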
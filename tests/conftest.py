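import numpy as np
import pytest

from visdcm.design import build_input_regressors, generate_trial_schedule
from visdcm.network import NetworkSpec, param_names
from visdcm.posterior import PriorSpec, default_priors
from visdcm.synth import paper_ground_truth


@pytest.fixture(scope="session")
def spec():
    return NetworkSpec.visual_imagery()


@pytest.fixture(scope="session")
def gt():
    return paper_ground_truth()


@pytest.fixture(scope="session")
def full_priors(spec):
    return default_priors(param_names(spec))


@pytest.fixture(scope="session")
def micro_inputs():
    """A 4-trial input series, enough to exercise the forward model cheaply."""
    sched = generate_trial_schedule(4, rng_seed=123)
    viv = np.array([1.0, 3.0, 2.0, 4.0])
    return sched, build_input_regressors(sched, viv, dt=0.1)


def make_linear_problem(seed=0, n=40, names=("a", "b", "c"),
                        theta=(0.9, 0.0, -0.5), noise_sd=0.3,
                        prior_var=1.0):
    """Linear-Gaussian toy problem with its exact conjugate solution."""
    from visdcm.inversion import LinearForward

    rng = np.random.default_rng(seed)
    names = list(names)
    X = rng.normal(size=(n, len(names)))
    theta = np.asarray(theta, float)
    y = X @ theta + rng.normal(0, noise_sd, n)
    prior = PriorSpec(names, np.zeros(len(names)),
                      np.full(len(names), prior_var))
    lam = np.log(1.0 / noise_sd**2)
    Pi = np.exp(lam) * X.T @ X + np.diag(1.0 / prior.variances)
    cov = np.linalg.inv(Pi)
    mu = cov @ (np.exp(lam) * X.T @ y)
    return {"X": X, "y": y, "prior": prior, "lam": lam, "theta": theta,
            "post_mean": mu, "post_cov": cov,
            "forward": LinearForward(X, names)}
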
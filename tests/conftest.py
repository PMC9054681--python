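import numpy as np
import pandas as pd
import pytest

import neuromir as nm


@pytest.fixture
def table2_counts():
    """The packaged worked-example genotype counts (580 subjects)."""
    return nm.XGenotypeCounts(n_AA=229, n_AG=24, n_GG=1, n_A=312, n_G=14)


@pytest.fixture
def small_cohort():
    """A small seeded cohort with a real miR effect, for fast model tests."""
    cfg = nm.OrdinalSimConfig(n_subjects=400, beta_mir=1.0, beta_e4=0.8,
                              beta_interaction=0.0, seed=42)
    return nm.simulate_ordinal_cohort(cfg)


@pytest.fixture
def noiseless_trace():
    cfg = nm.FuraSimConfig(noise_sd=0.0)
    return cfg, nm.simulate_fura_trace(cfg)


def binary_logistic_oracle(X, y):
    """Independent binary logistic MLE: P(y=1|x) = logistic(x.b - a).

    Direct numerical maximization of the Bernoulli log-likelihood with
    scipy, sharing no code with the proportional-odds fitter.  Returns
    (alpha, beta, loglik).
    """
    from scipy.optimize import minimize
    from scipy.special import expit

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)

    def nll(theta):
        a, b = theta[0], theta[1:]
        p1 = expit(X @ b - a)
        p1 = np.clip(p1, 1e-300, 1 - 1e-16)
        return -(y * np.log(p1) + (1 - y) * np.log(1 - p1)).sum()

    res = minimize(nll, np.zeros(1 + X.shape[1]), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x[0], res.x[1:], -res.fun


def random_binary_cohort(rng, n_max=200):
    """A random two-level dataset with a separation-free logistic structure."""
    from scipy.special import expit

    while True:
        n = int(rng.integers(60, n_max + 1))
        X = rng.normal(size=(n, 2))
        beta = rng.normal(scale=0.8, size=2)
        p1 = expit(rng.normal(scale=0.5) + X @ beta)
        y = (rng.random(n) < p1).astype(int)
        if 5 <= y.sum() <= n - 5:
            break
    cohort = pd.DataFrame({
        "x1": X[:, 0],
        "x2": X[:, 1],
        "diagnosis": pd.Categorical(np.where(y == 1, "case", "control"),
                                    categories=["control", "case"],
                                    ordered=True),
    })
    return cohort, X, y
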
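import numpy as np
import pandas as pd
import pytest

from clonofit import (
    AssayTable,
    CurveSimSpec,
    TwoWaySimSpec,
    simulate_curve_data,
    simulate_twoway_data,
)

# doses mirror a typical design: control + five doses up to 6 Gy,
# 8 replicate experiments -> 48 plates
CURVE_DOSES = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0)


@pytest.fixture(scope="session")
def curve_table() -> AssayTable:
    """Pure-Poisson LQ data, 8 experiments x 6 dose levels = 48 plates."""
    return simulate_curve_data(CurveSimSpec(doses=CURVE_DOSES, seed=17))


@pytest.fixture(scope="session")
def overdispersed_table() -> AssayTable:
    """LQ data with lognormal between-experiment variation (sd 0.3)."""
    return simulate_curve_data(
        CurveSimSpec(doses=CURVE_DOSES, replicate_sd=0.3, seed=29)
    )


@pytest.fixture(scope="session")
def two_group_table() -> AssayTable:
    """Two cell lines simulated from identical LQ parameters."""
    a = simulate_curve_data(CurveSimSpec(doses=CURVE_DOSES, seed=5, group_label="lineA"))
    b = simulate_curve_data(CurveSimSpec(doses=CURVE_DOSES, seed=6, group_label="lineB"))
    return AssayTable(pd.concat([a.data, b.data], ignore_index=True))


@pytest.fixture(scope="session")
def twoway_table() -> AssayTable:
    """2x2 factorial counts, 4 experiments x 4 design cells = 16 plates."""
    return simulate_twoway_data(TwoWaySimSpec(seed=11))


def poisson_neg_loglik(beta, X, y, offset):
    eta = X @ beta + offset
    return float(np.sum(np.exp(eta)) - y @ eta)


def fit_poisson_by_optimizer(X, y, offset):
    """Independent ML oracle: generic numerical maximization of the Poisson
    log-likelihood via scipy.optimize (no IRLS involved).  A trust-region
    minimization is polished by a root solve of the score equations."""
    from scipy.optimize import minimize, root

    def grad(beta):
        mu = np.exp(X @ beta + offset)
        return X.T @ (mu - y)

    def hess(beta):
        mu = np.exp(X @ beta + offset)
        return X.T @ (X * mu[:, None])

    res = minimize(
        lambda b: poisson_neg_loglik(b, X, y, offset),
        x0=np.zeros(X.shape[1]),
        jac=grad,
        hess=hess,
        method="trust-exact",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    polished = root(grad, res.x, jac=hess, method="hybr", tol=1e-14)
    beta = polished.x
    # standardized score ~ 0 at the optimum
    scale = np.abs(X.T @ np.exp(X @ beta + offset)) + 1.0
    assert np.max(np.abs(grad(beta)) / scale) < 1e-9
    return beta
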
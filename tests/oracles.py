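"""Independent oracles used by the tests.

The Poisson maximum-likelihood oracle is a generic numerical optimizer
(scipy trust-region Newton with exact gradient and Hessian); it shares no
code with the package's IRLS path.
"""

import numpy as np
from scipy import optimize

from exmort.glm_core import DesignMatrix
from exmort.panel_io import MonthCoord


def poisson_ml_oracle(X, y, offset):
    """Maximize the Poisson log-likelihood with a generic optimizer."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    offset = np.asarray(offset, float)

    def negll(beta):
        eta = X @ beta + offset
        return float(np.sum(np.exp(eta)) - y @ eta)

    def grad(beta):
        mu = np.exp(X @ beta + offset)
        return X.T @ (mu - y)

    def hess(beta):
        mu = np.exp(X @ beta + offset)
        return X.T @ (X * mu[:, None])

    beta0 = np.zeros(X.shape[1])
    res = optimize.minimize(
        negll, beta0, jac=grad, hess=hess, method="trust-exact",
        options={"gtol": 1e-7, "maxiter": 1000},
    )
    # with Hessian scale >> 1, a gradient norm of 1e-3 bounds the
    # coefficient error far below the 1e-6 comparison tolerance
    assert np.linalg.norm(grad(res.x)) < 1e-3
    return res.x


def plain_design(X, y, offset=None):
    """Wrap raw arrays as a DesignMatrix (for non-calendar fixtures)."""
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if offset is None:
        offset = np.zeros(n)
    coords = [MonthCoord(2013, 1).add(i) for i in range(n)]
    return DesignMatrix(
        X=X,
        offset=np.asarray(offset, float),
        y=np.asarray(y),
        coords=coords,
        year_center=2013,
        columns=tuple(f"x{j}" for j in range(p)),
    )
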
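import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, max_examples=50)
settings.load_profile("det")

_LOG2PI = math.log(2.0 * math.pi)


def simulate_pair(rng, n_groups=10, per_group=7, b0=0.0, b1=0.6,
                  sigma_B=0.5, sigma_e=0.3):
    """Draw one (y, x, groups) instance from the random-intercept model."""
    groups = np.repeat(np.arange(n_groups), per_group)
    n = groups.size
    x = rng.normal(0.0, 1.0, n)
    B = rng.normal(0.0, sigma_B, n_groups)
    y = b0 + b1 * x + B[groups] + rng.normal(0.0, sigma_e, n)
    return y, x, groups


def reml_loglik_dense(y, X, Z, lam):
    """Profiled REML log-likelihood by dense matrix algebra.

    Deliberately independent of the package's sufficient-statistic path:
    builds V* = I + lam Z Z' explicitly and uses inv/slogdet.
    Returns (loglik, b1).
    """
    n, p = X.shape
    Vs = np.eye(n) + lam * (Z @ Z.T)
    _, logdetV = np.linalg.slogdet(Vs)
    Vi = np.linalg.inv(Vs)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    s2 = (r @ Vi @ r) / (n - p)
    _, logdetA = np.linalg.slogdet(A)
    ll = -0.5 * ((n - p) * (_LOG2PI + 1.0) + (n - p) * np.log(s2)
                 + logdetV + logdetA)
    return ll, beta[1]


def grid_oracle(y, x, groups, coarse=281, fine=2001):
    """Brute-force REML over a dense variance-ratio grid.

    Coarse log-spaced sweep over [1e-8, 1e6] (plus lam = 0), then a fine
    local grid around the coarse argmax.  Returns (loglik, b1, lam) at
    the grid maximum.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    labels, codes = np.unique(groups, return_inverse=True)
    n = y.size
    X = np.column_stack([np.ones(n), x])
    Z = np.zeros((n, labels.size))
    Z[np.arange(n), codes] = 1.0

    lams = np.concatenate([[0.0], np.logspace(-8, 6, coarse)])
    vals = [reml_loglik_dense(y, X, Z, l) for l in lams]
    lls = np.array([v[0] for v in vals])
    i = int(np.argmax(lls))
    best = (lls[i], vals[i][1], lams[i])
    if 0 < i < len(lams) - 1:
        lo = math.log(lams[i - 1]) if lams[i - 1] > 0 else math.log(1e-10)
        hi = math.log(lams[i + 1])
        for l in np.exp(np.linspace(lo, hi, fine)):
            ll, b1 = reml_loglik_dense(y, X, Z, l)
            if ll > best[0]:
                best = (ll, b1, l)
    return best


def brute_force_qvalues(p, pi0=1.0):
    """Element-wise min-over-tail scan: q_i = pi0 * min over j with
    p_j >= p_i of (m * p_j / rank_j), clipped to [0, 1]."""
    p = np.asarray(p, float)
    m = p.size
    out = np.empty(m)
    sorted_p = np.sort(p)
    for i in range(m):
        candidates = [
            m * pj / (j + 1)
            for j, pj in enumerate(sorted_p)
            if pj >= p[i]
        ]
        out[i] = min(1.0, pi0 * min(candidates))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
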
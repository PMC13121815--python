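"""Independent numerical oracles used by the test suite.

Everything here is deliberately written against the model definition
only — brute-force quadrature and generic numerical optimization —
never by calling the variational code paths it is used to check.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, roots_hermitenorm


def marginal_loglik_ri_quadrature(Y, group_of, design, params, n_nodes=60):
    """Marginal log-likelihood of a 2PL-Ri model by nested Gauss-Hermite.

    Integrates one ability per person and one random intercept per
    item × group on probabilist-Hermite grids.  Exponential in J per
    group, so only usable for J ≤ 2.
    """
    nodes, wts = roots_hermitenorm(n_nodes)
    w = wts / np.sqrt(2.0 * np.pi)
    J = Y.shape[1]
    if J > 2:
        raise ValueError("quadrature oracle only supports J <= 2")
    Bm = params.intercept_prior_mean(design)
    mu_s = params.group_ability_mean(design)
    total = 0.0
    for s in range(design.S):
        members = np.flatnonzero(group_of == s)
        grids = [
            Bm[j, s] + np.sqrt(params.var_intercept[j]) * nodes for j in range(J)
        ]
        acc = 0.0
        if J == 1:
            combos = [((i1,), (grids[0][i1],)) for i1 in range(n_nodes)]
        else:
            combos = [
                ((i1, i2), (grids[0][i1], grids[1][i2]))
                for i1 in range(n_nodes)
                for i2 in range(n_nodes)
            ]
        for idx, bvals in combos:
            weight = np.prod([w[i] for i in idx])
            li = 1.0
            for i in members:
                th = mu_s[s] + nodes
                like = np.ones(n_nodes)
                for j in range(J):
                    pj = expit(params.slope_base[j] * th + bvals[j])
                    like = like * (pj if Y[i, j] > 0.5 else 1.0 - pj)
                li *= like @ w
            acc += weight * li
        total += np.log(acc)
    return total


def ml_2pl_quadrature(Y, n_nodes=41):
    """Marginal-ML 2PL estimates (theta ~ N(0,1)) by direct integration."""
    N, J = Y.shape
    nodes, wts = roots_hermitenorm(n_nodes)
    w = wts / np.sqrt(2.0 * np.pi)

    def nll(x):
        a, b = x[:J], x[J:]
        P = expit(a[None, None, :] * nodes[None, :, None] + b[None, None, :])
        like = np.where(Y[:, None, :] > 0.5, P, 1.0 - P).prod(axis=2) @ w
        return -np.log(np.maximum(like, 1e-300)).sum()

    res = minimize(
        nll,
        np.concatenate([np.ones(J), np.zeros(J)]),
        method="L-BFGS-B",
        options={"maxiter": 3000},
    )
    return res.x[:J], res.x[J:]


def maximize_block(neg_fn, x0, maxiter=4000):
    """Generic per-block numerical maximizer (Nelder-Mead, tight tolerances)."""
    res = minimize(
        neg_fn,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": maxiter},
    )
    return res.x


def truncnorm_moments_quadrature(mu, var):
    """Moments of N(mu, var) on (0, inf) by adaptive quadrature."""
    from scipy.integrate import quad

    sd = np.sqrt(var)
    hi = max(mu + 12 * sd, 12 * sd)

    def kernel(power):
        def f(x):
            return x**power * np.exp(-0.5 * ((x - mu) / sd) ** 2)

        val, _ = quad(f, 0.0, hi, epsabs=1e-14, epsrel=1e-12, limit=200)
        return val

    z = kernel(0)
    m1 = kernel(1) / z
    m2 = kernel(2) / z
    return m1, m2 - m1 * m1
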
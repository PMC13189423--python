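"""Independent brute-force and numerical oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, generic
convex solvers, dense algebra) and never shares code with the package
implementation it checks.
"""

import itertools

import numpy as np


def proximal_gradient_glasso(S, lam, step=None, max_iter=50000, tol=1e-10):
    """Generic proximal-gradient solver of the penalized precision objective.

    Maximizes log det(Theta) - Tr(S Theta) - lam * ||Theta||_1,offdiag by
    ISTA with backtracking; independent of any coordinate-descent code.
    """
    p = S.shape[0]
    theta = np.linalg.inv(S + lam * np.eye(p))
    t = step or 1.0 / np.linalg.norm(S, 2) ** 2

    def smooth(th):
        sign, ld = np.linalg.slogdet(th)
        if sign <= 0:
            return np.inf
        return -ld + np.trace(S @ th)

    def prox(th, t):
        out = np.sign(th) * np.maximum(np.abs(th) - t * lam, 0.0)
        np.fill_diagonal(out, np.diag(th))
        return out

    f = smooth(theta)
    for _ in range(max_iter):
        grad = S - np.linalg.inv(theta)
        tk = t
        while True:
            cand = prox(theta - tk * grad, tk)
            fc = smooth(cand)
            if np.isfinite(fc) and fc <= f + np.sum(grad * (cand - theta)) + np.sum(
                (cand - theta) ** 2
            ) / (2 * tk):
                break
            tk *= 0.5
            if tk < 1e-14:
                cand, fc = theta, f
                break
        if np.abs(cand - theta).max() < tol:
            theta = cand
            break
        theta, f = cand, fc
    return theta


def exhaustive_spanning_trees(n, edges):
    """All spanning trees of a graph as edge-index tuples (tiny n only)."""
    trees = []
    for combo in itertools.combinations(range(len(edges)), n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for ei in combo:
            i, j, _ = edges[ei]
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            trees.append(combo)
    return trees


def brute_silhouette(X, labels):
    """Double-loop silhouette widths with the s(i)=0 degenerate convention."""
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.linalg.norm(np.asarray(X[i]) - np.asarray(X[j]))
    out = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            out[i] = 0.0
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == c])
            for c in set(labels)
            if c != labels[i]
        )
        denom = max(a, b)
        out[i] = 0.0 if denom == 0 else (b - a) / denom
    return out


def censored_poisson_mle_grid(observed, n_censored, a, b, lo=0.01, hi=50.0, tol=1e-4):
    """Vectorized grid maximizer of the censored-Poisson likelihood."""
    from scipy.stats import poisson

    observed = np.asarray(observed, dtype=float)
    lams = np.arange(lo, hi, tol / 2)
    ll = np.zeros_like(lams)
    if observed.size:
        ll += poisson.logpmf(observed[:, None], lams[None, :]).sum(axis=0)
    if n_censored:
        mass = poisson.cdf(b, lams) - poisson.cdf(a - 1, lams)
        ll += n_censored * np.log(np.maximum(mass, 1e-300))
    return float(lams[np.argmax(ll)])


def metropolis_oracle(logpost, x0, prop_chol_upper, n_draws, burn, scale, seed):
    """Preconditioned random-walk Metropolis; returns draws (n_draws x dim)."""
    from scipy.linalg import solve_triangular

    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    lp = logpost(x)
    n = x.size
    draws = np.empty((n_draws, n))
    for i in range(n_draws + burn):
        prop = x + scale * solve_triangular(
            prop_chol_upper, rng.standard_normal(n), lower=False
        )
        lpp = logpost(prop)
        if np.log(rng.uniform()) < lpp - lp:
            x, lp = prop, lpp
        if i >= burn:
            draws[i - burn] = x
    return draws
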
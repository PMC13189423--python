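"""Conditional-dependence graph learning and spectral Laplacian filtering.

A sparse precision matrix over clusters is estimated by L1-penalized
Gaussian maximum likelihood (graphical lasso) on the cluster-level
surrogate series, with the penalty chosen by an extended BIC. The
nonzero pattern defines a graph whose Laplacian, after a low-pass
spectral filter retaining the smoothest fraction ``q`` of graph
frequencies, yields the spatial covariance operator ``Ltilde^2`` used in
the separable spatiotemporal prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg



@dataclass
class EmpiricalCovariance:
    matrix: np.ndarray  # C x C
    n_obs: int  # number of time observations T
    p_vars: int  # number of clusters C


@dataclass
class PrecisionEstimate:
    theta: np.ndarray  # C x C SPD precision
    penalty: float
    edge_set: frozenset[tuple[int, int]]  # (i, j) with i < j

    @property
    def n_edges(self) -> int:
        return len(self.edge_set)


@dataclass
class SpatialOperator:
    """Filtered graph Laplacian and the derived spatial covariance.

    ``covariance = Ltilde @ Ltilde + jitter * I`` where ``Ltilde`` keeps
    the ``ceil(q * C)`` smallest-eigenvalue components of ``L = D - A``.
    """

    adjacency: np.ndarray
    laplacian: np.ndarray
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # columns, orthonormal
    filter_q: float
    filtered_laplacian: np.ndarray
    covariance: np.ndarray
    jitter: float

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


def empirical_covariance(
    surrogate_series: np.ndarray, standardize: bool = True
) -> EmpiricalCovariance:
    """Covariance across clusters of a C x T surrogate series.

    Variables are clusters, observations are time points:
    ``S = Z^T Z / T`` on the column-centered (optionally z-scored)
    T x C data matrix.
    """
    X = np.asarray(surrogate_series, dtype=float).T  # T x C
    T, C = X.shape
    if T < 2:
        raise ValueError("need at least 2 time observations")
    Z = X - X.mean(axis=0)
    if standardize:
        sd = Z.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0).tolist()
            raise ValueError(f"constant series for clusters {bad}; cannot standardize")
        Z = Z / sd
    S = (Z.T @ Z) / T
    return EmpiricalCovariance(matrix=S, n_obs=T, p_vars=C)


def _edge_set(theta: np.ndarray, atol: float = 1e-10) -> frozenset[tuple[int, int]]:
    p = theta.shape[0]
    return frozenset(
        (i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if abs(theta[i, j]) > atol
    )


def _kkt_residual(theta: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Max violation of the stationarity conditions of the penalized problem."""
    G = S - np.linalg.inv(theta)
    p = S.shape[0]
    worst = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                worst = max(worst, abs(G[i, j]))
            elif abs(theta[i, j]) > 1e-12:
                worst = max(worst, abs(G[i, j] + lam * np.sign(theta[i, j])))
            else:
                worst = max(worst, max(0.0, abs(G[i, j]) - lam))
    return worst


def graphical_lasso(
    S: EmpiricalCovariance | np.ndarray,
    penalty: float,
    tol: float = 1e-8,
    max_iter: int = 500,
    theta_init: np.ndarray | None = None,
) -> PrecisionEstimate:
    """L1-penalized precision estimate (diagonal unpenalized).

    Maximizes ``log det(Theta) - Tr(S Theta) - penalty * ||Theta||_1,off``
    over symmetric positive-definite matrices, by block coordinate
    descent on the covariance (each column update is a lasso regression
    solved by inner coordinate descent). Convergence is declared when the
    stationarity (KKT) residual drops below ``tol`` scaled by the mean
    absolute off-diagonal of S; otherwise an error carrying the residual
    is raised.
    """
    Smat = S.matrix if isinstance(S, EmpiricalCovariance) else np.asarray(S, float)
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    Smat = 0.5 * (Smat + Smat.T)
    p = Smat.shape[0]
    eigmin = float(np.linalg.eigvalsh(Smat).min())
    if eigmin < -1e-8:
        raise ValueError(f"covariance not PSD (min eigenvalue {eigmin:.3g})")
    lam = float(penalty)
    if lam == 0:
        theta = np.linalg.inv(Smat + 1e-12 * np.eye(p))
        return PrecisionEstimate(theta=theta, penalty=0.0, edge_set=_edge_set(theta))

    # block coordinate descent (diagonal of W fixed at diag(S) + small ridge
    # when S is singular, so every W11 subproblem stays well posed)
    ridge = 0.0 if eigmin > 1e-10 else 1e-10
    W = Smat + ridge * np.eye(p)
    B = np.zeros((p, p))  # column regression coefficients
    idx_all = [np.array([i for i in range(p) if i != j]) for j in range(p)]
    scale = max(np.abs(Smat - np.diag(np.diag(Smat))).mean(), 1e-12)
    for _ in range(max_iter):
        w_change = 0.0
        for j in range(p):
            idx = idx_all[j]
            W11 = W[np.ix_(idx, idx)]
            s12 = Smat[idx, j]
            beta = B[idx, j].copy()
            for _ in range(200):
                delta = 0.0
                for k in range(p - 1):
                    r = s12[k] - W11[k] @ beta + W11[k, k] * beta[k]
                    new = np.sign(r) * max(abs(r) - lam, 0.0) / W11[k, k]
                    delta = max(delta, abs(new - beta[k]))
                    beta[k] = new
                if delta < 1e-14:
                    break
            B[idx, j] = beta
            w12 = W11 @ beta
            w_change = max(w_change, np.abs(W[idx, j] - w12).max())
            W[idx, j] = w12
            W[j, idx] = w12
        if w_change < 1e-12:
            break

    theta = np.zeros((p, p))
    for j in range(p):
        idx = idx_all[j]
        beta = B[idx, j]
        theta_jj = 1.0 / (W[j, j] - W[idx, j] @ beta)
        theta[j, j] = theta_jj
        theta[idx, j] = -beta * theta_jj
    theta = 0.5 * (theta + theta.T)
    theta[np.abs(theta) < 1e-10] = 0.0
    gap = _kkt_residual(theta, Smat, lam)
    if gap > max(tol, 1e-6) * max(1.0, scale):
        raise RuntimeError(
            f"graphical lasso did not converge: KKT residual {gap:.3g}"
        )
    return PrecisionEstimate(theta=theta, penalty=lam, edge_set=_edge_set(theta))


def gaussian_loglik(theta: np.ndarray, S: np.ndarray, n_obs: int) -> float:
    """Gaussian log-likelihood (T/2)(log det Theta - Tr(S Theta)).

    The additive ``-(T p / 2) log 2 pi`` constant is omitted; it cancels
    across models fit on the same data.
    """
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise np.linalg.LinAlgError("precision estimate is singular")
    return 0.5 * n_obs * (logdet - float(np.trace(S @ theta)))


def ebic(
    theta_hat: PrecisionEstimate,
    S: EmpiricalCovariance | np.ndarray,
    n_obs: int | None = None,
    p_vars: int | None = None,
    gamma: float = 0.5,
) -> float:
    """Extended BIC for graph selection: ``-2 l + 4|E| ln T + 4 gamma ln p``."""
    if isinstance(S, EmpiricalCovariance):
        Smat, T, p = S.matrix, S.n_obs, S.p_vars
    else:
        Smat, T, p = np.asarray(S, float), n_obs, p_vars
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    ll = gaussian_loglik(theta_hat.theta, Smat, T)
    return float(-2.0 * ll + 4.0 * theta_hat.n_edges * np.log(T) + 4.0 * gamma * np.log(p))


def constrained_mle(
    S: np.ndarray, edge_set: frozenset[tuple[int, int]], tol: float = 1e-10,
    max_iter: int = 2000,
) -> np.ndarray:
    """Gaussian MLE of the precision matrix restricted to a given support.

    Maximizes ``log det(Theta) - Tr(S Theta)`` subject to the zero
    pattern implied by the complement of ``edge_set``, by the classical
    modified-regression algorithm for graphical models with known
    structure: the glasso column sweep with no penalty and each column
    regression restricted to the column's neighbors.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    nb = {j: sorted({i for e in edge_set for i in e if j in e} - {j}) for j in range(p)}
    W = S.copy()
    B = {j: np.zeros(len(nb[j])) for j in range(p)}
    for _ in range(max_iter):
        change = 0.0
        for j in range(p):
            others = [i for i in range(p) if i != j]
            if not nb[j]:
                change = max(change, np.abs(W[others, j]).max(initial=0.0))
                W[others, j] = 0.0
                W[j, others] = 0.0
                continue
            Wnn = W[np.ix_(nb[j], nb[j])]
            beta = np.linalg.solve(Wnn, S[nb[j], j])
            B[j] = beta
            w12 = W[np.ix_(others, nb[j])] @ beta
            change = max(change, np.abs(W[others, j] - w12).max())
            W[others, j] = w12
            W[j, others] = w12
        if change < tol:
            break
    theta = np.zeros((p, p))
    for j in range(p):
        resid = W[j, j] - (W[nb[j], j] @ B[j] if nb[j] else 0.0)
        theta[j, j] = 1.0 / resid
        if nb[j]:
            theta[nb[j], j] = -B[j] * theta[j, j]
    return 0.5 * (theta + theta.T)


def default_penalty_path(S: EmpiricalCovariance | np.ndarray, n_points: int = 10) -> np.ndarray:
    """Log-spaced decreasing path from the all-shrinking penalty down to 1% of it."""
    Smat = S.matrix if isinstance(S, EmpiricalCovariance) else np.asarray(S, float)
    off = np.abs(Smat - np.diag(np.diag(Smat)))
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, 0.01 * lam_max, n_points)


def select_graph(
    S: EmpiricalCovariance,
    penalty_path: np.ndarray | None = None,
    gamma: float = 0.5,
    refit: bool = True,
) -> tuple[PrecisionEstimate, "pd.DataFrame"]:
    """Fit a graphical-lasso path and return the EBIC minimizer.

    With ``refit=True`` (default) the criterion's likelihood is evaluated
    at the support-constrained MLE of each candidate edge set, so model
    comparison reflects the support alone and not the L1 shrinkage bias
    of the path estimate. Ties in EBIC resolve to the sparser model
    (larger penalty, since the path is traversed in decreasing order).
    """
    import pandas as pd

    if penalty_path is None:
        penalty_path = default_penalty_path(S)
    penalty_path = np.asarray(penalty_path, dtype=float)
    if penalty_path.size == 0:
        raise ValueError("penalty path is empty")
    penalty_path = np.sort(penalty_path)[::-1]

    rows, fits = [], []
    errors = []
    score_cache: dict[frozenset, float] = {}
    for lam in penalty_path:
        try:
            est = graphical_lasso(S, lam)
        except Exception as exc:
            errors.append((lam, exc))
            continue
        if est.edge_set not in score_cache:
            scored = (
                PrecisionEstimate(
                    theta=constrained_mle(
                        S.matrix if isinstance(S, EmpiricalCovariance) else S,
                        est.edge_set,
                    ),
                    penalty=est.penalty,
                    edge_set=est.edge_set,
                )
                if refit
                else est
            )
            score_cache[est.edge_set] = ebic(scored, S, gamma=gamma)
        fits.append(est)
        rows.append(
            {
                "penalty": lam,
                "n_edges": est.n_edges,
                "ebic": score_cache[est.edge_set],
            }
        )
    if not fits:
        raise RuntimeError(f"all {len(errors)} path fits failed; first: {errors[0][1]}")
    diag = pd.DataFrame(rows)
    best = int(diag["ebic"].idxmin())  # first minimum = sparsest on ties
    return fits[best], diag


def low_pass_filter(
    eigenvalues: np.ndarray, q: float, descending: bool = False
) -> np.ndarray:
    """Keep the fraction ``q`` of eigenvalues (smallest by default).

    Indexing is 1-based inclusive: component ``i`` is kept iff
    ``i <= ceil(q * C)``, so ``q = 1`` keeps everything and any ``q > 0``
    retains the zero eigenvalue. ``descending=True`` keeps the largest
    fraction instead (the literal alternative reading).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    C = lam.size
    keep = int(np.ceil(q * C))
    order = np.argsort(lam)
    if descending:
        order = order[::-1]
    out = np.zeros_like(lam)
    out[order[:keep]] = lam[order[:keep]]
    return out


def build_spatial_operator(
    theta_hat: PrecisionEstimate | np.ndarray,
    q: float = 0.5,
    jitter: float | None = None,
    descending: bool = False,
    filter_fn: Callable[[np.ndarray, float], np.ndarray] | None = None,
) -> SpatialOperator:
    """Spatial covariance operator from a precision estimate's graph.

    The adjacency is the nonzero off-diagonal pattern of ``theta_hat``;
    ``L = D - A`` is eigendecomposed, a low-pass filter zeroes the
    rough (large-eigenvalue) graph frequencies, and the covariance is the
    matrix square of the filtered Laplacian plus a diagonal jitter that
    keeps it invertible. Default jitter: ``1e-6 * mean(diag(Lt^2) + 1)``.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    if isinstance(theta_hat, PrecisionEstimate):
        theta = theta_hat.theta
    else:
        theta = np.asarray(theta_hat, dtype=float)
    C = theta.shape[0]
    A = (np.abs(theta) > 1e-10).astype(float)
    np.fill_diagonal(A, 0.0)
    if A.sum() == 0:
        warnings.warn("empty graph: Laplacian is zero, covariance is jitter * I", RuntimeWarning)
    L = np.diag(A.sum(axis=1)) - A
    lam, U = np.linalg.eigh(L)  # ascending
    lam = np.maximum(lam, 0.0)  # clip numerical negatives of the PSD Laplacian
    if filter_fn is not None:
        lam_f = filter_fn(lam, q)
    else:
        lam_f = low_pass_filter(lam, q, descending=descending)
    Lt = (U * lam_f) @ U.T
    Lt = 0.5 * (Lt + Lt.T)
    cov0 = Lt @ Lt
    cov0 = 0.5 * (cov0 + cov0.T)
    if jitter is None:
        jitter = 1e-6 * float(np.mean(np.diag(cov0) + 1.0))
    cov = cov0 + jitter * np.eye(C)
    return SpatialOperator(
        adjacency=A,
        laplacian=L,
        eigenvalues=lam,
        eigenvectors=U,
        filter_q=float(q),
        filtered_laplacian=Lt,
        covariance=cov,
        jitter=float(jitter),
    )


def dirichlet_energy(signal: np.ndarray, laplacian: np.ndarray) -> float:
    """Graph roughness ``f^T L f`` of a signal over the graph (>= 0)."""
    f = np.asarray(signal, dtype=float)
    if f.shape[0] != laplacian.shape[0]:
        raise ValueError("signal length does not match Laplacian dimension")
    return float(f @ laplacian @ f)
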
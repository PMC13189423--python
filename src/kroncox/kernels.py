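"""Temporal kernels, Gram matrices and the separable Kronecker covariance.

The workhorse is the locally periodic kernel — a damped-periodic factor
times an RBF factor evaluated on the Euclidean distance between (time,
surrogate covariate) feature vectors — which captures quasi-annual
dynamics whose amplitude decays with input distance. Banded,
distributed-lag and cross-covariate interaction variants act on
seasonal-decomposition residuals. Kernels combine additively (uniform
convex weights) or multiplicatively (elementwise Schur product, which
preserves positive semidefiniteness). The spatiotemporal covariance is
the Kronecker product K (x) Lt2 with the cluster index varying fastest,
handled in factored form so large fields are never materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import linalg

from .spatialgraph import SpatialOperator


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of the locally periodic kernel family.

    sigma2: marginal variance (diagonal of the Gram matrix).
    rho_p: periodic length-scale — smaller values sharpen seasonal peaks.
    rho_rbf: squared-exponential damping scale (in squared input distance).
    period: months per cycle (12 for annual seasonality).
    periodic_factor: exponent multiplier c in exp(-c sin^2(.)/rho_p);
        1 by default, 2 selects the alternative convention.
    band_p: half-width of the banded kernel's indicator.
    lag_set: admissible |t1 - t2| lags for distributed-lag kernels.
    """

    sigma2: float = 1.0
    rho_p: float = 1.0
    rho_rbf: float = 10.0
    period: float = 12.0
    periodic_factor: int = 1
    band_p: int = 3
    lag_set: tuple[int, ...] = (0, 1, 12)

    def __post_init__(self):
        for name in ("sigma2", "rho_p", "rho_rbf", "period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.periodic_factor not in (1, 2):
            raise ValueError("periodic_factor must be 1 or 2")
        if self.band_p < 0:
            raise ValueError("band_p must be >= 0")
        if any(d < 0 for d in self.lag_set):
            raise ValueError("lag_set entries must be >= 0")


@dataclass
class GramMatrix:
    matrix: np.ndarray  # T x T symmetric
    kernel_spec: dict = field(default_factory=dict)

    @property
    def T(self) -> int:
        return self.matrix.shape[0]

    def jittered(self, rel: float = 1e-8) -> np.ndarray:
        """PSD-repaired, jittered matrix fit for use as a covariance.

        Band- and lag-truncated kernels are indefinite in general (the
        truncation indicator is not PSD), so negative eigenvalues are
        clipped to zero before the relative diagonal jitter is added.
        """
        K = psd_repair(self.matrix)
        d = float(np.mean(np.diag(K)))
        return K + rel * max(d, 1.0) * np.eye(self.T)


def psd_repair(K: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Clip negative eigenvalues to zero (no-op for PSD input)."""
    K = 0.5 * (K + K.T)
    w = np.linalg.eigvalsh(K)
    if w.min() >= -tol:
        return K
    w, V = np.linalg.eigh(K)
    out = (V * np.maximum(w, 0.0)) @ V.T
    return 0.5 * (out + out.T)


def _lp_from_distance(delta: np.ndarray | float, params: KernelParams) -> np.ndarray | float:
    d = np.asarray(delta, dtype=float)
    periodic = np.exp(
        -params.periodic_factor
        * np.sin(np.pi * d / params.period) ** 2
        / params.rho_p
    )
    rbf = np.exp(-(d**2) / (2.0 * params.rho_rbf))
    return params.sigma2 * periodic * rbf


def k_locally_periodic(u, v, params: KernelParams) -> float:
    """Locally periodic kernel on the Euclidean distance between inputs.

    ``sigma^2 exp(-c sin^2(pi ||u-v|| / period) / rho_p)
    exp(-||u-v||^2 / (2 rho_rbf))``; equals ``sigma^2`` at u = v.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if u.shape != v.shape:
        raise ValueError("inputs must have equal length")
    return float(_lp_from_distance(np.linalg.norm(u - v), params))


def standardize_features(F: np.ndarray) -> np.ndarray:
    """Column z-scores (constant columns map to zero)."""
    F = np.asarray(F, dtype=float)
    mu = F.mean(axis=0)
    sd = F.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (F - mu) / sd


def gram_from_inputs(
    inputs: np.ndarray, params: KernelParams, standardize: bool = True
) -> GramMatrix:
    """Gram matrix of the locally periodic kernel on per-time feature rows.

    ``inputs`` is T x f — e.g. ``[t]`` alone for a purely temporal
    kernel, or ``[t, S~_{.,t}]`` rows combining time with cluster-level
    surrogate covariates. Features are standardized column-wise before
    distances are taken so no covariate dominates by scale.
    """
    F = np.atleast_2d(np.asarray(inputs, dtype=float))
    if F.shape[0] == 1 and F.shape[1] > 1:
        F = F.T
    if np.any(~np.isfinite(F)):
        raise ValueError("inputs contain NaN or infinite features")
    if F.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    Z = standardize_features(F) if standardize else F
    sq = (Z**2).sum(axis=1)
    d2 = np.maximum(0.0, sq[:, None] + sq[None, :] - 2.0 * Z @ Z.T)
    K = _lp_from_distance(np.sqrt(d2), params)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, params.sigma2)
    return GramMatrix(matrix=K, kernel_spec={"kind": "locally_periodic", "params": params})


def time_gram(T: int, params: KernelParams) -> GramMatrix:
    """Purely temporal Gram matrix on raw (unstandardized) time indices.

    Raw months keep the 12-month period physically meaningful.
    """
    t = np.arange(T, dtype=float)
    d = np.abs(t[:, None] - t[None, :])
    K = _lp_from_distance(d, params)
    g = GramMatrix(matrix=0.5 * (K + K.T), kernel_spec={"kind": "time_lp", "params": params})
    return g


def k_banded(residuals: np.ndarray, t1: int, t2: int, params: KernelParams) -> float:
    """Locally periodic kernel on residual values, zeroed outside the band.

    ``k(R_t1, R_t2) 1{|t1 - t2| <= p}`` — captures short-memory residual
    autocorrelation the smooth kernels miss.
    """
    if abs(t1 - t2) > params.band_p:
        return 0.0
    return k_locally_periodic(residuals[t1], residuals[t2], params)


def k_distributed_lag(residuals: np.ndarray, t1: int, t2: int, params: KernelParams) -> float:
    """Banded kernel restricted to a designed set of lags ``|t1 - t2| in D``."""
    if not params.lag_set:
        raise ValueError("lag_set must be nonempty")
    if abs(t1 - t2) not in params.lag_set:
        return 0.0
    return k_locally_periodic(residuals[t1], residuals[t2], params)


def k_interaction(
    residuals_i: np.ndarray,
    residuals_j: np.ndarray,
    t1: int,
    t2: int,
    params: KernelParams,
) -> float:
    """Symmetrized cross-covariate lag kernel.

    The directional evaluation ``k(R_{i,t1}, R_{j,t2})`` is not symmetric
    in (t1, t2); the average of the two directions is returned so the
    assembled Gram matrix is a valid covariance.
    """
    if residuals_i is residuals_j or np.array_equal(residuals_i, residuals_j):
        return k_distributed_lag(residuals_i, t1, t2, params)
    if abs(t1 - t2) not in params.lag_set:
        return 0.0
    fwd = k_locally_periodic(residuals_i[t1], residuals_j[t2], params)
    bwd = k_locally_periodic(residuals_j[t1], residuals_i[t2], params)
    return 0.5 * (fwd + bwd)


def _banded_gram(residuals: np.ndarray, params: KernelParams, lag_indicator) -> np.ndarray:
    r = np.asarray(residuals, dtype=float)
    T = r.shape[0]
    d = np.abs(r[:, None] - r[None, :]) if r.ndim == 1 else np.linalg.norm(
        r[:, None, :] - r[None, :, :], axis=-1
    )
    K = np.asarray(_lp_from_distance(d, params))
    lag = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
    K = K * lag_indicator(lag)
    return 0.5 * (K + K.T)


def banded_gram(residuals: np.ndarray, params: KernelParams) -> GramMatrix:
    K = _banded_gram(residuals, params, lambda lag: (lag <= params.band_p).astype(float))
    return GramMatrix(matrix=K, kernel_spec={"kind": "banded", "params": params})


def distributed_lag_gram(residuals: np.ndarray, params: KernelParams) -> GramMatrix:
    lags = np.array(sorted(set(params.lag_set)))
    K = _banded_gram(residuals, params, lambda lag: np.isin(lag, lags).astype(float))
    return GramMatrix(matrix=K, kernel_spec={"kind": "distributed_lag", "params": params})


def interaction_gram(
    residuals_i: np.ndarray, residuals_j: np.ndarray, params: KernelParams
) -> GramMatrix:
    T = len(residuals_i)
    K = np.zeros((T, T))
    for t1 in range(T):
        for t2 in range(t1, T):
            K[t1, t2] = K[t2, t1] = k_interaction(residuals_i, residuals_j, t1, t2, params)
    return GramMatrix(matrix=K, kernel_spec={"kind": "interaction", "params": params})


def mix_kernels(
    components: Sequence[GramMatrix],
    mode: Literal["additive", "multiplicative"] = "additive",
    weights: Sequence[float] | None = None,
) -> GramMatrix:
    """Combine Gram matrices: weighted sum or elementwise product.

    Additive default weights are uniform convex (1/J each); the
    multiplicative default is 1 each. Elementwise products of PSD Gram
    matrices are PSD by the Schur product theorem.
    """
    if not components:
        raise ValueError("need at least one component")
    T = components[0].T
    if any(k.T != T for k in components):
        raise ValueError("component dimension mismatch")
    J = len(components)
    if mode == "additive":
        w = np.full(J, 1.0 / J) if weights is None else np.asarray(weights, float)
        K = sum(wj * k.matrix for wj, k in zip(w, components))
    elif mode == "multiplicative":
        w = np.ones(J) if weights is None else np.asarray(weights, float)
        K = np.ones((T, T))
        for wj, k in zip(w, components):
            K = K * (wj * k.matrix)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    K = 0.5 * (K + K.T)
    return GramMatrix(
        matrix=K,
        kernel_spec={
            "kind": "mixture",
            "mode": mode,
            "weights": list(map(float, w)),
            "components": [k.kernel_spec for k in components],
        },
    )


DENSE_CAP = 5000  # never materialize the full covariance above this C*T


@dataclass
class SpatioTemporalCovariance:
    """Separable covariance ``Sigma = K (x) Lt2`` held in factored form.

    The vec ordering has the cluster index varying fastest:
    ``Sigma[(t1, c1), (t2, c2)] = K[t1, t2] * Lt2[c1, c2]`` where the
    flat index is ``t * C + c``. Solves, log-determinants and sampling
    use the factor eigendecompositions, never the dense product, unless
    the field is small enough to spot-check densely.
    """

    temporal: np.ndarray  # T x T (jittered Gram)
    spatial: np.ndarray  # C x C (jittered operator covariance)

    _eigK: tuple[np.ndarray, np.ndarray] | None = None
    _eigL: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        self.temporal = np.asarray(self.temporal, dtype=float)
        self.spatial = np.asarray(self.spatial, dtype=float)

    @property
    def T(self) -> int:
        return self.temporal.shape[0]

    @property
    def C(self) -> int:
        return self.spatial.shape[0]

    @property
    def dim(self) -> int:
        return self.T * self.C

    def _eigs(self):
        if self._eigK is None:
            wk, Vk = np.linalg.eigh(self.temporal)
            wl, Vl = np.linalg.eigh(self.spatial)
            if wk.min() <= 0 or wl.min() <= 0:
                raise np.linalg.LinAlgError(
                    "covariance factors are not positive definite after jitter"
                )
            self._eigK = (wk, Vk)
            self._eigL = (wl, Vl)
        return self._eigK, self._eigL

    def entry(self, t1: int, c1: int, t2: int, c2: int) -> float:
        return float(self.temporal[t1, t2] * self.spatial[c1, c2])

    def dense(self) -> np.ndarray:
        if self.dim > DENSE_CAP:
            raise ValueError(f"refusing to materialize {self.dim}x{self.dim} covariance")
        return np.kron(self.temporal, self.spatial)

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """(K (x) L) v via vec(L V K^T) with V = unvec(v), cluster-fastest."""
        V = np.asarray(v, dtype=float).reshape(self.T, self.C).T  # C x T
        return (self.spatial @ V @ self.temporal.T).T.reshape(-1)

    def solve(self, v: np.ndarray) -> np.ndarray:
        (wk, Vk), (wl, Vl) = self._eigs()
        V = np.asarray(v, dtype=float).reshape(self.T, self.C).T  # C x T
        M = Vl.T @ V @ Vk  # rotate into the eigenbasis
        M = M / np.outer(wl, wk)
        out = Vl @ M @ Vk.T
        return out.T.reshape(-1)

    def logdet(self) -> float:
        (wk, _), (wl, _) = self._eigs()
        return float(self.C * np.sum(np.log(wk)) + self.T * np.sum(np.log(wl)))

    def precision_dense(self) -> np.ndarray:
        if self.dim > DENSE_CAP:
            raise ValueError("field too large for a dense precision")
        return np.kron(np.linalg.inv(self.temporal), np.linalg.inv(self.spatial))

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw fields F ~ N(0, K (x) L) via the factor Cholesky identity."""
        Lk = np.linalg.cholesky(self.temporal)
        Ll = np.linalg.cholesky(self.spatial)
        Z = rng.standard_normal((size, self.C, self.T))
        out = np.einsum("ca,sab,tb->sct", Ll, Z, Lk)  # Ll Z Lk^T per draw
        return out.transpose(0, 2, 1).reshape(size, -1)  # cluster fastest


def kron_covariance(
    K: GramMatrix | np.ndarray,
    spatial: SpatialOperator | np.ndarray,
    temporal_jitter: float = 1e-8,
) -> SpatioTemporalCovariance:
    """Assemble the separable covariance from temporal and spatial factors.

    The Gram matrix receives a relative diagonal jitter before use as a
    covariance factor; the spatial operator's covariance is already
    jittered at construction.
    """
    if isinstance(K, GramMatrix):
        Kmat = K.jittered(temporal_jitter)
    else:
        Kmat = np.asarray(K, dtype=float)
    Smat = spatial.covariance if isinstance(spatial, SpatialOperator) else np.asarray(spatial, float)
    cov = SpatioTemporalCovariance(temporal=Kmat, spatial=Smat)
    cov._eigs()  # validate positive definiteness eagerly
    return cov
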
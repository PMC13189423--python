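"""Declarative model specifications for the Poisson count families.

Five proposed models share a Poisson likelihood, cluster and
month-of-year fixed effects, and a latent Gaussian field with the
separable Kronecker prior; they differ only in the temporal kernel:

    M1  time-only locally periodic kernel
    M2  covariate locally periodic kernel ([t, surrogate] features)
    M3  multiplicative mixture of the two
    M4  additive mixture of the two
    M5  additive mixture of banded, distributed-lag and interaction
        residual kernels plus the time kernel

Reference models: M1R iid-normal cluster random effects (Poisson GLMM),
M2R a Besag-York-Mollie field (ICAR + iid heterogeneity), M3R an LGCP
with a single shared temporal GP and cluster intercepts only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from . import kernels as tk
from .kernels import GramMatrix, KernelParams, kron_covariance
from .spatialgraph import SpatialOperator
from .surrogates import ClusterPanel, decompose_panel

MODEL_NAMES = ("M1", "M2", "M3", "M4", "M5", "M1R", "M2R", "M3R")

FIXED_EFFECT_VARIANCE = 1000.0  # vague N(0, 1000) prior on alpha and beta
REFERENCE_MONTH = 12  # December omitted -> 11 free month effects


@dataclass
class FixedEffectsDesign:
    """Cluster one-hot plus month-of-year dummies (reference month dropped)."""

    matrix: np.ndarray  # (C*T) x (C + 11), rows ordered cluster-fastest
    cluster_cols: list[str]
    month_cols: list[str]

    @property
    def n_effects(self) -> int:
        return self.matrix.shape[1]

    @property
    def columns(self) -> list[str]:
        return self.cluster_cols + self.month_cols


def build_design(C: int, time_index, include_months: bool = True) -> FixedEffectsDesign:
    """Fixed-effects design over all (c, t) cells, cluster index fastest.

    Row for cell (c, t) has the cluster-c indicator set and, unless the
    calendar month of t is the reference month, that month's indicator.
    ``include_months=False`` gives cluster intercepts only (the shared
    time-GP reference model carries seasonality in its kernel instead).
    """
    import pandas as pd

    if C < 1:
        raise ValueError("C must be >= 1")
    months = np.asarray(pd.PeriodIndex(time_index, freq="M").month)
    T = months.size
    free_months = [m for m in range(1, 13) if m != REFERENCE_MONTH] if include_months else []
    X = np.zeros((C * T, C + len(free_months)))
    for t in range(T):
        for c in range(C):
            row = t * C + c
            X[row, c] = 1.0
            m = months[t]
            if free_months and m != REFERENCE_MONTH:
                X[row, C + free_months.index(m)] = 1.0
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design is rank deficient")
    return FixedEffectsDesign(
        matrix=X,
        cluster_cols=[f"alpha_{c + 1}" for c in range(C)],
        month_cols=[f"beta_m{m}" for m in free_months],
    )


@dataclass
class IcarStructure:
    """Intrinsic CAR structure: singular precision tau (D - A), sum-to-zero."""

    adjacency: np.ndarray

    def precision(self, tau: float = 1.0) -> np.ndarray:
        A = self.adjacency
        return tau * (np.diag(A.sum(axis=1)) - A)


@dataclass
class ModelSpec:
    """A validated, serializable model specification."""

    name: str
    n_clusters: int
    time_index: object  # pd.PeriodIndex
    latent: Literal["kron_gp", "iid", "bym", "time_gp"]
    kernel_params: KernelParams = field(default_factory=KernelParams)
    mixture_mode: str | None = None
    spatial_operator: SpatialOperator | None = None
    icar: IcarStructure | None = None
    tau: float = 1.0  # iid / BYM heterogeneity precision
    tau_icar: float = 1.0
    fixed_effect_variance: float = FIXED_EFFECT_VARIANCE
    likelihood: Literal["poisson", "negative_binomial"] = "poisson"

    # negative-binomial extension hook: overdispersion with log-gamma prior;
    # not exercised by the estimation routines shipped here.
    nb_overdispersion: float | None = None

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {self.name!r}")
        if self.latent in ("kron_gp",) and self.spatial_operator is None:
            raise ValueError(f"{self.name} needs a spatial operator")
        if self.latent == "bym" and self.icar is None:
            raise ValueError("BYM model needs an ICAR adjacency")

    @property
    def T(self) -> int:
        return len(self.time_index)

    @property
    def design(self) -> FixedEffectsDesign:
        return build_design(
            self.n_clusters, self.time_index, include_months=self.name != "M3R"
        )

    @property
    def latent_dim(self) -> int:
        """Dimension of the latent field F (before fixed effects)."""
        if self.latent == "time_gp":
            return self.T
        if self.latent in ("iid",):
            return self.n_clusters
        if self.latent == "bym":
            return 2 * self.n_clusters  # phi (ICAR) then iid component
        return self.n_clusters * self.T

    def latent_map(self) -> np.ndarray:
        """Z mapping the latent vector to the (c, t) cells (cluster fastest)."""
        C, T = self.n_clusters, self.T
        n_cells = C * T
        if self.latent == "kron_gp":
            return np.eye(n_cells)
        Z = np.zeros((n_cells, self.latent_dim))
        for t in range(T):
            for c in range(C):
                row = t * C + c
                if self.latent == "time_gp":
                    Z[row, t] = 1.0
                elif self.latent == "iid":
                    Z[row, c] = 1.0
                elif self.latent == "bym":
                    Z[row, c] = 1.0
                    Z[row, C + c] = 1.0
        return Z

    def temporal_gram(self, panel: ClusterPanel | None = None,
                      params: KernelParams | None = None) -> GramMatrix:
        """The model family's temporal Gram matrix at given hyperparameters."""
        p = params or self.kernel_params
        T = self.T
        if self.name in ("M1", "M3", "M4", "M5", "M3R"):
            Kt = tk.time_gram(T, p)
        if self.name in ("M2", "M3", "M4", "M5"):
            if panel is None:
                raise ValueError(f"{self.name} needs the cluster panel for covariates")
            feats = np.column_stack(
                [np.arange(T, dtype=float)]
                + [panel.covariates[c, :, i] for c in range(panel.n_clusters)
                   for i in range(panel.covariates.shape[2])]
            )
            Kx = tk.gram_from_inputs(feats, p)
        if self.name in ("M1", "M3R"):
            return Kt
        if self.name == "M2":
            return Kx
        if self.name == "M3":
            return tk.mix_kernels([Kt, Kx], mode="multiplicative")
        if self.name == "M4":
            return tk.mix_kernels([Kt, Kx], mode="additive")
        if self.name == "M5":
            R = decompose_panel(panel.covariates)
            comps: list[GramMatrix] = [Kt]
            d = R.shape[2]
            for c in range(panel.n_clusters):
                for i in range(d):
                    comps.append(tk.banded_gram(R[c, :, i], p))
                    comps.append(tk.distributed_lag_gram(R[c, :, i], p))
                for i in range(d):
                    for j in range(i + 1, d):
                        comps.append(tk.interaction_gram(R[c, :, i], R[c, :, j], p))
            return tk.mix_kernels(comps, mode="additive")
        raise ValueError(f"{self.name} has no temporal Gram matrix")

    def latent_prior_covariance(
        self, panel: ClusterPanel | None = None, params: KernelParams | None = None
    ) -> np.ndarray:
        """Dense prior covariance of the latent vector F (jittered, SPD)."""
        if self.latent == "kron_gp":
            cov = kron_covariance(self.temporal_gram(panel, params), self.spatial_operator)
            return cov.dense()
        if self.latent == "time_gp":
            return self.temporal_gram(panel, params).jittered()
        if self.latent == "iid":
            return np.eye(self.n_clusters) / self.tau
        if self.latent == "bym":
            C = self.n_clusters
            Q_icar = self.icar.precision(self.tau_icar)
            # sum-to-zero ICAR: pseudo-inverse covariance on the constraint space
            cov_icar = np.linalg.pinv(Q_icar, hermitian=True)
            jit = 1e-6 * (np.trace(cov_icar) / C + 1.0)
            out = np.zeros((2 * C, 2 * C))
            out[:C, :C] = cov_icar + jit * np.eye(C)
            out[C:, C:] = np.eye(C) / self.tau
            return out
        raise ValueError(f"unknown latent {self.latent!r}")

    def latent_prior_precision(
        self, panel: ClusterPanel | None = None, params: KernelParams | None = None
    ) -> np.ndarray:
        return np.linalg.inv(self.latent_prior_covariance(panel, params))

    def latent_prior_cholesky(
        self, panel: ClusterPanel | None = None, params: KernelParams | None = None
    ) -> np.ndarray:
        """Lower Cholesky factor of the latent prior covariance.

        For the Kronecker prior the factor is assembled as
        ``chol(K) (x) chol(S)`` — numerically stable even when the
        filtered spatial operator is nearly singular, since each factor
        is well conditioned on its own.
        """
        if self.latent == "kron_gp":
            from .kernels import kron_covariance

            cov = kron_covariance(self.temporal_gram(panel, params), self.spatial_operator)
            Lk = np.linalg.cholesky(cov.temporal)
            Ls = np.linalg.cholesky(cov.spatial)
            return np.kron(Lk, Ls)
        return np.linalg.cholesky(self.latent_prior_covariance(panel, params))

    def to_dict(self) -> dict:
        import pandas as pd

        return {
            "name": self.name,
            "n_clusters": self.n_clusters,
            "time_index": [str(p) for p in pd.PeriodIndex(self.time_index, freq="M")],
            "latent": self.latent,
            "kernel_params": asdict(self.kernel_params),
            "mixture_mode": self.mixture_mode,
            "tau": self.tau,
            "tau_icar": self.tau_icar,
            "fixed_effect_variance": self.fixed_effect_variance,
            "likelihood": self.likelihood,
            "nb_overdispersion": self.nb_overdispersion,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def spec_from_dict(d: dict, spatial_operator=None, icar=None) -> ModelSpec:
    import pandas as pd

    kp = d.get("kernel_params", {})
    if isinstance(kp, dict):
        kp = dict(kp)
        if "lag_set" in kp:
            kp["lag_set"] = tuple(kp["lag_set"])
        kp = KernelParams(**kp)
    return ModelSpec(
        name=d["name"],
        n_clusters=d["n_clusters"],
        time_index=pd.PeriodIndex(d["time_index"], freq="M"),
        latent=d["latent"],
        kernel_params=kp,
        mixture_mode=d.get("mixture_mode"),
        spatial_operator=spatial_operator,
        icar=icar,
        tau=d.get("tau", 1.0),
        tau_icar=d.get("tau_icar", 1.0),
        fixed_effect_variance=d.get("fixed_effect_variance", FIXED_EFFECT_VARIANCE),
        likelihood=d.get("likelihood", "poisson"),
        nb_overdispersion=d.get("nb_overdispersion"),
    )


_LATENT_FOR = {
    "M1": "kron_gp", "M2": "kron_gp", "M3": "kron_gp", "M4": "kron_gp",
    "M5": "kron_gp", "M1R": "iid", "M2R": "bym", "M3R": "time_gp",
}
_MIXTURE_FOR = {"M3": "multiplicative", "M4": "additive", "M5": "additive"}


def specify_model(
    name: str,
    panel: ClusterPanel,
    spatial_operator: SpatialOperator | None = None,
    kernel_params: KernelParams | None = None,
    icar_adjacency: np.ndarray | None = None,
    **kwargs,
) -> ModelSpec:
    """Build a validated spec for one of the model family names.

    Proposed models need ``spatial_operator``; M2R needs an adjacency for
    its ICAR component (the learned graph's adjacency is the natural
    choice). M1R's hyperparameter log(tau) carries a vague log-gamma
    prior Gamma(1, 1e-5); M3R shares one temporal GP across clusters.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model name {name!r}; choose from {MODEL_NAMES}")
    latent = _LATENT_FOR[name]
    icar = None
    if latent == "bym":
        if icar_adjacency is None:
            if spatial_operator is not None:
                icar_adjacency = spatial_operator.adjacency
            else:
                raise ValueError("M2R needs an ICAR adjacency")
        icar = IcarStructure(adjacency=np.asarray(icar_adjacency, float))
    return ModelSpec(
        name=name,
        n_clusters=panel.n_clusters,
        time_index=panel.time_index,
        latent=latent,
        kernel_params=kernel_params or KernelParams(),
        mixture_mode=_MIXTURE_FOR.get(name),
        spatial_operator=spatial_operator if latent == "kron_gp" else None,
        icar=icar,
        **kwargs,
    )


# Vague log-gamma hyperprior on log(tau) for the iid reference model.
LOG_TAU_PRIOR_SHAPE = 1.0
LOG_TAU_PRIOR_RATE = 0.00001


def log_tau_log_prior(log_tau: float) -> float:
    """log-density (up to a constant) of the vague log-gamma prior on log tau."""
    return LOG_TAU_PRIOR_SHAPE * log_tau - LOG_TAU_PRIOR_RATE * np.exp(log_tau)
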
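"""Deterministic approximate Bayesian inference for the latent Gaussian models.

Estimation follows the nested-Laplace recipe for latent Gaussian Poisson
models: for each hyperparameter configuration the joint latent vector
(latent field plus fixed effects) is optimized by Newton-Raphson with
step halving, giving a Gaussian approximation N(mu, Q^{-1}) at the
conditional mode; the Laplace evidence at each configuration weights a
Latin-hypercube grid of hyperparameters; marginal posteriors of every
scalar effect are the evidence-weighted Gaussian mixtures across grid
points. Predictive distributions, WAIC and DIC come from seeded draws
of that mixture. Only the Gaussian-approximation marginals are computed;
the full and simplified Laplace refinements are an extension point.

Numerically the optimization runs in whitened coordinates v with
u = L v for the prior covariance Cholesky factor L, so the prior
precision is the identity no matter how ill-conditioned the filtered
spatial operator makes the prior. The Laplace evidence is invariant
under this linear change of variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import gammaln
from scipy.stats import qmc

from .kernels import KernelParams
from .models import ModelSpec, log_tau_log_prior
from .surrogates import ClusterPanel

GRAD_TOL = 1e-8
MAX_NEWTON_ITER = 100
DEFAULT_DRAWS = 4000


class NonConvergenceError(RuntimeError):
    def __init__(self, msg: str, trace: list[float]):
        super().__init__(msg)
        self.trace = trace


@dataclass
class GaussianApprox:
    """Gaussian approximation at the conditional mode of (F, alpha, beta).

    Held in whitened coordinates: the posterior of v = L^{-1} u is
    N(v_mode, H^{-1}) with H = I + (Z L)' W (Z L); in the original
    coordinates the mode is ``mode = L v_mode`` and the covariance is
    ``L H^{-1} L'``. ``log_det_q`` refers to the precision of u.
    """

    mode: np.ndarray  # length n, original coordinates
    v_mode: np.ndarray = field(repr=False, default=None)
    transform: np.ndarray = field(repr=False, default=None)  # L, lower
    chol_h: np.ndarray = field(repr=False, default=None)  # upper, H = U'U
    log_det_h: float = 0.0
    log_det_transform: float = 0.0  # log |det L|
    converged: bool = False
    iterations: int = 0
    n_latent: int = 0

    @property
    def n(self) -> int:
        return self.mode.size

    @property
    def log_det_q(self) -> float:
        """log det of the posterior precision in original coordinates."""
        return self.log_det_h - 2.0 * self.log_det_transform

    def covariance(self) -> np.ndarray:
        Sv = cho_solve((self.chol_h, False), np.eye(self.n))
        return self.transform @ Sv @ self.transform.T

    def precision(self) -> np.ndarray:
        """Posterior precision in original coordinates (may be extreme)."""
        Linv = solve_triangular(self.transform, np.eye(self.n), lower=True)
        H = self.chol_h.T @ self.chol_h
        return Linv.T @ H @ Linv

    def marginal_sd(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.covariance()), 0.0))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draws from N(mode, L H^{-1} L') via back-substitution."""
        z = rng.standard_normal((self.n, size))
        v = self.v_mode[:, None] + solve_triangular(self.chol_h, z, lower=False)
        return self.transform @ v


@dataclass
class HyperGrid:
    """Latin-hypercube design over log-scaled hyperparameter intervals."""

    names: list[str]
    points: np.ndarray  # K x d, natural scale
    bounds: dict[str, tuple[float, float]]
    seed: int

    @property
    def K(self) -> int:
        return self.points.shape[0]

    def as_dicts(self) -> list[dict[str, float]]:
        return [dict(zip(self.names, row)) for row in self.points]


def lhs_grid(
    bounds: dict[str, tuple[float, float]], n_points: int, seed: int
) -> HyperGrid:
    """Latin hypercube over per-parameter log-scale intervals.

    Each axis is split into ``n_points`` equal strata on the log scale
    with exactly one point per stratum; the design is reproducible from
    the seed.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    names = list(bounds)
    for name, (lo, hi) in bounds.items():
        if not (0 < lo <= hi):
            raise ValueError(f"bad interval for {name}: ({lo}, {hi})")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n_points)
    log_lo = np.log([bounds[n][0] for n in names])
    log_hi = np.log([bounds[n][1] for n in names])
    pts = np.exp(log_lo + unit * (log_hi - log_lo))
    return HyperGrid(names=names, points=pts, bounds=dict(bounds), seed=seed)


DEFAULT_BOUNDS = {
    "sigma2": (0.01, 10.0),
    "rho_p": (0.1, 100.0),
    "rho_rbf": (1.0, 1000.0),
}


def _apply_point(spec: ModelSpec, point: dict[str, float]) -> ModelSpec:
    """New spec with the grid point's hyperparameters substituted."""
    kernel_fields = {"sigma2", "rho_p", "rho_rbf"}
    kp_updates = {k: v for k, v in point.items() if k in kernel_fields}
    other = {k: v for k, v in point.items() if k not in kernel_fields}
    kp = replace(spec.kernel_params, **kp_updates) if kp_updates else spec.kernel_params
    return replace(spec, kernel_params=kp, **other)


def _log_hyper_prior(spec: ModelSpec, point: dict[str, float]) -> float:
    lp = 0.0
    if "tau" in point:
        lp += log_tau_log_prior(np.log(point["tau"]))
    return lp


@dataclass
class LatentProblem:
    """Cached per-spec quantities for one dataset."""

    spec: ModelSpec
    y: np.ndarray  # flattened counts, cluster fastest
    Z: np.ndarray  # cells x n map from joint vector to linear predictor
    include: np.ndarray  # boolean per cell: contributes to the likelihood
    offset: np.ndarray  # log-exposure per cell (zeros by default)
    n_latent: int
    fe_variance: float
    likelihood: str = "poisson"  # "gaussian" gives the conjugate exact limit
    noise_var: float = 1.0  # observation variance for the gaussian likelihood

    @classmethod
    def build(
        cls,
        spec: ModelSpec,
        panel: ClusterPanel,
        exclude_cells: np.ndarray | None = None,
        counts: np.ndarray | None = None,
        offset: np.ndarray | None = None,
        likelihood: str = "poisson",
        noise_var: float = 1.0,
    ) -> "LatentProblem":
        Y = panel.counts if counts is None else counts
        y = np.asarray(Y, dtype=float).T.reshape(-1)  # (t, c) -> t*C + c
        design = spec.design
        Zl = spec.latent_map()
        Z = np.hstack([Zl, design.matrix])
        include = np.ones(y.size, dtype=bool)
        if exclude_cells is not None:
            include = ~np.asarray(exclude_cells, dtype=bool).T.reshape(-1)
        off = np.zeros(y.size) if offset is None else np.asarray(offset, float).T.reshape(-1)
        return cls(
            spec=spec,
            y=y,
            Z=Z,
            include=include,
            offset=off,
            n_latent=Zl.shape[1],
            fe_variance=spec.fixed_effect_variance,
            likelihood=likelihood,
            noise_var=noise_var,
        )

    def default_init(self) -> np.ndarray:
        """Latent field at zero; fixed effects from least squares on log(y + 0.5)."""
        n = self.Z.shape[1]
        u = np.zeros(n)
        sel = self.include
        X = self.Z[sel, self.n_latent :]
        if X.shape[1]:
            target = (
                self.y[sel]
                if self.likelihood == "gaussian"
                else np.log(self.y[sel] + 0.5)
            ) - self.offset[sel]
            beta, *_ = np.linalg.lstsq(X, target, rcond=None)
            u[self.n_latent :] = beta
        return u

    def prior_cholesky(self, panel: ClusterPanel, point: dict[str, float] | None) -> np.ndarray:
        """Lower Cholesky of the joint prior covariance blockdiag(Sigma_F, V_fe)."""
        spec = _apply_point(self.spec, point) if point else self.spec
        L_f = spec.latent_prior_cholesky(panel)
        n = self.Z.shape[1]
        m = self.n_latent
        L = np.zeros((n, n))
        L[:m, :m] = L_f
        L[m:, m:] = np.sqrt(self.fe_variance) * np.eye(n - m)
        return L

    def loglik(self, eta: np.ndarray) -> float:
        sel = self.include
        lam = eta[sel] + self.offset[sel]
        y = self.y[sel]
        if self.likelihood == "gaussian":
            s2 = self.noise_var
            return float(
                -0.5 * np.sum((y - lam) ** 2) / s2
                - 0.5 * y.size * np.log(2 * np.pi * s2)
            )
        return float(np.sum(y * lam - np.exp(lam) - gammaln(y + 1.0)))


def _poisson_logpmf(y: np.ndarray, log_lam: np.ndarray) -> np.ndarray:
    return y * log_lam - np.exp(log_lam) - gammaln(y + 1.0)


def gaussian_approx(
    problem: LatentProblem,
    prior_chol: np.ndarray,
    init: np.ndarray | None = None,
    tol: float = GRAD_TOL,
    max_iter: int = MAX_NEWTON_ITER,
) -> GaussianApprox:
    """Newton-Raphson mode finding with step halving in whitened coordinates.

    The objective is the log posterior of v = L^{-1} u: Poisson (or
    Gaussian) log-likelihood of the included cells at eta = Z L v plus
    the whitened prior -||v||^2 / 2. Each step solves (I + A' W A) dv =
    grad with A = Z L and halves the step until the objective does not
    decrease; iterations stop when the gradient's infinity norm drops
    below ``tol``. ``init`` is in original (u) coordinates.
    """
    L = prior_chol
    sel = problem.include
    A = problem.Z[sel] @ L
    ys = problem.y[sel]
    offs = problem.offset[sel]
    n = L.shape[0]
    gaussian = problem.likelihood == "gaussian"
    s2 = problem.noise_var

    if init is None:
        v = np.zeros(n)
    else:
        v = solve_triangular(L, init, lower=True)

    def objective(v):
        eta = A @ v + offs
        if gaussian:
            return float(-0.5 * np.sum((ys - eta) ** 2) / s2 - 0.5 * v @ v)
        if np.any(eta > 50):
            raise OverflowError(
                "linear predictor exceeds 50; consider centering counts or "
                "shrinking the prior variance"
            )
        return float(np.sum(ys * eta - np.exp(eta)) - 0.5 * v @ v)

    try:
        obj = objective(v)
    except OverflowError:
        v = np.zeros(n)
        obj = objective(v)
    # gradient entries scale with A'y, so convergence and line-search
    # slacks are relative: an absolute 1e-8 is unreachable in float64
    # once count sums reach ~1e5
    gscale = max(1.0, float(np.abs(A.T @ ys).max()))
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = A @ v + offs
        if gaussian:
            w = np.full(eta.shape, 1.0 / s2)
            grad = A.T @ (ys - eta) / s2 - v
        else:
            w = np.exp(eta)
            grad = A.T @ (ys - w) - v
        gnorm = float(np.abs(grad).max())
        trace.append(gnorm)
        if gnorm < tol * gscale:
            converged = True
            break
        H = np.eye(n) + (A.T * w) @ A
        cu = cho_factor(H, lower=False)
        step = cho_solve(cu, grad)
        t = 1.0
        accepted = False
        slack = 1e-10 * (1.0 + abs(obj))
        for _ in range(40):
            try:
                new_obj = objective(v + t * step)
            except OverflowError:
                t *= 0.5
                continue
            if new_obj >= obj - slack:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            raise NonConvergenceError("step halving failed to improve objective", trace)
        v = v + t * step
        obj = new_obj
    if not converged:
        eta = A @ v + offs
        grad = (A.T @ (ys - eta) / s2 if gaussian else A.T @ (ys - np.exp(eta))) - v
        if float(np.abs(grad).max()) > 1e-5 * gscale:
            raise NonConvergenceError(
                f"Newton did not converge in {max_iter} iterations "
                f"(last grad norm {trace[-1]:.3g})",
                trace,
            )
        converged = True

    eta = A @ v + offs
    w = np.full(eta.shape, 1.0 / s2) if gaussian else np.exp(eta)
    H = np.eye(n) + (A.T * w) @ A
    H = 0.5 * (H + H.T)
    U = cholesky(H, lower=False)
    log_det_h = 2.0 * float(np.sum(np.log(np.diag(U))))
    log_det_l = float(np.sum(np.log(np.diag(L))))
    return GaussianApprox(
        mode=L @ v,
        v_mode=v,
        transform=L,
        chol_h=U,
        log_det_h=log_det_h,
        log_det_transform=log_det_l,
        converged=converged,
        iterations=it,
        n_latent=problem.n_latent,
    )


def log_joint_at_mode(
    approx: GaussianApprox,
    problem: LatentProblem,
    log_hyper_prior: float = 0.0,
) -> float:
    """Laplace log evidence of one hyperparameter configuration.

    ``log pi(theta) + log p(y | u*) + log N(u*; 0, L L')
    - (1/2) log det Q + (n/2) log 2 pi``; after the whitening u = L v the
    2-pi and det-L terms cancel, leaving
    ``loglik(u*) - ||v*||^2 / 2 - log det(H) / 2``.
    """
    if not approx.converged:
        raise ValueError("evidence requires a converged approximation")
    eta = problem.Z @ approx.mode
    ll = problem.loglik(eta)
    return float(
        log_hyper_prior
        + ll
        - 0.5 * approx.v_mode @ approx.v_mode
        - 0.5 * approx.log_det_h
    )


def _mixture_quantile(
    mus: np.ndarray, sds: np.ndarray, deltas: np.ndarray, p: float
) -> float:
    sds = np.maximum(sds, 1e-300)
    lo = float(np.min(mus - 10 * sds) - 1e-12)
    hi = float(np.max(mus + 10 * sds) + 1e-12)

    def cdf(x):
        return float(np.sum(deltas * stats.norm.cdf(x, mus, sds))) - p

    return float(optimize.brentq(cdf, lo, hi, xtol=1e-10))


@dataclass
class FittedModel:
    """Posterior approximation across the hyperparameter grid."""

    spec: ModelSpec
    panel: ClusterPanel
    grid: HyperGrid
    approxes: list[GaussianApprox]
    log_evidence: np.ndarray  # per usable grid point
    weights: np.ndarray  # deltas, sum to 1
    problem: LatentProblem = field(repr=False, default=None)

    @property
    def n_effects(self) -> int:
        return self.approxes[0].n

    @property
    def effect_names(self) -> list[str]:
        m = self.approxes[0].n_latent
        design = self.spec.design
        return [f"F_{j}" for j in range(m)] + design.columns

    def marginal_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Mixture mean and sd of every scalar effect."""
        mus = np.array([a.mode for a in self.approxes])  # K x n
        sds = np.array([a.marginal_sd() for a in self.approxes])
        d = self.weights[:, None]
        mean = (d * mus).sum(0)
        second = (d * (sds**2 + mus**2)).sum(0)
        var = np.maximum(second - mean**2, 0.0)
        return mean, np.sqrt(var)

    def marginal_summary(self, probs=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        mus = np.array([a.mode for a in self.approxes])
        sds = np.array([a.marginal_sd() for a in self.approxes])
        mean, sd = self.marginal_moments()
        rows = []
        for j, name in enumerate(self.effect_names):
            qs = [
                _mixture_quantile(mus[:, j], sds[:, j], self.weights, p)
                for p in probs
            ]
            rows.append(
                {"effect": name, "mean": mean[j], "sd": sd[j]}
                | {f"q{100 * p:g}": q for p, q in zip(probs, qs)}
            )
        return pd.DataFrame(rows)

    def sample_joint(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draws (n x size) from the evidence-weighted Gaussian mixture."""
        ks = rng.choice(len(self.approxes), size=size, p=self.weights)
        out = np.empty((self.n_effects, size))
        for k in np.unique(ks):
            idx = np.flatnonzero(ks == k)
            out[:, idx] = self.approxes[k].sample(rng, idx.size)
        return out

    def linear_predictor_draws(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draws of eta = Z u at every cell: cells x size."""
        return self.problem.Z @ self.sample_joint(rng, size)

    def fitted_intensity(self, probs=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        """Posterior summaries of the intensity exp(eta) per (cluster, time) cell.

        Within each mixture component eta is Gaussian, so intensity
        quantiles are exp of mixture-eta quantiles; the mean uses the
        lognormal identity per component.
        """
        Z = self.problem.Z
        mus = np.array([Z @ a.mode for a in self.approxes])  # K x cells
        covd = [a.covariance() for a in self.approxes]
        sds = np.sqrt(
            np.maximum(
                np.array([np.einsum("ij,jk,ik->i", Z, Sk, Z) for Sk in covd]), 0.0
            )
        )
        d = self.weights[:, None]
        mean_lam = (d * np.exp(mus + 0.5 * sds**2)).sum(0)
        C = self.spec.n_clusters
        rows = []
        for cell in range(Z.shape[0]):
            t, c = divmod(cell, C)
            qs = {
                f"q{100 * p:g}": float(
                    np.exp(_mixture_quantile(mus[:, cell], sds[:, cell], self.weights, p))
                )
                for p in probs
            }
            rows.append({"cluster": c + 1, "t": t, "mean": mean_lam[cell]} | qs)
        return pd.DataFrame(rows)


def fit(
    spec: ModelSpec,
    panel: ClusterPanel,
    grid: HyperGrid,
    exclude_cells: np.ndarray | None = None,
    counts: np.ndarray | None = None,
    tol: float = GRAD_TOL,
    likelihood: str = "poisson",
    noise_var: float = 1.0,
) -> FittedModel:
    """Fit a model over the hyperparameter grid and mix by Laplace evidence.

    ``exclude_cells`` (C x T boolean) drops cells from the likelihood —
    the held-out/forecast mechanism; their latent values remain in the
    field and are conditioned on the observed cells through the prior.
    """
    problem = LatentProblem.build(
        spec,
        panel,
        exclude_cells=exclude_cells,
        counts=counts,
        likelihood=likelihood,
        noise_var=noise_var,
    )
    approxes, evidences, kept = [], [], []
    init = problem.default_init()
    failures = []
    for point in grid.as_dicts():
        try:
            L = problem.prior_cholesky(panel, point)
            approx = gaussian_approx(problem, L, init=init, tol=tol)
            ev = log_joint_at_mode(approx, problem, _log_hyper_prior(spec, point))
        except Exception as exc:
            failures.append((point, exc))
            continue
        init = approx.mode
        approxes.append(approx)
        evidences.append(ev)
        kept.append(point)
    if not approxes:
        raise RuntimeError(
            f"all {len(failures)} grid points failed; first: {failures[0][1]}"
        )
    if len(approxes) == 1 and grid.K > 1:
        import warnings

        warnings.warn("only one usable grid point; weights degenerate", RuntimeWarning)
    ev = np.asarray(evidences)
    w = np.exp(ev - ev.max())
    w /= w.sum()
    used_grid = HyperGrid(
        names=grid.names,
        points=np.array([[p[n] for n in grid.names] for p in kept]),
        bounds=grid.bounds,
        seed=grid.seed,
    )
    return FittedModel(
        spec=spec,
        panel=panel,
        grid=used_grid,
        approxes=approxes,
        log_evidence=ev,
        weights=w,
        problem=problem,
    )


def waic(fit_: FittedModel, n_draws: int = DEFAULT_DRAWS, seed: int = 0) -> float:
    """Watanabe-Akaike criterion from posterior draws (lower is better).

    ``WAIC = -2 sum_cells [log E_post p(y | lam) - Var_post log p(y | lam)]``
    over the cells included in the likelihood.
    """
    rng = np.random.default_rng(seed)
    eta = fit_.linear_predictor_draws(rng, n_draws)  # cells x draws
    sel = fit_.problem.include
    y = fit_.problem.y[sel]
    lp = _poisson_logpmf(y[:, None], eta[sel] + fit_.problem.offset[sel][:, None])
    lppd = np.log(np.exp(lp - lp.max(1, keepdims=True)).mean(1)) + lp.max(1)
    p_waic = lp.var(axis=1, ddof=1)
    return float(-2.0 * np.sum(lppd - p_waic))


def dic(fit_: FittedModel, n_draws: int = DEFAULT_DRAWS, seed: int = 0) -> float:
    """Deviance information criterion: ``2 E[D] - D(posterior mean intensity)``."""
    rng = np.random.default_rng(seed)
    eta = fit_.linear_predictor_draws(rng, n_draws)
    sel = fit_.problem.include
    y = fit_.problem.y[sel]
    off = fit_.problem.offset[sel][:, None]
    dev_draws = -2.0 * _poisson_logpmf(y[:, None], eta[sel] + off).sum(0)
    lam_bar = np.exp(eta[sel] + off).mean(1)
    dev_at_mean = -2.0 * float(
        np.sum(y * np.log(lam_bar) - lam_bar - gammaln(y + 1.0))
    )
    return float(2.0 * dev_draws.mean() - dev_at_mean)


@dataclass
class PredictiveDistribution:
    """Posterior predictive counts at held-out (cluster, time) cells."""

    cells: list[tuple[int, int]]  # (c, t) pairs, 0-based
    mean: np.ndarray
    variance: np.ndarray
    lower: np.ndarray  # equal-tailed 95% bounds
    upper: np.ndarray
    draws: np.ndarray | None = None  # cells x n_draws

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": [c + 1 for c, _ in self.cells],
                "t": [t for _, t in self.cells],
                "mean": self.mean,
                "variance": self.variance,
                "q2.5": self.lower,
                "q97.5": self.upper,
            }
        )


def _predict_cells(
    fit_: FittedModel, cells: list[tuple[int, int]], n_draws: int, rng
) -> PredictiveDistribution:
    C = fit_.spec.n_clusters
    idx = [t * C + c for c, t in cells]
    eta = fit_.linear_predictor_draws(rng, n_draws)[idx]  # cells x draws
    off = fit_.problem.offset[idx][:, None]
    lam = np.exp(eta + off)
    ydraw = rng.poisson(lam)
    lo = np.quantile(ydraw, 0.025, axis=1)
    hi = np.quantile(ydraw, 0.975, axis=1)
    return PredictiveDistribution(
        cells=list(cells),
        mean=lam.mean(axis=1),
        variance=lam.mean(axis=1) + lam.var(axis=1, ddof=1),
        lower=lo,
        upper=hi,
        draws=ydraw,
    )


def posterior_predictive(
    spec: ModelSpec,
    panel: ClusterPanel,
    grid: HyperGrid,
    horizon_cells: list[tuple[int, int]],
    mode: Literal["simultaneous", "rolling"] = "simultaneous",
    n_draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    rolling_stat: Literal["mean", "median"] = "mean",
) -> PredictiveDistribution:
    """Posterior predictive distribution at future/held-out cells.

    ``simultaneous`` drops all horizon cells from the likelihood in one
    fit and draws their counts jointly. ``rolling`` walks the horizon one
    month at a time: each step's forecast (rounded predictive mean by
    default) is appended to the history as a pseudo-observation before
    the next refit — the filtration grows with its own forecasts.
    """
    C, T = panel.n_clusters, panel.n_periods
    for c, t in horizon_cells:
        if not (0 <= c < C and 0 <= t < T):
            raise ValueError(f"cell ({c}, {t}) outside the panel")
    if np.any(~np.isfinite(panel.covariates)):
        bad = np.argwhere(~np.isfinite(panel.covariates))[:5]
        raise ValueError(f"missing covariates for cells {bad.tolist()}")

    if mode == "simultaneous":
        mask = np.zeros((C, T), dtype=bool)
        for c, t in horizon_cells:
            mask[c, t] = True
        fm = fit(spec, panel, grid, exclude_cells=mask)
        rng = np.random.default_rng(seed)
        return _predict_cells(fm, horizon_cells, n_draws, rng)

    if mode != "rolling":
        raise ValueError(f"unknown mode {mode!r}")

    steps = sorted({t for _, t in horizon_cells})
    counts = panel.counts.astype(float).copy()
    results: dict[tuple[int, int], tuple[float, float, float, float]] = {}
    draws_by_cell: dict[tuple[int, int], np.ndarray] = {}
    for step_i, t0 in enumerate(steps):
        rng = np.random.default_rng(seed + step_i)
        mask = np.zeros((C, T), dtype=bool)
        mask[:, t0:] = True  # everything from this step on is unseen
        fm = fit(spec, panel, grid, exclude_cells=mask, counts=np.round(counts).astype(int))
        step_cells = [(c, t) for c, t in horizon_cells if t == t0]
        pred = _predict_cells(fm, step_cells, n_draws, rng)
        for j, cell in enumerate(step_cells):
            results[cell] = (
                pred.mean[j],
                pred.variance[j],
                pred.lower[j],
                pred.upper[j],
            )
            draws_by_cell[cell] = pred.draws[j]
            stat = (
                pred.mean[j]
                if rolling_stat == "mean"
                else float(np.median(pred.draws[j]))
            )
            counts[cell[0], cell[1]] = np.round(stat)
    ordered = list(horizon_cells)
    return PredictiveDistribution(
        cells=ordered,
        mean=np.array([results[c][0] for c in ordered]),
        variance=np.array([results[c][1] for c in ordered]),
        lower=np.array([results[c][2] for c in ordered]),
        upper=np.array([results[c][3] for c in ordered]),
        draws=np.array([draws_by_cell[c] for c in ordered]),
    )
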
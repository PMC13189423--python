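"""Cluster-level surrogate construction from unit-level panels.

Counts are summed within clusters; covariates are aggregated by a
population-weighted mean whose weights can be refreshed on a calendar
window (annual by default, mirroring census-style population updates).
Interval-censored counts (privacy-masked small cells, e.g. "<11") are
imputed by a truncated-Poisson EM, and covariate series are decomposed
into trend + seasonal + residual so that residual-driven kernels can be
built downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geoclust import Partition

CENSOR_TOKEN = "<11"
DEFAULT_CENSOR_INTERVAL = (1, 10)


@dataclass
class ClusterPanel:
    """Cluster-by-time counts with per-cluster covariate surrogates."""

    counts: np.ndarray  # C x T nonnegative integers
    covariates: np.ndarray  # C x T x d
    cluster_populations: np.ndarray  # C (or C x T)
    time_index: pd.PeriodIndex  # monthly

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        self.covariates = np.asarray(self.covariates, dtype=float)
        if not isinstance(self.time_index, pd.PeriodIndex):
            self.time_index = pd.PeriodIndex(self.time_index, freq="M")
        if len(self.time_index) != self.counts.shape[1]:
            raise ValueError("time index length mismatch")

    @property
    def n_clusters(self) -> int:
        return self.counts.shape[0]

    @property
    def n_periods(self) -> int:
        return self.counts.shape[1]

    @property
    def month_of_year(self) -> np.ndarray:
        return np.asarray(self.time_index.month)


@dataclass
class CensoredCounts:
    values: np.ndarray  # integers where observed; ignored where masked
    censor_mask: np.ndarray  # True where censored
    censor_interval: tuple[int, int] = DEFAULT_CENSOR_INTERVAL

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        a, b = self.censor_interval
        if a < 1 or b < a:
            raise ValueError(f"bad censor interval [{a}, {b}]")


@dataclass
class DecomposedSeries:
    trend: np.ndarray
    seasonal: np.ndarray
    residual: np.ndarray
    period: int = 12

    @property
    def reconstruction(self) -> np.ndarray:
        return self.trend + self.seasonal + self.residual


def aggregate_counts(unit_counts: np.ndarray, partition: Partition) -> np.ndarray:
    """Sum unit counts within clusters: ``Y~[c, t] = sum_{i in c} Y[i, t]``."""
    Y = np.asarray(unit_counts)
    if np.any(Y < 0):
        raise ValueError("counts must be nonnegative")
    if not np.issubdtype(Y.dtype, np.integer):
        if not np.allclose(Y, np.round(Y)):
            raise ValueError("counts must be integers")
        Y = np.round(Y).astype(int)
    C = partition.n_clusters
    out = np.zeros((C, Y.shape[1]), dtype=Y.dtype)
    for c in range(C):
        out[c] = Y[partition.members(c)].sum(axis=0)
    return out


def aggregate_covariates(
    unit_covariates: np.ndarray,
    partition: Partition,
    weights: np.ndarray,
    time_index: pd.PeriodIndex | None = None,
    window: str = "annual",
) -> np.ndarray:
    """Population-weighted cluster means of unit covariates.

    ``weights`` is either per-unit (length N, time-invariant) or N x T
    (refreshed each period). With ``window="annual"`` and an N x T weight
    table, weights are frozen at each calendar year's first month within
    that year; ``window="fixed"`` uses the first column throughout.
    """
    X = np.asarray(unit_covariates, dtype=float)
    N, T, d = X.shape
    W = np.asarray(weights, dtype=float)
    if W.ndim == 1:
        W = np.repeat(W[:, None], T, axis=1)
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")

    if window == "fixed":
        W = np.repeat(W[:, :1], T, axis=1)
    elif window == "annual":
        if time_index is not None:
            years = np.asarray(pd.PeriodIndex(time_index, freq="M").year)
        else:
            years = np.arange(T) // 12
        Wnew = np.empty_like(W)
        for y in np.unique(years):
            cols = np.flatnonzero(years == y)
            Wnew[:, cols] = W[:, cols[0]][:, None]
        W = Wnew
    else:
        raise ValueError(f"unknown window {window!r}")

    C = partition.n_clusters
    out = np.empty((C, T, d))
    for c in range(C):
        idx = partition.members(c)
        wc = W[idx]  # members x T
        tot = wc.sum(axis=0)
        if np.any(tot <= 0):
            raise ValueError(f"cluster {c} has zero total weight at some period")
        out[c] = np.einsum("it,itd->td", wc, X[idx]) / tot[:, None]
    return out


def _trunc_poisson_mean(lam: float, a: int, b: int) -> float:
    """E[Y | a <= Y <= b] for Y ~ Poisson(lam)."""
    from scipy.stats import poisson

    ks = np.arange(a, b + 1)
    pmf = poisson.pmf(ks, lam)
    tot = pmf.sum()
    if tot <= 0:  # lambda far outside the interval; fall back to nearest bound
        return float(a if lam < a else b)
    return float((ks * pmf).sum() / tot)


def _censored_loglik(lam: float, observed: np.ndarray, n_cens: int, a: int, b: int) -> float:
    from scipy.stats import poisson

    ll = float(poisson.logpmf(observed, lam).sum()) if observed.size else 0.0
    if n_cens:
        pmass = poisson.cdf(b, lam) - poisson.cdf(a - 1, lam)
        ll += n_cens * np.log(max(pmass, 1e-300))
    return ll


def impute_censored_em(
    censored: CensoredCounts,
    groups: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, dict[int, float]]:
    """EM imputation of interval-censored counts with per-group Poisson rates.

    Groups typically index (cluster, calendar month) cells. The E-step
    replaces each censored entry by the truncated-Poisson mean
    ``E[Y | Y in [a, b]; lambda_g]``; the M-step resets ``lambda_g`` to
    the mean of observed values and current expectations. Returns
    (integer imputed counts, unrounded expectations, fitted rates). The
    censored-data log-likelihood is non-decreasing across iterations.
    """
    a, b = censored.censor_interval
    values = censored.values.astype(float).copy()
    mask = censored.censor_mask
    groups = np.asarray(groups)
    rates: dict[int, float] = {}
    expectations = values.copy()

    for g in np.unique(groups):
        sel = groups == g
        obs = values[sel & ~mask]
        n_cens = int((sel & mask).sum())
        if obs.size == 0 and n_cens == 0:
            continue
        lam = float(obs.mean()) if obs.size else (a + b) / 2.0
        lam = max(lam, 1e-8)
        if n_cens == 0:
            rates[int(g)] = lam
            continue
        prev_ll = -np.inf
        converged = False
        for _ in range(max_iter):
            ez = _trunc_poisson_mean(lam, a, b)
            new_lam = (obs.sum() + n_cens * ez) / (obs.size + n_cens)
            new_lam = max(new_lam, 1e-8)
            ll = _censored_loglik(new_lam, obs, n_cens, a, b)
            if ll < prev_ll - 1e-9:
                raise RuntimeError("EM log-likelihood decreased")  # pragma: no cover
            if abs(new_lam - lam) < tol:
                lam = new_lam
                converged = True
                break
            lam, prev_ll = new_lam, ll
        if not converged:
            raise RuntimeError(
                f"EM did not converge for group {g}: last rate {lam:.6g}"
            )
        rates[int(g)] = lam
        expectations[sel & mask] = _trunc_poisson_mean(lam, a, b)

    imputed = values.copy()
    imputed[mask] = np.clip(np.round(expectations[mask]), a, b)
    return imputed.astype(int), expectations, rates


def decompose_series(series: np.ndarray, period: int = 12) -> DecomposedSeries:
    """Classical additive decomposition into trend, seasonal and residual.

    Trend is a centered ``period``-term moving average with the edge
    months extended by the nearest defined trend value (so residuals are
    defined over the full series); seasonal is the month-of-year mean of
    the detrended series re-centered to sum to zero over one period;
    residual is the remainder, so trend + seasonal + residual = series
    exactly.
    """
    x = np.asarray(series, dtype=float)
    T = x.size
    if T < 2 * period:
        raise ValueError(f"need at least {2 * period} observations, got {T}")

    # centered moving average: for even period use the standard 2x(period) MA
    if period % 2 == 0:
        w = np.ones(period + 1)
        w[0] = w[-1] = 0.5
        w /= period
    else:
        w = np.ones(period) / period
    half = len(w) // 2
    core = np.convolve(x, w[::-1], mode="valid")  # defined at [half, T-half)
    trend = np.empty(T)
    trend[half : T - half] = core
    trend[:half] = core[0]
    trend[T - half :] = core[-1]

    detrended = x - trend
    months = np.arange(T) % period
    seasonal_means = np.array(
        [detrended[months == m].mean() for m in range(period)]
    )
    seasonal_means -= seasonal_means.mean()
    seasonal = seasonal_means[months]
    residual = x - trend - seasonal
    return DecomposedSeries(trend=trend, seasonal=seasonal, residual=residual, period=period)


def decompose_panel(covariates: np.ndarray, period: int = 12) -> np.ndarray:
    """Residual component of every (cluster, covariate) series: C x T x d."""
    C, T, d = covariates.shape
    R = np.empty_like(covariates)
    for c in range(C):
        for i in range(d):
            R[c, :, i] = decompose_series(covariates[c, :, i], period).residual
    return R


def read_long_panel(path_or_df) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.PeriodIndex, list[str]]:
    """Read a long-format CSV (unit_id, date, covariate..., count).

    Censoring may be encoded as the literal token ``"<11"`` in the count
    column. Returns (counts N x T float with NaN at censored cells,
    censor mask N x T, covariates N x T x d, monthly time index, unit ids).
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    df = df.copy()
    df["date"] = pd.PeriodIndex(df["date"], freq="M")
    units = sorted(df["unit_id"].astype(str).unique())
    times = pd.PeriodIndex(sorted(df["date"].unique()), freq="M")
    cov_cols = [c for c in df.columns if c not in ("unit_id", "date", "count")]
    N, T, d = len(units), len(times), len(cov_cols)
    counts = np.full((N, T), np.nan)
    mask = np.zeros((N, T), dtype=bool)
    X = np.full((N, T, d), np.nan)
    upos = {u: i for i, u in enumerate(units)}
    tpos = {t: i for i, t in enumerate(times)}
    for _, r in df.iterrows():
        i, t = upos[str(r["unit_id"])], tpos[r["date"]]
        raw = r["count"]
        if isinstance(raw, str) and raw.strip() == CENSOR_TOKEN:
            mask[i, t] = True
        else:
            counts[i, t] = float(raw)
        for k, c in enumerate(cov_cols):
            X[i, t, k] = float(r[c])
    return counts, mask, X, times, units
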
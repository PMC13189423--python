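"""Forecast evaluation metrics and protocols.

Prediction error is reported as scaled RMSPE — root mean squared
prediction error divided by the cluster's mean observed count — so
clusters of very different population sizes are comparable. A seasonal
climatology (same-calendar-month mean over the other years) supplies the
intensity-scale comparison target, and interval coverage is the fraction
of held-out counts inside the nominal predictive bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .inference import HyperGrid, PredictiveDistribution, posterior_predictive
from .models import ModelSpec
from .surrogates import ClusterPanel


@dataclass
class ForecastEvaluation:
    per_cluster: pd.DataFrame  # scaled RMSPE and coverage per cluster
    per_horizon: pd.DataFrame  # RMSPE / MAE / MAPE per horizon step
    overall_coverage: float
    protocol: dict = field(default_factory=dict)
    predictive: PredictiveDistribution | None = None


def scaled_rmspe(actual, predicted, mean_observed: float) -> float:
    """``sqrt(mean((actual - predicted)^2)) / mean_observed``.

    Invariant under common rescaling of all three arguments.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one cell")
    if mean_observed <= 0:
        raise ValueError("mean_observed must be > 0")
    return float(np.sqrt(np.mean((a - p) ** 2)) / mean_observed)


def seasonal_intensity_baseline(
    observed: np.ndarray,
    month_of_year: np.ndarray,
    target_cells: list[tuple[int, int]],
) -> np.ndarray:
    """Climatological intensity: same-calendar-month mean over other years.

    For a target cell (c, t) the estimate is the average of cluster c's
    observed counts at every other time point sharing t's calendar month.
    """
    Y = np.asarray(observed, dtype=float)
    months = np.asarray(month_of_year)
    out = np.empty(len(target_cells))
    for i, (c, t) in enumerate(target_cells):
        same = np.flatnonzero((months == months[t]) & (np.arange(Y.shape[1]) != t))
        if same.size == 0:
            raise ValueError(f"no other observations share the calendar month of t={t}")
        out[i] = Y[c, same].mean()
    return out


def interval_coverage(lower, upper, actual) -> float:
    """Fraction of cells with ``lower <= actual <= upper`` (inclusive)."""
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    a = np.asarray(actual, dtype=float)
    if np.any(lo > hi):
        raise ValueError("lower bound exceeds upper bound in some cell")
    if a.size == 0:
        return float("nan")
    return float(np.mean((a >= lo) & (a <= hi)))


def _mape(actual: np.ndarray, predicted: np.ndarray) -> tuple[float, int]:
    """MAPE over nonzero-actual cells; returns (value, n excluded zeros)."""
    nz = actual != 0
    excluded = int((~nz).sum())
    if nz.sum() == 0:
        return float("nan"), excluded
    return (
        float(np.mean(np.abs((actual[nz] - predicted[nz]) / actual[nz]))),
        excluded,
    )


def run_forecast_experiment(
    spec: ModelSpec,
    panel: ClusterPanel,
    grid: HyperGrid,
    origin: int,
    horizon: int,
    mode: Literal["simultaneous", "rolling"] = "simultaneous",
    n_draws: int = 4000,
    seed: int = 0,
) -> ForecastEvaluation:
    """Fit, forecast the ``horizon`` months after ``origin``, and score.

    ``origin`` is the last in-sample month index (0-based, exclusive of
    the horizon); cells (c, origin), ..., (c, origin + horizon - 1) are
    held out for every cluster. Metrics are computed only on the
    held-out window. Deterministic given the seed.
    """
    C, T = panel.n_clusters, panel.n_periods
    if origin + horizon > T:
        raise ValueError("origin + horizon exceeds the panel length")
    if horizon == 0:
        return ForecastEvaluation(
            per_cluster=pd.DataFrame(columns=["cluster", "scaled_rmspe", "coverage"]),
            per_horizon=pd.DataFrame(columns=["h", "rmspe", "mae", "mape"]),
            overall_coverage=float("nan"),
            protocol={"origin": origin, "horizon": 0, "mode": mode},
        )
    cells = [(c, t) for t in range(origin, origin + horizon) for c in range(C)]
    pred = posterior_predictive(
        spec, panel, grid, cells, mode=mode, n_draws=n_draws, seed=seed
    )
    actual = np.array([panel.counts[c, t] for c, t in cells], dtype=float)

    rows = []
    for c in range(C):
        sel = [i for i, (cc, _) in enumerate(cells) if cc == c]
        mu_obs = float(panel.counts[c, :origin].mean())
        rows.append(
            {
                "cluster": c + 1,
                "scaled_rmspe": scaled_rmspe(actual[sel], pred.mean[sel], mu_obs),
                "coverage": interval_coverage(
                    pred.lower[sel], pred.upper[sel], actual[sel]
                ),
            }
        )
    per_cluster = pd.DataFrame(rows)

    hrows = []
    for h in range(1, horizon + 1):
        t = origin + h - 1
        sel = [i for i, (_, tt) in enumerate(cells) if tt == t]
        err = actual[sel] - pred.mean[sel]
        mape, n_excl = _mape(actual[sel], pred.mean[sel])
        hrows.append(
            {
                "h": h,
                "rmspe": float(np.sqrt(np.mean(err**2))),
                "mae": float(np.mean(np.abs(err))),
                "mape": mape,
                "mape_zero_cells_excluded": n_excl,
            }
        )
    per_horizon = pd.DataFrame(hrows)
    overall = interval_coverage(pred.lower, pred.upper, actual)
    return ForecastEvaluation(
        per_cluster=per_cluster,
        per_horizon=per_horizon,
        overall_coverage=overall,
        protocol={"origin": origin, "horizon": horizon, "mode": mode, "seed": seed},
        predictive=pred,
    )
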
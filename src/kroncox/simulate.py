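"""Synthetic geographies, covariates and counts for validation studies.

Two generative regimes are provided. ``generate_latent_field_counts`` draws from
the model itself — a latent field with the separable Kronecker prior,
fixed effects, and Poisson observations — so that parameter-recovery
and calibration experiments have known ground truth. It is complemented
by ``generate_modulated_counts``, which produces intensity functions
whose seasonal amplitude and period drift linearly over time: a
deliberately nonstationary regime where fixed monthly effects alone
cannot track the signal. ``generate_geography`` plants cluster-
structured unit attributes on a map so the spanning-tree clustering has
a recoverable partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geoclust import SpatialUnit
from .kernels import GramMatrix, KernelParams, SpatioTemporalCovariance, kron_covariance
from .spatialgraph import SpatialOperator
from .surrogates import ClusterPanel


@dataclass
class SyntheticScenario:
    """Study conditions for the synthetic experiments.

    Defaults emulate the application scale the framework targets: a few
    dozen units grouped into a handful of clusters, five years of
    monthly data, and quasi-periodic covariates with annual cycles.
    """

    n_units: int = 30
    n_clusters: int = 4
    n_periods: int = 60
    n_covariates: int = 2
    layout: str = "random"  # or "lattice"
    attribute_dim: int = 3
    attribute_separation: float = 6.0  # closest center pair spacing, in noise sd units
    attribute_noise: float = 1.0
    kernel_truth: KernelParams = field(
        default_factory=lambda: KernelParams(sigma2=0.3, rho_p=1.0, rho_rbf=50.0)
    )
    filter_q: float = 0.75
    alpha_range: tuple[float, float] = (1.0, 2.5)  # cluster intercepts (log scale)
    beta_amplitude: float = 0.4  # seasonal fixed-effect amplitude
    base_log_intensity: float = 2.0  # modulated regime: a_c around this level
    amplitude0: float = 0.5  # modulated regime: initial seasonal amplitude
    amplitude_drift: float = 0.0  # per-month linear drift of the amplitude
    period0: float = 12.0  # initial period (months)
    period_drift: float = 0.0  # per-month linear drift of the period
    start: str = "2015-01"
    seed: int = 0


def _rng(scenario: SyntheticScenario, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(scenario.seed if seed is None else seed)


def generate_geography(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[list[SpatialUnit], np.ndarray]:
    """Units with coordinates, log-normal populations and planted attributes.

    Each unit belongs to one of C compact geographic blocks; its
    attribute vector is that block's latent center plus isotropic noise,
    so attribute-homogeneous contiguous clusters exist by construction.
    Returns (units, true cluster labels).
    """
    rng = _rng(scenario, seed)
    N, C, m = scenario.n_units, scenario.n_clusters, scenario.attribute_dim
    labels = np.sort(np.arange(N) % C)
    # geographic block centers on a coarse grid so blocks are spatially coherent
    base_lat, base_lon = 36.0, -120.0
    grid = int(np.ceil(np.sqrt(C)))
    # blocks adjoin (1 degree apart) so nearest-neighbor contiguity stays connected
    centers_geo = np.array(
        [(base_lat + 1.0 * (k // grid), base_lon + 1.0 * (k % grid)) for k in range(C)]
    )
    centers_attr = rng.standard_normal((C, m))
    if C > 1:
        # rescale so the closest pair of centers sits attribute_separation apart
        dists = [
            np.linalg.norm(centers_attr[a] - centers_attr[b])
            for a in range(C)
            for b in range(a + 1, C)
        ]
        centers_attr *= scenario.attribute_separation / max(min(dists), 1e-12)
    units = []
    for i in range(N):
        c = labels[i]
        if scenario.layout == "lattice":
            within = np.flatnonzero(labels == c).tolist().index(i)
            dlat, dlon = 0.3 * (within // 3), 0.3 * (within % 3)
        else:
            dlat, dlon = rng.uniform(-0.35, 0.35, size=2)
        attrs = centers_attr[c] + scenario.attribute_noise * rng.standard_normal(m)
        units.append(
            SpatialUnit(
                unit_id=f"u{i:03d}",
                centroid=(
                    float(centers_geo[c, 0] + dlat),
                    float(centers_geo[c, 1] + dlon),
                ),
                population=float(np.exp(rng.normal(11.0, 0.5))),
                attributes=attrs,
            )
        )
    return units, labels


def quasi_periodic_covariates(
    scenario: SyntheticScenario,
    seed: int | None = None,
    labels: np.ndarray | None = None,
    neighbor_corr: float = 0.7,
) -> np.ndarray:
    """Unit-level covariate series: annual cycle + regional signal + noise.

    With cluster ``labels``, units share a cluster-level stochastic
    component whose innovations are chain-correlated across cluster
    indices (coefficient ``neighbor_corr``), mimicking covariates like
    pollution that vary regionally with neighboring regions tracking
    each other — the structure the dependence-graph learner targets.
    """
    rng = _rng(scenario, seed)
    N, T, d = scenario.n_units, scenario.n_periods, scenario.n_covariates
    C = scenario.n_clusters
    t = np.arange(T)
    cluster_sig = np.zeros((C, T, d))
    if labels is not None:
        for j in range(d):
            innov = rng.normal(0, 1.0, size=(C, T))
            chain = np.empty((C, T))
            chain[0] = innov[0]
            for c in range(1, C):
                chain[c] = neighbor_corr * chain[c - 1] + np.sqrt(
                    1 - neighbor_corr**2
                ) * innov[c]
            # smooth in time with an AR(1) filter, scaled so the regional
            # signal is comparable to the seasonal cycle
            for c in range(C):
                for s in range(1, T):
                    chain[c, s] = 0.5 * chain[c, s - 1] + 0.6 * chain[c, s]
            cluster_sig[:, :, j] = 1.5 * chain
    X = np.empty((N, T, d))
    for i in range(N):
        c = int(labels[i]) if labels is not None else 0
        for j in range(d):
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.5, 1.5)
            trend = rng.normal(0, 0.005) * t
            ar = np.empty(T)
            ar[0] = rng.normal()
            for s in range(1, T):
                ar[s] = 0.6 * ar[s - 1] + rng.normal(0, 0.3)
            X[i, :, j] = (
                amp * np.sin(2 * np.pi * t / 12 + phase)
                + trend
                + (cluster_sig[c, :, j] if labels is not None else 0.0)
                + 0.3 * ar
            )
    return X


def _fixed_effects(scenario: SyntheticScenario, rng) -> tuple[np.ndarray, np.ndarray]:
    C = scenario.n_clusters
    lo, hi = scenario.alpha_range
    alpha = rng.uniform(lo, hi, size=C)
    months = np.arange(12)
    beta = scenario.beta_amplitude * np.sin(2 * np.pi * months / 12)
    beta = beta - beta[11]  # reference month (December) at zero
    return alpha, beta


def generate_latent_field_counts(
    scenario: SyntheticScenario,
    spatial_operator: SpatialOperator | np.ndarray,
    gram: GramMatrix | np.ndarray,
    seed: int | None = None,
) -> tuple[ClusterPanel, dict]:
    """Poisson counts from the separable latent Gaussian model.

    Draws ``F ~ N(0, K (x) Lt2)`` via the factor Cholesky identity,
    sets ``log Lambda = alpha_c + beta_{month(t)} + F_{c,t}`` and samples
    Poisson counts. Returns the panel plus a truth dict with the latent
    field, fixed effects and intensity for recovery tests.
    """
    rng = _rng(scenario, seed)
    C, T = scenario.n_clusters, scenario.n_periods
    cov = kron_covariance(gram, spatial_operator)
    if cov.C != C or cov.T != T:
        raise ValueError("factor dimensions do not match the scenario")
    F_flat = cov.sample(rng, size=1)[0]  # cluster fastest
    F = F_flat.reshape(T, C).T  # C x T
    alpha, beta = _fixed_effects(scenario, rng)
    time_index = pd.period_range(scenario.start, periods=T, freq="M")
    months = np.asarray(time_index.month) - 1
    eta = alpha[:, None] + beta[months][None, :] + F
    if np.any(eta > 30):
        raise ValueError(
            "log-intensity exceeds 30; reduce sigma2 or the fixed effects"
        )
    lam = np.exp(eta)
    Y = rng.poisson(lam)
    covariates = cluster_covariates(scenario, rng)
    panel = ClusterPanel(
        counts=Y,
        covariates=covariates,
        cluster_populations=np.full(C, 1e5),
        time_index=time_index,
    )
    truth = {"F": F, "alpha": alpha, "beta": beta, "intensity": lam}
    return panel, truth


def cluster_covariates(scenario: SyntheticScenario, rng) -> np.ndarray:
    """Cluster-level quasi-periodic covariates (C x T x d)."""
    C, T, d = scenario.n_clusters, scenario.n_periods, scenario.n_covariates
    t = np.arange(T)
    out = np.empty((C, T, d))
    for c in range(C):
        for j in range(d):
            phase = rng.uniform(0, 2 * np.pi)
            out[c, :, j] = (
                rng.uniform(0.5, 1.5) * np.sin(2 * np.pi * t / 12 + phase)
                + rng.normal(0, 0.005) * t
                + rng.normal(0, 0.15, size=T)
            )
    return out


def modulated_intensity(scenario: SyntheticScenario, rng=None) -> np.ndarray:
    """Deterministic drifting-seasonality intensity surface (C x T).

    ``Lambda_{c,t} = exp(a_c + A_c(t) sin(2 pi t / P_c(t)))`` with the
    amplitude and period drifting linearly; zero drift gives an exactly
    periodic surface.
    """
    if rng is None:
        rng = _rng(scenario, None)
    C, T = scenario.n_clusters, scenario.n_periods
    t = np.arange(T, dtype=float)
    a = scenario.base_log_intensity + rng.uniform(-0.3, 0.3, size=C)
    lam = np.empty((C, T))
    for c in range(C):
        A = scenario.amplitude0 + scenario.amplitude_drift * t
        P = scenario.period0 + scenario.period_drift * t
        if np.any(P <= 0):
            raise ValueError("period drifts through zero within the horizon")
        lam[c] = np.exp(a[c] + A * np.sin(2 * np.pi * t / P))
    return lam


def generate_modulated_counts(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[ClusterPanel, np.ndarray]:
    """Poisson counts with frequency- and amplitude-modulated intensities."""
    rng = _rng(scenario, seed)
    lam = modulated_intensity(scenario, rng)
    Y = rng.poisson(lam)
    covariates = cluster_covariates(scenario, rng)
    time_index = pd.period_range(scenario.start, periods=scenario.n_periods, freq="M")
    panel = ClusterPanel(
        counts=Y,
        covariates=covariates,
        cluster_populations=np.full(scenario.n_clusters, 1e5),
        time_index=time_index,
    )
    return panel, lam


def units_to_frame(units: list[SpatialUnit]) -> pd.DataFrame:
    m = units[0].attributes.size
    return pd.DataFrame(
        [
            {
                "unit_id": u.unit_id,
                "lat": u.centroid[0],
                "lon": u.centroid[1],
                "population": u.population,
            }
            | {f"attr_{j + 1}": u.attributes[j] for j in range(m)}
            for u in units
        ]
    )


def unit_counts_from_panel(
    panel_counts: np.ndarray, labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Disaggregate cluster counts to units multinomially (for round-trip tests)."""
    C, T = panel_counts.shape
    N = labels.size
    out = np.zeros((N, T), dtype=int)
    for c in range(C):
        members = np.flatnonzero(labels == c)
        probs = np.full(members.size, 1.0 / members.size)
        for t in range(T):
            out[members, t] = rng.multinomial(panel_counts[c, t], probs)
    return out
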
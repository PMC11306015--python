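"""Synthetic plot-level maize trial generator.

Emulates the statistical structure the yield models assume so every pipeline
stage is testable without field data: a two-cluster genetic marker matrix
(doubled-haploid hybrids vs replicated check hybrids), seven acquisition
dates spanning V8-R5 placed on a simulated weather record by cumulative
growing degree days, vegetation-like canopy reflectance spectra and
normalized-height LiDAR point clouds that evolve over the season, and yields
driven by planted per-date importance profiles (structural signal early,
chlorophyll-dynamics signal mid/late) plus Gaussian noise.

The planted importance profiles and yield coefficients are returned as
ground truth so interpretation experiments (does attention recover the
planted dates?) have a known answer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import truncnorm
from shapely.geometry import Polygon, box

from .errors import ConfigurationError, DomainError
from .lidar import PlotPointCloud, extract_lidar_features, LIDAR_FEATURE_NAMES
from .models import ModalityTensor
from .spectral import (
    PlotSpectrum,
    SPECTRAL_FEATURE_NAMES,
    extract_spectral_features,
    trim_row_ends,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "SpectrumStageParams",
    "generate_marker_matrix",
    "generate_plot_spectrum",
    "generate_canopy_point_cloud",
    "generate_weather",
    "daily_gdd",
    "accumulate_weather",
    "generate_yields",
    "generate_dataset",
    "write_dataset",
    "DATE_GDD_TARGETS",
    "WEATHER_FEATURE_NAMES",
]

#: cumulative GDD at the seven acquisition dates (V8 ... R5)
DATE_GDD_TARGETS = (499, 857, 1222, 1494, 1660, 1803, 2288)

WEATHER_FEATURE_NAMES = ("cum_gdd", "cum_precip", "cum_radiation")

#: two-row plot of 4.575 m x 1.5 m with 0.40 m trimmed from each row end
PLOT_BOUNDS = trim_row_ends((0.0, 0.0, 4.575, 1.5), 0.40)


def full_season_profiles(n_dates: int = 7) -> dict:
    """Spread importance profiles with signal through the whole season.

    LiDAR importance peaks around flowering (3rd date), hyperspectral during
    early grain fill (5th date), but every date carries some signal - the
    regime the date-subset scenarios are meant to probe.
    """
    t = np.arange(n_dates)
    lidar = np.exp(-0.5 * ((t - 2.0) / 1.6) ** 2)
    hyper = np.exp(-0.5 * ((t - 4.0) / 1.6) ** 2)
    return {"lidar": lidar / lidar.sum(), "hyperspectral": hyper / hyper.sum()}


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SyntheticConfig:
    """Study-design parameters of a synthetic trial.

    The defaults are the conditions the pipeline is exercised under: 500
    plots, 7 dates, a two-cluster genetic structure with ~5% checks, LiDAR
    yield signal planted at the 3rd date and hyperspectral signal at the 5th,
    and yield noise giving an oracle R^2 of 0.9 against a signal with
    standard deviation 9 bu/ac-equivalent units.
    """

    n_plots: int = 500
    n_dates: int = 7
    n_varieties: int = 250
    n_markers: int = 2000
    n_clusters: int = 2
    cluster_divergence: float = 0.8
    check_fraction: float = 0.05
    noise_sd: float = 3.0
    signal_sd: float = 9.0
    yield_mean: float = 150.0
    importance_profile: dict = field(default_factory=lambda: {})
    n_pixels: int = 16
    n_bands: int = 270
    pixel_noise_sd: float = 0.01
    point_density: float = 150.0
    nonlinearity: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_plots", "n_dates", "n_varieties", "n_markers", "n_clusters"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0.0 <= self.cluster_divergence <= 1.0:
            raise ConfigurationError("cluster_divergence must lie in [0, 1]")
        if not 0.0 <= self.check_fraction <= 1.0:
            raise ConfigurationError("check_fraction must lie in [0, 1]")
        if not self.importance_profile:
            lidar = np.zeros(self.n_dates)
            lidar[min(2, self.n_dates - 1)] = 1.0
            hyper = np.zeros(self.n_dates)
            hyper[min(4, self.n_dates - 1)] = 1.0
            self.importance_profile = {"lidar": lidar, "hyperspectral": hyper}
        for m, prof in self.importance_profile.items():
            prof = np.asarray(prof, dtype=float)
            if prof.size != self.n_dates:
                raise ConfigurationError(f"importance profile of {m} has wrong length")
            if np.any(prof < 0) or not np.isclose(prof.sum(), 1.0):
                raise ConfigurationError("importance profiles must be nonnegative and sum to 1")
            self.importance_profile[m] = prof


@dataclass
class GroundTruth:
    importance_profile: dict
    coefficients: dict
    cluster_effects: np.ndarray
    signal_sd: float
    noise_sd: float

    @property
    def oracle_r2(self) -> float:
        """Expected R^2 of the best possible predictor (signal fraction)."""
        s2, n2 = self.signal_sd**2, self.noise_sd**2
        return s2 / (s2 + n2)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    marker_matrix: np.ndarray
    variety_clusters: np.ndarray
    plot_table: pd.DataFrame
    weather: pd.DataFrame
    acquisition_days: np.ndarray
    tensors: dict
    ground_truth: GroundTruth
    spectra: dict | None = None
    point_clouds: dict | None = None


# ---------------------------------------------------------------------------
# genetics

def generate_marker_matrix(
    n_varieties: int,
    n_markers: int,
    n_clusters: int,
    divergence: float,
    seed: int,
    cluster_weights=None,
):
    """Marker dosage matrix in {0,1,2} with planted cluster labels.

    Each marker has a base allele frequency; clusters deviate from it by an
    amount scaling with `divergence` (0 = no structure), and genotypes are
    binomial draws from the cluster-specific frequencies.
    """
    if not 0.0 <= divergence <= 1.0:
        raise DomainError("divergence must lie in [0, 1]")
    if min(n_varieties, n_markers, n_clusters) < 1:
        raise DomainError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    if cluster_weights is None:
        cluster_weights = np.full(n_clusters, 1.0 / n_clusters)
    cluster_weights = np.asarray(cluster_weights, dtype=float)
    labels = rng.choice(n_clusters, size=n_varieties, p=cluster_weights)
    base = rng.uniform(0.1, 0.9, size=n_markers)
    deltas = rng.normal(0.0, 0.25, size=(n_clusters, n_markers))
    freqs = np.clip(base + divergence * deltas, 0.02, 0.98)
    matrix = rng.binomial(2, freqs[labels])
    return matrix, labels


# ---------------------------------------------------------------------------
# canopy spectra

@dataclass
class SpectrumStageParams:
    """Growth-stage control of the reflectance curve.

    chlorophyll     : 0 (senescent) .. 1 (peak green); drives red absorption
                      depth and the red-edge position
    nir_plateau     : NIR reflectance level, scales with biomass
    red_reflectance : reflectance in the red absorption trough (~670 nm)
    """

    chlorophyll: float
    nir_plateau: float
    red_reflectance: float


def _reflectance_curve(wl: np.ndarray, p: SpectrumStageParams) -> np.ndarray:
    chl = float(np.clip(p.chlorophyll, 0.0, 1.0))
    # visible region through control points: blue trough, green peak, red trough
    vis_pts_x = np.array([380.0, 500.0, 550.0, 620.0, 670.0, 700.0, 1010.0])
    green = 0.04 + 0.08 * chl + 0.5 * max(p.red_reflectance - 0.05, 0.0)
    vis_pts_y = np.array(
        [0.03, 0.04, green, (green + p.red_reflectance) / 2,
         p.red_reflectance, p.red_reflectance, p.red_reflectance]
    )
    vis = PchipInterpolator(vis_pts_x, vis_pts_y)(wl)
    # red edge: logistic transition to a gently sloped NIR plateau
    edge_pos = 705.0 + 30.0 * chl
    sig = 1.0 / (1.0 + np.exp(-(wl - edge_pos) / 8.0))
    nir = p.nir_plateau * (1.0 + 3e-4 * (wl - 850.0))
    return vis * (1.0 - sig) + nir * sig


def generate_plot_spectrum(
    stage_params: SpectrumStageParams,
    n_pixels: int,
    pixel_noise_sd: float,
    seed: int,
    n_bands: int = 270,
) -> PlotSpectrum:
    """Vegetation-like pixel spectra on a 400-1000 nm grid.

    Reflectances falling outside [0, 1] after noise are clipped (warned).
    """
    rng = np.random.default_rng(seed)
    wl = np.linspace(400.0, 1000.0, n_bands)
    mean_curve = _reflectance_curve(wl, stage_params)
    pixels = mean_curve[None, :] + (
        rng.normal(0.0, pixel_noise_sd, size=(n_pixels, n_bands))
        if pixel_noise_sd > 0
        else 0.0
    )
    if np.any(pixels < 0.0) or np.any(pixels > 1.0):
        warnings.warn("reflectance outside [0, 1]: clipping")
        pixels = np.clip(pixels, 0.0, 1.0)
    return PlotSpectrum(wl, pixels)


# ---------------------------------------------------------------------------
# canopy point clouds

def generate_canopy_point_cloud(
    mean_height: float,
    height_sd: float,
    cover_fraction: float,
    density: float,
    plot_polygon: Polygon,
    seed: int,
) -> PlotPointCloud:
    """Plot returns: ground at h=0 with fraction (1-cover), canopy from a
    truncated normal(mean_height, height_sd) restricted to h >= 0."""
    if density <= 0:
        raise DomainError("point density must be positive")
    if plot_polygon.is_empty or plot_polygon.area <= 0:
        raise DomainError("plot polygon is empty")
    if not 0.0 <= cover_fraction <= 1.0:
        raise DomainError("cover_fraction must lie in [0, 1]")
    if mean_height < 0:
        raise DomainError("mean_height must be >= 0")
    rng = np.random.default_rng(seed)
    n = max(1, int(round(density * plot_polygon.area)))
    xmin, ymin, xmax, ymax = plot_polygon.bounds
    xs = np.empty(n)
    ys = np.empty(n)
    filled = 0
    while filled < n:  # rejection sampling; exact for rectangles
        cx = rng.uniform(xmin, xmax, size=n - filled)
        cy = rng.uniform(ymin, ymax, size=n - filled)
        from shapely import points as _shapely_points

        keep = plot_polygon.contains(_shapely_points(np.column_stack([cx, cy])))
        k = int(keep.sum())
        xs[filled : filled + k] = cx[keep]
        ys[filled : filled + k] = cy[keep]
        filled += k
    is_canopy = rng.random(n) < cover_fraction
    heights = np.zeros(n)
    n_canopy = int(is_canopy.sum())
    if n_canopy and height_sd > 0:
        a = (0.0 - mean_height) / height_sd
        heights[is_canopy] = truncnorm.rvs(
            a, np.inf, loc=mean_height, scale=height_sd, size=n_canopy,
            random_state=rng,
        )
    elif n_canopy:
        heights[is_canopy] = mean_height
    return PlotPointCloud(xs, ys, heights, plot_polygon, ground_flag=~is_canopy)


# ---------------------------------------------------------------------------
# weather

def daily_gdd(tmin_f: np.ndarray, tmax_f: np.ndarray) -> np.ndarray:
    """US maize growing-degree-day rule: base 50 F, cap 86 F.

    GDD = max(0, (min(Tmax, 86) + max(Tmin, 50))/2 - 50).
    """
    t_hi = np.minimum(np.asarray(tmax_f, dtype=float), 86.0)
    t_lo = np.maximum(np.asarray(tmin_f, dtype=float), 50.0)
    return np.maximum(0.0, (t_hi + t_lo) / 2.0 - 50.0)


def generate_weather(
    season_days: int, seed: int, temp_noise_sd: float = 4.0
) -> pd.DataFrame:
    """Daily Tmin/Tmax (F), precipitation (mm) and radiation (MJ/m^2).

    Temperatures follow a seasonal sinusoid (planting in mid spring, peak in
    mid summer) plus noise; Tmax >= Tmin holds by construction.
    """
    if season_days < 1:
        raise DomainError("season_days must be >= 1")
    rng = np.random.default_rng(seed)
    day = np.arange(season_days)
    tmean = 62.0 + 16.0 * np.sin(np.pi * (day + 10) / (season_days + 30))
    spread = rng.uniform(12.0, 22.0, size=season_days)
    noise = rng.normal(0.0, temp_noise_sd, size=season_days)
    tmax = tmean + spread / 2.0 + noise
    tmin = tmax - spread
    wet = rng.random(season_days) < 0.3
    precip = np.where(wet, rng.exponential(8.0, size=season_days), 0.0)
    cloud = np.where(wet, rng.uniform(0.3, 0.8, size=season_days), rng.uniform(0.0, 0.3, size=season_days))
    radiation = (18.0 + 8.0 * np.sin(np.pi * (day + 10) / (season_days + 30))) * (1.0 - 0.5 * cloud)
    frame = pd.DataFrame(
        {
            "day": day,
            "tmin_f": tmin,
            "tmax_f": tmax,
            "precip_mm": precip,
            "radiation_mj": radiation,
        }
    )
    frame["gdd"] = daily_gdd(frame["tmin_f"], frame["tmax_f"])
    return frame


def accumulate_weather(daily: pd.DataFrame, acquisition_days) -> np.ndarray:
    """Cumulative (GDD, precipitation, radiation) since planting at each date.

    `acquisition_days` index the `day` column; accumulation is inclusive, so
    an acquisition on planting day carries day-1 contributions only.
    """
    days = np.asarray(acquisition_days, dtype=int)
    if np.any(days < daily["day"].min()) or np.any(days > daily["day"].max()):
        raise DomainError("acquisition date outside weather record")
    gdd = daily["gdd"].to_numpy() if "gdd" in daily else daily_gdd(
        daily["tmin_f"].to_numpy(), daily["tmax_f"].to_numpy()
    )
    cums = np.column_stack(
        [
            np.cumsum(gdd),
            np.cumsum(daily["precip_mm"].to_numpy()),
            np.cumsum(daily["radiation_mj"].to_numpy()),
        ]
    )
    pos = np.searchsorted(daily["day"].to_numpy(), days)
    return cums[pos]


# ---------------------------------------------------------------------------
# yields

def generate_yields(
    tensors: dict,
    cluster_of_plot: np.ndarray,
    importance_profile: dict,
    noise_sd: float,
    seed: int,
    signal_sd: float = 9.0,
    yield_mean: float = 150.0,
    cluster_effects: np.ndarray | None = None,
    nonlinearity: float = 0.0,
):
    """True and observed yields from date-weighted modality features.

    Per modality m, signal_m(i) = sum_t w_m[t] * (z_m[i,t,:] . gamma_m[t])
    with z the per-feature-per-date standardized tensor and gamma_m[t] the
    leading principal axis of date t's features; each modality part is
    normalized to unit variance, the summed signal is rescaled to
    `signal_sd`, shifted by a per-cluster effect around `yield_mean`, and
    observed yields add N(0, noise_sd).  With ``nonlinearity`` > 0 a mild
    saturating tanh bend is mixed in before rescaling.  The realized
    coefficients are stored in the returned ground truth.
    """
    rng = np.random.default_rng(seed)
    parts = []
    coefficients = {}
    for m, prof in importance_profile.items():
        t = tensors[m]
        prof = np.asarray(prof, dtype=float)
        if prof.size != t.n_dates:
            raise DomainError(f"importance profile of {m} has length {prof.size}, "
                              f"expected {t.n_dates}")
        v = t.values
        mean = v.mean(axis=0, keepdims=True)
        sd = v.std(axis=0, keepdims=True)
        z = (v - mean) / np.where(sd == 0, 1.0, sd)
        # the planted per-date signal is the leading principal axis of that
        # date's features (canopy vigour / chlorophyll status): linear,
        # well-conditioned despite strong feature collinearity
        gamma = np.zeros((t.n_dates, v.shape[2]))
        part = np.zeros(v.shape[0])
        for d in np.flatnonzero(prof > 0):
            zd = z[:, d, :]
            _, _, vt = np.linalg.svd(zd, full_matrices=False)
            u = vt[0] * np.sign(vt[0].sum() or 1.0)
            gamma[d] = prof[d] * u
            part += prof[d] * (zd @ u)
        # normalize so every modality contributes equal signal variance:
        # the planted importance, not the coefficient scale, sets the shares
        sd_p = part.std()
        if sd_p > 0:
            gamma = gamma / sd_p
            part = part / sd_p
        coefficients[m] = gamma
        parts.append(part)
    raw = np.sum(parts, axis=0)
    sd_raw = raw.std()
    z = raw / (sd_raw if sd_raw > 0 else 1.0)
    if nonlinearity > 0:
        z = (1.0 - nonlinearity) * z + nonlinearity * np.tanh(z)
        z = z / z.std()
    n_clusters = int(cluster_of_plot.max()) + 1
    if cluster_effects is None:
        cluster_effects = rng.normal(0.0, 3.0, size=n_clusters)
    true_yield = yield_mean + signal_sd * z + cluster_effects[cluster_of_plot]
    observed = true_yield + (
        rng.normal(0.0, noise_sd, size=true_yield.size) if noise_sd > 0 else 0.0
    )
    truth = GroundTruth(
        importance_profile={m: np.asarray(p) for m, p in importance_profile.items()},
        coefficients=coefficients,
        cluster_effects=np.asarray(cluster_effects, dtype=float),
        signal_sd=signal_sd,
        noise_sd=noise_sd,
    )
    return true_yield, observed, truth


# ---------------------------------------------------------------------------
# full dataset

def _season_curves(gdd: np.ndarray):
    """Canopy development as a function of cumulative GDD (nominal plot)."""
    height = 2.4 / (1.0 + np.exp(-(gdd - 1000.0) / 250.0))
    chl = (1.0 / (1.0 + np.exp(-(gdd - 600.0) / 150.0))) * (
        1.0 / (1.0 + np.exp(-(1900.0 - gdd) / 200.0))
    )
    cover = 0.97 / (1.0 + np.exp(-(gdd - 700.0) / 180.0))
    plateau = 0.28 + 0.22 / (1.0 + np.exp(-(gdd - 800.0) / 200.0))
    return height, chl, cover, plateau


def generate_dataset(config: SyntheticConfig, keep_raw: bool = False) -> SyntheticDataset:
    """Generate a complete synthetic trial as a pure function of the config.

    Features are extracted from the generated spectra and point clouds with
    the same extraction code the real pipeline uses, then yields are planted
    on the extracted feature tensors.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # genetics: one DH cluster per design, checks in the last cluster
    weights = np.full(cfg.n_clusters, (1.0 - cfg.check_fraction) / max(cfg.n_clusters - 1, 1))
    if cfg.n_clusters > 1:
        weights[-1] = cfg.check_fraction
    else:
        weights[:] = 1.0
    markers, var_clusters = generate_marker_matrix(
        cfg.n_varieties, cfg.n_markers, cfg.n_clusters, cfg.cluster_divergence,
        seed=int(rng.integers(2**31 - 1)), cluster_weights=weights,
    )
    check_varieties = np.flatnonzero(var_clusters == cfg.n_clusters - 1)
    dh_varieties = np.flatnonzero(var_clusters != cfg.n_clusters - 1)
    if check_varieties.size == 0:
        check_varieties = dh_varieties[:1]

    n_checks = int(round(cfg.check_fraction * cfg.n_plots))
    variety_of_plot = np.empty(cfg.n_plots, dtype=int)
    is_check = np.zeros(cfg.n_plots, dtype=bool)
    check_slots = rng.choice(cfg.n_plots, size=n_checks, replace=False)
    is_check[check_slots] = True
    variety_of_plot[is_check] = rng.choice(check_varieties, size=n_checks)
    dh_assign = np.resize(dh_varieties, cfg.n_plots - n_checks)
    variety_of_plot[~is_check] = rng.permutation(dh_assign)
    cluster_of_plot = var_clusters[variety_of_plot]

    # weather and acquisition dates at the target cumulative GDDs
    weather = generate_weather(150, seed=int(rng.integers(2**31 - 1)))
    cum_gdd = np.cumsum(weather["gdd"].to_numpy())
    targets = np.asarray(DATE_GDD_TARGETS, dtype=float)[: cfg.n_dates]
    if cfg.n_dates > len(DATE_GDD_TARGETS):
        targets = np.linspace(targets[0], cum_gdd[-1] * 0.95, cfg.n_dates)
    acq_days = np.searchsorted(cum_gdd, np.minimum(targets, cum_gdd[-1] - 1))
    gdd_at_dates = cum_gdd[acq_days]

    h0, chl0, cov0, plat0 = _season_curves(gdd_at_dates)

    # plot latent traits and per-date idiosyncratic variation
    b = rng.normal(0.0, 1.0, size=cfg.n_plots)   # structural vigour
    c = rng.normal(0.0, 1.0, size=cfg.n_plots)   # chlorophyll status
    # independent idiosyncratic draws per canopy channel: planted importance
    # must stay separable by modality, so structural (height/cover) and
    # spectral (chlorophyll/NIR plateau) deviations are not shared
    eta = rng.normal(0.0, 1.0, size=(cfg.n_plots, cfg.n_dates))
    xi = rng.normal(0.0, 1.0, size=(cfg.n_plots, cfg.n_dates))
    zeta = rng.normal(0.0, 1.0, size=(cfg.n_plots, cfg.n_dates))
    kappa = rng.normal(0.0, 1.0, size=(cfg.n_plots, cfg.n_dates))

    polygon = box(*PLOT_BOUNDS)
    spec_values = np.zeros((cfg.n_plots, cfg.n_dates, len(SPECTRAL_FEATURE_NAMES)))
    lidar_values = np.zeros((cfg.n_plots, cfg.n_dates, len(LIDAR_FEATURE_NAMES)))
    spectra = {} if keep_raw else None
    clouds = {} if keep_raw else None
    seed_seq = np.random.SeedSequence(cfg.seed + 7)
    child_seeds = seed_seq.generate_state(2 * cfg.n_plots * cfg.n_dates) % (2**31 - 1)

    k = 0
    for i in range(cfg.n_plots):
        for t in range(cfg.n_dates):
            # persistent traits (b, c) at ~10%; date-specific deviations at
            # ~20-25% so per-date importance stays identifiable from the data
            height = max(0.02, h0[t] * (1.0 + 0.10 * b[i] + 0.25 * eta[i, t]))
            chl = float(np.clip(chl0[t] * (1.0 + 0.08 * c[i] + 0.18 * xi[i, t]), 0.0, 1.0))
            cover = float(np.clip(cov0[t] * (1.0 + 0.04 * b[i] + 0.08 * kappa[i, t]), 0.0, 1.0))
            plateau = float(np.clip(plat0[t] * (1.0 + 0.06 * c[i] + 0.15 * zeta[i, t]), 0.05, 0.8))
            red = 0.04 + 0.10 * (1.0 - chl)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spectrum = generate_plot_spectrum(
                    SpectrumStageParams(chl, plateau, red),
                    n_pixels=cfg.n_pixels,
                    pixel_noise_sd=cfg.pixel_noise_sd,
                    seed=int(child_seeds[k]),
                    n_bands=cfg.n_bands,
                )
            cloud = generate_canopy_point_cloud(
                mean_height=height,
                height_sd=max(0.02, 0.12 * height),
                cover_fraction=cover,
                density=cfg.point_density,
                plot_polygon=polygon,
                seed=int(child_seeds[k + 1]),
            )
            k += 2
            spec_values[i, t] = extract_spectral_features(spectrum).values
            lidar_values[i, t] = extract_lidar_features(cloud).values
            if keep_raw:
                spectra[(i, t)] = spectrum
                clouds[(i, t)] = cloud

    weather_values = accumulate_weather(weather, acq_days)
    tensors = {
        "hyperspectral": ModalityTensor(
            spec_values, gdd_at_dates, SPECTRAL_FEATURE_NAMES, "hyperspectral"
        ),
        "lidar": ModalityTensor(
            lidar_values, gdd_at_dates, LIDAR_FEATURE_NAMES, "lidar"
        ),
        "weather": ModalityTensor(
            np.broadcast_to(weather_values, (cfg.n_plots,) + weather_values.shape).copy(),
            gdd_at_dates,
            WEATHER_FEATURE_NAMES,
            "weather",
        ),
    }

    true_yield, observed, truth = generate_yields(
        tensors,
        cluster_of_plot,
        cfg.importance_profile,
        noise_sd=cfg.noise_sd,
        seed=int(rng.integers(2**31 - 1)),
        signal_sd=cfg.signal_sd,
        yield_mean=cfg.yield_mean,
        nonlinearity=cfg.nonlinearity,
    )

    plot_table = pd.DataFrame(
        {
            "plot_id": np.arange(cfg.n_plots),
            "variety_id": variety_of_plot,
            "is_check": is_check,
            "cluster": cluster_of_plot,
            "true_yield": true_yield,
            "observed_yield": observed,
        }
    )
    return SyntheticDataset(
        config=cfg,
        marker_matrix=markers,
        variety_clusters=var_clusters,
        plot_table=plot_table,
        weather=weather,
        acquisition_days=acq_days,
        tensors=tensors,
        ground_truth=truth,
        spectra=spectra,
        point_clouds=clouds,
    )


# ---------------------------------------------------------------------------
# persistence

def write_dataset(dataset: SyntheticDataset, out_dir, include_raw: bool = False):
    """Write the dataset as plain-text files under `out_dir`."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.plot_table.to_csv(out / "plot_table.csv", index=False)
    pd.DataFrame(dataset.marker_matrix).to_csv(out / "marker_matrix.csv", index=False)
    dataset.weather.to_csv(out / "weather.csv", index=False)
    for m, t in dataset.tensors.items():
        n, T, F = t.values.shape
        frame = pd.DataFrame(
            t.values.reshape(n * T, F), columns=list(t.feature_names)
        )
        frame.insert(0, "date", np.tile(t.dates, n))
        frame.insert(0, "plot_id", np.repeat(np.arange(n), T))
        frame.to_csv(out / f"features_{m}.csv", index=False)
    truth = dataset.ground_truth
    payload = {
        "importance_profile": {m: p.tolist() for m, p in truth.importance_profile.items()},
        "coefficients": {m: g.tolist() for m, g in truth.coefficients.items()},
        "cluster_effects": truth.cluster_effects.tolist(),
        "signal_sd": truth.signal_sd,
        "noise_sd": truth.noise_sd,
        "oracle_r2": truth.oracle_r2,
    }
    (out / "ground_truth.json").write_text(json.dumps(payload, indent=2))
    if include_raw and dataset.spectra is not None:
        arrays = {"wavelengths": next(iter(dataset.spectra.values())).wavelengths}
        for (i, t), s in dataset.spectra.items():
            arrays[f"{i}|{t}"] = s.pixels
        np.savez(out / "spectra.npz", **arrays)
        rows = []
        for (i, t), cl in dataset.point_clouds.items():
            rows.append(
                pd.DataFrame(
                    {"plot_id": i, "date": t, "x": cl.x, "y": cl.y,
                     "height": cl.height, "ground": cl.ground_flag}
                )
            )
        pd.concat(rows).to_csv(out / "point_clouds.csv", index=False)
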
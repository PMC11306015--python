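"""Plot-level hyperspectral feature extraction.

Turns per-plot sets of pixel reflectance spectra (VNIR, 400-1000 nm) into the
nine features used by the yield models: two band-range integrals, one
integral of the first spectral derivative over the NIR, and six vegetation
indices (VOG3, NDRE, MCARI2, DATT3, PSRI, RDVI).  Also provides empirical
line radiance-to-reflectance calibration and OSAVI-based vegetation masking.

Conventions
-----------
* Band lookup is nearest-band with ties broken toward the lower wavelength.
* Indices are computed per pixel over the vegetation mask, then averaged;
  pixels with a zero denominator are dropped (logged).
* Integrals use the trapezoid rule on the band grid with linear
  interpolation at the range endpoints.
* RDVI is implemented with the plain sum denominator used by our feature
  table; the canonical square-root denominator is available via
  ``rdvi_canonical=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ConfigurationError, EmptyPlotError

logger = logging.getLogger(__name__)

__all__ = [
    "PlotSpectrum",
    "CalibrationTarget",
    "SpectralFeatureVector",
    "SPECTRAL_FEATURE_NAMES",
    "empirical_line_calibrate",
    "osavi_mask",
    "band_at",
    "vegetation_index",
    "integrate_band_range",
    "integrate_first_derivative",
    "extract_spectral_features",
    "trim_row_ends",
]

#: fixed feature order of the spectral feature vector
SPECTRAL_FEATURE_NAMES = (
    "Intg_670_780",
    "Intg_910_1000",
    "IntgDeriv_NIR",
    "VOG3",
    "NDRE",
    "MCARI2",
    "DATT3",
    "PSRI",
    "RDVI",
)

#: wavelength range (nm) of the NIR first-derivative integral
NIR_DERIVATIVE_RANGE = (910.0, 1000.0)

VEGETATION_INDICES = ("VOG3", "NDRE", "MCARI2", "DATT3", "PSRI", "RDVI")


@dataclass
class PlotSpectrum:
    """Pixel reflectance spectra of one plot on one date.

    wavelengths : (n_bands,) strictly increasing band centres in nm
    pixels      : (n_pixels, n_bands) reflectance in [0, 1]
    mask        : (n_pixels,) vegetation flags; all-True when omitted
    """

    wavelengths: np.ndarray
    pixels: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=float))
        if np.any(np.diff(self.wavelengths) <= 0):
            raise DomainError("wavelengths must be strictly increasing")
        if self.pixels.shape[1] != self.wavelengths.size:
            raise DomainError("pixel band count does not match wavelength grid")
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape[0], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]

    def masked_pixels(self) -> np.ndarray:
        out = self.pixels[self.mask]
        if out.shape[0] == 0:
            raise EmptyPlotError("no vegetation pixels retained in plot")
        return out

    def mean_spectrum(self) -> np.ndarray:
        """Mean reflectance over masked pixels."""
        return self.masked_pixels().mean(axis=0)


@dataclass
class CalibrationTarget:
    """A field calibration tarp of known reflectance."""

    nominal_reflectance: float
    measured_radiance: np.ndarray

    def __post_init__(self):
        self.measured_radiance = np.asarray(self.measured_radiance, dtype=float)


@dataclass
class SpectralFeatureVector:
    values: np.ndarray
    names: tuple = field(default=SPECTRAL_FEATURE_NAMES)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.names):
            raise DomainError("spectral feature vector must have 9 entries")

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


def empirical_line_calibrate(
    radiance: np.ndarray, targets: list[CalibrationTarget]
) -> np.ndarray:
    """Per-band least-squares line from radiance to reflectance.

    Fits reflectance = gain * radiance + offset independently per band on the
    calibration targets (nominal reflectances vs measured radiances) and
    applies it to every pixel.
    """
    radiance = np.atleast_2d(np.asarray(radiance, dtype=float))
    if len(targets) < 2:
        raise ConfigurationError("empirical line calibration needs >= 2 targets")
    L = np.stack([t.measured_radiance for t in targets])  # (m, bands)
    if L.shape[1] != radiance.shape[1]:
        raise DomainError("target radiance bands do not match pixel bands")
    R = np.array([t.nominal_reflectance for t in targets])[:, None]  # (m,1)
    Lbar = L.mean(axis=0, keepdims=True)
    var = ((L - Lbar) ** 2).sum(axis=0)
    bad = np.flatnonzero(var == 0.0)
    if bad.size:
        raise DomainError(
            f"zero radiance spread among targets in band index {bad[0]}"
        )
    gain = ((L - Lbar) * (R - R.mean())).sum(axis=0) / var
    offset = R.mean() - gain * Lbar.ravel()
    return radiance * gain + offset


def band_at(spectrum: PlotSpectrum, wavelength: float) -> np.ndarray:
    """Per-pixel reflectance at the band nearest `wavelength` (nm).

    A wavelength exactly midway between two bands resolves to the lower one.
    """
    wl = spectrum.wavelengths
    if wavelength < wl[0] or wavelength > wl[-1]:
        raise DomainError(
            f"wavelength {wavelength} nm outside grid [{wl[0]}, {wl[-1]}]"
        )
    idx = int(np.argmin(np.abs(wl - wavelength)))  # argmin takes the lower tie
    return spectrum.pixels[:, idx]


def osavi_mask(spectrum: PlotSpectrum, threshold: float = 0.4) -> np.ndarray:
    """Vegetation mask from the optimised soil-adjusted vegetation index.

    OSAVI = (rho800 - rho670) / (rho800 + rho670 + 0.16); pixels with
    OSAVI >= threshold are flagged as vegetation.
    """
    nir = band_at(spectrum, 800.0)
    red = band_at(spectrum, 670.0)
    osavi = (nir - red) / (nir + red + 0.16)
    return osavi >= threshold


def _index_per_pixel(spectrum: PlotSpectrum, name: str, rdvi_canonical: bool):
    b = lambda lam: band_at(spectrum, lam)  # noqa: E731
    if name == "VOG3":
        num, den = b(734) - b(747), b(715) + b(720)
    elif name == "NDRE":
        num, den = b(790) - b(720), b(790) + b(720)
    elif name == "MCARI2":
        val = ((b(750) - b(705)) - 0.2 * (b(700) - b(550)))
        num, den = val * b(750), b(705)
    elif name == "DATT3":
        num, den = b(754), b(704)
    elif name == "PSRI":
        num, den = b(678) - b(500), b(750)
    elif name == "RDVI":
        num = b(800) - b(670)
        den = b(800) + b(670)
        if rdvi_canonical:
            den = np.sqrt(den)
    else:
        raise ConfigurationError(f"unknown vegetation index {name!r}")
    return num, den


def vegetation_index(
    spectrum: PlotSpectrum, index_name: str, rdvi_canonical: bool = False
) -> float:
    """Plot-level vegetation index: per-pixel value averaged over the mask.

    Pixels whose denominator is exactly zero are excluded (count logged);
    if no pixel survives an :class:`EmptyPlotError` is raised.
    """
    num, den = _index_per_pixel(spectrum, index_name, rdvi_canonical)
    num, den = num[spectrum.mask], den[spectrum.mask]
    if num.size == 0:
        raise EmptyPlotError("no vegetation pixels retained in plot")
    ok = den != 0.0
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d zero-denominator pixels", index_name, n_dropped)
    if not ok.any():
        raise EmptyPlotError(f"{index_name}: all pixels had zero denominator")
    return float(np.mean(num[ok] / den[ok]))


def _range_grid(wl: np.ndarray, y: np.ndarray, lam_a: float, lam_b: float):
    """Grid points of y over [lam_a, lam_b] with interpolated endpoints."""
    if lam_a >= lam_b:
        raise DomainError("integration bounds must satisfy lam_a < lam_b")
    if lam_a < wl[0] or lam_b > wl[-1]:
        raise DomainError("integration bounds outside wavelength grid")
    inner = (wl > lam_a) & (wl < lam_b)
    xs = np.concatenate(([lam_a], wl[inner], [lam_b]))
    ys = np.concatenate(
        ([np.interp(lam_a, wl, y)], y[inner], [np.interp(lam_b, wl, y)])
    )
    return xs, ys


def integrate_band_range(
    spectrum: PlotSpectrum, lam_a: float, lam_b: float
) -> float:
    """Area under the masked-mean spectral curve over [lam_a, lam_b] nm."""
    y = spectrum.mean_spectrum()
    xs, ys = _range_grid(spectrum.wavelengths, y, lam_a, lam_b)
    return float(np.trapezoid(ys, xs))


def integrate_first_derivative(
    spectrum: PlotSpectrum, lam_a: float, lam_b: float
) -> float:
    """Integral of dS/dlambda of the masked-mean spectrum over [lam_a, lam_b].

    The derivative is the finite-difference slope of each band interval
    (piecewise constant at interval midpoints) and the integral weights each
    slope by its overlap with [lam_a, lam_b].  This pairing makes the
    fundamental-theorem identity exact on the sampled curve: the result
    equals the interpolated S(lam_b) - S(lam_a) to rounding error.
    """
    wl = spectrum.wavelengths
    if lam_a >= lam_b:
        raise DomainError("integration bounds must satisfy lam_a < lam_b")
    if lam_a < wl[0] or lam_b > wl[-1]:
        raise DomainError("integration bounds outside wavelength grid")
    y = spectrum.mean_spectrum()
    slopes = np.diff(y) / np.diff(wl)
    lo = np.clip(wl[:-1], lam_a, lam_b)
    hi = np.clip(wl[1:], lam_a, lam_b)
    return float(np.sum(slopes * (hi - lo)))


def extract_spectral_features(
    spectrum: PlotSpectrum, rdvi_canonical: bool = False
) -> SpectralFeatureVector:
    """All nine spectral features of one plot, in fixed order."""
    values = [
        integrate_band_range(spectrum, 670.0, 780.0),
        integrate_band_range(spectrum, 910.0, 1000.0),
        integrate_first_derivative(spectrum, *NIR_DERIVATIVE_RANGE),
    ]
    for name in VEGETATION_INDICES:
        values.append(vegetation_index(spectrum, name, rdvi_canonical))
    return SpectralFeatureVector(np.array(values))


def trim_row_ends(bounds: tuple, trim_length: float = 0.40) -> tuple:
    """Shrink a rectangular plot along its long axis by `trim_length` (m).

    `bounds` is (xmin, ymin, xmax, ymax); the trimmed bounds are returned.
    Mirrors the field practice of discarding row ends before extraction.
    """
    xmin, ymin, xmax, ymax = bounds
    if xmax - xmin >= ymax - ymin:
        xmin, xmax = xmin + trim_length, xmax - trim_length
    else:
        ymin, ymax = ymin + trim_length, ymax - trim_length
    if xmin >= xmax or ymin >= ymax:
        raise DomainError("trim length exceeds plot dimensions")
    return (xmin, ymin, xmax, ymax)


# ---------------------------------------------------------------------------
# I/O helpers

def read_spectra_npz(path) -> dict:
    """Read plot spectra from an NPZ archive.

    Layout: 'wavelengths' plus one '<plot_id>|<date>' array of pixel spectra
    per plot-date.  Returns {(plot_id, date): PlotSpectrum}.
    """
    archive = np.load(path)
    wl = archive["wavelengths"]
    out = {}
    for key in archive.files:
        if key == "wavelengths":
            continue
        plot_id, date = key.split("|", 1)
        out[(plot_id, date)] = PlotSpectrum(wl, archive[key])
    return out


def read_spectra_csv(path) -> dict:
    """Read plot spectra from a wide CSV: plot_id, date, then one column per
    wavelength (numeric column names in nm); one row per pixel."""
    frame = pd.read_csv(path)
    wl_cols = [c for c in frame.columns if c not in ("plot_id", "date")]
    wl = np.array([float(c) for c in wl_cols])
    out = {}
    for (plot_id, date), grp in frame.groupby(["plot_id", "date"]):
        out[(plot_id, date)] = PlotSpectrum(wl, grp[wl_cols].to_numpy())
    return out


def write_features_csv(rows: list[dict], path) -> pd.DataFrame:
    """Write per-plot-date feature rows (plot_id, date, features...) to CSV."""
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame
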
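"""Raman bone-matrix composition indices.

A spectral map (hundreds of spectra on a rectangular grid, ~800-1800 cm^-1)
is reduced to six scalar indices per specimen:

* mineral-to-matrix ratios: phosphate nu1 (962 cm^-1) over the amide I
  envelope (1600-1720 cm^-1) and over the amide III envelope
  (1215-1365 cm^-1);
* carbonate-to-phosphate ratio (carbonate 1070 cm^-1 / phosphate nu1);
* carbonate-to-amide-I ratio;
* crystallinity = 1 / FWHM of the nu1 phosphate peak (from a single-Gaussian
  fit, robust to noise);
* amide I subpeak ratio 1666/1685 cm^-1 from a constrained four-Gaussian
  decomposition of the amide I envelope (a collagen-quality index).

Processing chain: cosmic-ray removal, per-specimen averaging, linear
baseline removal under each band of interest, then band areas (or peak
heights) and peak fits.  All indices are invariant under global intensity
scaling of the spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit.models import GaussianModel

from .config import RamanConfig
from .errors import DomainError, ValidationError

__all__ = [
    "RamanSpectrum",
    "RamanMap",
    "RamanIndices",
    "expected_grid_count",
    "remove_cosmic_rays",
    "average_map",
    "linear_baseline",
    "band_area",
    "band_height",
    "compute_indices",
]

GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = 2.3548 sigma


@dataclass
class RamanSpectrum:
    """One spectrum: strictly increasing wavenumber axis (cm^-1) + intensity."""

    wavenumber: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.shape != self.intensity.shape or self.wavenumber.ndim != 1:
            raise ValidationError("axis and intensity must be equal-length 1D arrays")
        if len(self.wavenumber) > 1 and not np.all(np.diff(self.wavenumber) > 0):
            raise ValidationError("wavenumber axis must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavenumber)


def expected_grid_count(lx_um: float, ly_um: float, step_um: float) -> int:
    """Number of spectra on an Lx x Ly um grid at the given step, endpoints
    inclusive: (floor(Lx/step)+1) * (floor(Ly/step)+1).

    A 200 x 30 um map at a 5 um step gives 41 * 7 = 287 spectra.
    """
    if step_um <= 0:
        raise DomainError("step must be positive")
    return (int(lx_um // step_um) + 1) * (int(ly_um // step_um) + 1)


@dataclass
class RamanMap:
    """A grid of spectra sharing one wavenumber axis.

    ``intensities`` is (n_spectra, n_channels); ``x_um``/``y_um`` give the
    grid positions.  The spectrum count must match the inclusive-endpoint
    grid formula for the map extent and step.
    """

    wavenumber: np.ndarray
    intensities: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    step_um: float

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        n, c = self.intensities.shape
        if c != len(self.wavenumber):
            raise ValidationError("intensity channel count must match the axis")
        if len(self.x_um) != n or len(self.y_um) != n:
            raise ValidationError("one (x, y) position is required per spectrum")
        lx = float(np.ptp(self.x_um))
        ly = float(np.ptp(self.y_um))
        expect = expected_grid_count(lx, ly, self.step_um)
        if n != expect:
            raise ValidationError(
                f"{n} spectra inconsistent with a {lx} x {ly} um grid at "
                f"{self.step_um} um step (expected {expect})")

    def __len__(self) -> int:
        return len(self.intensities)

    def spectrum(self, i: int) -> RamanSpectrum:
        return RamanSpectrum(self.wavenumber, self.intensities[i])


@dataclass
class RamanIndices:
    """The six matrix-composition scalars for one specimen.

    ``crystallinity`` carries units of cm (1/FWHM); the rest are
    dimensionless ratios.  ``fit_ok`` is False when a peak fit failed to
    converge; diagnostics then describe why.
    """

    mmr_amide1: float
    mmr_amide3: float
    carbonate_phosphate: float
    carbonate_amide1: float
    crystallinity: float
    amide1_sub_ratio: float
    fit_ok: bool = True
    diagnostics: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "mmr_amide1": self.mmr_amide1,
            "mmr_amide3": self.mmr_amide3,
            "carbonate_phosphate": self.carbonate_phosphate,
            "carbonate_amide1": self.carbonate_amide1,
            "crystallinity": self.crystallinity,
            "amide1_sub_ratio": self.amide1_sub_ratio,
        }


# --------------------------------------------------------------------------
# processing chain
# --------------------------------------------------------------------------

def remove_cosmic_rays(spec: RamanSpectrum, z_thresh: float = 8.0) -> RamanSpectrum:
    """Replace cosmic-ray spikes by linear interpolation of their neighbours.

    A channel is a spike when the robust z-score of its discrete Laplacian
    (I_k - (I_{k-1} + I_{k+1})/2) exceeds ``z_thresh``; the z-scale is the
    median absolute deviation, so genuine bands do not inflate it.  Runs of
    up to two adjacent spikes are handled by interpolating across the whole
    flagged run.  Spike-free spectra are returned unchanged.
    """
    if len(spec) < 5:
        return spec
    y = spec.intensity
    lap = np.zeros_like(y)
    lap[1:-1] = y[1:-1] - 0.5 * (y[:-2] + y[2:])
    mad = np.median(np.abs(lap - np.median(lap)))
    scale = 1.4826 * mad if mad > 0 else np.std(lap)
    if scale == 0:
        return spec
    z = np.abs(lap - np.median(lap)) / scale
    bad = z > z_thresh
    # a large spike contaminates the Laplacian of its neighbours: only keep
    # flags that are local maxima of |lap| or adjacent to another flag
    if not np.any(bad):
        return spec
    keep = bad.copy()
    for k in np.flatnonzero(bad):
        neighbours = np.abs(lap[max(0, k - 1):k + 2])
        if np.abs(lap[k]) < np.max(neighbours):
            # neighbour has the stronger anomaly; drop unless itself extreme
            if z[k] < 2 * z_thresh:
                keep[k] = False
    if not np.any(keep):
        return spec
    good = ~keep
    fixed = y.copy()
    fixed[keep] = np.interp(spec.wavenumber[keep], spec.wavenumber[good], y[good])
    return RamanSpectrum(spec.wavenumber, fixed)


def average_map(rmap: RamanMap, z_thresh: float | None = None) -> RamanSpectrum:
    """Channel-wise arithmetic mean over all spectra of a map.

    When ``z_thresh`` is given, each spectrum is despiked first.
    """
    if z_thresh is None:
        mean = rmap.intensities.mean(axis=0)
    else:
        cleaned = np.stack([
            remove_cosmic_rays(rmap.spectrum(i), z_thresh).intensity
            for i in range(len(rmap))
        ])
        mean = cleaned.mean(axis=0)
    return RamanSpectrum(rmap.wavenumber, mean)


def _region_slice(spec: RamanSpectrum, region: tuple[float, float]) -> slice:
    lo, hi = region
    w = spec.wavenumber
    if lo < w[0] or hi > w[-1] or lo >= hi:
        raise DomainError(f"region {region} outside the spectral axis "
                          f"[{w[0]}, {w[-1]}]")
    i0 = int(np.searchsorted(w, lo, side="left"))
    i1 = int(np.searchsorted(w, hi, side="right"))
    return slice(i0, i1)


def linear_baseline(spec: RamanSpectrum, region: tuple[float, float],
                    anchor_channels: int = 5, clip: bool = False) -> RamanSpectrum:
    """Subtract a straight baseline under one band of interest.

    The line passes through the mean intensity of ``anchor_channels``-wide
    windows at each edge of the region; the corrected band (region channels
    only) is returned.  A spectrum that is exactly linear over the region
    maps to the zero band, and the operation is idempotent up to noise in
    the anchor windows.  ``clip=True`` additionally clamps negative
    corrected intensities to zero (off by default: rectifying noise biases
    band areas).
    """
    sl = _region_slice(spec, region)
    w = spec.wavenumber[sl]
    y = spec.intensity[sl]
    m = min(anchor_channels, max(1, len(w) // 2))
    x_lo, y_lo = w[:m].mean(), y[:m].mean()
    x_hi, y_hi = w[-m:].mean(), y[-m:].mean()
    slope = (y_hi - y_lo) / (x_hi - x_lo) if x_hi > x_lo else 0.0
    corrected = y - (y_lo + slope * (w - x_lo))
    if clip:
        corrected = np.clip(corrected, 0.0, None)
    return RamanSpectrum(w, corrected)


def band_area(spec: RamanSpectrum, region: tuple[float, float]) -> float:
    """Trapezoidal band integral over the region (a.u. * cm^-1)."""
    sl = _region_slice(spec, region)
    return float(np.trapezoid(spec.intensity[sl], spec.wavenumber[sl]))


def band_height(spec: RamanSpectrum, center: float, halfwidth: float = 5.0) -> float:
    """Maximum intensity within +-halfwidth cm^-1 of the band center."""
    sl = _region_slice(spec, (center - halfwidth, center + halfwidth))
    return float(np.max(spec.intensity[sl]))


# --------------------------------------------------------------------------
# index computation
# --------------------------------------------------------------------------

def _fit_phosphate_fwhm(band: RamanSpectrum, center: float) -> tuple[float, bool, dict]:
    model = GaussianModel()
    params = model.guess(band.intensity, x=band.wavenumber)
    params["center"].set(value=center, min=center - 10, max=center + 10)
    params["sigma"].set(min=0.5, max=30.0)
    result = model.fit(band.intensity, params, x=band.wavenumber)
    fwhm = GAUSS_FWHM * result.params["sigma"].value
    ok = bool(result.success) and fwhm > 0
    return fwhm, ok, {"phosphate_fit_redchi": float(result.redchi)}


def _fit_amide_i_subpeaks(band: RamanSpectrum, cfg: RamanConfig):
    """Constrained multi-Gaussian decomposition of the amide I envelope.

    Centers start at the configured positions and may shift by at most
    ``amide_i_center_bound``; amplitudes (areas) are non-negative.  Returns
    the fitted area of the subpeak initialized nearest 1666 over the one
    nearest 1685.
    """
    model = None
    params = None
    prefixes = []
    span = band.wavenumber[-1] - band.wavenumber[0]
    for i, c in enumerate(cfg.amide_i_subpeak_centers):
        g = GaussianModel(prefix=f"g{i}_")
        p = g.make_params()
        p[f"g{i}_center"].set(value=c, min=c - cfg.amide_i_center_bound,
                              max=c + cfg.amide_i_center_bound)
        p[f"g{i}_sigma"].set(value=8.0, min=1.5, max=span / 3.0)
        p[f"g{i}_amplitude"].set(value=max(band.intensity.max(), 1e-12) * 10.0,
                                 min=0.0)
        if model is None:
            model, params = g, p
        else:
            model = model + g
            params.update(p)
        prefixes.append(f"g{i}_")
    result = model.fit(band.intensity, params, x=band.wavenumber)
    centers = np.array([result.params[p + "center"].value for p in prefixes])
    areas = np.array([result.params[p + "amplitude"].value for p in prefixes])
    # identify the 1666 and 1685 subpeaks by initial center, not fitted order
    init = np.array(cfg.amide_i_subpeak_centers)
    i_1666 = int(np.argmin(np.abs(init - 1666.0)))
    i_1685 = int(np.argmin(np.abs(init - 1685.0)))
    ok = bool(result.success) and areas[i_1685] > 0
    ratio = areas[i_1666] / areas[i_1685] if areas[i_1685] > 0 else float("nan")
    return ratio, ok, {
        "amide_i_fit_redchi": float(result.redchi),
        "amide_i_centers": centers.tolist(),
        "amide_i_areas": areas.tolist(),
    }


def compute_indices(spec: RamanSpectrum, cfg: RamanConfig | None = None) -> RamanIndices:
    """Compute the six matrix indices from an averaged, despiked spectrum.

    Each band is baseline-corrected independently with a straight line
    anchored at its region edges.  Ratios use band areas by default
    (``cfg.use_heights`` switches the 962 and 1070 bands to peak heights).
    A failed peak fit does not raise: the result is flagged via ``fit_ok``
    with diagnostics attached.
    """
    cfg = cfg or RamanConfig()
    phos = linear_baseline(spec, cfg.phosphate_region, cfg.baseline_anchor_channels)
    carb = linear_baseline(spec, cfg.carbonate_region, cfg.baseline_anchor_channels)
    am1 = linear_baseline(spec, cfg.amide_i_region, cfg.baseline_anchor_channels)
    am3 = linear_baseline(spec, cfg.amide_iii_region, cfg.baseline_anchor_channels)

    a_phos = band_area(phos, cfg.phosphate_region)
    a_carb = band_area(carb, cfg.carbonate_region)
    a_am1 = band_area(am1, cfg.amide_i_region)
    a_am3 = band_area(am3, cfg.amide_iii_region)
    if cfg.use_heights:
        a_phos = band_height(phos, cfg.phosphate_center)
        a_carb = band_height(carb, cfg.carbonate_center)

    fwhm, ok_p, diag_p = _fit_phosphate_fwhm(phos, cfg.phosphate_center)
    sub_ratio, ok_a, diag_a = _fit_amide_i_subpeaks(am1, cfg)

    return RamanIndices(
        mmr_amide1=a_phos / a_am1,
        mmr_amide3=a_phos / a_am3,
        carbonate_phosphate=a_carb / a_phos,
        carbonate_amide1=a_carb / a_am1,
        crystallinity=1.0 / fwhm,
        amide1_sub_ratio=sub_ratio,
        fit_ok=ok_p and ok_a,
        diagnostics={**diag_p, **diag_a},
    )
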
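"""Ground-truth-known synthetic inputs for every pipeline stage.

Each generator emulates one acquisition modality with parameters that are
known exactly, so every analysis module can be validated as a recovery
problem:

* :func:`simulate_bend_test` — a displacement-controlled three-point bend
  test of a notched beam with machine-control emulation (2 N preload at
  2 um/s, 1 um/s ramp to 15 N, then 0.15 um/s, 1 Hz sampling, partial
  unloads triggered at -0.45 N/um over 15 points) driven by a prescribed
  quadratic J-R law;
* :func:`simulate_raman_map` — sum-of-Gaussians band model on a linear
  baseline with Gaussian noise and Poisson-placed cosmic-ray spikes;
* :func:`simulate_qbei_image` — Gaussian calcium field pushed through the
  inverse gray calibration and quantized to the detector bit depth;
* :func:`simulate_indentation` — forward Oliver-Pharr model (Kick loading,
  power-law unloading, linear-in-depth CSM stiffness);
* :func:`simulate_pore_volume` — straight cylindrical canals on a grid;
* :func:`simulate_cohort` — per-parameter Gaussian two-group cohorts.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .config import FractureConfig, IndentConfig, QbeiConfig, RamanConfig
from .core_io import (BendTestRecord, CrackLengthTable, MaterialConstants,
                      SpecimenGeometry)
from .errors import ValidationError
from .fracture import elastic_j, geometry_factor, stress_intensity
from .indentation import IndentationCurve
from .microstructure import BinaryVolume
from .qbei import QbeiCalibration
from .raman import GAUSS_FWHM, RamanMap

__all__ = [
    "VirtualSpecimen", "simulate_bend_test", "crack_compliance",
    "RamanTruth", "simulate_raman_map",
    "simulate_qbei_image", "simulate_indentation",
    "simulate_pore_volume", "CohortSpec", "simulate_cohort",
    "default_geometry", "default_material",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def default_geometry() -> SpecimenGeometry:
    """The standard beam: 2 x 3 x 12 mm, 10 mm span, notch at half height."""
    return SpecimenGeometry(B=2.0, W=3.0, L=12.0, S=10.0, a0=1.5)


def default_material() -> MaterialConstants:
    """Cortical-bone constants used throughout: E = 19.5 GPa, nu = 0.3."""
    return MaterialConstants(E=19.5, nu=0.3)


# --------------------------------------------------------------------------
# virtual bend test
# --------------------------------------------------------------------------

def crack_compliance(geom: SpecimenGeometry, mat: MaterialConstants,
                     n_grid: int = 4000):
    """Specimen compliance C(a) (um/N) consistent with the K formula.

    The energy-release rate G = K^2 (1 - nu^2)/E and G = (P^2 / 2B) dC/da
    give ``dC/da = 2 S^2 f(a/W)^2 (1 - nu^2) / (E B W^3)``, independent of
    load; integrating from a = 0 and adding the uncracked-beam bending
    compliance S^3/(48 E I), I = B W^3 / 12, yields C(a).  Returns a
    callable a_mm -> C (um/N) built on a dense trapezoid grid.
    """
    s_m, b_m, w_m = geom.S * 1e-3, geom.B * 1e-3, geom.W * 1e-3
    e_pa = mat.E * 1e9
    inertia = b_m * w_m**3 / 12.0
    c0 = s_m**3 / (48.0 * e_pa * inertia)          # m/N
    a_grid = np.linspace(1e-9, 0.97 * w_m, n_grid)
    dcda = (2.0 * s_m**2 * geometry_factor(a_grid / w_m) ** 2
            * (1.0 - mat.nu**2) / (e_pa * b_m * w_m**3))
    c_crack = np.concatenate([[0.0], np.cumsum(
        0.5 * (dcda[1:] + dcda[:-1]) * np.diff(a_grid))])
    c_total_um = (c0 + c_crack) * 1e6              # m/N -> um/N

    def compliance(a_mm):
        return np.interp(np.asarray(a_mm, dtype=float) * 1e-3, a_grid, c_total_um)

    return compliance


@dataclass
class VirtualSpecimen:
    """Ground truth for one virtual bend test.

    ``jr_coeffs`` define the resistance law J(delta_a) = c0 + c1 da + c2 da^2
    with da in um and J in J/m^2; it must be non-negative (and should be
    non-decreasing for stable growth) over the simulated extension range.
    ``plasticity_fraction`` scales the plastic displacement inserted at each
    growth increment relative to the elastic displacement gained from the
    compliance increase (0 = perfectly elastic specimen).
    """

    geom: SpecimenGeometry = field(default_factory=default_geometry)
    mat: MaterialConstants = field(default_factory=default_material)
    jr_coeffs: tuple[float, float, float] = (100.0, 0.5, 1.5e-3)
    plasticity_fraction: float = 0.5
    noise_sd_n: float = 0.05
    da_step_um: float = 25.0
    da_max_um: float = 700.0
    preload_rate_um_s: float = 2.0
    ramp_rate_um_s: float = 1.0
    slow_rate_um_s: float = 0.15
    ramp_to_n: float = 15.0
    unload_rate_um_s: float = 1.0
    unload_fraction: float = 0.5
    max_load_n: float = 60.0
    seed: int = 0

    def jr_law(self, delta_a_um):
        c0, c1, c2 = self.jr_coeffs
        da = np.asarray(delta_a_um, dtype=float)
        return c0 + c1 * da + c2 * da * da

    def __post_init__(self) -> None:
        da = np.linspace(0.0, self.da_max_um, 64)
        if np.any(self.jr_law(da) < 0):
            raise ValidationError("J-R law must be non-negative over the growth range")


def simulate_bend_test(vs: VirtualSpecimen,
                       cfg: FractureConfig | None = None,
                       ) -> tuple[BendTestRecord, CrackLengthTable]:
    """Emulate the bend-test machine on a virtual specimen.

    Displacement advances at the protocol rates with one sample per second.
    The load follows P = (delta - delta_pl)/C(a).  Crack growth is
    discretized in ``da_step_um`` increments: the crack advances to the next
    increment as soon as the total J there (elastic part from the relaxed
    load at the longer crack, plus the plastic J accumulated so far with the
    same fixed-slope area accounting the analyzer uses) reaches the J-R law.
    Each advance inserts a plastic displacement proportional to
    ``plasticity_fraction`` and produces a load drop; the machine logic
    monitors the rolling slope of the recorded curve and inserts a partial
    unload (to ``unload_fraction`` of the trigger load) when it falls below
    the threshold.  The test ends at ``da_max_um`` of extension, or at
    ``max_load_n`` if the resistance law is never reached (warning case:
    empty crack table).

    Returns the noisy record and the crack-length table (total lengths a,
    one entry per growth event sample).
    """
    cfg = cfg or FractureConfig()
    rng = _rng(vs.seed)
    compliance = crack_compliance(vs.geom, vs.mat)
    geom, mat = vs.geom, vs.mat
    k0 = 1.0 / float(compliance(geom.a0))      # N/um, initial loading slope
    b_m, w_m = geom.B * 1e-3, geom.W * 1e-3

    delta = 0.0          # machine displacement, um
    delta_pl = 0.0       # accumulated plastic displacement, um
    a_mm = geom.a0
    j_pl = 0.0           # analyzer-convention plastic J, J/m^2
    a_run = 0.0          # running integral P ddelta since last event, N*um
    p_ev = 0.0           # true load at the last event sample
    a_ev_mm = geom.a0    # crack length at the start of the current increment
    phase = "preload"
    rate = vs.preload_rate_um_s
    since_resume = 0
    p_trigger = 0.0

    t_list: list[float] = []
    p_list: list[float] = []
    d_list: list[float] = []
    ev_idx: list[int] = []
    ev_a: list[float] = []

    p_true_prev = 0.0
    delta_prev = 0.0
    t = 0.0
    max_steps = 100000
    done = False
    for _ in range(max_steps):
        t += 1.0
        delta += rate
        p_true = max((delta - delta_pl) / compliance(a_mm), 0.0)

        event_here = False
        if phase in ("preload", "ramp", "slow"):
            # crack-growth check, possibly several increments in one step
            while (a_mm - geom.a0) * 1e3 + vs.da_step_um <= vs.da_max_um + 1e-9:
                a_next = a_mm + vs.da_step_um * 1e-3
                da_next = (a_next - geom.a0) * 1e3
                p_h = max((delta - delta_pl) / compliance(a_next), 0.0)
                j_h = elastic_j(stress_intensity(p_h, geom, a_next), mat)
                if j_h + j_pl < vs.jr_law(da_next):
                    break
                dp = vs.plasticity_fraction * p_h * (compliance(a_next)
                                                     - compliance(a_mm))
                delta_pl += dp
                a_mm = a_next
                p_true = max((delta - delta_pl) / compliance(a_mm), 0.0)
                event_here = True

        # accumulate the area integral along the true path
        a_run += 0.5 * (p_true_prev + p_true) * (delta - delta_prev)
        p_true_prev, delta_prev = p_true, delta

        p_rec = max(p_true + rng.normal(0.0, vs.noise_sd_n), 0.0) \
            if vs.noise_sd_n > 0 else p_true
        t_list.append(t)
        p_list.append(p_rec)
        d_list.append(delta)
        i_now = len(t_list) - 1
        since_resume += 1

        if event_here:
            # close the plastic increment with the fixed-slope construction
            d_apl = max(a_run + (p_ev**2 - p_true**2) / (2.0 * k0), 0.0) * 1e-6
            j_pl += 2.0 * d_apl / (b_m * (geom.W - a_ev_mm) * 1e-3)
            a_run = 0.0
            p_ev = p_true
            a_ev_mm = a_mm
            ev_idx.append(i_now)
            ev_a.append(a_mm * 1e3)
            if (a_mm - geom.a0) * 1e3 >= vs.da_max_um - 1e-9:
                done = True

        # phase / machine-control transitions
        if phase == "preload" and p_true >= cfg.preload_n:
            phase, rate = "ramp", vs.ramp_rate_um_s
            a_run, p_ev = 0.0, p_true           # start of the first increment
        elif phase == "ramp" and p_true >= vs.ramp_to_n:
            phase, rate = "slow", vs.slow_rate_um_s
        elif phase in ("ramp", "slow"):
            w = cfg.slope_window
            if since_resume >= w and len(p_list) >= w:
                pw = np.array(p_list[-w:])
                dw = np.array(d_list[-w:])
                den = w * (dw * dw).sum() - dw.sum() ** 2
                if den > 0:
                    slope = (w * (dw * pw).sum() - dw.sum() * pw.sum()) / den
                    if slope <= cfg.unload_slope_threshold:
                        phase = "unload"
                        p_trigger = p_true
                        rate = -vs.unload_rate_um_s
        if phase == "unload" and p_true <= vs.unload_fraction * p_trigger:
            phase = "slow"
            rate = vs.slow_rate_um_s
            since_resume = 0

        if done or p_true >= vs.max_load_n:
            break
    else:
        raise ValidationError("bend-test simulation did not terminate")

    rec = BendTestRecord(np.array(t_list), np.array(p_list), np.array(d_list))
    table = CrackLengthTable(np.array(ev_idx, dtype=int), np.array(ev_a),
                             w_um=geom.W * 1e3)
    return rec, table


# --------------------------------------------------------------------------
# Raman maps
# --------------------------------------------------------------------------

@dataclass
class RamanTruth:
    """Band model underlying a synthetic bone spectrum.

    Bands are (center cm^-1, sigma cm^-1, total area) Gaussians grouped by
    the index they feed.  Band placement keeps every integration-region edge
    essentially signal-free so a straight anchored baseline is exact.
    """

    phosphate: tuple[float, float, float] = (962.0, 5.0, 100.0)
    carbonate: tuple[float, float, float] = (1070.0, 6.0, 12.0)
    amide_iii: tuple[tuple[float, float, float], ...] = (
        (1250.0, 9.0, 12.0), (1272.0, 9.0, 10.0), (1320.0, 11.0, 14.0))
    amide_i: tuple[tuple[float, float, float], ...] = (
        (1618.0, 4.5, 4.0), (1645.0, 6.0, 10.0),
        (1666.0, 6.0, 16.0), (1685.0, 6.0, 14.0))
    baseline_offset: float = 2.0
    baseline_slope: float = 5e-4     # a.u. per cm^-1

    def all_bands(self):
        return (self.phosphate, self.carbonate, *self.amide_iii, *self.amide_i)

    @staticmethod
    def _area_in(band, region) -> float:
        c, s, a = band
        lo, hi = region
        return a * 0.5 * (erf((hi - c) / (s * math.sqrt(2)))
                          - erf((lo - c) / (s * math.sqrt(2))))

    def expected_indices(self, cfg: RamanConfig | None = None) -> dict:
        """Analytic values of the six indices (areas truncated to regions)."""
        cfg = cfg or RamanConfig()
        a_p = self._area_in(self.phosphate, cfg.phosphate_region)
        a_c = self._area_in(self.carbonate, cfg.carbonate_region)
        a_1 = sum(self._area_in(b, cfg.amide_i_region) for b in self.amide_i)
        a_3 = sum(self._area_in(b, cfg.amide_iii_region) for b in self.amide_iii)
        i1666 = [b for b in self.amide_i if abs(b[0] - 1666) < 10][0]
        i1685 = [b for b in self.amide_i if abs(b[0] - 1685) < 10][0]
        return {
            "mmr_amide1": a_p / a_1,
            "mmr_amide3": a_p / a_3,
            "carbonate_phosphate": a_c / a_p,
            "carbonate_amide1": a_c / a_1,
            "crystallinity": 1.0 / (GAUSS_FWHM * self.phosphate[1]),
            "amide1_sub_ratio": i1666[2] / i1685[2],
        }

    def clean_spectrum(self, wavenumber: np.ndarray) -> np.ndarray:
        w = np.asarray(wavenumber, dtype=float)
        y = self.baseline_offset + self.baseline_slope * (w - w[0])
        for c, s, a in self.all_bands():
            y = y + a / (s * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((w - c) / s) ** 2)
        return y


def simulate_raman_map(truth: RamanTruth | None = None,
                       extent_um: tuple[float, float] = (200.0, 30.0),
                       step_um: float = 5.0,
                       snr: float | None = 50.0,
                       spike_rate: float = 0.02,
                       axis: np.ndarray | None = None,
                       seed=0) -> RamanMap:
    """Synthetic spectral map on an inclusive-endpoint grid.

    The default 200 x 30 um extent at 5 um step yields 287 spectra.  ``snr``
    is the phosphate peak height over the Gaussian noise sigma (None =
    noiseless); cosmic-ray spikes are Poisson-placed per spectrum with the
    given rate and amplitudes of 30-100 noise sigmas.
    """
    truth = truth or RamanTruth()
    rng = _rng(seed)
    if axis is None:
        axis = np.arange(800.0, 1800.0 + 0.5, 1.0)
    clean = truth.clean_spectrum(axis)
    nx = int(extent_um[0] // step_um) + 1
    ny = int(extent_um[1] // step_um) + 1
    xs, ys = np.meshgrid(np.arange(nx) * step_um, np.arange(ny) * step_um)
    n = nx * ny
    phos_height = truth.phosphate[2] / (truth.phosphate[1] * math.sqrt(2 * math.pi))
    noise_sd = 0.0 if snr is None else phos_height / snr
    spectra = np.tile(clean, (n, 1))
    if noise_sd > 0:
        spectra = spectra + rng.normal(0.0, noise_sd, size=spectra.shape)
    if spike_rate > 0:
        amp_scale = max(noise_sd, 0.02 * phos_height)
        counts = rng.poisson(spike_rate, size=n)
        for i in np.flatnonzero(counts):
            chans = rng.integers(2, len(axis) - 2, size=counts[i])
            spectra[i, chans] += rng.uniform(30.0, 100.0, size=counts[i]) * amp_scale
    return RamanMap(wavenumber=axis, intensities=spectra,
                    x_um=xs.ravel(), y_um=ys.ravel(), step_um=step_um)


# --------------------------------------------------------------------------
# qBEI images
# --------------------------------------------------------------------------

def simulate_qbei_image(mu_ca: float, sigma_ca: float,
                        calib: QbeiCalibration | None = None,
                        shape: tuple[int, int] = (1024, 1024),
                        bit_depth: int = 8,
                        seed=0) -> tuple[np.ndarray, QbeiCalibration]:
    """Gaussian calcium field mapped through the inverse calibration.

    The per-pixel Ca wt% ~ N(mu, sigma) is converted to gray values with the
    calibration's inverse and quantized to the detector bit depth (None
    skips quantization and returns floats).  Returns the image and the
    calibration whose standard grays were used.
    """
    calib = calib or QbeiCalibration(gray_carbon=28.0, gray_aluminum=219.0)
    rng = _rng(seed)
    ca = rng.normal(mu_ca, sigma_ca, size=shape)
    gray = calib.ca_to_gray(ca)
    if bit_depth is None:
        return gray, calib
    top = 2**bit_depth - 1
    img = np.clip(np.rint(gray), 0, top).astype(np.uint8 if bit_depth <= 8
                                                else np.uint16)
    return img, calib


# --------------------------------------------------------------------------
# indentation curves
# --------------------------------------------------------------------------

def _solve_contact(e_gpa: float, h_gpa: float, h_max_nm: float,
                   cfg: IndentConfig) -> tuple[float, float]:
    """(P_max N, S N/m) consistent with the Oliver-Pharr relations."""
    e_r_inv = ((1.0 - cfg.nu_sample**2) / (e_gpa * 1e9)
               + (1.0 - cfg.nu_indenter**2) / (cfg.e_indenter_gpa * 1e9))
    e_r = 1.0 / e_r_inv
    h_max = h_max_nm * 1e-9
    h_c = 0.9 * h_max
    for _ in range(200):
        area = cfg.area_coeff * h_c**2
        p = h_gpa * 1e9 * area
        s = 2.0 * cfg.beta / math.sqrt(math.pi) * e_r * math.sqrt(area)
        h_c_new = h_max - cfg.epsilon * p / s
        if h_c_new <= 0:
            raise ValidationError("inconsistent E/H: contact depth collapsed")
        if abs(h_c_new - h_c) < 1e-15:
            h_c = h_c_new
            break
        h_c = h_c_new
    area = cfg.area_coeff * h_c**2
    return h_gpa * 1e9 * area, 2.0 * cfg.beta / math.sqrt(math.pi) * e_r * math.sqrt(area)


def simulate_indentation(e_gpa: float, h_gpa: float,
                         cfg: IndentConfig | None = None,
                         h_max_nm: float = 2000.0,
                         n_loading: int = 200, n_unloading: int = 100,
                         m_exponent: float = 1.5,
                         noise_rel: float = 0.0,
                         seed=0) -> IndentationCurve:
    """Forward-model indentation curve for a homogeneous half-space.

    Loading follows Kick's law P = C h^2 with a CSM stiffness channel
    S(h) = S_max h / h_max (the self-similar solution); unloading is the
    power law ``P = alpha (h - h_f)^m`` whose value and slope at h_max match
    (P_max, S_max).  Optional multiplicative load noise.
    """
    cfg = cfg or IndentConfig()
    rng = _rng(seed)
    p_max, s_max = _solve_contact(e_gpa, h_gpa, h_max_nm, cfg)
    h_load = np.linspace(0.0, h_max_nm, n_loading)
    p_load = p_max * (h_load / h_max_nm) ** 2            # N
    s_load = s_max * h_load / h_max_nm                   # N/m
    # unloading: value and slope continuous at h_max
    s_nm = s_max * 1e-9                                  # N per nm
    h_f = h_max_nm - m_exponent * p_max / s_nm
    alpha = p_max / (h_max_nm - h_f) ** m_exponent
    h_unload = np.linspace(h_max_nm, h_f + 1e-6, n_unloading + 1)[1:]
    p_unload = alpha * (h_unload - h_f) ** m_exponent
    depth = np.concatenate([h_load, h_unload])
    load = np.concatenate([p_load, p_unload]) * 1e3      # N -> mN
    stiff = np.concatenate([s_load, np.full(len(h_unload), np.nan)])
    if noise_rel > 0:
        load = load * (1.0 + rng.normal(0.0, noise_rel, size=load.shape))
        load = np.clip(load, 0.0, None)
    return IndentationCurve(depth_nm=depth, load_mn=load,
                            stiffness_n_per_m=stiff)


# --------------------------------------------------------------------------
# pore volumes
# --------------------------------------------------------------------------

def simulate_pore_volume(canal_diameter_um: float = 60.0,
                         canal_spacing_um: float = 150.0,
                         shape: tuple[int, int, int] = (48, 48, 48),
                         voxel_um: float = 6.0,
                         seed=0) -> tuple[BinaryVolume, dict]:
    """Binary volume with straight z-aligned cylindrical canals on a grid.

    Canal centers sit on a square lattice with the given spacing, offset by
    half a spacing from the volume edge.  Returns the volume (envelope =
    full box) and the analytic ground truth: continuous porosity and the
    canal diameter.
    """
    nz, ny, nx = shape
    r_um = canal_diameter_um / 2.0
    ys = (np.arange(ny) + 0.5) * voxel_um
    xs = (np.arange(nx) + 0.5) * voxel_um
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    centers_y = np.arange(canal_spacing_um / 2.0, ny * voxel_um, canal_spacing_um)
    centers_x = np.arange(canal_spacing_um / 2.0, nx * voxel_um, canal_spacing_um)
    # spacing larger than the volume: one canal, aligned to a voxel center so
    # the phantom is symmetric about a sample point
    if len(centers_y) == 0:
        centers_y = np.array([(ny // 2 + 0.5) * voxel_um])
    if len(centers_x) == 0:
        centers_x = np.array([(nx // 2 + 0.5) * voxel_um])
    cross = np.zeros((ny, nx), dtype=bool)
    for cy in centers_y:
        for cx in centers_x:
            cross |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_um**2
    pores = np.broadcast_to(cross, shape).copy()
    envelope = np.ones(shape, dtype=bool)
    truth = {
        "porosity_pct": 100.0 * len(centers_y) * len(centers_x) * math.pi * r_um**2
        / (ny * voxel_um * nx * voxel_um),
        "canal_diameter_um": canal_diameter_um,
        "n_canals": len(centers_y) * len(centers_x),
    }
    return BinaryVolume(voxel_um=voxel_um, pores=pores, envelope=envelope), truth


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Two-group cohort layout: group sizes, per-parameter Gaussians and
    standardized effect sizes (case mean = mean + effect * sd).

    Default parameter means/SDs mirror typical elderly-male cortical-bone
    control values (carbonate/phosphate ratio, amide I subpeak ratio,
    CaMean/CaPeak, indentation modulus and hardness, cortical porosity).
    """

    n_control: int = 18
    n_case: int = 11
    parameters: dict = field(default_factory=lambda: {
        "carbonate_phosphate": (0.1173, 0.0097),
        "amide1_sub_ratio": (1.137, 0.163),
        "camean_wtpct": (25.54, 0.45),
        "capeak_wtpct": (25.84, 0.51),
        "e_gpa": (19.26, 0.5),
        "h_gpa": (0.78, 0.02),
        "ct_po_pct": (2.0, 1.0),
    })
    effects: dict = field(default_factory=dict)
    group_names: tuple[str, str] = ("control", "t2dm")

    def __post_init__(self) -> None:
        if self.n_control < 3 or self.n_case < 3:
            raise ValidationError("group sizes must be at least 3")
        for name, (mu, sd) in self.parameters.items():
            if sd <= 0:
                raise ValidationError(f"SD of parameter {name!r} must be positive")


def simulate_cohort(cs: CohortSpec | None = None, seed=0) -> pd.DataFrame:
    """Draw a tidy two-group results table (columns parameter, group, value)."""
    cs = cs or CohortSpec()
    rng = _rng(seed)
    rows = []
    for name, (mu, sd) in cs.parameters.items():
        shift = cs.effects.get(name, 0.0) * sd
        for v in rng.normal(mu, sd, size=cs.n_control):
            rows.append({"parameter": name, "group": cs.group_names[0], "value": v})
        for v in rng.normal(mu + shift, sd, size=cs.n_case):
            rows.append({"parameter": name, "group": cs.group_names[1], "value": v})
    return pd.DataFrame(rows)
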
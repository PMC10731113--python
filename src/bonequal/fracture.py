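"""Elastic-plastic J-integral R-curves from notched-beam bend tests.

The fracture resistance of a single-edge-notched bend (SENB) beam is
quantified by the nonlinear-elastic J-integral, split into an elastic and a
plastic part and evaluated at each crack-growth event::

    K_I  = P * S / (B * W^{3/2}) * f(a/W)          mode-I stress intensity
    J_el = K_I^2 * (1 - nu^2) / E                  elastic part (J/m^2)
    J_pl = 2 * A_pl / (B * (W - a))                plastic part (J/m^2)
    J_tot = J_el + J_pl

``f(a/W)`` is the standard SENB geometry factor.  ``A_pl`` is the plastic
(non-recoverable) area under the load-displacement curve between two
crack-growth events, enclosed by parallel lines whose slope equals the
loading slope before the first crack extension.  With that fixed reference
slope, the energy released by the compliance increase of a growing crack is
partly attributed to A_pl as well; the first growth increment, where the
crack was stationary beforehand, is free of this effect.

J_pl accumulates as a sum of incremental plastic areas between successive
events, each normalized by the ligament at the start of its increment.  No
crack-growth (eta/gamma) correction is applied: the printed per-area formula
is used literally.

Loads enter in N, displacements in um, geometry in mm, E in GPa; J values
are returned in J/m^2 and K in Pa*sqrt(m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .config import FractureConfig
from .core_io import BendTestRecord, CrackLengthTable, MaterialConstants, SpecimenGeometry
from .errors import DomainError, ValidationError

__all__ = [
    "geometry_factor",
    "stress_intensity",
    "elastic_j",
    "segment_record",
    "plastic_area",
    "plastic_j",
    "build_r_curve",
    "fit_r_curve",
    "SegmentedRecord",
    "RCurve",
    "RCurveFit",
]


def geometry_factor(a_over_w):
    """SENB geometry factor f(a/W) for three-point bending.

    f = 3*sqrt(x) * [1.99 - x(1-x)(2.15 - 3.93x + 2.7x^2)]
        / (2*(1+2x)*(1-x)^{3/2}),   x = a/W in (0, 1).

    Vanishes as sqrt(x) for x -> 0 and diverges as (1-x)^{-3/2} for x -> 1;
    strictly increasing over the practically used range.
    """
    x = np.asarray(a_over_w, dtype=float)
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise DomainError("a/W must lie strictly inside (0, 1)")
    num = 3.0 * np.sqrt(x) * (1.99 - x * (1.0 - x) * (2.15 - 3.93 * x + 2.7 * x * x))
    den = 2.0 * (1.0 + 2.0 * x) * (1.0 - x) ** 1.5
    out = num / den
    return float(out) if np.isscalar(a_over_w) else out


def stress_intensity(p_n: float, geom: SpecimenGeometry, a_mm) -> float:
    """Mode-I stress intensity K_I = P*S/(B*W^{3/2}) * f(a/W), in Pa*sqrt(m).

    Linear (homogeneous of degree 1) in the load P.
    """
    a_mm = np.asarray(a_mm, dtype=float)
    if np.any(np.asarray(p_n) < 0):
        raise DomainError("load P must be non-negative")
    if np.any(a_mm <= 0) or np.any(a_mm >= geom.W):
        raise DomainError("crack length a must lie in (0, W)")
    s_m, b_m, w_m = geom.S * 1e-3, geom.B * 1e-3, geom.W * 1e-3
    k = p_n * s_m / (b_m * w_m**1.5) * geometry_factor(a_mm / geom.W)
    return float(k) if np.isscalar(p_n) and a_mm.ndim == 0 else k


def elastic_j(k_i, mat: MaterialConstants):
    """Elastic J-integral J_el = K_I^2 (1 - nu^2) / E, in J/m^2.

    Quadratic (homogeneous of degree 2) in K_I.
    """
    k = np.asarray(k_i, dtype=float)
    if np.any(k < 0):
        raise DomainError("K_I must be non-negative")
    j = k**2 * (1.0 - mat.nu**2) / (mat.E * 1e9)
    return float(j) if np.isscalar(k_i) else j


def plastic_j(a_pl_j: float, geom: SpecimenGeometry, a_mm: float) -> float:
    """Plastic J-integral J_pl = 2*A_pl/(B*(W - a)), A_pl in joules, J/m^2."""
    if a_pl_j < 0:
        raise DomainError("plastic area A_pl must be non-negative")
    if a_mm >= geom.W:
        raise DomainError("crack length a must be smaller than W")
    return 2.0 * a_pl_j / (geom.B * 1e-3 * (geom.W - a_mm) * 1e-3)


# --------------------------------------------------------------------------
# record segmentation
# --------------------------------------------------------------------------

@dataclass
class SegmentedRecord:
    """A bend record partitioned into preload / loading / unloading segments.

    ``segments`` is a list of ``(kind, start, stop)`` half-open index ranges
    that partition the record.  ``loading_slope`` is the least-squares
    stiffness (N/um) of the loading branch before the first detected event;
    ``trigger_index`` lists samples where the rolling slope crossed the
    machine's unload threshold.
    """

    record: BendTestRecord
    segments: list[tuple[str, int, int]]
    loading_slope: float
    trigger_index: np.ndarray

    def __post_init__(self) -> None:
        if not self.loading_slope > 0:
            raise ValidationError("loading slope must be positive")


def _rolling_slope(displ: np.ndarray, load: np.ndarray, window: int) -> np.ndarray:
    """Least-squares slope dP/ddelta over the trailing ``window`` points.

    Entry i covers samples [i-window+1, i]; the first window-1 entries are NaN.
    """
    n = len(displ)
    out = np.full(n, np.nan)
    if n < window:
        return out
    # running first/second moments for O(n) sliding least squares
    x = displ
    y = load
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    i = np.arange(window - 1, n)
    lo, hi = i - window + 1, i + 1
    sx = cs[hi] - cs[lo]
    sy = cy[hi] - cy[lo]
    sxx = cxx[hi] - cxx[lo]
    sxy = cxy[hi] - cxy[lo]
    den = window * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        out[i] = np.where(np.abs(den) > 0, (window * sxy - sx * sy) / den, np.nan)
    return out


def segment_record(rec: BendTestRecord, cfg: FractureConfig | None = None) -> SegmentedRecord:
    """Partition a bend record and estimate the initial loading slope.

    Mirrors the testing machine's control logic: loads at/below the preload
    threshold (2 N) form the preload; displacement reversals mark partial
    unloads; a rolling straight-line slope over the configured window
    (default -0.45 N/um over 15 points) flags crack-growth triggers.

    The loading slope is a least-squares fit on the loading branch before the
    first trigger, restricted to 20-80 % of the load at that trigger (the
    whole-record maximum if no trigger fired) to avoid the preload toe and
    near-event nonlinearity.
    """
    cfg = cfg or FractureConfig()
    n = len(rec)
    if n < cfg.slope_window:
        raise ValidationError(
            f"record of length {n} is shorter than the slope window {cfg.slope_window}")

    # preload: leading samples at or below the preload force
    i_pre = 0
    while i_pre < n and rec.load_n[i_pre] <= cfg.preload_n:
        i_pre += 1

    slope = _rolling_slope(rec.displ_um, rec.load_n, cfg.slope_window)
    triggered = np.flatnonzero(slope <= cfg.unload_slope_threshold)
    triggered = triggered[triggered >= i_pre]

    # loading/unloading from displacement direction
    kinds = np.where(np.diff(rec.displ_um, prepend=rec.displ_um[0] - 1.0) < 0,
                     "unloading", "loading")
    segments: list[tuple[str, int, int]] = []
    if i_pre > 0:
        segments.append(("preload", 0, i_pre))
    start = i_pre
    for i in range(i_pre + 1, n):
        if kinds[i] != kinds[start]:
            segments.append((str(kinds[start]), start, i))
            start = i
    if start < n:
        segments.append((str(kinds[start]), start, n))

    first_event = int(triggered[0]) if len(triggered) else n - 1
    p_ref = rec.load_n[first_event] if len(triggered) else float(np.max(rec.load_n))
    lo, hi = cfg.slope_fit_range
    sel = np.arange(i_pre, first_event + 1)
    sel = sel[(rec.load_n[sel] >= lo * p_ref) & (rec.load_n[sel] <= hi * p_ref)]
    if len(sel) < 2:
        raise ValidationError("too few points to estimate the loading slope")
    k = np.polyfit(rec.displ_um[sel], rec.load_n[sel], 1)[0]
    return SegmentedRecord(rec, segments, float(k), triggered)


def plastic_area(seg: SegmentedRecord, event_i: int, event_j: int) -> float:
    """Plastic area (J) between two crack-growth events.

    Trapezoidal integral of P ddelta between the event samples plus the
    triangle correction for the two parallel elastic lines (slope = initial
    loading slope) through the event points::

        A_pl = int_{d_i}^{d_j} P ddelta + (P_i^2 - P_j^2) / (2 k)

    which is the area enclosed between the curve, the two parallel lines and
    the zero-load axis.  Exactly zero when both events lie on one elastic
    line; equals P0 * d_p for a parallelogram offset by a pure plastic
    displacement d_p at constant load P0.  Negative round-off is clipped to 0.
    """
    k = seg.loading_slope
    if not k > 0:
        raise ValidationError("loading slope must be positive")
    if not 0 <= event_i <= event_j < len(seg.record):
        raise ValidationError("event indices must be ordered and inside the record")
    p = seg.record.load_n[event_i:event_j + 1]
    d = seg.record.displ_um[event_i:event_j + 1]
    area_num = np.trapezoid(p, d)                      # N*um
    tri = (p[0] ** 2 - p[-1] ** 2) / (2.0 * k)         # N*um
    return max(float(area_num + tri), 0.0) * 1e-6      # -> J


# --------------------------------------------------------------------------
# R-curve assembly and fitting
# --------------------------------------------------------------------------

@dataclass
class RCurveFit:
    """Ordinary least-squares polynomial fit of J(delta_a) with a pointwise
    confidence band from the regression covariance (t-distribution)."""

    coeffs: np.ndarray          # ascending: c0, c1, c2, ...
    cov: np.ndarray
    dof: int
    sigma2: float
    ci_level: float

    def predict(self, delta_a_um) -> np.ndarray:
        x = np.asarray(delta_a_um, dtype=float)
        return np.polynomial.polynomial.polyval(x, self.coeffs)

    def ci_halfwidth(self, delta_a_um) -> np.ndarray:
        """Half-width of the pointwise CI of the fitted mean at delta_a."""
        x = np.atleast_1d(np.asarray(delta_a_um, dtype=float))
        design = np.vander(x, len(self.coeffs), increasing=True)
        var = np.einsum("ij,jk,ik->i", design, self.cov, design)
        tval = sps.t.ppf(0.5 + self.ci_level / 2.0, self.dof)
        out = tval * np.sqrt(var)
        return out if np.ndim(delta_a_um) else float(out[0])


@dataclass
class RCurve:
    """Fracture-resistance curve: per-event crack extension and J values.

    ``j_tot = j_el + j_pl`` holds exactly at every event.
    """

    delta_a_um: np.ndarray
    j_el: np.ndarray
    j_pl: np.ndarray
    j_tot: np.ndarray
    event_index: np.ndarray
    fit: RCurveFit | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.delta_a_um) < 0):
            raise ValidationError("crack extension must be non-decreasing")
        if np.any(self.j_el < 0) or np.any(self.j_pl < 0):
            raise ValidationError("J components must be non-negative")


def build_r_curve(rec: BendTestRecord, cracks: CrackLengthTable,
                  geom: SpecimenGeometry, mat: MaterialConstants,
                  cfg: FractureConfig | None = None,
                  seg: SegmentedRecord | None = None) -> RCurve:
    """Assemble the elastic/plastic/total J R-curve for one specimen.

    For each crack-table event i the elastic part is evaluated from the
    recorded load at that sample and the instantaneous crack length a_i
    (``cfg.jel_crack_length = "initial"`` switches to a0).  The plastic part
    is the cumulative sum of incremental plastic areas between successive
    events, each normalized by the ligament at the start of its increment;
    the increment before the first event starts at the end of the preload
    with a = a0.
    """
    cfg = cfg or FractureConfig()
    if len(cracks) == 0:
        raise ValidationError("crack table is empty: no events to evaluate")
    if seg is None:
        seg = segment_record(rec, cfg)

    # de-duplicate shared indices, keeping the larger crack length
    idx, a_um = [], []
    for i, a in zip(cracks.index, cracks.a_um):
        if idx and i == idx[-1]:
            a_um[-1] = max(a_um[-1], a)
        else:
            idx.append(int(i))
            a_um.append(float(a))
    idx_arr = np.array(idx)
    a_arr = np.array(a_um)
    if np.any(idx_arr >= len(rec)) or np.any(idx_arr < 0):
        raise ValidationError("crack table indices must lie inside the record")
    preload_end = seg.segments[0][2] if seg.segments and seg.segments[0][0] == "preload" else 0
    if idx_arr[0] < preload_end:
        raise ValidationError("first crack event precedes the end of the preload")

    a0_um = geom.a0 * 1e3
    if np.any(a_arr < a0_um):
        raise ValidationError("crack lengths must not be shorter than the notch a0")
    delta_a = a_arr - a0_um

    b_m = geom.B * 1e-3
    j_el = np.empty(len(idx_arr))
    j_pl = np.empty(len(idx_arr))
    prev_idx = preload_end
    prev_a_mm = geom.a0
    acc = 0.0
    for n, (i, a) in enumerate(zip(idx_arr, a_arr)):
        a_mm = a / 1e3 if cfg.jel_crack_length == "instantaneous" else geom.a0
        k_i = stress_intensity(float(rec.load_n[i]), geom, a_mm)
        j_el[n] = elastic_j(k_i, mat)
        d_apl = plastic_area(seg, prev_idx, int(i))
        acc += 2.0 * d_apl / (b_m * (geom.W - prev_a_mm) * 1e-3)
        j_pl[n] = acc
        prev_idx, prev_a_mm = int(i), a / 1e3
    return RCurve(delta_a, j_el, j_pl, j_el + j_pl, idx_arr)


def fit_r_curve(delta_a_um, j, degree: int = 2, ci: float = 0.95) -> RCurveFit:
    """Least-squares polynomial fit of J against crack extension.

    Plain OLS of the configured degree (default second order, the standard
    rising-R-curve description) with a pointwise confidence band computed
    from the coefficient covariance and Student's t quantile.  Requires at
    least ``degree + 2`` points so the residual variance is estimable.
    """
    x = np.asarray(delta_a_um, dtype=float)
    y = np.asarray(j, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("delta_a and J must be equal-length 1D arrays")
    n, p = len(x), degree + 1
    if n < p + 1:
        raise ValidationError(f"need at least {p + 1} points for a degree-{degree} fit")
    design = np.vander(x, p, increasing=True)
    coeffs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coeffs
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(design.T @ design)
    return RCurveFit(coeffs=coeffs, cov=sigma2 * xtx_inv, dof=dof,
                     sigma2=sigma2, ci_level=ci)
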
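"""Oliver-Pharr analysis of Berkovich nanoindentation curves.

Hardness H and Young's modulus E are extracted from the unloading branch of
a depth-sensing indentation test:

* fit ``P = alpha (h - h_f)^m`` to the upper part of the unloading curve
  (50-90 % of P_max by default);
* unloading stiffness ``S = dP/dh`` evaluated at h_max;
* contact depth ``h_c = h_max - epsilon P_max / S`` (epsilon = 0.75);
* ideal Berkovich contact area ``A = 24.56 h_c^2``;
* ``H = P_max / A``;
* reduced modulus ``E_r = sqrt(pi) S / (2 beta sqrt(A))`` and
  ``1/E_r = (1 - nu^2)/E + (1 - nu_i^2)/E_i`` with diamond indenter
  constants, solved for the sample modulus E.

Continuous-stiffness-measurement (CSM) curves carry a stiffness channel
S(h); the same relations then yield depth profiles E(h), H(h), summarized
over a configurable depth window (default 1000-2000 nm, past the
surface-roughness regime).

Boundary units: depth nm, load mN, stiffness N/m; results in GPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import IndentConfig
from .errors import FitFlag, ValidationError

__all__ = ["IndentationCurve", "IndentationResult", "oliver_pharr",
           "csm_profile", "specimen_summary"]


@dataclass
class IndentationCurve:
    """Load-depth record of one indent, optional CSM stiffness channel."""

    depth_nm: np.ndarray
    load_mn: np.ndarray
    stiffness_n_per_m: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth_nm = np.asarray(self.depth_nm, dtype=float)
        self.load_mn = np.asarray(self.load_mn, dtype=float)
        if self.depth_nm.shape != self.load_mn.shape:
            raise ValidationError("depth and load must be equal length")
        if np.any(self.depth_nm < 0):
            raise ValidationError("depths must be non-negative")
        if self.stiffness_n_per_m is not None:
            self.stiffness_n_per_m = np.asarray(self.stiffness_n_per_m, dtype=float)
            if self.stiffness_n_per_m.shape != self.depth_nm.shape:
                raise ValidationError("stiffness channel must match the curve length")

    def branches(self) -> tuple[slice, slice]:
        """(loading, unloading) index ranges, split at maximum depth."""
        i_max = int(np.argmax(self.depth_nm))
        return slice(0, i_max + 1), slice(i_max, len(self.depth_nm))


@dataclass
class IndentationResult:
    """Per-indent Oliver-Pharr outputs."""

    e_gpa: float
    h_gpa: float
    h_c_nm: float
    stiffness_n_per_m: float
    p_max_mn: float
    h_max_nm: float
    m_exponent: float | None = None

    def __post_init__(self) -> None:
        if not (self.e_gpa > 0 and self.h_gpa > 0):
            raise ValidationError("E and H must be positive")
        if not self.h_c_nm < self.h_max_nm:
            raise ValidationError("contact depth must be below maximum depth")


def _reduced_to_sample_modulus(e_r_pa: float, cfg: IndentConfig) -> float:
    inv = 1.0 / e_r_pa - (1.0 - cfg.nu_indenter**2) / (cfg.e_indenter_gpa * 1e9)
    if inv <= 0:
        raise FitFlag("reduced modulus exceeds the indenter stiffness limit")
    return (1.0 - cfg.nu_sample**2) / inv


def _e_h_from_contact(p_n: float, h_nm: float, s_n_per_m: float,
                      cfg: IndentConfig) -> tuple[float, float, float]:
    """(E GPa, H GPa, h_c nm) from load, depth and stiffness at one point."""
    h_m = h_nm * 1e-9
    h_c_m = h_m - cfg.epsilon * p_n / s_n_per_m
    if h_c_m <= 0:
        raise FitFlag("non-positive contact depth")
    area_m2 = cfg.area_coeff * h_c_m**2
    hardness = p_n / area_m2
    e_r = math.sqrt(math.pi) * s_n_per_m / (2.0 * cfg.beta * math.sqrt(area_m2))
    e_sample = _reduced_to_sample_modulus(e_r, cfg)
    return e_sample / 1e9, hardness / 1e9, h_c_m * 1e9


def oliver_pharr(curve: IndentationCurve,
                 cfg: IndentConfig | None = None) -> IndentationResult:
    """End-of-test Oliver-Pharr analysis of a single indent.

    The unloading branch needs at least 10 points; the power-law fit is
    restricted to loads between 50 % and 90 % of P_max (configurable) and
    the stiffness is the fitted dP/dh evaluated at the maximum depth.  An
    unloading exponent outside [1, 2.5] or a non-convergent fit flags the
    indent via :class:`bonequal.errors.FitFlag`.
    """
    cfg = cfg or IndentConfig()
    _, unload = curve.branches()
    h_u = curve.depth_nm[unload]
    p_u = curve.load_mn[unload]
    if len(h_u) < 10:
        raise ValidationError("unloading branch must contain at least 10 points")
    p_max = float(np.max(curve.load_mn))
    h_max = float(np.max(curve.depth_nm))
    lo, hi = cfg.unload_fit_range
    sel = (p_u >= lo * p_max) & (p_u <= hi * p_max)
    if sel.sum() < 4:
        raise ValidationError("too few unloading points inside the fit window")
    h_fit, p_fit = h_u[sel], p_u[sel]

    def power(h, alpha, h_f, m):
        return alpha * np.clip(h - h_f, 1e-12, None) ** m

    p0 = (p_max / max(h_max - h_fit.min(), 1.0) ** 1.5, 0.8 * h_fit.min(), 1.5)
    try:
        popt, _ = curve_fit(power, h_fit, p_fit, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitFlag(f"unloading fit did not converge: {exc}") from exc
    alpha, h_f, m = popt
    if not (cfg.m_bounds[0] <= m <= cfg.m_bounds[1]) or h_f >= h_max:
        raise FitFlag(f"unloading exponent m={m:.3f} or residual depth out of range")

    # S = dP/dh at h_max, converted from mN/nm to N/m (1 mN/nm = 1e6 N/m)
    s_mn_per_nm = alpha * m * (h_max - h_f) ** (m - 1.0)
    s_n_per_m = s_mn_per_nm * 1e6
    e_gpa, h_gpa, h_c_nm = _e_h_from_contact(p_max * 1e-3, h_max, s_n_per_m, cfg)
    return IndentationResult(e_gpa=e_gpa, h_gpa=h_gpa, h_c_nm=h_c_nm,
                             stiffness_n_per_m=s_n_per_m, p_max_mn=p_max,
                             h_max_nm=h_max, m_exponent=float(m))


def csm_profile(curve: IndentationCurve, cfg: IndentConfig | None = None
                ) -> tuple[pd.DataFrame, IndentationResult]:
    """Depth-resolved E(h), H(h) from the CSM stiffness channel.

    Every loading-branch sample with positive load, depth and stiffness is
    converted through the same contact relations as the end-of-test
    analysis.  The returned summary averages E and H over the configured
    depth window.
    """
    cfg = cfg or IndentConfig()
    if curve.stiffness_n_per_m is None:
        raise ValidationError("curve has no CSM stiffness channel")
    load_sl, _ = curve.branches()
    rows = []
    for h, p, s in zip(curve.depth_nm[load_sl], curve.load_mn[load_sl],
                       curve.stiffness_n_per_m[load_sl]):
        if h <= 0 or p <= 0 or s <= 0:
            continue
        try:
            e, hard, h_c = _e_h_from_contact(p * 1e-3, h, s, cfg)
        except FitFlag:
            continue
        rows.append({"depth_nm": h, "E_GPa": e, "H_GPa": hard, "h_c_nm": h_c,
                     "S_N_per_m": s, "P_mN": p})
    df = pd.DataFrame(rows)
    lo, hi = cfg.csm_window_nm
    win = df[(df.depth_nm >= lo) & (df.depth_nm <= hi)]
    if win.empty:
        raise ValidationError("no CSM samples inside the averaging window")
    last = win.iloc[-1]
    summary = IndentationResult(
        e_gpa=float(win.E_GPa.mean()), h_gpa=float(win.H_GPa.mean()),
        h_c_nm=float(last.h_c_nm), stiffness_n_per_m=float(last.S_N_per_m),
        p_max_mn=float(df.P_mN.max()), h_max_nm=float(df.depth_nm.max()))
    return df, summary


def specimen_summary(results: list[IndentationResult]) -> pd.DataFrame:
    """Mean +- SD of E and H over the indents of one specimen."""
    if not results:
        raise ValidationError("no indents to summarize")
    e = np.array([r.e_gpa for r in results])
    h = np.array([r.h_gpa for r in results])
    ddof = 1 if len(results) > 1 else 0
    return pd.DataFrame({
        "parameter": ["E_GPa", "H_GPa"],
        "mean": [e.mean(), h.mean()],
        "sd": [e.std(ddof=ddof), h.std(ddof=ddof)],
        "n": [len(results)] * 2,
    })
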
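"""Analysis configuration.

Every tunable of the pipeline lives here with its default.  Units are fixed at
the boundary (N, um, mm, GPa, cm^-1, wt%); conversion to SI happens once,
inside the computations that need it.

Defaults mirror the acquisition/testing protocol the pipeline targets:

* bend testing: 2 N preload, partial-unload trigger at -0.45 N/um over a
  15-point rolling window, 1 Hz sampling;
* Raman: band windows around the phosphate nu1 (962 cm^-1), carbonate
  (1070 cm^-1), amide III (1215-1365 cm^-1) and amide I (1600-1720 cm^-1)
  envelopes, amide I decomposed into four Gaussian subpeaks;
* qBEI: carbon/aluminum standards anchored at gray 25/225 with a linear
  gray -> calcium-wt% relation (osteoid ~ 0 wt%, pure hydroxyapatite
  ~ 39.86 wt% at gray 255);
* nanoindentation: Berkovich/diamond constants for the Oliver-Pharr
  inversion;
* statistics: alpha = 0.05, Lilliefors-gated t / Mann-Whitney U choice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError


@dataclass
class FractureConfig:
    """Bend-test segmentation and R-curve fitting parameters."""

    preload_n: float = 2.0              # N; loads at/below this are preload
    unload_slope_threshold: float = -0.45  # N/um; machine unload trigger
    slope_window: int = 15              # points in the rolling slope fit
    slope_fit_range: tuple[float, float] = (0.2, 0.8)  # fraction of first-event load
    fit_degree: int = 2                 # R-curve polynomial degree
    ci_level: float = 0.95              # pointwise confidence band level
    jel_crack_length: str = "instantaneous"  # or "initial": a used for K at each event

    def __post_init__(self) -> None:
        if self.slope_window < 2:
            raise ValidationError("slope_window must be >= 2")
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError("ci_level must lie in (0, 1)")
        if self.jel_crack_length not in ("instantaneous", "initial"):
            raise ValidationError("jel_crack_length must be 'instantaneous' or 'initial'")


@dataclass
class RamanConfig:
    """Band windows (cm^-1) and estimator settings for the matrix indices."""

    phosphate_region: tuple[float, float] = (910.0, 990.0)
    phosphate_center: float = 962.0
    carbonate_region: tuple[float, float] = (1040.0, 1100.0)
    carbonate_center: float = 1070.0
    amide_iii_region: tuple[float, float] = (1215.0, 1365.0)
    amide_i_region: tuple[float, float] = (1600.0, 1720.0)
    # four-Gaussian amide I decomposition; only 1666/1685 enter the subpeak ratio
    amide_i_subpeak_centers: tuple[float, ...] = (1610.0, 1640.0, 1666.0, 1685.0)
    amide_i_center_bound: float = 8.0   # cm^-1 allowed shift of each subpeak center
    baseline_anchor_channels: int = 5   # channels averaged at each region edge
    cosmic_ray_z_threshold: float = 8.0
    use_heights: bool = False           # peak heights instead of areas for 962/1070

    def __post_init__(self) -> None:
        if self.baseline_anchor_channels < 1:
            raise ValidationError("baseline_anchor_channels must be >= 1")


@dataclass
class QbeiConfig:
    """Gray-level calibration anchors and BMDD histogram settings."""

    anchor_carbon: float = 25.0         # reference gray of the carbon standard
    anchor_aluminum: float = 225.0      # reference gray of the aluminum standard
    ca_slope: float = 0.17330           # wt% per gray level (Roschger convention)
    ca_intercept: float = -4.3325       # wt% at gray 0; gray 255 -> 39.86 wt%
    bin_width: float = 0.1              # wt% histogram bin
    min_pixels: int = 1000
    cawidth_estimator: str = "sd"       # "sd" (textual definition) or "fwhm"
    mask_min_component_px: int = 50     # small-object removal in the bone mask

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be > 0")
        if self.cawidth_estimator not in ("sd", "fwhm"):
            raise ValidationError("cawidth_estimator must be 'sd' or 'fwhm'")


@dataclass
class IndentConfig:
    """Berkovich tip / Oliver-Pharr constants (standard diamond-tip defaults)."""

    nu_sample: float = 0.3
    e_indenter_gpa: float = 1141.0
    nu_indenter: float = 0.07
    beta: float = 1.034                 # tip-geometry stiffness correction
    epsilon: float = 0.75               # sink-in factor for contact depth
    area_coeff: float = 24.56           # ideal Berkovich: A = 24.56 h_c^2
    unload_fit_range: tuple[float, float] = (0.5, 0.9)  # fraction of P_max fitted
    csm_window_nm: tuple[float, float] = (1000.0, 2000.0)  # depth-average window
    m_bounds: tuple[float, float] = (1.0, 2.5)  # acceptable unloading exponents


@dataclass
class StatsConfig:
    alpha: float = 0.05
    normality: str = "lilliefors"       # or "ks" (raw KS against fitted normal)
    force_test: str | None = None       # None | "t" | "mwu"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.normality not in ("lilliefors", "ks"):
            raise ValidationError("normality must be 'lilliefors' or 'ks'")
        if self.force_test not in (None, "t", "mwu"):
            raise ValidationError("force_test must be None, 't' or 'mwu'")


@dataclass
class AnalysisConfig:
    """Top-level configuration: one sub-config per pipeline stage plus RNG seed."""

    fracture: FractureConfig = field(default_factory=FractureConfig)
    raman: RamanConfig = field(default_factory=RamanConfig)
    qbei: QbeiConfig = field(default_factory=QbeiConfig)
    indent: IndentConfig = field(default_factory=IndentConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: dict) -> "AnalysisConfig":
        """Build a config from a nested mapping; unknown keys are rejected."""
        cfg = cls()
        for section, values in data.items():
            if section == "seed":
                cfg.seed = int(values)
                continue
            if not hasattr(cfg, section):
                raise ValidationError(f"unknown config section {section!r}")
            sub = getattr(cfg, section)
            if not dataclasses.is_dataclass(sub):
                raise ValidationError(f"config section {section!r} is not a table")
            fields = {f.name for f in dataclasses.fields(sub)}
            unknown = set(values) - fields
            if unknown:
                raise ValidationError(f"unknown keys in [{section}]: {sorted(unknown)}")
            coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in values.items()}
            setattr(cfg, section, dataclasses.replace(sub, **coerced))
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Read a TOML or YAML config file (decided by extension)."""
        path = Path(path)
        if path.suffix.lower() == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            import yaml

            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)
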
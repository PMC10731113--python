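"""Shared domain types and file I/O.

Specimens are single-edge-notched bend (SENB) beams: thickness ``B``, height
``W``, length ``L``, tested on a support span ``S`` with a starter notch of
length ``a0`` cut into one face.  The remaining ligament is ``b = W - a``.

All CSV dialects are comma-separated with a mandatory header row, ``.``
decimal separator and UTF-8 encoding.  Units are fixed at the file boundary:
seconds, newtons, micrometres for bend records; micrometres for crack
lengths; cm^-1 for Raman axes; millimetres/GPa in the geometry and material
tables.  Every reader/writer pair is a lossless round trip on valid input,
and every validation failure raises a typed error from :mod:`bonequal.errors`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError

__all__ = [
    "SpecimenGeometry",
    "MaterialConstants",
    "BendTestRecord",
    "CrackLengthTable",
    "read_bend_record",
    "write_bend_record",
    "read_crack_table",
    "write_crack_table",
    "read_spectrum",
    "write_spectrum",
    "read_map",
    "write_map",
    "read_tiff_image",
    "write_tiff_image",
    "read_volume",
    "write_volume",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecimenGeometry:
    """SENB beam dimensions in millimetres.

    Parameters
    ----------
    B, W, L :
        Beam thickness, height and length (mm).
    S :
        Support span of the three-point bend fixture (mm); must fit inside L.
    a0 :
        Initial notch length measured from the notched face (mm); must be
        smaller than W.
    """

    B: float
    W: float
    L: float
    S: float
    a0: float

    def __post_init__(self) -> None:
        for name in ("B", "W", "L", "S", "a0"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"geometry field {name} must be > 0")
        if not self.a0 < self.W:
            raise ValidationError("initial notch a0 must be smaller than height W")
        if not self.S < self.L:
            raise ValidationError("support span S must be smaller than length L")

    def ligament_mm(self, a_mm: float | np.ndarray) -> float | np.ndarray:
        """Remaining ligament b = W - a (mm)."""
        return self.W - a_mm

    def ligament_fraction_pct(self, delta_a_um: float) -> float:
        """Crack extension as a percentage of the initial ligament b = W - a0."""
        return 100.0 * (delta_a_um / 1000.0) / (self.W - self.a0)


@dataclass(frozen=True)
class MaterialConstants:
    """Isotropic elastic constants: modulus E (GPa) and Poisson ratio nu."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValidationError("elastic modulus E must be > 0")
        if not 0.0 <= self.nu < 0.5:
            raise ValidationError("Poisson ratio nu must lie in [0, 0.5)")


@dataclass
class BendTestRecord:
    """A 1 Hz load-displacement record from a notched-beam bend test.

    Arrays are equal-length; time is strictly increasing; loads are
    non-negative.  Displacements are raw machine values (they decrease during
    partial unloads)."""

    time_s: np.ndarray
    load_n: np.ndarray
    displ_um: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.load_n = np.asarray(self.load_n, dtype=float)
        self.displ_um = np.asarray(self.displ_um, dtype=float)
        n = len(self.time_s)
        if len(self.load_n) != n or len(self.displ_um) != n:
            raise ValidationError("time, load and displacement must be equal length")
        if n and not np.all(np.diff(self.time_s) > 0):
            raise ValidationError("time must be strictly increasing")
        if n and np.min(self.load_n) < 0:
            raise ValidationError("loads must be non-negative")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class CrackLengthTable:
    """Crack lengths digitized per growth increment.

    ``index`` points into the bend record (strictly increasing); ``a_um`` is
    the total crack length (notch + extension) measured from the notched
    face, non-decreasing and below the beam height."""

    index: np.ndarray
    a_um: np.ndarray
    w_um: float | None = None  # beam height, if known, for the a < W check

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=int)
        self.a_um = np.asarray(self.a_um, dtype=float)
        if len(self.index) != len(self.a_um):
            raise ValidationError("crack table columns must be equal length")
        if len(self.index) > 1:
            if not np.all(np.diff(self.index) > 0):
                raise ValidationError("crack table indices must be strictly increasing")
            if np.any(np.diff(self.a_um) < 0):
                raise ValidationError("crack lengths must be non-decreasing")
        if self.w_um is not None and len(self.a_um) and np.max(self.a_um) >= self.w_um:
            raise ValidationError("crack lengths must stay below the beam height W")

    def __len__(self) -> int:
        return len(self.index)


# --------------------------------------------------------------------------
# CSV readers / writers
# --------------------------------------------------------------------------

def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_bend_record(path: str | Path) -> BendTestRecord:
    """Read a bend record CSV with columns ``time_s, load_N, displ_um``."""
    df = _read_csv(path, ["time_s", "load_N", "displ_um"])
    return BendTestRecord(df["time_s"].to_numpy(), df["load_N"].to_numpy(),
                          df["displ_um"].to_numpy())


def write_bend_record(rec: BendTestRecord, path: str | Path) -> None:
    pd.DataFrame({"time_s": rec.time_s, "load_N": rec.load_n,
                  "displ_um": rec.displ_um}).to_csv(path, index=False, float_format="%.17g")


def read_crack_table(path: str | Path, w_um: float | None = None) -> CrackLengthTable:
    """Read a crack-length table CSV with columns ``index, a_um``."""
    df = _read_csv(path, ["index", "a_um"])
    return CrackLengthTable(df["index"].to_numpy(), df["a_um"].to_numpy(), w_um=w_um)


def write_crack_table(table: CrackLengthTable, path: str | Path) -> None:
    pd.DataFrame({"index": table.index, "a_um": table.a_um}).to_csv(path, index=False, float_format="%.17g")


def read_spectrum(path: str | Path):
    """Read a two-column spectrum CSV (``wavenumber_cm1, intensity``)."""
    from .raman import RamanSpectrum

    df = _read_csv(path, ["wavenumber_cm1", "intensity"])
    return RamanSpectrum(df["wavenumber_cm1"].to_numpy(), df["intensity"].to_numpy())


def write_spectrum(spec, path: str | Path) -> None:
    pd.DataFrame({"wavenumber_cm1": spec.wavenumber,
                  "intensity": spec.intensity}).to_csv(path, index=False, float_format="%.17g")


def read_map(path: str | Path, step_um: float):
    """Read a wide-format spectral map CSV.

    Columns are ``x_um, y_um`` followed by one column per wavenumber (the
    header carries the numeric axis values).  All rows share the axis.
    """
    from .raman import RamanMap

    df = _read_csv(path, ["x_um", "y_um"])
    chan_cols = [c for c in df.columns if c not in ("x_um", "y_um")]
    if not chan_cols:
        raise FormatError(f"{path}: map has no spectral channels")
    try:
        axis = np.array([float(c) for c in chan_cols])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavenumber column header") from exc
    return RamanMap(
        wavenumber=axis,
        intensities=df[chan_cols].to_numpy(dtype=float),
        x_um=df["x_um"].to_numpy(dtype=float),
        y_um=df["y_um"].to_numpy(dtype=float),
        step_um=step_um,
    )


def write_map(rmap, path: str | Path) -> None:
    df = pd.DataFrame(rmap.intensities,
                      columns=[repr(float(w)) for w in rmap.wavenumber])
    df.insert(0, "y_um", rmap.y_um)
    df.insert(0, "x_um", rmap.x_um)
    df.to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# TIFF images and volumes
# --------------------------------------------------------------------------

def read_tiff_image(path: str | Path) -> np.ndarray:
    """Read a single grayscale TIFF image (2D, 8- or 16-bit)."""
    try:
        img = tifffile.imread(path)
    except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
        raise FormatError(f"{path}: unreadable TIFF ({exc})") from exc
    if img.ndim != 2:
        raise FormatError(f"{path}: expected a 2D image, got shape {img.shape}")
    return img


def write_tiff_image(img: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, img)


def read_volume(paths: list[str | Path] | str | Path) -> np.ndarray:
    """Read a volume as a multi-page TIFF or an ordered list of slice files.

    All slices must share one shape; the result is a (z, y, x) array.
    """
    if isinstance(paths, (str, Path)):
        try:
            vol = tifffile.imread(paths)
        except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
            raise FormatError(f"{paths}: unreadable TIFF stack ({exc})") from exc
        if vol.ndim == 2:
            vol = vol[None]
        if vol.ndim != 3:
            raise FormatError(f"{paths}: expected a 3D stack, got shape {vol.shape}")
        return vol
    slices = [read_tiff_image(p) for p in paths]
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise FormatError(f"volume slices have mismatched shapes: {sorted(shapes)}")
    return np.stack(slices)


def write_volume(vol: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(vol))
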
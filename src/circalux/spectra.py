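"""Absolute spectral irradiance distributions and SPD file I/O.

A :class:`Spectrum` is a wavelength grid (nm) plus absolute spectral
irradiance (W m^-2 nm^-1).  SPD files are plain delimited text with two
columns (``wavelength_nm``, ``spectral_irradiance_W_m2_nm``); lines starting
with ``#`` are comments, and ``# key: value`` comment lines round-trip as
metadata.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import colorimetry
from .observers import ObserverBundle

__all__ = [
    "Spectrum",
    "read_spd",
    "write_spd",
    "resample",
    "photopic_illuminance",
    "scale_to_illuminance",
    "chromaticity_cct_duv",
    "LUMINOUS_EFFICACY_MAX",
]

#: Maximum luminous efficacy of radiation, lm W^-1 (683 lm/W at 555 nm).
LUMINOUS_EFFICACY_MAX = 683.0

SOURCE_CLASSES = ("incandescent", "fluorescent", "led", "daylight", "other")


@dataclass(frozen=True)
class Spectrum:
    """Absolute spectral irradiance on a strictly increasing grid."""

    id: str
    grid: np.ndarray
    irradiance: np.ndarray
    source_class: str = "other"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        irr = np.asarray(self.irradiance, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "irradiance", irr)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("grid must be 1-D with at least 2 samples")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if irr.shape != grid.shape:
            raise ValueError("irradiance/grid shape mismatch")
        neg = np.where(irr < 0)[0]
        if neg.size:
            i = int(neg[0])
            raise ValueError(
                f"negative irradiance at row {i} (lambda = {grid[i]:g} nm)"
            )
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(f"unknown source_class {self.source_class!r}")

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, irradiance=self.irradiance * factor)


def read_spd(path) -> Spectrum:
    """Parse a two-column SPD text file into a :class:`Spectrum`."""
    path = Path(path)
    meta: dict = {}
    wl: list[float] = []
    irr: list[float] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*([\w.-]+)\s*:\s*(.*)$", line)
            if m:
                meta[m.group(1)] = m.group(2)
            continue
        tokens = re.split(r"[,\s;]+", line)
        if len(tokens) < 2:
            raise ValueError(f"{path}: row {lineno}: expected two columns")
        try:
            w, e = float(tokens[0]), float(tokens[1])
        except ValueError as exc:
            # tolerate a single non-numeric header row
            if lineno == 1 or (not wl and not meta.get("_seen_data")):
                continue
            raise ValueError(f"{path}: row {lineno}: non-numeric data") from exc
        if e < 0:
            raise ValueError(
                f"{path}: row {lineno}: negative irradiance {e:g} at {w:g} nm"
            )
        wl.append(w)
        irr.append(e)
    if len(wl) < 2:
        raise ValueError(f"{path}: fewer than two data rows")
    wl_arr = np.asarray(wl)
    if np.any(np.diff(wl_arr) <= 0):
        i = int(np.where(np.diff(wl_arr) <= 0)[0][0])
        raise ValueError(
            f"{path}: wavelengths not strictly increasing near {wl_arr[i]:g} nm"
        )
    source_class = meta.pop("source_class", "other")
    return Spectrum(
        id=meta.pop("id", path.stem),
        grid=wl_arr,
        irradiance=np.asarray(irr),
        source_class=source_class if source_class in SOURCE_CLASSES else "other",
        metadata=meta,
    )


def write_spd(spectrum: Spectrum, path) -> None:
    """Write a :class:`Spectrum` as delimited text (6 significant digits)."""
    path = Path(path)
    lines = [
        "# circalux SPD file",
        f"# id: {spectrum.id}",
        f"# source_class: {spectrum.source_class}",
    ]
    for key, value in spectrum.metadata.items():
        lines.append(f"# {key}: {value}")
    lines.append("# wavelength_nm, spectral_irradiance_W_m2_nm")
    for w, e in zip(spectrum.grid, spectrum.irradiance):
        lines.append(f"{w:g},{e:.6g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``grid``; zero outside the source support."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("target grid is empty")
    if grid[0] < 360.0 or grid[-1] > 830.0:
        raise ValueError("target grid must lie within [360, 830] nm")
    values = np.interp(grid, spectrum.grid, spectrum.irradiance, left=0.0, right=0.0)
    return replace(spectrum, grid=grid, irradiance=values)


def photopic_illuminance(spectrum: Spectrum, bundle: ObserverBundle) -> float:
    """Photopic illuminance 683 * integral(E_lambda V_lambda dlambda), in lx."""
    s = spectrum if np.array_equal(spectrum.grid, bundle.grid) else resample(spectrum, bundle.grid)
    return LUMINOUS_EFFICACY_MAX * float(
        np.trapezoid(s.irradiance * bundle.V.values, bundle.grid)
    )


def scale_to_illuminance(spectrum: Spectrum, target_lx: float, bundle: ObserverBundle) -> Spectrum:
    """Rescale so the photopic illuminance equals ``target_lx``; shape unchanged."""
    if target_lx <= 0:
        raise ValueError("target illuminance must be positive")
    current = photopic_illuminance(spectrum, bundle)
    if current <= 0:
        raise ValueError(
            f"spectrum {spectrum.id!r} has non-positive photopic illuminance"
        )
    return spectrum.scaled(target_lx / current)


def chromaticity_cct_duv(spectrum: Spectrum, bundle: ObserverBundle) -> colorimetry.ChromaticityResult:
    """Chromaticity (x, y, z), CCT and Duv of a spectrum (scale-invariant)."""
    s = spectrum if np.array_equal(spectrum.grid, bundle.grid) else resample(spectrum, bundle.grid)
    return colorimetry.cct_duv(s.irradiance, bundle)
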
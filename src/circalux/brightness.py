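"""Spectral brightness metrics: Fotios-Levermore L_eq, Bullough B2, M_TUD.

All three metrics add short-wavelength (S-cone) and/or melanopsin signals to
the photopic channel to better track perceived brightness of polychromatic
white light.  Signal ratios (S-cone/photopic, melanopsin/photopic) follow the
equal-energy normalization convention: a ratio equals 1 for a spectrally flat
source.  Any other global ratio convention multiplies L_eq by a constant and
shifts M_TUD smoothly, leaving every downstream correlation unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observers import ObserverBundle
from .spectra import Spectrum, photopic_illuminance, resample

__all__ = [
    "BrightnessConstants",
    "leq_fotios",
    "b2_bullough",
    "m_tud",
    "m_tud_from_spectrum",
    "spectrum_ratios",
    "DEFAULT_BRIGHTNESS_CONSTANTS",
]


@dataclass(frozen=True)
class BrightnessConstants:
    """Published constants of the three brightness models."""

    fotios_exponent: float = 0.24
    b2_s_weight: float = 0.6
    b2_mel_weight: float = 0.5
    tud_scale: float = 8.9974
    tud_ev_exp: float = 0.2629
    tud_s_exp: float = 0.074
    tud_g_exp: float = 0.0424
    tud_g_weight: float = 0.5
    tud_offset: float = 1.3307


DEFAULT_BRIGHTNESS_CONSTANTS = BrightnessConstants()


def _on_grid(spectrum: Spectrum, bundle: ObserverBundle) -> np.ndarray:
    s = spectrum if np.array_equal(spectrum.grid, bundle.grid) else resample(spectrum, bundle.grid)
    return s.irradiance


def _ee_ratio(e: np.ndarray, num: np.ndarray, den: np.ndarray, grid: np.ndarray) -> float:
    """Equal-energy-normalized signal ratio: unity for a flat spectrum."""
    n = np.trapezoid(e * num, grid) / np.trapezoid(num, grid)
    d = np.trapezoid(e * den, grid) / np.trapezoid(den, grid)
    return float(n / d)


def spectrum_ratios(spectrum: Spectrum, bundle: ObserverBundle) -> tuple[float, float]:
    """(S-cone/photopic, melanopsin/photopic) ratios of a spectrum, both
    equal-energy normalized."""
    e = _on_grid(spectrum, bundle)
    g = bundle.grid
    s_ratio = _ee_ratio(e, bundle.S_cone.values, bundle.V.values, g)
    mel_ratio = _ee_ratio(e, bundle.M_c.values, bundle.V.values, g)
    return s_ratio, mel_ratio


def leq_fotios(spectrum: Spectrum, bundle: ObserverBundle,
               constants: BrightnessConstants = DEFAULT_BRIGHTNESS_CONSTANTS) -> float:
    """Fotios-Levermore equivalent luminance L_eq = L_v * (S/V)^0.24.

    L_v is represented by the photopic illuminance of the (irradiance) input;
    S/V is the equal-energy-normalized S-cone/photopic ratio, so L_eq = L_v
    for a flat spectrum.
    """
    lv = photopic_illuminance(spectrum, bundle)
    if lv <= 0:
        raise ValueError("L_eq undefined for a zero-luminance spectrum")
    e = _on_grid(spectrum, bundle)
    sv = _ee_ratio(e, bundle.S_cone.values, bundle.V.values, bundle.grid)
    return lv * sv ** constants.fotios_exponent


def b2_bullough(spectrum: Spectrum, bundle: ObserverBundle, g: float = 1.0,
                constants: BrightnessConstants = DEFAULT_BRIGHTNESS_CONSTANTS) -> float:
    """Bullough brightness signal B2 = V + 0.6 g S + 0.5 Mel.

    Each term is the trapezoidal integral of the absolute spectrum against
    the peak-normalized function; ``g`` is the adaptation-dependent S-cone
    multiplier and must be supplied by the caller (default 1.0).
    """
    if g < 0:
        raise ValueError("adaptation factor g must be non-negative")
    e = _on_grid(spectrum, bundle)
    wl = bundle.grid
    v = np.trapezoid(e * bundle.V.values, wl)
    s = np.trapezoid(e * bundle.S_cone.values, wl)
    mel = np.trapezoid(e * bundle.M_c.values, wl)
    return float(v + constants.b2_s_weight * g * s + constants.b2_mel_weight * mel)


def m_tud(ev_lx: float, s_ratio: float, mel_ratio: float,
          constants: BrightnessConstants = DEFAULT_BRIGHTNESS_CONSTANTS) -> float:
    """TU Darmstadt brightness M from illuminance and the two signal ratios.

    M = 8.9974 * [E_v^0.2629 * (S^0.074 + 0.5 * G^0.0424)] - 1.3307 with
    S = s_ratio * E_v and G = mel_ratio * E_v.  This entry path reproduces
    published worked examples directly from printed ratios.
    """
    if ev_lx < 0:
        raise ValueError("illuminance must be non-negative")
    if ev_lx == 0:
        return -constants.tud_offset
    if s_ratio <= 0 or mel_ratio <= 0:
        raise ValueError("signal ratios must be positive for E_v > 0")
    s = s_ratio * ev_lx
    g = mel_ratio * ev_lx
    core = ev_lx ** constants.tud_ev_exp * (
        s ** constants.tud_s_exp + constants.tud_g_weight * g ** constants.tud_g_exp
    )
    return constants.tud_scale * core - constants.tud_offset


def m_tud_from_spectrum(spectrum: Spectrum, bundle: ObserverBundle,
                        constants: BrightnessConstants = DEFAULT_BRIGHTNESS_CONSTANTS) -> float:
    """M_TUD of an absolute spectrum, deriving E_v and the two ratios from it."""
    ev = photopic_illuminance(spectrum, bundle)
    if ev == 0:
        return -constants.tud_offset
    s_ratio, mel_ratio = spectrum_ratios(spectrum, bundle)
    return m_tud(ev, s_ratio, mel_ratio, constants)
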
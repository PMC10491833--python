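"""Non-visual (circadian) metrics: CL_A 1.0/2.0, CS, mEDI, melatonin suppression.

The circadian-light models of Rea et al. combine a melanopsin term with a
blue-versus-yellow (b-y) cone-opponent term and rod terms.  The sign of the
b-y signal selects the model branch: for "warm" spectra (b-y <= 0) only the
melanopsin (plus, in the 2.0 model, a rod) term survives; for "cold" spectra
(b-y > 0) the opponent and second rod terms are added.  Both model versions
are anchored so that CIE illuminant A at 1000 photopic lux gives CL_A = 1000.

The opponent switch is computed with the macular-corrected, peak-normalized
S_c and V_c functions in both versions (see docs/methods.md for why the 1.0
model is not evaluated with unnormalized functions).

CS converts circadian light to predicted fractional nocturnal melatonin
suppression through a logistic function saturating at 0.7; mEDI is the
D65-equivalent melanopic illuminance of CIE S 026; the Gimenez et al.
suppression formula is provided verbatim as printed in its secondary source,
flagged ``as_printed`` (it is internally inconsistent; see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import colorimetry
from .observers import ObserverBundle
from .spectra import Spectrum, resample

__all__ = [
    "CircadianModelConstants",
    "CircadianLightResult",
    "opponent_by",
    "cla_2018",
    "cla_2021",
    "circadian_stimulus",
    "medi",
    "gimenez_suppression",
    "GimenezResult",
    "DEFAULT_CONSTANTS",
]


@dataclass(frozen=True)
class CircadianModelConstants:
    """Published constants of the CL_A / CS model family."""

    norm: float = 1548.0          # illuminant-A anchoring factor
    k: float = 0.2616             # b-y opponent weight
    a_by_2018: float = 0.7        # CL_A 1.0 opponent gain
    a_rod_2018: float = 3.3       # CL_A 1.0 rod gain
    a_by_2021: float = 0.21       # CL_A 2.0 opponent gain
    a_rod1: float = 2.3           # CL_A 2.0 rod gain (both branches)
    a_rod2: float = 1.60          # CL_A 2.0 rod gain (cold branch)
    g1: float = 1.00              # S-cone weight in the first rod denominator
    g2: float = 0.16              # S-cone weight in the second rod denominator
    rod_sat: float = 6.5          # rod saturation constant, W m^-2 (scotopic)
    cs_halfsat: float = 355.7     # CS logistic half-saturation
    cs_exponent: float = 1.1026   # CS logistic exponent
    cs_max: float = 0.7           # CS saturation level


DEFAULT_CONSTANTS = CircadianModelConstants()


@dataclass(frozen=True)
class CircadianLightResult:
    """A CL_A value with branch flag and per-term breakdown.

    ``value == norm * sum(terms.values())`` to within 1e-9; each entry of
    ``terms`` is a signed contribution before the 1548 anchoring factor.
    """

    value: float
    version: str                 # "2018" | "2021"
    branch: str                  # "warm" (b-y <= 0) | "cold" (b-y > 0)
    by_signal: float
    terms: dict = field(default_factory=dict)


def _on_grid(spectrum: Spectrum, bundle: ObserverBundle) -> np.ndarray:
    s = spectrum if np.array_equal(spectrum.grid, bundle.grid) else resample(spectrum, bundle.grid)
    return s.irradiance


def _integral(e: np.ndarray, f: np.ndarray, grid: np.ndarray) -> float:
    return float(np.trapezoid(e * f, grid))


def opponent_by(spectrum: Spectrum, bundle: ObserverBundle, version: str = "2021",
                constants: CircadianModelConstants = DEFAULT_CONSTANTS) -> float:
    """Signed blue-versus-yellow opponent signal of the CL_A models.

    Both versions use the macular-corrected, peak-normalized S_c and V_c:
    b-y = integral(S_c E) - k * integral(V_c E).
    """
    if version not in ("2018", "2021"):
        raise ValueError("version must be '2018' or '2021'")
    e = _on_grid(spectrum, bundle)
    g = bundle.grid
    return _integral(e, bundle.S_c.values, g) - constants.k * _integral(e, bundle.V_c.values, g)


def _rod_saturation(e: np.ndarray, bundle: ObserverBundle,
                    constants: CircadianModelConstants) -> tuple[float, float]:
    """(scotopic irradiance integral, saturation factor 1 - exp(-./RodSat))."""
    vp = _integral(e, bundle.Vprime.values, bundle.grid)
    return vp, -float(np.expm1(-vp / constants.rod_sat))


def cla_2018(spectrum: Spectrum, bundle: ObserverBundle,
             constants: CircadianModelConstants = DEFAULT_CONSTANTS) -> CircadianLightResult:
    """Circadian light CL_A 1.0 (2018 model) for an absolute spectrum.

    Warm branch: norm * integral(M_c E).  Cold branch adds the opponent term
    a_by * (b-y) and subtracts a_rod * (1 - exp(-scotopic/RodSat)).
    """
    e = _on_grid(spectrum, bundle)
    g = bundle.grid
    mel = _integral(e, bundle.M_c.values, g)
    by = opponent_by(spectrum, bundle, "2018", constants)
    terms = {"melanopsin": mel}
    if by > 0:
        branch = "cold"
        _, sat = _rod_saturation(e, bundle, constants)
        terms["opponent"] = constants.a_by_2018 * by
        terms["rod"] = -constants.a_rod_2018 * sat
    else:
        branch = "warm"
    value = constants.norm * sum(terms.values())
    return CircadianLightResult(value=value, version="2018", branch=branch,
                                by_signal=by, terms=terms)


def cla_2021(spectrum: Spectrum, bundle: ObserverBundle,
             constants: CircadianModelConstants = DEFAULT_CONSTANTS) -> CircadianLightResult:
    """Circadian light CL_A 2.0 (2021 model) for an absolute spectrum.

    Both branches subtract a rod term a_rod1 * (scotopic / (V_c + g1 S_c
    weighted integrals)) * (1 - exp(-scotopic/RodSat)); the cold branch adds
    the opponent term a_by * (integral(S_c E) - k * integral(V E / mp)) and
    subtracts a second rod term with g2 in the denominator.
    """
    e = _on_grid(spectrum, bundle)
    g = bundle.grid
    mel = _integral(e, bundle.M_c.values, g)
    vc = _integral(e, bundle.V_c.values, g)
    sc = _integral(e, bundle.S_c.values, g)
    vp, sat = _rod_saturation(e, bundle, constants)
    by = sc - constants.k * vc
    terms = {"melanopsin": mel}
    if vp > 0:
        terms["rod1"] = -constants.a_rod1 * (vp / (vc + constants.g1 * sc)) * sat
    else:
        terms["rod1"] = 0.0
    if by > 0:
        branch = "cold"
        # cold-branch opponent amplitude as printed: k weights int(V E / mp)
        v_over_mp = _integral(e, bundle.V.values / bundle.mp.values, g)
        terms["opponent"] = constants.a_by_2021 * (sc - constants.k * v_over_mp)
        terms["rod2"] = (
            -constants.a_rod2 * (vp / (vc + constants.g2 * sc)) * sat
            if vp > 0 else 0.0
        )
    else:
        branch = "warm"
    value = constants.norm * sum(terms.values())
    return CircadianLightResult(value=value, version="2021", branch=branch,
                                by_signal=by, terms=terms)


def circadian_stimulus(cla: float, t: float = 1.0, f: float = 1.0,
                       constants: CircadianModelConstants = DEFAULT_CONSTANTS) -> float:
    """Circadian stimulus CS from a circadian-light value.

    CS = 0.7 - 0.7 / (1 + (CL_A * t * f / 355.7)^1.1026), with exposure time
    ``t`` in hours and the spatial-distribution factor ``f`` (0.5 superior
    field, 1.0 central field, 2.0 Ganzfeld).  Bounded in [0, 0.7); strictly
    increasing in CL_A * t * f.
    """
    if cla < 0:
        raise ValueError("CL_A must be non-negative")
    if t <= 0:
        raise ValueError("exposure time must be positive")
    if f <= 0:
        raise ValueError("field factor must be positive")
    if f not in (0.5, 1.0, 2.0):
        warnings.warn(
            f"field factor f = {f} is outside the documented set {{0.5, 1.0, 2.0}}",
            stacklevel=2,
        )
    dose = cla * t * f
    if dose == 0.0:
        return 0.0
    return constants.cs_max - constants.cs_max / (
        1.0 + (dose / constants.cs_halfsat) ** constants.cs_exponent
    )


def _melanopic_d65_divisor(bundle: ObserverBundle) -> float:
    """Melanopic irradiance of D65 at 1 photopic lux, cached on the bundle."""
    key = "_melanopic_d65_divisor"
    div = bundle.metadata.get(key)
    if div is None:
        g = bundle.grid
        d65 = colorimetry.d65_spd(g)
        lux = 683.0 * np.trapezoid(d65 * bundle.V.values, g)
        div = float(np.trapezoid(d65 * bundle.s_mel.values, g) / lux)
        bundle.metadata[key] = div
    return div


def medi(spectrum: Spectrum, bundle: ObserverBundle) -> float:
    """Melanopic equivalent daylight (D65) illuminance, lx.

    Melanopic irradiance of the spectrum divided by the melanopic irradiance
    of D65 at one photopic lux; the divisor is computed from the bundled
    tables with the same quadrature, so mEDI(D65 at E lx) = E identically.
    """
    e = _on_grid(spectrum, bundle)
    mel = _integral(e, bundle.s_mel.values, bundle.grid)
    return mel / _melanopic_d65_divisor(bundle)


@dataclass(frozen=True)
class GimenezResult:
    """Melatonin suppression from the Gimenez et al. formula, as printed.

    ``value`` is the signed result of the printed expression; ``magnitude``
    its absolute value in percent.  ``as_printed`` is always True: the
    transcribed formula contradicts its own source's asymptotics (suppression
    should approach 100 % at infinite illuminance but the printed form tends
    to 0), so the output carries a caveat and is excluded from headline
    comparisons.
    """

    value: float
    magnitude: float
    as_printed: bool
    caveat: str


_GIMENEZ_CAVEAT = (
    "formula evaluated verbatim as printed; its large-mEDI limit contradicts "
    "the stated 100 % saturation of the source model - interpret with care"
)


def gimenez_suppression(medi_lx: float, duration_min: float = 60.0,
                        pupil_dilated: int = 0) -> GimenezResult:
    """Nocturnal melatonin suppression (percent) from mEDI, as printed.

    suppression = (0 - 100) / (1 + log10(mEDI * 1e6) / (9.002 - 0.008 * dt
    - 0.462 * dil)), with dt the exposure duration in minutes and dil in
    {0, 1}.
    """
    if medi_lx <= 0:
        raise ValueError("mEDI must be positive")
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    if pupil_dilated not in (0, 1):
        raise ValueError("pupil_dilated must be 0 or 1")
    divisor = 9.002 - 0.008 * duration_min - 0.462 * pupil_dilated
    value = (0.0 - 100.0) / (1.0 + np.log10(medi_lx * 1e6) / divisor)
    return GimenezResult(value=float(value), magnitude=abs(float(value)),
                         as_printed=True, caveat=_GIMENEZ_CAVEAT)
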
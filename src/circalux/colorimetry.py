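"""Chromaticity, CCT/Duv and reference-illuminant generators.

CCT is found by an Ohno-style search: the Planckian locus is pre-sampled in
the CIE 1960 (u, v) diagram at a multiplicative temperature step of 0.04 %
(better than 1 K below 3000 K), the nearest locus point is located by direct
search, and the minimum is refined by parabolic interpolation, giving an
effective resolution well below 1 K.  Duv is the signed (u, v) distance from
the locus, positive above it (v larger than the Planckian v).

The locus is computed with the same bundled colour-matching functions used
for the test spectrum, so a Planckian input is recovered essentially exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observers import ObserverBundle, _load_table

__all__ = [
    "planckian_spd",
    "daylight_spd",
    "d65_spd",
    "tristimulus",
    "chromaticity_xy",
    "uv1960",
    "ChromaticityResult",
    "cct_duv",
]

#: Second radiation constant, nm K.
C2 = 1.4388e7

#: Chromaticity of CIE standard illuminant D65.
D65_XY = (0.31272, 0.32903)

#: |Duv| beyond which a correlated colour temperature is not meaningful.
DUV_VALID_LIMIT = 0.05


def planckian_spd(grid: np.ndarray, temperature: float) -> np.ndarray:
    """Relative Planckian (blackbody) spectral distribution on ``grid`` (nm).

    Normalized to 1 at its in-range maximum; absolute scale is arbitrary.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    wl = np.asarray(grid, dtype=float)
    spd = wl ** -5.0 / np.expm1(C2 / (wl * temperature))
    return spd / spd.max()


def _daylight_m1m2(xd: float, yd: float) -> tuple[float, float]:
    m = 0.0241 + 0.2562 * xd - 0.7341 * yd
    m1 = (-1.3515 - 1.7703 * xd + 5.9114 * yd) / m
    m2 = (0.0300 - 31.4424 * xd + 30.0717 * yd) / m
    return m1, m2


def daylight_chromaticity(cct: float) -> tuple[float, float]:
    """CIE D-series chromaticity (x_D, y_D) for 4000 K <= CCT <= 25000 K."""
    if not 4000.0 <= cct <= 25000.0:
        raise ValueError("D-series CCT must be within [4000, 25000] K")
    t = cct
    if t <= 7000.0:
        xd = 0.244063 + 0.09911e3 / t + 2.9678e6 / t**2 - 4.6070e9 / t**3
    else:
        xd = 0.237040 + 0.24748e3 / t + 1.9018e6 / t**2 - 2.0064e9 / t**3
    yd = -3.000 * xd**2 + 2.870 * xd - 0.275
    return xd, yd


def daylight_spd(grid: np.ndarray, cct: float | None = None,
                 xy: tuple[float, float] | None = None) -> np.ndarray:
    """Relative CIE D-series spectral distribution on ``grid``.

    Either ``cct`` (4000-25000 K) or an explicit daylight-locus chromaticity
    ``xy`` must be given.  Negative reconstruction overshoot (possible at the
    grid edges) is clipped to zero.
    """
    if (cct is None) == (xy is None):
        raise ValueError("give exactly one of cct or xy")
    if xy is None:
        xy = daylight_chromaticity(cct)
    m1, m2 = _daylight_m1m2(*xy)
    table, _ = _load_table("cie_daylight_components.csv")
    wl = np.asarray(grid, dtype=float)
    s0 = np.interp(wl, table[:, 0], table[:, 1], left=0.0, right=0.0)
    s1 = np.interp(wl, table[:, 0], table[:, 2], left=0.0, right=0.0)
    s2 = np.interp(wl, table[:, 0], table[:, 3], left=0.0, right=0.0)
    spd = np.clip(s0 + m1 * s1 + m2 * s2, 0.0, None)
    return spd / spd.max()


def d65_spd(grid: np.ndarray) -> np.ndarray:
    """Relative D65, reconstructed from the daylight components at its
    defining chromaticity (0.31272, 0.32903)."""
    return daylight_spd(grid, xy=D65_XY)


def tristimulus(irradiance: np.ndarray, bundle: ObserverBundle) -> tuple[float, float, float]:
    """Unnormalized CIE XYZ trapezoidal integrals of ``irradiance`` on the
    bundle grid."""
    e = np.asarray(irradiance, dtype=float)
    g = bundle.grid
    return (
        float(np.trapezoid(e * bundle.cmf_x.values, g)),
        float(np.trapezoid(e * bundle.cmf_y.values, g)),
        float(np.trapezoid(e * bundle.cmf_z.values, g)),
    )


def chromaticity_xy(irradiance: np.ndarray, bundle: ObserverBundle) -> tuple[float, float]:
    X, Y, Z = tristimulus(irradiance, bundle)
    s = X + Y + Z
    if s <= 0:
        raise ValueError("chromaticity undefined for a non-positive spectrum")
    return X / s, Y / s


def uv1960(x: float, y: float) -> tuple[float, float]:
    """CIE 1960 UCS coordinates from (x, y) chromaticity."""
    d = -2.0 * x + 12.0 * y + 3.0
    return 4.0 * x / d, 6.0 * y / d


@dataclass(frozen=True)
class ChromaticityResult:
    x: float
    y: float
    z: float
    cct: float
    duv: float
    cct_valid: bool  # False when |Duv| > 0.05 (CCT not meaningful)


class _PlanckLocus:
    """Planckian locus sampled in (u, v) for one observer bundle."""

    T_MIN, T_MAX = 1000.0, 25000.0
    STEP = 1.0004  # multiplicative sampling step, ~0.04 %

    def __init__(self, bundle: ObserverBundle):
        n = int(np.ceil(np.log(self.T_MAX / self.T_MIN) / np.log(self.STEP))) + 1
        self.T = self.T_MIN * self.STEP ** np.arange(n)
        grid = bundle.grid
        wl5 = grid ** -5.0
        u = np.empty(n)
        v = np.empty(n)
        xw = bundle.cmf_x.values
        yw = bundle.cmf_y.values
        zw = bundle.cmf_z.values
        for i, t in enumerate(self.T):
            spd = wl5 / np.expm1(C2 / (grid * t))
            X = np.trapezoid(spd * xw, grid)
            Y = np.trapezoid(spd * yw, grid)
            Z = np.trapezoid(spd * zw, grid)
            s = X + 15.0 * Y + 3.0 * Z
            u[i] = 4.0 * X / s
            v[i] = 6.0 * Y / s
        self.u, self.v = u, v

    def uv_at(self, t: float, bundle: ObserverBundle) -> tuple[float, float]:
        spd = bundle.grid ** -5.0 / np.expm1(C2 / (bundle.grid * t))
        X, Y, Z = tristimulus(spd, bundle)
        s = X + 15.0 * Y + 3.0 * Z
        return 4.0 * X / s, 6.0 * Y / s


_LOCUS_ATTR = "_circalux_planck_locus"


def _locus_for(bundle: ObserverBundle) -> _PlanckLocus:
    locus = bundle.metadata.get(_LOCUS_ATTR)
    if locus is None:
        locus = _PlanckLocus(bundle)
        bundle.metadata[_LOCUS_ATTR] = locus
    return locus


def cct_duv(irradiance: np.ndarray, bundle: ObserverBundle) -> ChromaticityResult:
    """Chromaticity, CCT and Duv of an absolute or relative spectrum.

    Scale-invariant.  When |Duv| exceeds 0.05 the result is flagged invalid
    rather than silently reported.
    """
    x, y = chromaticity_xy(irradiance, bundle)
    us, vs = uv1960(x, y)
    locus = _locus_for(bundle)
    d2 = (locus.u - us) ** 2 + (locus.v - vs) ** 2
    i = int(np.argmin(d2))
    if 0 < i < d2.size - 1:
        # parabolic vertex through the three bracketing samples (log-T space)
        y0, y1, y2 = d2[i - 1], d2[i], d2[i + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom > 0 else 0.0
        shift = float(np.clip(shift, -1.0, 1.0))
        log_t = np.log(locus.T[i]) + shift * np.log(locus.STEP)
        t_best = float(np.exp(log_t))
    else:
        t_best = float(locus.T[i])
    ub, vb = locus.uv_at(t_best, bundle)
    dist = float(np.hypot(us - ub, vs - vb))
    duv = dist if vs >= vb else -dist
    return ChromaticityResult(
        x=x, y=y, z=1.0 - x - y, cct=t_best, duv=duv,
        cct_valid=abs(duv) <= DUV_VALID_LIMIT,
    )
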
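"""Tabulated observer sensitivity and transmittance functions.

Every metric in this package is a weighted integral of a spectral irradiance
distribution against one or more of seven observer functions: the photopic and
scotopic luminous efficiency functions V and V', the Smith-Pokorny S-cone
fundamental, the melanopsin sensitivity M_c (corrected for crystalline-lens
transmittance), the macular pigment transmittance mp, the melanopic action
spectrum s_mel, and the 2-degree colour-matching functions used for
chromaticity.  :func:`load_bundle` resamples all of them onto one common
wavelength grid so that downstream integrations never mix grids.

The published tables are shipped as plain-text two-column files under
``circalux/data``.  The melanopsin function is not tabulated anywhere in a
citable standard at the precision needed, so it is built analytically from the
Govardovskii A1 visual-pigment template (lambda_max = 480 nm) converted to an
energy basis and multiplied by the bundled crystalline-lens transmittance,
then peak-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

__all__ = [
    "SensitivityFunction",
    "ObserverBundle",
    "load_bundle",
    "corrected_function",
    "govardovskii_nomogram",
    "default_grid",
]

#: Default working grid: 380-780 nm at 1 nm (trapezoidal quadrature).
DEFAULT_GRID_START = 380.0
DEFAULT_GRID_STOP = 780.0
DEFAULT_GRID_STEP = 1.0

#: Default peak optical density of the macular pigment (2-degree field).
DEFAULT_MACULAR_PEAK_DENSITY = 0.35


def default_grid() -> np.ndarray:
    """The package's default wavelength grid, 380-780 nm at 1 nm."""
    n = int(round((DEFAULT_GRID_STOP - DEFAULT_GRID_START) / DEFAULT_GRID_STEP)) + 1
    return np.linspace(DEFAULT_GRID_START, DEFAULT_GRID_STOP, n)


@dataclass(frozen=True)
class SensitivityFunction:
    """A spectral sensitivity or transmittance function on a wavelength grid.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"V"`` or ``"s_mel"``.
    grid:
        Wavelengths in nm, strictly increasing.
    values:
        Dimensionless non-negative weights on ``grid``.
    normalization:
        ``"peak-1"`` if ``max(values) == 1``, otherwise ``"as-published"``.
    provenance:
        Free-text note on the source table or construction.
    """

    name: str
    grid: np.ndarray
    values: np.ndarray
    normalization: str = "as-published"
    provenance: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError(f"{self.name}: grid must be 1-D with >= 2 points")
        if np.any(np.diff(grid) <= 0):
            raise ValueError(f"{self.name}: grid must be strictly increasing")
        if values.shape != grid.shape:
            raise ValueError(f"{self.name}: values/grid shape mismatch")
        if np.any(values < 0):
            raise ValueError(f"{self.name}: values must be non-negative")
        if self.normalization == "peak-1" and abs(values.max() - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: declared peak-1 but max is {values.max()}")

    def __call__(self, wavelengths) -> np.ndarray:
        """Linear interpolation; zero outside the tabulated support."""
        return np.interp(np.asarray(wavelengths, dtype=float), self.grid, self.values, left=0.0, right=0.0)

    def resample(self, grid: np.ndarray) -> "SensitivityFunction":
        return replace(self, grid=np.asarray(grid, dtype=float), values=self(grid))

    @property
    def peak_wavelength(self) -> float:
        return float(self.grid[int(np.argmax(self.values))])


@dataclass(frozen=True)
class ObserverBundle:
    """All observer functions resampled onto one shared wavelength grid.

    ``cmf_x/cmf_y/cmf_z`` are the 2-degree colour-matching functions, rescaled
    at construction so that their trapezoidal integrals over the bundle grid
    are exactly equal; this pins the chromaticity of the equal-energy spectrum
    to exactly (1/3, 1/3) while changing each function by well under 0.2 %.
    """

    grid: np.ndarray
    V: SensitivityFunction
    Vprime: SensitivityFunction
    S_cone: SensitivityFunction
    M_c: SensitivityFunction
    mp: SensitivityFunction
    s_mel: SensitivityFunction
    cmf_x: SensitivityFunction
    cmf_y: SensitivityFunction
    cmf_z: SensitivityFunction
    V_c: SensitivityFunction = None  # macular-corrected, peak-normalized (Eq.-8-style)
    S_c: SensitivityFunction = None  # macular-corrected, peak-normalized (Eq.-9-style)
    metadata: dict = field(default_factory=dict)

    def functions(self) -> dict:
        return {
            f.name: f
            for f in (self.V, self.Vprime, self.S_cone, self.M_c, self.mp,
                      self.s_mel, self.cmf_x, self.cmf_y, self.cmf_z,
                      self.V_c, self.S_c)
        }


def _load_table(filename: str) -> tuple[np.ndarray, str]:
    """Read a bundled two-or-more-column table; returns (array, provenance)."""
    ref = resources.files("circalux.data").joinpath(filename)
    if not ref.is_file():
        raise FileNotFoundError(
            f"bundled observer table {filename!r} is missing from circalux.data"
        )
    text = ref.read_text(encoding="utf-8")
    header = [ln[1:].strip() for ln in text.splitlines() if ln.startswith("#")]
    rows = [
        [float(tok) for tok in ln.split(",")]
        for ln in text.splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    return np.asarray(rows, dtype=float), " ".join(header)


def govardovskii_nomogram(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """Govardovskii et al. A1 visual-pigment template, quantal basis.

    Alpha band plus beta band, peak-normalized to 1 at ``lambda_max``.
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_b = 189.0 + 0.315 * lambda_max
    b_b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lam_b) / b_b) ** 2))
    s = alpha + beta
    return s / s.max()


def corrected_function(f: SensitivityFunction, mp: SensitivityFunction) -> SensitivityFunction:
    """Macular-pigment-corrected, peak-normalized variant of ``f``.

    Returns (f/mp) / max(f/mp).  Both functions must share a grid; a zero
    anywhere in ``mp`` is a fatal error (the division is undefined).
    """
    if f.grid.shape != mp.grid.shape or not np.array_equal(f.grid, mp.grid):
        raise ValueError("corrected_function: f and mp must share a wavelength grid")
    if np.any(mp.values <= 0):
        raise ValueError("corrected_function: mp contains zeros; division undefined")
    ratio = f.values / mp.values
    ratio = ratio / ratio.max()
    return SensitivityFunction(
        name=f"{f.name}_c",
        grid=f.grid,
        values=ratio,
        normalization="peak-1",
        provenance=f"({f.name}/mp)/max, after {f.provenance}",
    )


def load_bundle(
    grid: np.ndarray | None = None,
    *,
    macular_peak_density: float = DEFAULT_MACULAR_PEAK_DENSITY,
    melanopsin_lambda_max: float = 480.0,
) -> ObserverBundle:
    """Load every observer table, resampled onto ``grid``.

    Parameters
    ----------
    grid:
        Target wavelength grid in nm; must lie within [360, 830] nm with a
        step of at most 5 nm.  Defaults to 380-780 nm at 1 nm.
    macular_peak_density:
        Peak optical density applied to the bundled relative macular pigment
        density before conversion to transmittance.
    melanopsin_lambda_max:
        Peak of the melanopsin opsin template in nm.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    if grid[0] < 360.0 or grid[-1] > 830.0:
        raise ValueError("grid must lie within [360, 830] nm")
    if np.max(np.diff(grid)) > 5.0 + 1e-12:
        raise ValueError("grid step must be <= 5 nm")

    meta: dict = {}

    def _sf(filename: str, name: str, column: int = 1, normalization: str = "as-published"):
        table, prov = _load_table(filename)
        meta[name] = prov
        f = SensitivityFunction(name, table[:, 0], table[:, column],
                                normalization="as-published", provenance=prov)
        f = f.resample(grid)
        if normalization == "peak-1":
            f = replace(f, values=f.values / f.values.max(), normalization="peak-1")
        return f

    V = _sf("cie1924_photopic.csv", "V", normalization="peak-1")
    Vp = _sf("cie1951_scotopic.csv", "Vprime", normalization="peak-1")
    S = _sf("smith_pokorny_s_cone.csv", "S_cone", normalization="peak-1")
    s_mel = _sf("melanopic_s026.csv", "s_mel", normalization="peak-1")

    mac_table, mac_prov = _load_table("macular_density.csv")
    mac_density = np.interp(grid, mac_table[:, 0], mac_table[:, 1], left=0.0, right=0.0)
    mp_values = 10.0 ** (-macular_peak_density * mac_density)
    mp = SensitivityFunction("mp", grid, mp_values, "as-published",
                             f"peak density {macular_peak_density}; {mac_prov}")
    meta["mp"] = mac_prov

    lens_table, lens_prov = _load_table("lens_density.csv")
    lens_density = np.interp(grid, lens_table[:, 0], lens_table[:, 1],
                             left=lens_table[0, 1], right=lens_table[-1, 1])
    lens_tau = 10.0 ** (-lens_density)
    # melanopsin: quantal opsin template -> energy basis (x lambda) -> lens filter
    mc_values = govardovskii_nomogram(grid, melanopsin_lambda_max) * grid * lens_tau
    mc_values = mc_values / mc_values.max()
    M_c = SensitivityFunction(
        "M_c", grid, mc_values, "peak-1",
        f"Govardovskii A1 template (lambda_max {melanopsin_lambda_max} nm), energy basis, "
        f"times crystalline-lens transmittance ({lens_prov}), peak-normalized",
    )
    meta["M_c"] = M_c.provenance

    cmf_table, cmf_prov = _load_table("cie1931_cmf_2deg.csv")
    meta["cmf"] = cmf_prov
    cmfs = []
    raw = [
        np.interp(grid, cmf_table[:, 0], cmf_table[:, c], left=0.0, right=0.0)
        for c in (1, 2, 3)
    ]
    integrals = [np.trapezoid(v, grid) for v in raw]
    target = integrals[1]  # anchor on ybar
    for name, v, integral in zip(("cmf_x", "cmf_y", "cmf_z"), raw, integrals):
        scaled = v * (target / integral)
        cmfs.append(SensitivityFunction(name, grid, scaled, "as-published",
                                        f"{cmf_prov}; integral-matched on bundle grid"))
    cmf_x, cmf_y, cmf_z = cmfs

    V_c = corrected_function(V, mp)
    S_c = corrected_function(S, mp)

    return ObserverBundle(
        grid=grid, V=V, Vprime=Vp, S_cone=S, M_c=M_c, mp=mp, s_mel=s_mel,
        cmf_x=cmf_x, cmf_y=cmf_y, cmf_z=cmf_z, V_c=V_c, S_c=S_c, metadata=meta,
    )
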
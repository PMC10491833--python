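"""Seeded synthetic stand-in for a measured light-source corpus.

The correlation analysis in this package was designed for a corpus of 884
measured spectra (28 incandescent, 252 fluorescent, 419 LED, 185 daylight)
spanning 2201-17815 K in CCT; that corpus is not publicly deposited, so this
module generates a parametric ensemble with the same class composition and
CCT coverage.  Families are the canonical parametric stand-ins:

* ``planckian`` - blackbody radiators, optionally behind a smooth spectral
  tilt filter (filtered incandescents);
* ``fluorescent`` - mercury emission lines (Gaussians, sigma 2 nm) over a
  warm/cool phosphor-band mixture;
* ``led`` - blue pump Gaussian (peak 440-460 nm, FWHM ~20 nm) plus a broad
  phosphor Gaussian, white point set by the pump/phosphor ratio;
* ``daylight`` - CIE D-series reconstructions (4000-25000 K).

Each generated spectrum is solved to a target CCT by a 1-D root search on the
family's mixing parameter, then accepted only if the achieved CCT falls in
the class range and |Duv| < 0.02; otherwise the target is redrawn.  The same
config and seed reproduce the ensemble bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import colorimetry
from .observers import ObserverBundle, load_bundle, default_grid
from .spectra import Spectrum

__all__ = ["EnsembleConfig", "synth_spd", "generate_ensemble", "DEFAULT_COUNTS"]

DEFAULT_COUNTS = {
    "incandescent": 28,
    "fluorescent": 252,
    "led": 419,
    "daylight": 185,
}

#: Default per-class CCT target ranges (K), all within the corpus range
#: [2201, 17815]; the extreme CCTs of the corpus are daylight.
DEFAULT_CCT_RANGES = {
    "incandescent": (2201.0, 5000.0),
    "fluorescent": (2700.0, 6500.0),
    "led": (2201.0, 9000.0),
    "daylight": (4000.0, 17815.0),
}

GLOBAL_CCT_RANGE = (2201.0, 17815.0)
DUV_LIMIT = 0.02
MAX_RETRIES = 60

_HG_LINES = (404.7, 435.8, 546.1, 577.0)


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of the synthetic corpus; seed is mandatory."""

    seed: int
    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    cct_ranges: dict = field(default_factory=lambda: dict(DEFAULT_CCT_RANGES))
    grid_start: float = 380.0
    grid_stop: float = 780.0
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        for cls, n in self.counts.items():
            if n < 0:
                raise ValueError(f"count for {cls!r} must be >= 0")
        for cls, (lo, hi) in self.cct_ranges.items():
            if not (GLOBAL_CCT_RANGE[0] <= lo < hi <= GLOBAL_CCT_RANGE[1]):
                raise ValueError(
                    f"CCT range for {cls!r} must lie within {GLOBAL_CCT_RANGE}"
                )

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return np.linspace(self.grid_start, self.grid_stop, n)


def _gaussian(wl: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def synth_spd(family: str, params: dict, grid: np.ndarray) -> Spectrum:
    """Build one relative spectrum of the given family on ``grid``.

    Parameters per family:

    * ``planckian``: ``T`` (> 0 K); optional ``filter_slope`` (a smooth
      exponential tilt ``exp(slope * (lambda - 560)/100)``).
    * ``daylight``: ``cct`` in [4000, 25000] K (the D-series domain; the
      incandescent range is served by the planckian family).
    * ``led``: ``blue_peak`` nm, ``blue_fwhm`` nm, ``phosphor_center`` nm,
      ``phosphor_fwhm`` nm, ``ratio`` (pump/phosphor amplitude, > 0).
    * ``fluorescent``: ``line_amps`` (4 amplitudes for the 405/436/546/578 nm
      mercury lines), ``alpha`` (warm->cool phosphor mix in [0, 1]), optional
      ``band_amps`` overrides for the red/green/blue phosphor bands.
    """
    wl = np.asarray(grid, dtype=float)
    if family == "planckian":
        t = params["T"]
        if t <= 0:
            raise ValueError("planckian family needs T > 0 K")
        spd = colorimetry.planckian_spd(wl, t)
        slope = params.get("filter_slope", 0.0)
        if slope:
            spd = spd * np.exp(slope * (wl - 560.0) / 100.0)
        source_class = "incandescent"
    elif family == "daylight":
        cct = params["cct"]
        if not 4000.0 <= cct <= 25000.0:
            raise ValueError(
                "daylight family covers 4000-25000 K (use planckian below 4000 K)"
            )
        spd = colorimetry.daylight_spd(wl, cct=cct)
        source_class = "daylight"
    elif family == "led":
        ratio = params["ratio"]
        if ratio <= 0:
            raise ValueError("led pump/phosphor ratio must be positive")
        spd = ratio * _gaussian(wl, params["blue_peak"], params["blue_fwhm"]) + _gaussian(
            wl, params["phosphor_center"], params["phosphor_fwhm"]
        )
        source_class = "led"
    elif family == "fluorescent":
        amps = params["line_amps"]
        alpha = params["alpha"]
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("fluorescent mix alpha must be in [0, 1]")
        lines = sum(a * _gaussian(wl, c, 4.7) for a, c in zip(amps, _HG_LINES))
        red, green, blue = params.get("band_amps", (1.0, 0.4, 1.0))
        warm = red * _gaussian(wl, 611.0, 33.0) + 0.35 * green * _gaussian(wl, 545.0, 60.0)
        cool = 0.25 * red * _gaussian(wl, 611.0, 33.0) + green * _gaussian(
            wl, 545.0, 60.0
        ) + blue * _gaussian(wl, 450.0, 70.0)
        spd = 0.35 * lines + (1.0 - alpha) * warm + alpha * cool
        source_class = "fluorescent"
    else:
        raise ValueError(f"unknown family {family!r}")
    spd = np.clip(spd, 0.0, None)
    return Spectrum(
        id=params.get("id", family),
        grid=wl,
        irradiance=spd / spd.max(),
        source_class=params.get("source_class", source_class),
        metadata={"family": family},
    )


def _achieved(spec: Spectrum, bundle: ObserverBundle) -> colorimetry.ChromaticityResult:
    return colorimetry.cct_duv(spec.irradiance, bundle)


def _solve_mix(make, lo: float, hi: float, target: float,
               bundle: ObserverBundle) -> tuple[Spectrum, float] | None:
    """Root-find the family mixing parameter so achieved CCT == target."""

    def err(p: float) -> float:
        return _achieved(make(p), bundle).cct - target

    try:
        e_lo, e_hi = err(lo), err(hi)
    except ValueError:
        return None
    if e_lo * e_hi > 0:
        return None
    p = brentq(err, lo, hi, xtol=1e-6, rtol=1e-12, maxiter=100)
    return make(p), p


def _draw_incandescent(rng, target, grid, bundle):
    if target <= 3300.0 and rng.random() < 0.7:
        return synth_spd("planckian", {"T": target}, grid), {"T": target}
    # filtered incandescent: 2856 K radiator behind an exponential tilt
    def make(slope):
        return synth_spd("planckian", {"T": 2856.0, "filter_slope": slope}, grid)

    solved = _solve_mix(make, -3.0, 3.0, target, bundle)
    if solved is None:
        return None
    spec, slope = solved
    return spec, {"T": 2856.0, "filter_slope": slope}


def _draw_fluorescent(rng, target, grid, bundle):
    amps = (1.0 + 0.3 * rng.standard_normal(4)).clip(0.2, 2.0)
    bands = (1.0 + 0.25 * rng.standard_normal(3)).clip(0.3, 2.0)
    params = {"line_amps": tuple(amps), "band_amps": tuple(bands)}

    def make(alpha):
        return synth_spd("fluorescent", {**params, "alpha": alpha}, grid)

    solved = _solve_mix(make, 0.0, 1.0, target, bundle)
    if solved is None:
        return None
    spec, alpha = solved
    return spec, {**params, "alpha": alpha}


def _draw_led(rng, target, grid, bundle):
    # warmer targets want redder phosphors; jitter around that trend
    center = float(np.interp(target, [2201.0, 4000.0, 6500.0, 9000.0],
                             [625.0, 595.0, 567.0, 552.0]))
    params = {
        "blue_peak": float(rng.uniform(440.0, 460.0)),
        "blue_fwhm": float(rng.uniform(18.0, 24.0)),
        "phosphor_center": float(np.clip(center + rng.normal(0.0, 10.0), 540.0, 640.0)),
        "phosphor_fwhm": float(rng.uniform(80.0, 120.0)),
    }

    def make(log_ratio):
        return synth_spd("led", {**params, "ratio": float(np.exp(log_ratio))}, grid)

    solved = _solve_mix(make, np.log(1e-3), np.log(50.0), target, bundle)
    if solved is None:
        return None
    spec, log_ratio = solved
    return spec, {**params, "ratio": float(np.exp(log_ratio))}


def _draw_daylight(rng, target, grid, bundle):
    return synth_spd("daylight", {"cct": target}, grid), {"cct": target}


_DRAWERS = {
    "incandescent": _draw_incandescent,
    "fluorescent": _draw_fluorescent,
    "led": _draw_led,
    "daylight": _draw_daylight,
}


def generate_ensemble(config: EnsembleConfig,
                      bundle: ObserverBundle | None = None) -> tuple[list[Spectrum], dict]:
    """Generate the full synthetic corpus plus a manifest.

    Returns (spectra, manifest); the manifest records the config echo and,
    per spectrum, the family, the solved parameters, the target CCT and the
    achieved CCT/Duv.  CCT targets are drawn log-uniformly within each class
    range; draws whose achieved CCT leaves the class range or whose |Duv|
    exceeds 0.02 are rejected and redrawn (bounded retries).
    """
    grid = config.grid()
    if bundle is None or not np.array_equal(bundle.grid, grid):
        bundle = load_bundle(grid)
    rng = np.random.default_rng(config.seed)
    spectra: list[Spectrum] = []
    records: list[dict] = []
    for cls in ("incandescent", "fluorescent", "led", "daylight"):
        n = config.counts.get(cls, 0)
        lo, hi = config.cct_ranges.get(cls, DEFAULT_CCT_RANGES[cls])
        draw = _DRAWERS[cls]
        for i in range(n):
            ok = False
            for _ in range(MAX_RETRIES):
                # pad 2 K so root-search tolerance cannot leave the range
                target = float(np.exp(rng.uniform(np.log(lo + 2.0), np.log(hi - 2.0))))
                out = draw(rng, target, grid, bundle)
                if out is None:
                    continue
                spec, params = out
                ach = _achieved(spec, bundle)
                if not (lo <= ach.cct <= hi) or abs(ach.duv) > DUV_LIMIT:
                    continue
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"could not synthesize a {cls} spectrum near CCT target "
                    f"{target:.0f} K after {MAX_RETRIES} retries"
                )
            sid = f"{cls}_{i:03d}"
            spec = Spectrum(id=sid, grid=grid, irradiance=spec.irradiance,
                            source_class=cls, metadata=dict(spec.metadata))
            spectra.append(spec)
            records.append({
                "id": sid,
                "source_class": cls,
                "family": spec.metadata["family"],
                "params": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in params.items()},
                "target_cct": target,
                "achieved_cct": ach.cct,
                "achieved_duv": ach.duv,
            })
    manifest = {
        "config": {
            "seed": config.seed,
            "counts": dict(config.counts),
            "cct_ranges": {k: list(v) for k, v in config.cct_ranges.items()},
            "grid": [config.grid_start, config.grid_stop, config.grid_step],
        },
        "n_spectra": len(spectra),
        "spectra": records,
    }
    return spectra, manifest
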
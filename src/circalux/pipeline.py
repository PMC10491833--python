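"""Correlation/conversion analysis over a spectrum ensemble.

The pipeline rescales every spectrum to a set of photopic illuminance levels
(default 125/500/750 lx), evaluates all brightness and non-visual metrics per
(spectrum, level) row, then computes pairwise Pearson r-squared matrices -
for all rows, for the warm partition (CCT <= 3710 K) and for the cold
partition (CCT > 3710 K) - together with ordinary-least-squares conversion
fits between metric pairs and a Planckian branch-discontinuity sweep.

Correlations are pooled across the illuminance levels by default (a
``per_level`` switch preserves the alternative).  The partition boundary sits
on CCT, the empirical proxy for the b-y opponent sign; the actual per-row
b-y sign is recorded so the two partitions can be compared.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import brightness, circadian, colorimetry
from .observers import ObserverBundle, load_bundle
from .spectra import Spectrum, photopic_illuminance, scale_to_illuminance, chromaticity_cct_duv

__all__ = [
    "METRIC_COLUMNS",
    "DEFAULT_LEVELS",
    "CCT_PARTITION_K",
    "FitResult",
    "compute_metric_table",
    "pairwise_r2",
    "linear_fit",
    "discontinuity_sweep",
    "build_report",
]

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = (125.0, 500.0, 750.0)

#: Empirical CCT proxy for the warm/cold b-y partition.
CCT_PARTITION_K = 3710.0

#: Metric columns of the central table.
METRIC_COLUMNS = [
    "E_v", "mEDI", "CL_A_2018", "CL_A_2021", "CS_2018", "CS_2021",
    "gimenez_as_printed", "L_eq", "M_TUD",
]

#: Headline metrics for the r-squared matrices (the as-printed melatonin
#: formula is computed per row but excluded from ordering checks).
HEADLINE_METRICS = ["mEDI", "CL_A_2018", "CL_A_2021", "CS_2018", "CS_2021",
                    "L_eq", "M_TUD"]


@dataclass(frozen=True)
class FitResult:
    """A pairwise metric conversion fit (OLS of y on x)."""

    x_metric: str
    y_metric: str
    subset: str           # "all" | "warm" | "cold"
    slope: float
    intercept: float
    r2: float
    rmse: float           # root mean squared residual, y units
    n: int


def compute_metric_table(
    spectra: list[Spectrum],
    bundle: ObserverBundle | None = None,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    t_hours: float = 1.0,
    f_field: float = 1.0,
    duration_min: float = 60.0,
    pupil_dilated: int = 0,
    constants: circadian.CircadianModelConstants = circadian.DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Evaluate every metric for every spectrum at every illuminance level.

    Returns a DataFrame with one row per (spectrum, level), ordered by
    (spectrum id, level).  Spectra with zero photopic luminance are skipped
    with a logged warning.
    """
    if not spectra:
        raise ValueError("no spectra given")
    if any(lv <= 0 for lv in levels):
        raise ValueError("illuminance levels must be positive")
    if bundle is None:
        bundle = load_bundle(spectra[0].grid)
    rows = []
    for spec in sorted(spectra, key=lambda s: s.id):
        if photopic_illuminance(spec, bundle) <= 0:
            logger.warning("skipping zero-luminance spectrum %r", spec.id)
            continue
        chrom = chromaticity_cct_duv(spec, bundle)
        by = circadian.opponent_by(spec, bundle, "2021", constants)
        for level in levels:
            s = scale_to_illuminance(spec, level, bundle)
            ev = photopic_illuminance(s, bundle)
            r18 = circadian.cla_2018(s, bundle, constants)
            r21 = circadian.cla_2021(s, bundle, constants)
            medi = circadian.medi(s, bundle)
            rows.append({
                "id": spec.id,
                "source_class": spec.source_class,
                "level": level,
                "CCT": chrom.cct,
                "Duv": chrom.duv,
                "by_sign": 1 if by > 0 else -1,
                "E_v": ev,
                "mEDI": medi,
                "CL_A_2018": r18.value,
                "CL_A_2021": r21.value,
                "CS_2018": circadian.circadian_stimulus(max(r18.value, 0.0), t_hours, f_field, constants),
                "CS_2021": circadian.circadian_stimulus(max(r21.value, 0.0), t_hours, f_field, constants),
                "gimenez_as_printed": circadian.gimenez_suppression(medi, duration_min, pupil_dilated).value,
                "L_eq": brightness.leq_fotios(s, bundle),
                "M_TUD": brightness.m_tud_from_spectrum(s, bundle),
            })
    return pd.DataFrame(rows)


def _subset(table: pd.DataFrame, which: str,
            cct_threshold: float = CCT_PARTITION_K) -> pd.DataFrame:
    if which == "all":
        return table
    if which == "warm":
        return table[table["CCT"] <= cct_threshold]
    if which == "cold":
        return table[table["CCT"] > cct_threshold]
    raise ValueError(f"unknown subset {which!r}")


def pairwise_r2(
    table: pd.DataFrame,
    metrics: list[str] | None = None,
    cct_threshold: float = CCT_PARTITION_K,
    per_level: bool = False,
) -> dict[str, pd.DataFrame]:
    """Pearson r-squared matrices for the all/warm/cold subsets.

    An undefined r-squared (a metric constant within a subset) is reported as
    NaN - an explicit missing marker, never a silent zero.  With
    ``per_level`` the matrices are averaged over per-level matrices instead
    of pooling rows across levels.
    """
    metrics = metrics or HEADLINE_METRICS
    out: dict[str, pd.DataFrame] = {}
    for which in ("all", "warm", "cold"):
        sub = _subset(table, which, cct_threshold)
        if len(sub) < 3:
            raise ValueError(f"subset {which!r} has fewer than 3 rows")
        if per_level:
            mats = [g[metrics].corr() ** 2 for _, g in sub.groupby("level")]
            out[which] = sum(mats) / len(mats)
        else:
            out[which] = sub[metrics].corr() ** 2
    return out


def linear_fit(
    table: pd.DataFrame,
    x_metric: str,
    y_metric: str,
    subset: str = "all",
    cct_threshold: float = CCT_PARTITION_K,
) -> FitResult:
    """Ordinary least squares of ``y_metric`` on ``x_metric`` over a subset."""
    sub = _subset(table, subset, cct_threshold)
    if len(sub) < 3:
        raise ValueError(f"subset {subset!r} has fewer than 3 rows")
    x = sub[x_metric].to_numpy(dtype=float)
    y = sub[y_metric].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"{x_metric} is constant in subset {subset!r}")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    rmse = float(np.sqrt(np.mean(model.resid ** 2)))
    return FitResult(x_metric=x_metric, y_metric=y_metric, subset=subset,
                     slope=float(slope), intercept=float(intercept),
                     r2=float(model.rsquared), rmse=rmse, n=len(sub))


def discontinuity_sweep(
    bundle: ObserverBundle | None = None,
    cct_min: float = 2200.0,
    cct_max: float = 8000.0,
    step: float = 25.0,
    level: float = 500.0,
    constants: circadian.CircadianModelConstants = circadian.DEFAULT_CONSTANTS,
) -> tuple[pd.DataFrame, dict]:
    """Sweep Planckian radiators across CCT and locate the branch boundary.

    Returns (per-CCT table, summary).  The summary reports, per model
    version, the CCT interval bracketing the b-y sign change and the jump
    |Delta| of each metric across that boundary pair of grid points; mEDI,
    which has no case split, is included as the continuous control.
    """
    if step > 25.0:
        raise ValueError("sweep step must be <= 25 K")
    if bundle is None:
        bundle = load_bundle()
    grid = bundle.grid
    ccts = np.arange(cct_min, cct_max + 0.5 * step, step)
    rows = []
    for t in ccts:
        spec = Spectrum(id=f"planck_{t:.0f}", grid=grid,
                        irradiance=colorimetry.planckian_spd(grid, t))
        s = scale_to_illuminance(spec, level, bundle)
        r18 = circadian.cla_2018(s, bundle, constants)
        r21 = circadian.cla_2021(s, bundle, constants)
        rows.append({
            "CCT": float(t),
            "by_signal": r21.by_signal,
            "branch_2018": r18.branch,
            "branch_2021": r21.branch,
            "CL_A_2018": r18.value,
            "CL_A_2021": r21.value,
            "CS_2018": circadian.circadian_stimulus(max(r18.value, 0.0), constants=constants),
            "CS_2021": circadian.circadian_stimulus(max(r21.value, 0.0), constants=constants),
            "mEDI": circadian.medi(s, bundle),
        })
    sweep = pd.DataFrame(rows)
    summary: dict = {"level_lx": level, "step_K": step}
    for version in ("2018", "2021"):
        branches = sweep[f"branch_{version}"].to_numpy()
        change = np.nonzero(branches[:-1] != branches[1:])[0]
        if change.size == 0:
            summary[version] = {"boundary_found": False}
            continue
        i = int(change[0])
        jumps = {
            m: abs(float(sweep[m].iloc[i + 1] - sweep[m].iloc[i]))
            for m in ("CL_A_2018", "CL_A_2021", "CS_2018", "CS_2021", "mEDI")
        }
        summary[version] = {
            "boundary_found": True,
            "boundary_cct_low": float(sweep["CCT"].iloc[i]),
            "boundary_cct_high": float(sweep["CCT"].iloc[i + 1]),
            "jumps": jumps,
        }
    return sweep, summary


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def build_report(
    table: pd.DataFrame,
    fits: list[FitResult],
    sweep_summary: dict,
    config_echo: dict,
    out_path=None,
    matrices_dir=None,
    metrics: list[str] | None = None,
    cct_threshold: float = CCT_PARTITION_K,
    per_level: bool = False,
) -> dict:
    """Assemble the correlation report; optionally write JSON and CSVs.

    Regenerating the report from the same table yields byte-identical output
    (sorted keys, fixed float rounding).
    """
    matrices = pairwise_r2(table, metrics, cct_threshold, per_level)
    report = {
        "config": config_echo,
        "n_rows": int(len(table)),
        "cct_threshold_K": cct_threshold,
        "r2_matrices": {
            which: {
                "metrics": list(mat.columns),
                "values": [[None if np.isnan(v) else float(v) for v in row]
                           for row in mat.to_numpy()],
            }
            for which, mat in matrices.items()
        },
        "fits": [asdict(f) for f in fits],
        "discontinuity_sweep": sweep_summary,
    }
    report = _round_floats(report)
    if out_path is not None:
        Path(out_path).write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    if matrices_dir is not None:
        d = Path(matrices_dir)
        d.mkdir(parents=True, exist_ok=True)
        for which, mat in matrices.items():
            mat.round(6).to_csv(d / f"r2_{which}.csv")
    return report
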
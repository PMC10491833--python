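"""Spectrum container, SPD file I/O, photometric normalization, chromaticity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from circalux.spectra import (
    Spectrum,
    read_spd,
    write_spd,
    resample,
    photopic_illuminance,
    scale_to_illuminance,
    chromaticity_cct_duv,
)
from circalux.colorimetry import planckian_spd, daylight_spd


def test_spd_round_trip(tmp_path, planck_2700):
    path = tmp_path / "p.spd"
    spec = planck_2700.scaled(3.7e-3)
    write_spd(spec, path)
    back = read_spd(path)
    assert back.id == spec.id
    np.testing.assert_allclose(back.grid, spec.grid)
    np.testing.assert_allclose(back.irradiance, spec.irradiance, rtol=1e-5)


def test_read_rejects_non_monotone(tmp_path):
    path = tmp_path / "bad.spd"
    path.write_text("400,0.1\n395,0.2\n410,0.1\n")
    with pytest.raises(ValueError, match="increasing"):
        read_spd(path)


def test_read_rejects_negative_row(tmp_path):
    path = tmp_path / "neg.spd"
    path.write_text("400,0.1\n405,-0.2\n410,0.1\n")
    with pytest.raises(ValueError, match="row 2"):
        read_spd(path)


def test_all_zero_spectrum_parses(tmp_path, grid):
    path = tmp_path / "zero.spd"
    write_spd(Spectrum("z", grid, np.zeros_like(grid)), path)
    back = read_spd(path)
    assert np.all(back.irradiance == 0)


def test_spectrum_rejects_non_monotone_grid():
    with pytest.raises(ValueError):
        Spectrum("x", np.array([400.0, 395.0, 410.0]), np.ones(3))


def test_resample_identity_and_constant(planck_2700, grid):
    same = resample(planck_2700, grid)
    np.testing.assert_allclose(same.irradiance, planck_2700.irradiance)
    const = Spectrum("c", grid, np.full_like(grid, 2.5))
    coarse = resample(const, np.arange(400.0, 700.0, 7.0))
    np.testing.assert_allclose(coarse.irradiance, 2.5)


def test_resample_quadrature_stability(bundle, grid):
    """Planckian photopic illuminance moves < 0.5 % between 1 and 5 nm grids."""
    spec = Spectrum("p", grid, planckian_spd(grid, 2856.0))
    e1 = photopic_illuminance(spec, bundle)
    from circalux.observers import load_bundle
    g5 = np.arange(380.0, 782.0, 5.0)
    e5 = photopic_illuminance(resample(spec, g5), load_bundle(g5))
    assert abs(e1 - e5) / e1 < 0.005


def test_resample_empty_grid(planck_2700):
    with pytest.raises(ValueError):
        resample(planck_2700, np.array([]))


def test_photopic_illuminance_basics(bundle, grid, planck_2700):
    zero = Spectrum("z", grid, np.zeros_like(grid))
    assert photopic_illuminance(zero, bundle) == 0.0
    e = photopic_illuminance(planck_2700, bundle)
    assert photopic_illuminance(planck_2700.scaled(2.0), bundle) == pytest.approx(2 * e)


def test_monochromatic_555_line(bundle, grid):
    """1 W m^-2 in a 1 nm bin at 555 nm is about 683 lx."""
    irr = np.zeros_like(grid)
    irr[np.argmin(np.abs(grid - 555.0))] = 1.0
    assert photopic_illuminance(Spectrum("line", grid, irr), bundle) == pytest.approx(683.0, rel=1e-3)


def test_scale_to_illuminance_contract(bundle, planck_2700):
    s = scale_to_illuminance(planck_2700, 500.0, bundle)
    assert photopic_illuminance(s, bundle) == pytest.approx(500.0, rel=1e-9)
    # idempotent
    s2 = scale_to_illuminance(s, 500.0, bundle)
    np.testing.assert_allclose(s2.irradiance, s.irradiance, rtol=1e-12)
    # explicit factor
    factor = 500.0 / photopic_illuminance(planck_2700, bundle)
    np.testing.assert_allclose(s.irradiance, planck_2700.irradiance * factor)


def test_scale_zero_spectrum_errors(bundle, grid):
    zero = Spectrum("z", grid, np.zeros_like(grid))
    with pytest.raises(ValueError):
        scale_to_illuminance(zero, 125.0, bundle)


def test_planckian_cct_recovery(bundle, grid):
    spec = Spectrum("p5000", grid, planckian_spd(grid, 5000.0))
    r = chromaticity_cct_duv(spec, bundle)
    assert r.cct == pytest.approx(5000.0, abs=2.0)
    assert abs(r.duv) < 1e-4
    assert r.cct_valid


def test_daylight_6504_cct(bundle, grid):
    spec = Spectrum("d6504", grid, daylight_spd(grid, cct=6504.0))
    r = chromaticity_cct_duv(spec, bundle)
    assert r.cct == pytest.approx(6504.0, abs=10.0)
    assert r.duv > 0


def test_equal_energy_chromaticity(bundle, grid):
    spec = Spectrum("ee", grid, np.ones_like(grid))
    r = chromaticity_cct_duv(spec, bundle)
    assert r.x == pytest.approx(1.0 / 3.0, abs=1e-12)
    assert r.y == pytest.approx(1.0 / 3.0, abs=1e-12)
    assert 5300 < r.cct < 5600  # near the Planckian-crossing of the EE point


@given(st.floats(min_value=1e-3, max_value=1e3))
def test_chromaticity_scale_invariant(bundle, factor):
    grid = bundle.grid
    spec = Spectrum("p", grid, planckian_spd(grid, 4000.0))
    r1 = chromaticity_cct_duv(spec, bundle)
    r2 = chromaticity_cct_duv(spec.scaled(factor), bundle)
    assert r1.x == pytest.approx(r2.x, abs=1e-12)
    assert r1.cct == pytest.approx(r2.cct, rel=1e-9)
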
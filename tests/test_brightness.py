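"""Brightness metrics: L_eq (Fotios), B2 (Bullough), M_TUD."""

import numpy as np
import pytest

from circalux import brightness as br
from circalux.spectra import Spectrum, photopic_illuminance, scale_to_illuminance


def test_leq_equal_energy_is_lv(bundle, grid):
    """A flat spectrum has S/V = 1, so L_eq equals the photopic value."""
    spec = Spectrum("ee", grid, np.full_like(grid, 1e-3))
    assert br.leq_fotios(spec, bundle) == pytest.approx(
        photopic_illuminance(spec, bundle), rel=1e-12)


def test_leq_linear_in_level(bundle, planck_2700):
    one = br.leq_fotios(planck_2700, bundle)
    assert br.leq_fotios(planck_2700.scaled(2.0), bundle) == pytest.approx(2 * one, rel=1e-12)


def test_leq_blue_rich_exceeds_warm(bundle, d65, illuminant_a):
    """At equal photopic level, D65 (higher S/V) is brighter than illuminant A."""
    d = scale_to_illuminance(d65, 500.0, bundle)
    a = scale_to_illuminance(illuminant_a, 500.0, bundle)
    assert br.leq_fotios(d, bundle) > br.leq_fotios(a, bundle)


def test_leq_zero_luminance_errors(bundle, grid):
    with pytest.raises(ValueError):
        br.leq_fotios(Spectrum("z", grid, np.zeros_like(grid)), bundle)


def test_b2_terms_and_additivity(bundle, grid, planck_2700, d65):
    zero = Spectrum("z", grid, np.zeros_like(grid))
    assert br.b2_bullough(zero, bundle) == 0.0
    # g = 0 drops the S-cone term
    e = planck_2700.irradiance
    v = np.trapezoid(e * bundle.V.values, grid)
    mel = np.trapezoid(e * bundle.M_c.values, grid)
    assert br.b2_bullough(planck_2700, bundle, g=0.0) == pytest.approx(v + 0.5 * mel, rel=1e-12)
    # linearity over spectra
    s12 = Spectrum("sum", grid, planck_2700.irradiance + d65.irradiance)
    assert br.b2_bullough(s12, bundle) == pytest.approx(
        br.b2_bullough(planck_2700, bundle) + br.b2_bullough(d65, bundle), rel=1e-12)
    with pytest.raises(ValueError):
        br.b2_bullough(planck_2700, bundle, g=-0.1)


@pytest.mark.parametrize("ev,s_ratio,mel_ratio,expected", [
    (108.0, 0.27, 0.14, 55.32),   # Amber 1 reference condition
    (94.0, 3.29, 1.13, 62.15),    # Amber 2 test condition, row 1
    (125.0, 0.27, 0.14, 58.27),   # Amber 1 test condition, row 2
])
def test_m_tud_worked_examples(ev, s_ratio, mel_ratio, expected):
    assert br.m_tud(ev, s_ratio, mel_ratio) == pytest.approx(expected, rel=0.01)


def test_m_tud_relative_differences():
    """Row-wise equibrightness pairs differ by +12.3 % and -10.5 % (within 0.5 pp)."""
    ref1 = br.m_tud(108.0, 0.27, 0.14)
    test1 = br.m_tud(94.0, 3.29, 1.13)
    ref2 = br.m_tud(108.0, 3.29, 1.13)
    test2 = br.m_tud(125.0, 0.27, 0.14)
    assert 100.0 * (test1 - ref1) / ref1 == pytest.approx(12.3, abs=0.5)
    assert 100.0 * (test2 - ref2) / ref2 == pytest.approx(-10.5, abs=0.5)


def test_m_tud_zero_and_validation():
    assert br.m_tud(0.0, 0.27, 0.14) == pytest.approx(-1.3307)
    with pytest.raises(ValueError):
        br.m_tud(100.0, 0.0, 0.14)
    with pytest.raises(ValueError):
        br.m_tud(-1.0, 0.27, 0.14)


def test_m_tud_monotone_in_each_argument():
    base = br.m_tud(200.0, 0.8, 0.6)
    assert br.m_tud(220.0, 0.8, 0.6) > base
    assert br.m_tud(200.0, 0.9, 0.6) > base
    assert br.m_tud(200.0, 0.8, 0.7) > base


def test_m_tud_from_spectrum_consistent(bundle, d65):
    """The spectrum entry path equals the ratio entry path with its own ratios."""
    s = scale_to_illuminance(d65, 500.0, bundle)
    s_ratio, mel_ratio = br.spectrum_ratios(s, bundle)
    assert br.m_tud_from_spectrum(s, bundle) == pytest.approx(
        br.m_tud(500.0, s_ratio, mel_ratio), rel=1e-9)
    # equal-energy normalization: flat spectrum has both ratios = 1
    ee = Spectrum("ee", bundle.grid, np.ones_like(bundle.grid))
    r1, r2 = br.spectrum_ratios(ee, bundle)
    assert r1 == pytest.approx(1.0, rel=1e-12)
    assert r2 == pytest.approx(1.0, rel=1e-12)
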
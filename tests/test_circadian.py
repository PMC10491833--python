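"""Circadian-light models, CS conversion, mEDI, melatonin-suppression formula."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from circalux import circadian as cd
from circalux.colorimetry import d65_spd, planckian_spd
from circalux.spectra import Spectrum, scale_to_illuminance


@pytest.fixture(scope="module")
def zero_spectrum(grid):
    return Spectrum("zero", grid, np.zeros_like(grid))


def test_opponent_sign_by_cct(bundle, planck_2700, d65):
    """Warm radiators give b-y < 0, cool daylight b-y > 0."""
    warm = scale_to_illuminance(planck_2700, 500.0, bundle)
    cool = scale_to_illuminance(d65, 500.0, bundle)
    assert cd.opponent_by(warm, bundle, "2021") < 0
    assert cd.opponent_by(cool, bundle, "2021") > 0


def test_opponent_zero_spectrum(bundle, zero_spectrum):
    assert cd.opponent_by(zero_spectrum, bundle) == 0.0


def test_cla_2018_zero_and_homogeneity(bundle, zero_spectrum, illuminant_a):
    assert cd.cla_2018(zero_spectrum, bundle).value == 0.0
    assert cd.cla_2018(zero_spectrum, bundle).branch == "warm"
    a1000 = cd.cla_2018(scale_to_illuminance(illuminant_a, 1000.0, bundle), bundle)
    a500 = cd.cla_2018(scale_to_illuminance(illuminant_a, 500.0, bundle), bundle)
    assert a1000.branch == "warm"
    assert a500.value == pytest.approx(a1000.value / 2.0, rel=1e-9)


def test_cla_illuminant_a_anchor(bundle, illuminant_a):
    """Definitional anchor: CL_A(illuminant A at 1000 lx) = 1000 within 2 %."""
    res = cd.cla_2018(scale_to_illuminance(illuminant_a, 1000.0, bundle), bundle)
    assert res.value == pytest.approx(1000.0, rel=0.02)


def test_cla_terms_sum_to_value(bundle, planck_2700, d65):
    for base in (planck_2700, d65):
        s = scale_to_illuminance(base, 500.0, bundle)
        for fn in (cd.cla_2018, cd.cla_2021):
            r = fn(s, bundle)
            assert r.value == pytest.approx(1548.0 * sum(r.terms.values()), abs=1e-9)
            assert (r.branch == "cold") == (r.by_signal > 0)


def test_cla_2021_not_scale_homogeneous(bundle, planck_2700):
    """The rod-saturation factor breaks degree-1 homogeneity of CL_A 2.0."""
    s = scale_to_illuminance(planck_2700, 500.0, bundle)
    doubled = cd.cla_2021(s.scaled(2.0), bundle).value
    assert doubled != pytest.approx(2.0 * cd.cla_2021(s, bundle).value, rel=1e-6)


def test_cla_2021_branch_flips_with_opponent(bundle, grid):
    """Branch flag flips exactly where the 2021 b-y signal crosses zero."""
    ccts = np.arange(3000.0, 4500.0, 50.0)
    signs, branches = [], []
    for t in ccts:
        s = scale_to_illuminance(Spectrum("p", grid, planckian_spd(grid, t)), 500.0, bundle)
        r = cd.cla_2021(s, bundle)
        signs.append(r.by_signal > 0)
        branches.append(r.branch == "cold")
    assert signs == branches
    assert not signs[0] and signs[-1]  # one crossing inside the window


def test_cs_half_saturation_and_examples():
    assert cd.circadian_stimulus(355.7) == pytest.approx(0.35, abs=1e-12)
    assert cd.circadian_stimulus(0.0) == 0.0
    assert cd.circadian_stimulus(3557.0) == pytest.approx(0.6488, abs=2e-4)
    # t and f multiply the dose
    assert cd.circadian_stimulus(355.7 / 2, t=2.0) == pytest.approx(0.35, abs=1e-12)
    assert cd.circadian_stimulus(355.7 / 2, f=2.0) == pytest.approx(0.35, abs=1e-12)


def test_cs_bounded_and_monotone():
    grid_cla = np.logspace(-2, 9, 400)
    cs = np.array([cd.circadian_stimulus(c) for c in grid_cla])
    assert np.all(cs < 0.7)
    assert np.all(np.diff(cs) > 0)


def test_cs_validation():
    with pytest.raises(ValueError):
        cd.circadian_stimulus(-1.0)
    with pytest.raises(ValueError):
        cd.circadian_stimulus(100.0, t=0.0)
    with pytest.warns(UserWarning):
        cd.circadian_stimulus(100.0, f=0.7)


@given(st.floats(min_value=0.0, max_value=1e6), st.floats(min_value=0.1, max_value=10.0))
def test_cs_monotone_in_dose(cla, t):
    assert cd.circadian_stimulus(cla * 1.01 + 1e-9, t) >= cd.circadian_stimulus(cla, t)


def test_medi_d65_identity(bundle, d65):
    for level in (125.0, 500.0, 750.0):
        s = scale_to_illuminance(d65, level, bundle)
        assert cd.medi(s, bundle) == pytest.approx(level, rel=1e-6)


def test_medi_zero_and_homogeneous(bundle, zero_spectrum, planck_2700):
    assert cd.medi(zero_spectrum, bundle) == 0.0
    s = scale_to_illuminance(planck_2700, 500.0, bundle)
    assert cd.medi(s.scaled(3.0), bundle) == pytest.approx(3.0 * cd.medi(s, bundle), rel=1e-12)


def test_medi_illuminant_a_against_brute_force(bundle, illuminant_a):
    """Independent rectangle-rule integration over the bundled tables."""
    from importlib import resources

    def load(name):
        rows = [
            [float(t) for t in ln.split(",")]
            for ln in resources.files("circalux.data").joinpath(name)
            .read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        return np.array(rows)

    g = bundle.grid
    smel_tab = load("melanopic_s026.csv")
    smel = np.interp(g, smel_tab[:, 0], smel_tab[:, 1])
    s = scale_to_illuminance(illuminant_a, 1000.0, bundle)
    d65_1lx = scale_to_illuminance(Spectrum("d", g, d65_spd(g)), 1.0, bundle)
    oracle = np.sum(s.irradiance * smel) / np.sum(d65_1lx.irradiance * smel)
    assert cd.medi(s, bundle) == pytest.approx(oracle, rel=1e-4)


def test_gimenez_as_printed_examples():
    r = cd.gimenez_suppression(100.0, 60.0, 0)
    assert r.value == pytest.approx(-51.58, abs=0.01)
    assert r.magnitude == pytest.approx(51.58, abs=0.01)
    assert r.as_printed and "verbatim" in r.caveat
    assert cd.gimenez_suppression(305.3, 60.0, 0).magnitude == pytest.approx(50.1, abs=0.05)
    # divisor at (60 min, no dilation) is 9.002 - 0.48 = 8.522
    assert 9.002 - 0.008 * 60.0 - 0.462 * 0 == pytest.approx(8.522)


def test_gimenez_validation():
    with pytest.raises(ValueError):
        cd.gimenez_suppression(0.0)
    with pytest.raises(ValueError):
        cd.gimenez_suppression(100.0, -5.0)
    with pytest.raises(ValueError):
        cd.gimenez_suppression(100.0, 60.0, 2)
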
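import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from circalux.observers import load_bundle
from circalux.colorimetry import planckian_spd, d65_spd
from circalux.ensemble import EnsembleConfig, generate_ensemble
from circalux.pipeline import compute_metric_table
from circalux.spectra import Spectrum

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    return load_bundle()


@pytest.fixture(scope="session")
def grid(bundle):
    return bundle.grid


@pytest.fixture(scope="session")
def planck_2700(grid):
    return Spectrum("planck2700", grid, planckian_spd(grid, 2700.0))


@pytest.fixture(scope="session")
def illuminant_a(grid):
    return Spectrum("illA", grid, planckian_spd(grid, 2856.0))


@pytest.fixture(scope="session")
def d65(grid):
    return Spectrum("d65", grid, d65_spd(grid), source_class="daylight")


@pytest.fixture(scope="session")
def small_ensemble(bundle):
    """A 40-spectrum ensemble for oracle and plumbing tests."""
    cfg = EnsembleConfig(
        seed=20240917,
        counts={"incandescent": 5, "fluorescent": 10, "led": 15, "daylight": 10},
    )
    spectra, manifest = generate_ensemble(cfg, bundle)
    return spectra, manifest


@pytest.fixture(scope="session")
def default_ensemble(bundle):
    """The full default corpus stand-in (884 spectra)."""
    cfg = EnsembleConfig(seed=20240917)
    spectra, manifest = generate_ensemble(cfg, bundle)
    return spectra, manifest


@pytest.fixture(scope="session")
def default_metric_table(default_ensemble, bundle):
    spectra, _ = default_ensemble
    return compute_metric_table(spectra, bundle)
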
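import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import betaseed as bs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def y90():
    return bs.get_nuclide("90Y")


@pytest.fixture(scope="session")
def spectrum_y90(y90):
    return bs.build_spectrum(y90, n_bins=500)


@pytest.fixture(scope="session")
def kernel_y90(spectrum_y90):
    return bs.CSDAKernel(spectrum_y90)


@pytest.fixture(scope="session")
def seed_spec():
    return bs.yas_seed()


@pytest.fixture(scope="session")
def small_sim(seed_spec, spectrum_y90):
    """Quick engine run for structural/unit checks."""
    return bs.SeedDoseModel(seed_spec, spectrum_y90).fit(
        n_histories=150_000, rng_seed=11
    )


@pytest.fixture(scope="session")
def big_sim(seed_spec, spectrum_y90):
    """Production-size engine run shared by the statistical checks."""
    return bs.SeedDoseModel(seed_spec, spectrum_y90).fit(
        n_histories=1_000_000, rng_seed=20260930
    )


@pytest.fixture(scope="session")
def table4():
    return bs.load_reference_table("table4_radial_dose_rate").data


@pytest.fixture(scope="session")
def table6():
    return bs.load_reference_table("table6_gL").data
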
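import pytest

from tscocryst import LibraryConfig, make_fingerprint_library
from tscocryst.design_space import FractionField, GranulatorSpec


@pytest.fixture(scope="session")
def default_library():
    """Full 21-fingerprint library on the default 1,000-point grid."""
    return make_fingerprint_library(seed=1)


@pytest.fixture(scope="session")
def small_library():
    """Six-fingerprint library — full-column-rank at order 3, so
    linear-only mixtures are exactly recoverable."""
    cfg = LibraryConfig(families={"CO": 4, "DI": 1, "DN": 1})
    return make_fingerprint_library(cfg, seed=7)


@pytest.fixture(scope="session")
def pipeline_library():
    """Seven-fingerprint library containing CO-2 and CO-5, used by the
    design-space / controller pipeline tests."""
    cfg = LibraryConfig(families={"CO": 5, "DI": 1, "DN": 1})
    return make_fingerprint_library(cfg, seed=11)


@pytest.fixture(scope="session")
def cocrystal_field():
    return FractionField.default_cocrystal_field()


@pytest.fixture(scope="session")
def granulator():
    return GranulatorSpec(L=1.0, f=0.01, psi=1.0)
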
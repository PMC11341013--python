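import numpy as np
import pytest

from chscreen import make_variant_catalog, simulate_matched_discovery_cohort
from chscreen.simulate import catalog_annotations


@pytest.fixture(scope="session")
def small_catalog():
    """50-variant catalog with 5 planted panel mutations."""
    catalog, truth = make_variant_catalog(50, 5, seed=3)
    return catalog, truth


@pytest.fixture(scope="session")
def small_discovery(small_catalog):
    """Matched tumor/blood calls for 200 patients over the small catalog."""
    catalog, truth = small_catalog
    calls = simulate_matched_discovery_cohort(catalog, 200, seed=11)
    return calls, catalog, truth


@pytest.fixture(scope="session")
def small_annotations(small_catalog):
    catalog, _ = small_catalog
    return catalog_annotations(catalog)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
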
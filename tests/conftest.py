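import pytest
from hypothesis import settings

from whey2xanthin import rsm, synthdata

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """The packaged 30-run central composite design with both responses."""
    return synthdata.table1_design()


@pytest.fixture(scope="session")
def surfaces(table1):
    """Quadratic surfaces fitted to both responses of the packaged design."""
    return {
        name: rsm.fit_quadratic(table1, name)
        for name in ("bcrx_mg_l", "biomass_g_l")
    }


@pytest.fixture(scope="session")
def table3():
    """Packaged kinetic parameter sets keyed by cheese-whey dose (% v/v)."""
    return synthdata.table3_params()
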
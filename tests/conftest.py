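import numpy as np
import pytest

import pilespot as ps
from pilespot import synthetic as syn


@pytest.fixture(scope="session")
def piles():
    return ps.load_pile_specs()


@pytest.fixture(scope="session")
def a1(piles):
    return piles["A1"]


@pytest.fixture(scope="session")
def c1(piles):
    return piles["C1"]


@pytest.fixture(scope="session")
def published(piles):
    return ps.load_published_inventory()


def interior_queries(rng, sites, n):
    """Strictly interior query points as positive convex combinations of sites."""
    w = rng.dirichlet(np.ones(len(sites)), size=n)
    return w @ sites


def make_quiet_scenario(pile, seed=0, anomalies=(), noise_sd=None):
    return ps.preset_scenario("quiet", pile, seed=seed, anomalies=anomalies,
                              noise_sd=noise_sd)


def injection_at(loc, spot_type, day):
    """A single-day anomaly centred exactly on a probe tip, strong enough to
    clear every threshold by well over two instrument resolutions on the
    quiet background."""
    if spot_type == "hot":
        return syn.SpotInjection(
            "hot", (loc.x_m, loc.y_m, loc.z_m), 0.5, (day, day),
            delta_temp_C=30.0, delta_o2_pct=-8.0, delta_co2_pct=6.0,
            delta_co_ppm=500.0,
        )
    return syn.SpotInjection(
        "cold", (loc.x_m, loc.y_m, loc.z_m), 0.5, (day, day),
        delta_temp_C=-20.0, delta_o2_pct=8.0, delta_co2_pct=-3.0,
    )
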
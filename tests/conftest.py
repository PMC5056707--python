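import numpy as np
import pytest

from gsikit.assignment import holdout_split
from gsikit.core import counts_by_group
from gsikit.panel import rank_and_select, wc_theta_per_locus
from gsikit.simulate import SimConfig, demo18, simulate_baseline

DEMO_SEED = 11


@pytest.fixture(scope="session")
def demo_baseline():
    """The default 18-river demonstration baseline (864 fish, 300 loci)."""
    gm, hierarchy, loci = simulate_baseline(demo18(seed=DEMO_SEED))
    return gm, hierarchy


@pytest.fixture(scope="session")
def demo_split(demo_baseline):
    gm, hierarchy = demo_baseline
    train, hold = holdout_split(gm, hierarchy, per_site_holdout=6, seed=1)
    return train, hold, hierarchy


@pytest.fixture(scope="session")
def demo_ranked(demo_split):
    """River-level theta ranking on the training set."""
    train, hold, hierarchy = demo_split
    theta = wc_theta_per_locus(counts_by_group(train, hierarchy, "river"))
    return rank_and_select(theta, (12, 24, 96, 192, 288))


@pytest.fixture(scope="session")
def small_baseline():
    """Six well-differentiated rivers: fast and assignable near-perfectly."""
    cfg = SimConfig(n_regions=2, rivers_per_region=3, sites_per_river=2,
                    fish_per_site=20, n_loci=150, f_region=0.05, f_river=0.15,
                    f_site=0.002, seed=7)
    gm, hierarchy, loci = simulate_baseline(cfg)
    return gm, hierarchy


@pytest.fixture(scope="session")
def planted_baseline():
    """Same six rivers but with two river pairs made genetically identical."""
    cfg = SimConfig(n_regions=2, rivers_per_region=3, sites_per_river=2,
                    fish_per_site=20, n_loci=150, f_region=0.05, f_river=0.15,
                    f_site=0.002, seed=7)
    gm, hierarchy, loci = simulate_baseline(
        cfg, identical_river_pairs=[(0, 1), (3, 4)])
    return gm, hierarchy


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
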
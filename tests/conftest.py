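"""Shared fixtures: worked small systems and the reduced sweep."""

import numpy as np
import pytest

from cisterna.boolean_core import Orbit, RuleSet
from cisterna.network_analysis import build_network
from cisterna.rule_sampling import SweepGrid, sweep

MASTER_SEED = 1


def make_rules(N, g_edges, f_edges, A=None):
    """RuleSet from explicit (compartment, vesicle) index pairs."""
    size = 1 << N
    G = np.zeros((size, size), dtype=bool)
    F = np.zeros((size, size), dtype=bool)
    for i, j in g_edges:
        G[i, j] = True
    for i, j in f_edges:
        F[i, j] = True
    return RuleSet(N=N, G=G, F=F, A=A)


@pytest.fixture
def n2_rules():
    """The two-label maturation chain: [10] buds X, [01] buds Y, Y fuses
    into [10]; X vesicles are orphans sustaining the chain homotypically."""
    return make_rules(2, g_edges=[(2, 2), (1, 1)], f_edges=[(2, 1)], A=1)


@pytest.fixture
def balanced_n1_rules():
    """Single-label transport balance: [1] buds and re-accepts its vesicle."""
    return make_rules(1, g_edges=[(1, 1)], f_edges=[(1, 1)], A=1)


@pytest.fixture
def period2_rules():
    """Hand-built two-cycle: {[11]} <-> {[01],[10]} under the update."""
    return make_rules(2, g_edges=[(3, 2), (2, 2)], f_edges=[(1, 2)], A=1)


def _networks_from(result):
    nets = []
    for rec in result.records:
        orbit = Orbit(states=[rec.state], period=1,
                      steps_to_orbit=rec.steps_to_orbit, reached=True,
                      homotypic_types=rec.homotypic_types)
        nets.append(build_network(rec.rules, orbit))
    return nets


@pytest.fixture(scope="session")
def sweep_n7():
    """Reduced N=7 sweep (2 rule draws per parameter combination)."""
    return sweep(SweepGrid.reduced(master_seed=MASTER_SEED))


@pytest.fixture(scope="session")
def networks_n7(sweep_n7):
    return _networks_from(sweep_n7)


@pytest.fixture(scope="session")
def networks_all_n(networks_n7):
    """Homeostatic networks pooled over N=4..7 (reduced replication)."""
    nets = []
    for N in (4, 5, 6):
        grid = SweepGrid(N_values=(N,), rules_per_combo=2,
                         master_seed=MASTER_SEED)
        nets.extend(_networks_from(sweep(grid)))
    return nets + list(networks_n7)
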
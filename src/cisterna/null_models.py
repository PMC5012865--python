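"""Degree-preserving randomization of creation and maturation edges.

The null model asks whether motif and chain statistics of homeostatic
networks follow from local node properties alone. Vesicle edges are removed
outright; the remaining creation and maturation edges are randomized by
repeated target swaps, allowed only within an edge type. A candidate swap of
(a -> b, c -> d) into (a -> d, c -> b) is rejected if it would lose or
create a self-edge or produce a duplicate (source, target) pair within the
type. Per node and per edge type, in-degrees, out-degrees and the self-edge
set are therefore preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_analysis import TrafficNetwork

__all__ = ["ShuffleConfig", "shuffle_network", "shuffle_ensemble"]


@dataclass(frozen=True)
class ShuffleConfig:
    """Swap budget and replication for the shuffled ensemble.

    ``swaps_per_edge`` scales the attempted-swap budget with the number of
    edges of each type (rejected attempts consume budget); 10 attempts per
    edge mixes these small graphs thoroughly. 1000 replicates per network
    is the reference ensemble size.
    """

    swaps_per_edge: int = 10
    replicates: int = 1000

    def __post_init__(self):
        if self.swaps_per_edge < 1 or self.replicates < 1:
            raise ValueError("swap budget and replicates must be positive")


def _swap_edges(edges: list, budget: int, rng: np.random.Generator) -> list:
    """Randomize edge targets in place, preserving degrees and self-edges."""
    movable = [k for k, (a, b) in enumerate(edges) if a != b]
    if len(movable) < 2:
        return edges
    present = set(edges)
    for _ in range(budget):
        k1, k2 = rng.choice(len(movable), size=2, replace=False)
        e1, e2 = edges[movable[k1]], edges[movable[k2]]
        if e1 == e2:
            continue
        a, b = e1
        c, d = e2
        n1, n2 = (a, d), (c, b)
        if n1[0] == n1[1] or n2[0] == n2[1]:     # would create a self-edge
            continue
        if n1 == n2 or n1 in present or n2 in present:
            continue
        present.discard(e1)
        present.discard(e2)
        present.add(n1)
        present.add(n2)
        edges[movable[k1]] = n1
        edges[movable[k2]] = n2
    return edges


def shuffle_network(net: TrafficNetwork, cfg: ShuffleConfig,
                    rng: np.random.Generator) -> TrafficNetwork:
    """One shuffled replicate: vesicle edges dropped, creation and
    maturation edges target-swapped within type."""
    creation = sorted(net.creation_edges)
    maturation = sorted(net.maturation_edges.items())
    creation = _swap_edges(list(creation), cfg.swaps_per_edge * len(creation), rng)
    maturation = _swap_edges(list(maturation), cfg.swaps_per_edge * len(maturation), rng)
    return TrafficNetwork(
        N=net.N, nodes=net.nodes, vesicle_edges={},
        creation_edges=frozenset(creation),
        maturation_edges=dict(maturation),
        homotypic_types=net.homotypic_types,
        updates=None,
        meta={**net.meta, "shuffled": True})


def shuffle_ensemble(net: TrafficNetwork, cfg: ShuffleConfig,
                     rng: np.random.Generator):
    """Generator of ``cfg.replicates`` shuffled copies of ``net``."""
    for _ in range(cfg.replicates):
        yield shuffle_network(net, cfg, rng)
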
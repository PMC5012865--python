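"""Traffic graphs of homeostatic states and their statistics.

A homeostatic (period-1) state maps onto a directed graph whose nodes are
the compartment compositions present, with three typed edge sets read off a
single Boolean update:

* vesicle edges: source -> target wherever some budded vesicle type couples
  the pair through the budding and fusion rules;
* creation edges: source -> nucleated compartment, for each orphan vesicle
  type undergoing homotypic fusion;
* maturation edges: a compartment's composition at t -> its composition at
  t+1, absent when the compartment is in transport balance.

On top of this the module computes everything reported about such networks:
connected subsets, maturation chains and cycles with their terminal fates,
the catalog of three-compartment creation/maturation motifs and per-network
motif counts, retrograde-vesicle fractions over compartment pairs, molecular
sinks, and per-network summary tables.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .boolean_core import Orbit, RuleSet, step_cell

__all__ = [
    "TrafficNetwork",
    "MaturationChain",
    "MotifCatalog",
    "build_network",
    "connected_subsets",
    "find_chains",
    "enumerate_motifs",
    "count_motifs",
    "retrograde_stats",
    "RetrogradeStats",
    "label_sinks",
    "summarize",
]


@dataclass
class TrafficNetwork:
    """A homeostatic vesicle traffic network.

    ``vesicle_edges`` maps ordered node pairs to the set of vesicle
    composition indices carried; ``maturation_edges`` maps each maturing
    node to its (unique) successor; ``updates`` records the full update
    image of every node (0 = vesiculation), when known.
    """

    N: int
    nodes: tuple
    vesicle_edges: dict
    creation_edges: frozenset     # ordered (source, created) pairs
    maturation_edges: dict        # node -> node, successor != node
    homotypic_types: frozenset = frozenset()
    updates: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = tuple(sorted(self.nodes))
        node_set = set(self.nodes)
        for (a, b) in self.vesicle_edges:
            if a not in node_set or b not in node_set:
                raise ValueError("vesicle edge endpoint not a node")
        for a, b in self.maturation_edges.items():
            if a == b:
                raise ValueError("maturation self-edge is not allowed")

    @property
    def n_compartments(self) -> int:
        return len(self.nodes)

    @property
    def vesicle_types(self) -> frozenset:
        """All distinct budded vesicle types (edge-borne plus orphans)."""
        out = set(self.homotypic_types)
        for js in self.vesicle_edges.values():
            out.update(js)
        return frozenset(out)

    @property
    def stable_nodes(self) -> frozenset:
        """Transport-balanced compartments: update image equals themselves."""
        if self.updates is None:
            return frozenset(n for n in self.nodes if n not in self.maturation_edges)
        return frozenset(n for n in self.nodes if self.updates.get(n) == n)

    @property
    def dissipating_nodes(self) -> frozenset:
        if self.updates is None:
            return frozenset()
        return frozenset(n for n in self.nodes if self.updates.get(n) == 0)

    def creation_targets(self) -> frozenset:
        return frozenset(j for _, j in self.creation_edges)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph(N=self.N)
        g.add_nodes_from(self.nodes)
        for (a, b), js in self.vesicle_edges.items():
            g.add_edge(a, b, kind="vesicle", vesicles=tuple(sorted(js)))
        for a, b in sorted(self.creation_edges):
            g.add_edge(a, b, kind="creation")
        for a, b in sorted(self.maturation_edges.items()):
            g.add_edge(a, b, kind="maturation")
        return g

    def is_trivial(self) -> bool:
        """True when no compartment connects to any other (self-edges only)."""
        if any(a != b for a, b in self.vesicle_edges):
            return False
        if any(a != b for a, b in self.creation_edges):
            return False
        return not self.maturation_edges


def build_network(rules: RuleSet, orbit: Orbit) -> TrafficNetwork:
    """Read the typed traffic graph off one update of a homeostatic state."""
    if not orbit.homeostatic:
        raise ValueError("traffic networks are defined for homeostatic "
                         "(period-1, nonempty) orbits")
    state = orbit.states[0]
    sr = step_cell(state, rules)
    if sr.next_state != state:
        raise ValueError("orbit state is not a fixed point of the update")

    node_set = set(state)
    vesicle_edges: dict = {}
    for i1 in state:
        for j in rules._g_rows[i1]:
            j = int(j)
            for i2 in state:
                if rules.F[i2, j]:
                    vesicle_edges.setdefault((i1, i2), set()).add(j)
    vesicle_edges = {k: frozenset(v) for k, v in vesicle_edges.items()}

    creation = set()
    for j in sr.created:
        if j not in node_set:  # cannot happen at a fixed point; be defensive
            raise ValueError("created compartment missing from the fixed point")
        for i in state:
            if rules.G[i, j]:
                creation.add((i, j))

    return TrafficNetwork(
        N=rules.N, nodes=state, vesicle_edges=vesicle_edges,
        creation_edges=frozenset(creation), maturation_edges=dict(sr.matured),
        homotypic_types=sr.created, updates=dict(sr.updates))


def connected_subsets(net: TrafficNetwork) -> list:
    """Weakly connected components over the union of all three edge types."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((a, b) for (a, b) in net.vesicle_edges if a != b)
    g.add_edges_from((a, b) for (a, b) in net.creation_edges if a != b)
    g.add_edges_from(net.maturation_edges.items())
    return [frozenset(c) for c in nx.connected_components(g)]


@dataclass
class MaturationChain:
    """A creation-fed run of maturation edges.

    ``path`` lists the visited compartments starting at the created one;
    ``length`` counts maturation edges traversed. A chain ends either at a
    compartment with no outgoing maturation edge (``terminal_kind="fixed"``,
    with ``dissipates`` telling whether that compartment's next update is the
    null composition) or, if a visited compartment recurs, in a maturation
    cycle stored separately (``terminal_kind="cycle"``).
    """

    start: int
    path: tuple
    length: int
    terminal_kind: str            # "fixed" | "cycle"
    terminal: int
    dissipates: bool | None = None
    cycle: tuple | None = None


def _canonical_cycle(nodes: Sequence[int]) -> tuple:
    nodes = tuple(nodes)
    k = int(np.argmin(nodes))
    return nodes[k:] + nodes[:k]


def find_chains(net: TrafficNetwork):
    """One maturation chain per compartment with an incoming creation edge.

    Returns ``(chains, cycles)`` where ``cycles`` lists the distinct
    maturation cycles reached by any chain, in canonical rotation.
    """
    chains: list[MaturationChain] = []
    cycles: set[tuple] = set()
    succ = net.maturation_edges
    for start in sorted(net.creation_targets()):
        seq = [start]
        pos = {start: 0}
        cur = start
        while True:
            nxt = succ.get(cur)
            if nxt is None:
                dissip = None
                if net.updates is not None:
                    dissip = net.updates.get(cur) == 0
                chains.append(MaturationChain(
                    start=start, path=tuple(seq), length=len(seq) - 1,
                    terminal_kind="fixed", terminal=cur, dissipates=dissip))
                break
            if nxt in pos:
                cyc = _canonical_cycle(seq[pos[nxt]:])
                cycles.add(cyc)
                chains.append(MaturationChain(
                    start=start, path=tuple(seq), length=len(seq) - 1,
                    terminal_kind="cycle", terminal=cur, cycle=cyc))
                break
            seq.append(nxt)
            pos[nxt] = len(seq) - 1
            cur = nxt
    return chains, sorted(cycles)


# --------------------------------------------------------------------------
# Three-compartment motifs over creation + maturation edges.
#
# A labeled motif on nodes {0,1,2} with two directed edge types (each with
# self-loops) is an 18-bit code: bit  t*9 + u*3 + v  set iff there is a
# type-t edge u -> v, with t=0 creation, t=1 maturation. There are 2^18 =
# 262,144 labeled graphs; keeping those weakly connected over the union of
# edge types and identifying graphs under the 6 node permutations yields the
# motif catalog.
# --------------------------------------------------------------------------

_PERMS3 = tuple(itertools.permutations(range(3)))


def _bit_permutations(edge_types: int = 2) -> np.ndarray:
    """For each node permutation, where each bit of the code moves to."""
    nbits = 9 * edge_types
    table = np.zeros((len(_PERMS3), nbits), dtype=np.int64)
    for pi, perm in enumerate(_PERMS3):
        for t in range(edge_types):
            for u in range(3):
                for v in range(3):
                    table[pi, t * 9 + u * 3 + v] = t * 9 + perm[u] * 3 + perm[v]
    return table


def _apply_bit_perm(codes: np.ndarray, mapping: np.ndarray) -> np.ndarray:
    out = np.zeros_like(codes)
    for b in range(mapping.size):
        out |= ((codes >> b) & 1) << int(mapping[b])
    return out


def _connected3_mask(codes: np.ndarray, edge_types: int = 2) -> np.ndarray:
    """Weak connectivity over the union of edge types (self-loops ignored)."""
    linked = []
    for (u, v) in ((0, 1), (0, 2), (1, 2)):
        mask = 0
        for t in range(edge_types):
            mask |= 1 << (t * 9 + u * 3 + v)
            mask |= 1 << (t * 9 + v * 3 + u)
        linked.append((codes & mask) != 0)
    linked = np.stack(linked)
    return linked.sum(axis=0) >= 2


def canonical_code(code: int, edge_types: int = 2) -> int:
    """Minimum code over the 6 node permutations (scalar version)."""
    table = _bit_permutations(edge_types)
    best = None
    for pi in range(table.shape[0]):
        mapped = 0
        for b in range(table.shape[1]):
            if (code >> b) & 1:
                mapped |= 1 << int(table[pi, b])
        best = mapped if best is None else min(best, mapped)
    return best


@dataclass
class MotifCatalog:
    """Deterministic, indexed catalog of connected 3-node motif classes."""

    edge_types: int
    classes: np.ndarray                 # sorted canonical codes
    canon: np.ndarray                   # canonical code for every labeled code
    index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {int(c): k for k, c in enumerate(self.classes)}

    def __len__(self) -> int:
        return len(self.classes)


def enumerate_motifs(edge_types: int = 2) -> MotifCatalog:
    """Brute-force the full labeled space and canonicalize.

    For two edge types this enumerates all 262,144 labeled graphs and yields
    the connected-motif catalog (43,700 classes).
    """
    nbits = 9 * edge_types
    codes = np.arange(1 << nbits, dtype=np.int64)
    table = _bit_permutations(edge_types)
    canon = codes.copy()
    for pi in range(1, table.shape[0]):
        np.minimum(canon, _apply_bit_perm(codes, table[pi]), out=canon)
    connected = _connected3_mask(codes, edge_types)
    classes = np.unique(canon[connected])
    return MotifCatalog(edge_types=edge_types, classes=classes, canon=canon)


def _motif_code(triple: Sequence[int], creation: Iterable, maturation: Iterable) -> int:
    idx = {node: k for k, node in enumerate(triple)}
    code = 0
    for a, b in creation:
        if a in idx and b in idx:
            code |= 1 << (idx[a] * 3 + idx[b])
    for a, b in maturation:
        if a in idx and b in idx:
            code |= 1 << (9 + idx[a] * 3 + idx[b])
    return code


def count_motifs(net: TrafficNetwork, catalog: MotifCatalog) -> Counter:
    """Count induced connected 3-node creation/maturation subgraphs.

    Every 3-subset of compartments contributes at most one motif instance:
    the exact induced edge pattern, when weakly connected. Returns a Counter
    keyed by catalog index; presence/absence is just its support.
    """
    creation = sorted(net.creation_edges)
    maturation = sorted(net.maturation_edges.items())
    incident: set[int] = set()
    for a, b in itertools.chain(creation, maturation):
        if a != b:
            incident.add(a)
            incident.add(b)
    counts: Counter = Counter()
    canon = catalog.canon
    for triple in itertools.combinations(sorted(incident), 3):
        code = _motif_code(triple, creation, maturation)
        if code and bool(_connected3_mask(np.array([code]))[0]):
            counts[catalog.index[int(canon[code])]] += 1
    return counts


@dataclass
class RetrogradeStats:
    """Fractions of ordered compartment pairs (A, B) carrying a B->A vesicle.

    ``f_all`` is over all ordered pairs of distinct compartments; each
    conditional restricts to pairs where A sends a vesicle to B, B matures
    to A, or A matures to B. Conditionals with no qualifying pairs are None.
    """

    f_all: float | None
    f_vesicle_pairs: float | None
    f_b_matures_to_a: float | None
    f_a_matures_to_b: float | None
    n_maturation_edges: int


def retrograde_stats(net: TrafficNetwork) -> RetrogradeStats:
    nodes = net.nodes
    ves = {(a, b) for (a, b) in net.vesicle_edges if a != b}
    mat = set(net.maturation_edges.items())
    n = len(nodes)

    def frac(pairs):
        pairs = list(pairs)
        if not pairs:
            return None
        return sum((b, a) in ves for a, b in pairs) / len(pairs)

    all_pairs = [(a, b) for a in nodes for b in nodes if a != b]
    return RetrogradeStats(
        f_all=frac(all_pairs),
        f_vesicle_pairs=frac(ves),
        f_b_matures_to_a=frac((a, b) for (b, a) in mat),
        f_a_matures_to_b=frac(mat),
        n_maturation_edges=len(mat),
    )


def _label_bit(N: int, label: int) -> int:
    return 1 << (N - 1 - label)


def label_sinks(net: TrafficNetwork, labels: Iterable[int] | None = None) -> frozenset:
    """Labels whose flow graph traps them in a compartment group.

    For each label (0-based, leftmost label first) the flow graph keeps the
    vesicle edges whose carried vesicles contain the label, plus the creation
    edges whose orphan vesicle does. The label has a sink iff some terminal
    strongly connected component of that graph has an incoming flow edge and
    no outgoing one: the label is received by the group and never leaves, so
    homeostasis of amounts would need compensatory synthesis.
    """
    labels = range(net.N) if labels is None else labels
    out: set[int] = set()
    for n in labels:
        bit = _label_bit(net.N, n)
        g = nx.DiGraph()
        g.add_nodes_from(net.nodes)
        for (a, b), js in net.vesicle_edges.items():
            if any(j & bit for j in js):
                g.add_edge(a, b)
        for (a, b) in net.creation_edges:
            if b & bit:
                g.add_edge(a, b)
        cond = nx.condensation(g)
        for scc in cond.nodes:
            if cond.out_degree(scc) == 0 and cond.in_degree(scc) > 0:
                out.add(n)
                break
    return frozenset(out)


def summarize(networks: Iterable[TrafficNetwork]) -> pd.DataFrame:
    """Per-network summary table of the reported statistics."""
    rows = []
    for k, net in enumerate(networks):
        chains, cycles = find_chains(net)
        subsets = connected_subsets(net)
        n = net.n_compartments
        maturing = len(net.maturation_edges)
        created = len(net.creation_targets())
        lengths = [c.length for c in chains]
        rows.append({
            "network": k,
            "n_compartments": n,
            "n_vesicle_types": len(net.vesicle_types),
            "n_stable": len(net.stable_nodes),
            "maturation_fraction": maturing / n if n else np.nan,
            "creation_fraction": created / n if n else np.nan,
            "n_chains": len(chains),
            "max_chain_length": max(lengths, default=0),
            "chain_lengths": tuple(lengths),
            "has_cycle": bool(cycles),
            "n_homotypic": len(net.homotypic_types),
            "n_subsets": len(subsets),
            "trivial": net.is_trivial(),
            "mean_labels_per_compartment":
                float(np.mean([bin(i).count("1") for i in net.nodes])) if n else np.nan,
        })
    return pd.DataFrame(rows)
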
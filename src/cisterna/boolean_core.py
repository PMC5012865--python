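"""Deterministic Boolean dynamics of vesicle traffic.

A cell is a set of membrane compartments, each identified by which of ``N``
molecular labels (SNAREs, GTPases, lipids, cargo...) it carries in high
amounts. Compartment and vesicle identities are length-``N`` binary vectors;
we encode each vector as the integer whose binary digits it spells, leftmost
element most significant, so for ``N = 3`` index 5 is the composition
``[101]``. Index 0 (no labels) is the null composition: a compartment that
loses every label has vesiculated and is dropped from the cell state.

Dynamics are fixed by two binary rule matrices over the ``C = V = 2**N - 1``
nonzero compositions: the budding matrix ``G`` (compartment *i* emits vesicle
type *j*) and the fusion matrix ``F`` (vesicle *j* fuses into compartment
*i*). Vesicles inherit a subset of their source compartment's labels, so
``G[i, j] = 1`` requires ``j`` to be a bitwise subset of ``i``; each row of
``G`` carries at most ``A`` distinct vesicle types, one per adaptor/coatomer
complex. ``F`` is unconstrained.

At every synchronous timestep each compartment collapses its outgoing and
incoming vesicle streams into single OR'd vectors and updates by binary mass
balance: a label is gained if it fuses in and does not bud out, and lost if
it buds out and does not fuse in. Budded vesicle types with no fusion target
among the present compartments are orphans; they nucleate new compartments of
their own composition by homotypic fusion. Iterating the update over the
finite state space must reach a periodic orbit; a period-1 orbit is a
homeostatic state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "Composition",
    "RuleSet",
    "Orbit",
    "StepResult",
    "index_to_bits",
    "bits_to_index",
    "budded_vesicles",
    "vesicle_flows",
    "collapse_or",
    "update_compartment",
    "find_orphans",
    "step_cell",
    "run_to_orbit",
]

#: A cell state is a sorted tuple of distinct nonzero composition indices.
CellState = tuple


def index_to_bits(index: int, N: int) -> np.ndarray:
    """Binary label vector of a composition index (leftmost bit = MSB).

    >>> index_to_bits(5, 3)
    array([1, 0, 1], dtype=uint8)
    """
    index = int(index)
    if not 0 <= index <= (1 << N) - 1:
        raise ValueError(f"index {index} out of range for N={N}")
    return np.array([(index >> (N - 1 - n)) & 1 for n in range(N)], dtype=np.uint8)


def bits_to_index(bits: Iterable[int]) -> int:
    """Inverse of :func:`index_to_bits`."""
    out = 0
    for b in bits:
        b = int(b)
        if b not in (0, 1):
            raise ValueError("bits must be 0 or 1")
        out = (out << 1) | b
    return out


@dataclass(frozen=True)
class Composition:
    """A compartment or vesicle identity: an index plus its bit vector."""

    index: int
    N: int

    @property
    def bits(self) -> np.ndarray:
        return index_to_bits(self.index, self.N)

    def __str__(self) -> str:  # e.g. "[101]"
        return "[" + "".join(map(str, self.bits)) + "]"


class RuleSet:
    """Budding and fusion rules for one traffic system.

    Parameters
    ----------
    N
        Number of molecular label types.
    G, F
        Boolean arrays of shape ``(2**N, 2**N)``; row/column 0 correspond to
        the null composition and must be empty. ``G[i, j]`` means compartment
        ``i`` buds vesicle ``j``; ``F[i, j]`` means vesicle ``j`` fuses into
        compartment ``i``.
    A
        Adaptor/coatomer count bounding the distinct vesicle types per G row.
    """

    def __init__(self, N: int, G: np.ndarray, F: np.ndarray, A: int | None = None,
                 meta: dict | None = None):
        size = 1 << N
        G = np.asarray(G, dtype=bool)
        F = np.asarray(F, dtype=bool)
        if G.shape != (size, size) or F.shape != (size, size):
            raise ValueError(f"G and F must have shape ({size}, {size})")
        self.N = int(N)
        self.A = int(A) if A is not None else int(max(1, G.sum(axis=1).max(initial=1)))
        self.G = G
        self.F = F
        self.meta = dict(meta or {})
        self.validate()
        # compiled helpers for the inner loop
        self._row_out_or = np.zeros(size, dtype=np.int64)
        self._g_rows: list[np.ndarray] = []
        for i in range(size):
            js = np.flatnonzero(G[i])
            self._g_rows.append(js)
            if js.size:
                self._row_out_or[i] = np.bitwise_or.reduce(js)

    @property
    def C(self) -> int:
        return (1 << self.N) - 1

    V = C

    def validate(self) -> None:
        size = 1 << self.N
        if self.G[0].any() or self.G[:, 0].any():
            raise ValueError("null composition must not bud or be budded")
        if self.F[0].any() or self.F[:, 0].any():
            raise ValueError("null composition must not fuse or be fused")
        i_idx, j_idx = np.nonzero(self.G)
        if np.any((j_idx & i_idx) != j_idx):
            raise ValueError("G violates the subset (Sierpinski) constraint")
        if self.G.sum(axis=1).max(initial=0) > self.A:
            raise ValueError(f"a G row has more than A={self.A} vesicle types")
        if size != self.G.shape[0]:
            raise ValueError("inconsistent N")

    def __eq__(self, other) -> bool:
        return (isinstance(other, RuleSet) and self.N == other.N
                and np.array_equal(self.G, other.G) and np.array_equal(self.F, other.F))

    def __repr__(self) -> str:
        return (f"RuleSet(N={self.N}, A={self.A}, "
                f"nG={int(self.G.sum())}, nF={int(self.F.sum())})")


@dataclass
class StepResult:
    """Bookkeeping for one synchronous update of the cell state."""

    next_state: CellState
    created: frozenset        # orphan vesicle types nucleating new compartments
    matured: dict             # old composition -> new composition (old != new)
    dissipated: frozenset     # compartments updating to the null composition
    updates: dict             # every present compartment -> its image (may be 0)


@dataclass
class Orbit:
    """A periodic orbit of the Boolean dynamics.

    ``homotypic_types`` are the orphan vesicle types nucleating compartments
    within the orbit; in a homeostatic (period-1) state these are exactly the
    vesicle types that must be granted homotypic fusion to sustain it.
    """

    states: list
    period: int
    steps_to_orbit: int
    reached: bool
    homotypic_types: frozenset = field(default_factory=frozenset)

    @property
    def homeostatic(self) -> bool:
        return self.reached and self.period == 1 and not self.degenerate

    @property
    def degenerate(self) -> bool:
        """True for the empty cell, a fixed point not counted as a network."""
        return self.reached and all(len(s) == 0 for s in self.states)


def _check_state(state: Iterable[int], N: int) -> CellState:
    state = tuple(sorted({int(i) for i in state}))
    if state and (state[0] < 1 or state[-1] > (1 << N) - 1):
        raise ValueError("cell state indices must lie in 1..2^N-1")
    return state


def budded_vesicles(state: CellState, rules: RuleSet) -> frozenset:
    """All vesicle types budded anywhere in the cell at this timepoint."""
    out: set[int] = set()
    for i in state:
        out.update(rules._g_rows[i].tolist())
    return frozenset(out)


def vesicle_flows(i: int, state: CellState, rules: RuleSet):
    """Outgoing and incoming vesicle types for compartment ``i``.

    Incoming vesicles are restricted to types actually budded somewhere at
    this timepoint; budded types with no target anywhere are orphans.
    """
    if i not in state:
        raise ValueError(f"compartment {i} not present in state")
    jt = budded_vesicles(state, rules)
    outgoing = frozenset(rules._g_rows[i].tolist())
    incoming = frozenset(j for j in jt if rules.F[i, j])
    return outgoing, incoming


def collapse_or(vesicles: Iterable[int]) -> int:
    """Bitwise OR of vesicle compositions, as a composition index.

    The integer encoding makes OR of label vectors identical to integer OR;
    an empty set collapses to the null composition 0.
    """
    out = 0
    for j in vesicles:
        out |= int(j)
    return out


def update_compartment(c: int, incoming: int, outgoing: int, N: int | None = None) -> int:
    """Binary mass balance: gain what fuses in and does not bud out, keep
    what does not bud out, lose the rest. May return 0 (vesiculation)."""
    mask = (1 << N) - 1 if N is not None else ~0
    if N is not None and not (0 <= c <= mask and 0 <= incoming <= mask and 0 <= outgoing <= mask):
        raise ValueError("composition out of range for N")
    return (incoming | (c & ~outgoing)) & (mask if N is not None else (c | incoming))


def find_orphans(state: CellState, rules: RuleSet) -> frozenset:
    """Budded vesicle types with no fusion target among present compartments."""
    if not state:
        return frozenset()
    jt = sorted(budded_vesicles(state, rules))
    if not jt:
        return frozenset()
    rows = np.asarray(state, dtype=np.intp)
    cols = np.asarray(jt, dtype=np.intp)
    has_target = rules.F[np.ix_(rows, cols)].any(axis=0)
    return frozenset(np.asarray(cols)[~has_target].tolist())


def step_cell(state: CellState, rules: RuleSet) -> StepResult:
    """One synchronous update of the whole cell.

    Orphan vesicle types homotypically nucleate compartments of their own
    composition; every present compartment updates by binary mass balance;
    the null composition is dropped; duplicates collapse (presence/absence
    of each compositional type is all that is tracked).
    """
    state = _check_state(state, rules.N)
    if not state:
        return StepResult((), frozenset(), {}, frozenset(), {})
    jt = sorted(budded_vesicles(state, rules))
    rows = np.asarray(state, dtype=np.intp)
    if jt:
        cols = np.asarray(jt, dtype=np.intp)
        fsub = rules.F[np.ix_(rows, cols)]
        has_target = fsub.any(axis=0)
        orphans = frozenset(cols[~has_target].tolist())
    else:
        cols = np.empty(0, dtype=np.intp)
        fsub = np.zeros((len(state), 0), dtype=bool)
        orphans = frozenset()

    updates: dict[int, int] = {}
    matured: dict[int, int] = {}
    dissipated: set[int] = set()
    new: set[int] = set(orphans)
    for k, i in enumerate(state):
        in_js = cols[fsub[k]]
        inc = int(np.bitwise_or.reduce(in_js)) if in_js.size else 0
        out = int(rules._row_out_or[i])
        c2 = inc | (i & ~out)
        updates[i] = c2
        if c2 == 0:
            dissipated.add(i)
        else:
            new.add(c2)
            if c2 != i:
                matured[i] = c2
    return StepResult(tuple(sorted(new)), orphans, matured, frozenset(dissipated), updates)


def run_to_orbit(rules: RuleSet, initial: Iterable[int], max_steps: int = 1024) -> Orbit:
    """Iterate the Boolean update until a previously visited state recurs.

    The dynamics are deterministic over a finite state space, so every
    trajectory ends on a periodic orbit; ``max_steps`` (1024 by default)
    caps the search and non-convergence is reported, not raised.
    """
    state = _check_state(initial, rules.N)
    seen: dict[CellState, int] = {state: 0}
    trajectory = [state]
    for t in range(1, max_steps + 1):
        state = step_cell(state, rules).next_state
        if state in seen:
            first = seen[state]
            states = trajectory[first:]
            homotypic: set[int] = set()
            for s in states:
                homotypic.update(find_orphans(s, rules))
            return Orbit(states=states, period=t - first, steps_to_orbit=first,
                         reached=True, homotypic_types=frozenset(homotypic))
        seen[state] = t
        trajectory.append(state)
    return Orbit(states=[trajectory[-1]], period=0, steps_to_orbit=max_steps,
                 reached=False, homotypic_types=frozenset())
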
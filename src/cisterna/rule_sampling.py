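"""Random sampling of budding/fusion rules and the homeostatic-network sweep.

Rules are drawn from a four-parameter family: ``N`` label types, ``A``
adaptor/coatomer complexes, a cargo-loading propensity ``g`` and a fusion
propensity ``f``. For each compartment composition, each of the ``A``
adaptors loads every label of the source independently with probability
``g``; the resulting vesicle types (duplicates and the empty vesicle
dropped) fill the compartment's G row. Every entry of the fusion matrix is
an independent Bernoulli(``f``) coin. Sampling is uniform over this family —
the sweep is an unbiased census of vesicle traffic rule space.

All randomness flows through :class:`numpy.random.Generator` streams split
from a master :class:`numpy.random.SeedSequence` by (combo index, replicate),
so any single run in a sweep can be replayed in isolation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .boolean_core import Orbit, RuleSet, run_to_orbit

__all__ = [
    "SamplerParams",
    "SweepGrid",
    "SweepRecord",
    "SweepResult",
    "sample_rules",
    "sample_initial_state",
    "run_seed_sequence",
    "replay_record",
    "sweep",
]


@dataclass(frozen=True)
class SamplerParams:
    """Parameters of the random rule family."""

    N: int
    A: int
    g: float
    f: float

    def __post_init__(self):
        if self.N < 1 or self.A < 1:
            raise ValueError("N and A must be positive integers")
        if not (0.0 <= self.g <= 1.0 and 0.0 <= self.f <= 1.0):
            raise ValueError("g and f must lie in [0, 1]")


def _default_g_values() -> tuple:
    return tuple(np.round(np.arange(1, 20) * 0.05, 3))


def _default_f_values() -> tuple:
    vals = set(np.round(np.arange(1, 20) * 0.05, 3)) | {0.025, 0.075, 1.0}
    return tuple(sorted(vals))


@dataclass(frozen=True)
class SweepGrid:
    """A grid of sampler parameter combinations.

    The full default grid (N in 4..7, A in 1..5, 19 g values, 22 f values)
    has 8360 combinations with 10 replicates each; :meth:`reduced` restricts
    to N=7 with 2 replicates for quick, statistically faithful estimates.
    """

    N_values: tuple = (4, 5, 6, 7)
    A_values: tuple = (1, 2, 3, 4, 5)
    g_values: tuple = field(default_factory=_default_g_values)
    f_values: tuple = field(default_factory=_default_f_values)
    rules_per_combo: int = 10
    master_seed: int = 0

    @classmethod
    def reduced(cls, master_seed: int = 0) -> "SweepGrid":
        return cls(N_values=(7,), rules_per_combo=2, master_seed=master_seed)

    @property
    def n_combos(self) -> int:
        return (len(self.N_values) * len(self.A_values)
                * len(self.g_values) * len(self.f_values))

    def combos(self) -> Iterator[SamplerParams]:
        for N, A, g, f in itertools.product(
                self.N_values, self.A_values, self.g_values, self.f_values):
            yield SamplerParams(N=N, A=A, g=float(g), f=float(f))


def sample_rules(params: SamplerParams, rng: np.random.Generator) -> RuleSet:
    """Draw one (G, F) rule pair.

    For each compartment i, A candidate vesicles are formed by masking the
    compartment's labels with independent Bernoulli(g) coins; duplicates and
    the empty vesicle are discarded, so G rows carry 0..A vesicle types. F is
    elementwise Bernoulli(f) over all nonzero (compartment, vesicle) pairs.
    """
    N, A, g, f = params.N, params.A, params.g, params.f
    size = 1 << N
    G = np.zeros((size, size), dtype=bool)
    # one g-coin per (compartment, adaptor, label); draw in a single block so
    # the stream layout is stable and documented
    coins = rng.random((size - 1, A, N)) < g
    for i in range(1, size):
        cbits = [(i >> (N - 1 - n)) & 1 for n in range(N)]
        for a in range(A):
            j = 0
            for n in range(N):
                j = (j << 1) | (cbits[n] & int(coins[i - 1, a, n]))
            if j:
                G[i, j] = True
    F = rng.random((size, size)) < f
    F[0, :] = False
    F[:, 0] = False
    return RuleSet(N=N, G=G, F=F, A=A,
                   meta={"g": g, "f": f})


def sample_initial_state(N: int, rng: np.random.Generator) -> tuple:
    """Random initial cell: Uniform{1..2N-1} compartments, each drawn
    uniformly over the 2^N-1 nonzero compositions; duplicates collapse."""
    count = int(rng.integers(1, 2 * N))
    draws = rng.integers(1, 1 << N, size=count)
    return tuple(sorted(set(draws.tolist())))


def run_seed_sequence(master_seed: int, combo_index: int, replicate: int) -> np.random.SeedSequence:
    """Seed stream for one (combo, replicate) run; replayable in isolation."""
    return np.random.SeedSequence(entropy=master_seed,
                                  spawn_key=(combo_index, replicate))


@dataclass
class SweepRecord:
    """One homeostatic network found by the sweep, with full provenance."""

    params: SamplerParams
    combo_index: int
    replicate: int
    master_seed: int
    initial: tuple
    state: tuple                 # the homeostatic compartment set
    steps_to_orbit: int
    homotypic_types: frozenset
    rules: RuleSet | None = None


@dataclass
class SweepResult:
    grid: SweepGrid
    records: list
    runs: int
    reached: int
    homeostatic: int
    degenerate: int
    per_combo: pd.DataFrame

    @property
    def orbit_fraction(self) -> float:
        return self.reached / self.runs

    @property
    def homeostatic_fraction(self) -> float:
        """Fraction of reached orbits that are (non-degenerate) homeostatic."""
        return self.homeostatic / self.reached if self.reached else float("nan")


def replay_record(rec: SweepRecord) -> tuple[RuleSet, Orbit]:
    """Re-run one stored sweep record from its seeds; bit-exact."""
    rng = np.random.Generator(np.random.PCG64(
        run_seed_sequence(rec.master_seed, rec.combo_index, rec.replicate)))
    rules = sample_rules(rec.params, rng)
    initial = sample_initial_state(rec.params.N, rng)
    orbit = run_to_orbit(rules, initial)
    return rules, orbit


def sweep(grid: SweepGrid, max_steps: int = 1024, keep_rules: bool = True,
          progress=None) -> SweepResult:
    """Sample rules and initial conditions over the grid and collect every
    non-degenerate homeostatic (period-1) outcome.

    Per-run non-convergence within ``max_steps`` is counted, never raised.
    """
    records: list[SweepRecord] = []
    rows = []
    runs = reached = homeo = degen = 0
    combos = grid.combos()
    if progress is not None:
        combos = progress(list(combos))
    for ci, params in enumerate(combos):
        c_runs = c_reached = c_homeo = 0
        for rep in range(grid.rules_per_combo):
            rng = np.random.Generator(np.random.PCG64(
                run_seed_sequence(grid.master_seed, ci, rep)))
            rules = sample_rules(params, rng)
            initial = sample_initial_state(params.N, rng)
            orbit = run_to_orbit(rules, initial, max_steps=max_steps)
            runs += 1
            c_runs += 1
            if orbit.reached:
                reached += 1
                c_reached += 1
                if orbit.degenerate:
                    degen += 1
                elif orbit.homeostatic:
                    homeo += 1
                    c_homeo += 1
                    records.append(SweepRecord(
                        params=params, combo_index=ci, replicate=rep,
                        master_seed=grid.master_seed, initial=initial,
                        state=orbit.states[0],
                        steps_to_orbit=orbit.steps_to_orbit,
                        homotypic_types=orbit.homotypic_types,
                        rules=rules if keep_rules else None))
        rows.append({"combo": ci, "N": params.N, "A": params.A,
                     "g": params.g, "f": params.f, "runs": c_runs,
                     "orbits": c_reached, "homeostatic": c_homeo})
    return SweepResult(grid=grid, records=records, runs=runs, reached=reached,
                       homeostatic=homeo, degenerate=degen,
                       per_combo=pd.DataFrame(rows))
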
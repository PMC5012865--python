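# Methods

`cisterna` models a eukaryotic cell as a set of membrane compartments that
exchange transport vesicles, asking which compartment networks can sustain
themselves when the molecular rules of budding and fusion are drawn at
random. This note records the models, the conventions the implementation
fixes where the design was open, the scales the default computations run at,
and known limitations.

## The Boolean traffic model

Compartment and vesicle identities are binary vectors over `N` molecular
label types (coats, SNAREs, GTPases, lipids, cargo), encoded as the integer
whose binary digits they spell (leftmost label = most significant bit; index
5 at `N = 3` is `[101]`). Index 0 is the null composition; a compartment
reaching it has fully vesiculated and is removed. The model is agnostic to
amounts, sizes and kinetic rates: only presence/absence matters, so a cell
state is the *set* of composition indices present.

Dynamics are fixed by two binary matrices over the `2^N − 1` nonzero
compositions: `G[i, j] = 1` means compartment `i` buds vesicle type `j`
(vesicle labels must be a bitwise subset of the source's — the Sierpinski
constraint — and a row of `G` holds at most `A` distinct vesicle types, one
per adaptor/coatomer complex), and `F[i, j] = 1` means vesicle `j` fuses
into compartment `i` when one is present. Each synchronous timestep:

1. every present compartment buds all its `G`-row vesicle types;
2. each compartment collapses its outgoing and its incoming (budded and
   `F`-accepted) vesicle streams into single OR'd vectors;
3. each label updates by binary mass balance — gained if fusing in and not
   budding out, lost if budding out and not fusing in;
4. budded vesicle types with no fusion target among present compartments
   (orphans) nucleate new compartments of their own composition by homotypic
   fusion. Orphanhood is re-derived from scratch every step; no memory of
   which types were granted homotypic fusion is kept.

The state space is finite and the map deterministic, so every trajectory
ends on a periodic orbit; orbits are detected by hashing visited states,
with a cap of 1024 steps (configurable). A period-1 orbit is a homeostatic
state: the set of compositions repeats even as individual compartments
mature, dissipate, and are re-created. The empty cell is a valid fixed
point but is flagged degenerate and excluded from homeostatic statistics.
The orphan types still being nucleated in a homeostatic state are its
homotypic vesicle types — the assumption the steady state needs.

For `N ≤ 3` the dynamics are cross-checked in the tests against a naive
per-bit reimplementation iterated over every initial state.

## Random rule sampling and the sweep

Rules are drawn from a four-parameter family `(N, A, g, f)`: for each
compartment, each of `A` adaptors masks the source labels with independent
Bernoulli(`g`) coins (duplicates and the empty vesicle are dropped), and
every `F` entry is Bernoulli(`f`). Initial cells draw Uniform{1..2N−1}
compartments (duplicates collapse), each uniform over the nonzero
compositions. The reference grid is `N ∈ {4..7}`, `A ∈ {1..5}`,
`g ∈ {0.05..0.95 step 0.05}`, `f` the same plus `{0.025, 0.075, 1}` — 8360
combinations. The default *reduced* sweep used by the tests and the
acceptance script runs `N = 7` with 2 rule draws per combination (4180
runs, ~20 s) rather than the full 10; the full grid sits behind a flag.
Randomness is split per (combo, replicate) from a master seed via
`numpy.random.SeedSequence` spawn keys, so any single run replays in
isolation bit-exactly.

## Traffic networks and their statistics

A homeostatic state maps to a graph with three typed edge sets read off one
update: vesicle edges (some budded type couples source to acceptor),
creation edges (orphan-budding source to the nucleated compartment; a
self-edge when a compartment buds its own orphan type), and maturation
edges (composition at `t` to composition at `t+1`, absent under transport
balance; at most one per node, never a self-edge). Derived statistics
follow the published analyses: weakly connected subsets over the union of
edge types; maturation chains (one per compartment with an incoming
creation edge, followed along maturation edges until a node with no
successor — classified *fixed*, and *dissipating* when its next update is
null — or until a node repeats, storing the maturation cycle); retrograde
fractions (share of ordered pairs `(A, B)`, `A ≠ B`, with a `B→A` vesicle
edge, overall and conditioned on `A→B` vesicle traffic or maturation in
either direction; vesicle self-edges are excluded); per-label molecular
sinks (a label has a sink iff the digraph of vesicle and creation edges
carrying it contains a terminal strongly connected component with an
incoming edge — the label enters a compartment group and never leaves,
implying compensatory synthesis); and per-network summary tables.

Three-compartment motifs are taken over creation + maturation edges only.
The catalog enumerates all `2^18 = 262,144` labeled 3-node graphs with two
directed edge types and self-loops, keeps those weakly connected over the
union of edge types (self-loops ignored for connectivity), and identifies
graphs under the 6 node permutations, yielding 43,700 classes. This
convention — self-loops allowed, weak connectivity, induced-subgraph
instances — was validated by reproducing that count exactly; the
enumeration engine is generic over the number of edge types and is checked
against an independent edge-list canonicalizer and against `networkx`
isomorphism in the tests. Motif instances in a network are induced: every
3-subset of nodes contributes at most one instance.

## Shuffled nulls

The degree-preserving null removes all vesicle edges and repeatedly swaps
the targets of two same-type edges, rejecting any swap that would lose or
create a self-edge or duplicate a (source, target) pair within a type.
This preserves, exactly and per edge type, every node's in- and out-degree
and the self-edge set. The attempt budget defaults to 10 swap attempts per
edge of each type (rejections consume budget) — these graphs are small and
mix quickly; the budget is configurable. The reference ensemble is 1000
replicates per network; tests use smaller ensembles and check that shuffled
chain-length distributions keep the geometric profile of the originals.

## The microscopic maturation model

The two-label stochastic model tracks a census `n(x, y)` of compartments
with integer contents, plus free pools `nX = n(1,0)`, `nY = n(0,1)`;
anything with `x + y ≥ 2` is a compartment, and a compartment budding down
to a single unit rejoins the free pools. Reactions: homotypic nucleation of
`(2,0)` at rate `A·nX(nX−1)`; budding at `B·x` and `D·y` per compartment;
X-vesicle fusion at `A·x²/(x+y)²·nX` (cooperative in `x`, collapsing to the
homotypic constant at vesicle size); Y-vesicle fusion at `C·x·nY`.
Compartments never fuse to each other. The simulator is an exact Gillespie
direct-method loop; both totals are asserted conserved throughout. Default
parameters are `{xtot, ytot} = {250, 5000}` vesicle units and
`{A, B, C, D} = {1000, 10, 5, 1}` (units·min⁻¹ and min⁻¹; `1/D` is the
vesiculation timescale). The initial condition (unstated in the source
analyses) is all mass free; the default run is 60 simulated minutes with a
20% burn-in before time-averaging, by which point the pools are stationary
(checked out to 200 min).

A structural property worth recording: at stationarity, Y-pool balance
forces `C·nY·Σx = D·Σy`, and X conservation pins compartment-bound X at
`Σx ≈ xtot − nX ≈ xtot`, so the stationary Y pool is essentially
`D·ytot/(C·xtot) = 4.0` at the default parameters. The simulation measures
≈ 4.1. This pins the free Y pool independently of every other detail of
the dynamics, and it is why the package's computed `nȲ` differs from some
previously reported figures for this parameter set; the X pool (~0.38) has
no such rigid constraint.

In the mean-field limit a single compartment obeys
`dx/dt = A·n̄X·x²/(x+y)² − Bx`, `dy/dt = C·n̄Y·x − Dy` with the
time-averaged pools as constants. The interior fixed point is known in
closed form, and linear stability gives the instability condition
`B/(B+D) · Cn̄Y/(Cn̄Y+D) > 1/2` (X must bud fast, Y must fuse fast),
verified in the tests both symbolically-derived and against numerical
Jacobian eigenvalues across a parameter scan. In the unstable regime the
ODE trajectory is not periodic on its own: after the maturation excursion
both contents collapse toward the origin (x at rate ≈ B, y at rate D), and
the fusion factor vanishes, so renucleation is impossible within the ODE.
The physical cycle is a relaxation loop closed by the discrete homotypic
nucleation event, and `limit_cycle` accordingly integrates one excursion
from vesicle-pair size `(2, ~0)` and terminates it where `x + y` falls
back below 2, reporting that nucleation-to-vesiculation time (~3.5 min at
defaults) as the period.

## Spatial layout and stacking

Compartment positions in 2-D minimize
`E = Σ_{i≠j} 1/s_ij + (a0 + a_ij)·s_ij²` over ordered pairs, with
`a_ij = 1` iff a vesicle edge runs `i → j` (self-edges ignored) and
baseline attraction `a0 = 0.1`: repulsion spreads compartments uniformly,
vesicle fluxes act as springs. Only vesicle edges enter the optimization.
Minimization is L-BFGS-B with the analytic gradient from 10 random restarts
(default); the two-body optima `s* = 5^{1/3} ≈ 1.710` (no edge) and
`(5/6)^{1/3} ≈ 0.941` (one edge) are recovered to 1e−3 in the tests, and
energies are invariant under rigid motions, so positions are reported
centered with arbitrary orientation.

The stacking metric of a layout is the mean distance between
maturation-connected pairs divided by the layout's nearest-neighbor
distance, taken as the *minimum* pair separation of the configuration —
the literal single "nearest neighbor distance", a convention validated by
reproducing the published share of stacked networks (the per-node-mean
alternative systematically inflates stacking scores). The null control
permutes compartment identities over the same positions and averages the
metric over 10 permutations to suppress single-draw noise. Aggregate
statistics use every network with ≥ 10 compartments and ≥ 1 maturation
edge.

## What the generator does and does not emulate

The synthetic rule/initial-condition generator *is* the study population:
its defaults (grid, Bernoulli sampling, Uniform{1..2N−1} initial sizes,
1024-step cap) define the conditions under which all reported fractions
are measured, at 2 replicates per combination instead of 10. Passing tests
therefore show that the implementation reproduces the statistical behavior
of that ensemble — not that any statement holds for measured biological
traffic networks; no empirical data enters anywhere. Reduced replication
widens sampling error on the sweep fractions by roughly `√5`, which the
test tolerances absorb.

## Numerical choices and degenerate inputs

- Orbit hashing uses exact state tuples; determinism is bit-exact given
  seeds, so stored runs replay identically.
- Ties and orderings: states, edges and catalogs are kept sorted, so all
  outputs are order-stable across platforms.
- `retrograde_stats` returns `None` for conditionals with no qualifying
  pairs; `stacking_metric` is undefined (None) without maturation edges;
  the empty cell state steps to itself with no events.
- Coincident layout positions are rejected as singular; random restarts
  avoid them with probability one.
- The Gillespie loop re-draws propensities per event (compartment counts
  are a few hundred at most); census conservation is asserted every 4096
  events and at the end.
- ODE integration uses LSODA with `rtol 1e−8`, `atol 1e−12`; the
  vesiculation event terminates integration.

## Known limitations

- Quantitative fluxes, compartment sizes, and heterotypic
  compartment–compartment fusion are outside the Boolean model by design.
- The homotypic-fusion protocol applies the orphan-nucleation update at
  every step; a sequential "grant one orphan type at a time" variant can
  in principle visit different transients (the two coincide whenever the
  nucleation update is a fixed point).
- The microscopic model covers exactly two label types; its census
  simulator is exact but not optimized for very large totals.
- The shuffle null's mixing budget is heuristic (10 attempts/edge); for
  graphs with many constrained edges the chain may mix slowly, though the
  degree/self-edge invariants hold regardless.
- Layout optimization is local; with 10 restarts small networks reliably
  reach the global basin, but very large networks may not.
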
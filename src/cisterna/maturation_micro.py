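"""Microscopic two-label maturation model: exact stochastic kinetics and its
mean-field limit.

Two molecule types X and Y travel on distinct vesicles, each vesicle
carrying one unit. Anything larger than a vesicle is a compartment, with
integer content (x, y), x + y >= 2; the free pools are nX = n(1,0) and
nY = n(0,1). Allowed reactions (probabilities per unit time):

* two X vesicles fuse homotypically into a (2,0) compartment, rate
  ``A * nX * (nX - 1)``;
* a compartment buds an X or Y vesicle, rates ``B*x*n`` and ``D*y*n``;
* an X vesicle fuses to a compartment, rate ``A * x^2/(x+y)^2 * nX * n``
  (X promotes its own fusion cooperatively; the rate collapses to the
  homotypic constant when the compartment is itself vesicle-sized);
* a Y vesicle fuses to a compartment, rate ``C * x * nY * n``.

Compartments never fuse to one another. Total X and Y amounts are conserved
exactly. The stochastic system is simulated with Gillespie's direct method;
individual compartments trace creation -> maturation -> vesiculation cycles
while the census and free pools stay stationary.

In the mean-field limit a single compartment obeys

    dx/dt = A nX x^2 / (x+y)^2 - B x
    dy/dt = C nY x - D y

with the time-averaged pools as constants. Linear stability of the interior
fixed point yields an instability condition: the fixed point is unstable —
and compositions approach a limit cycle — iff

    B/(B+D) * C nY / (C nY + D) > 1/2,

i.e. X vesicles must bud out fast and Y vesicles must fuse in fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MicroParams",
    "MicroState",
    "MicroTrajectory",
    "reaction_rates",
    "gillespie_run",
    "ode_field",
    "interior_fixed_point",
    "jacobian",
    "stability_condition",
    "limit_cycle",
]


@dataclass(frozen=True)
class MicroParams:
    """Rate constants and conserved totals.

    ``xtot``/``ytot`` are in vesicle units; ``A`` is in units per minute,
    ``B``, ``C``, ``D`` in inverse minutes (``1/D`` is roughly the time a
    compartment takes to vesiculate fully). Defaults are the reference
    parameter set for the cisternal-maturation regime.
    """

    xtot: int = 250
    ytot: int = 5000
    A: float = 1000.0
    B: float = 10.0
    C: float = 5.0
    D: float = 1.0

    def __post_init__(self):
        if min(self.xtot, self.ytot) <= 0 or min(self.A, self.B, self.C, self.D) <= 0:
            raise ValueError("all parameters must be positive")


@dataclass
class MicroState:
    """Instantaneous census: free pools plus per-compartment contents."""

    nX: int
    nY: int
    x: np.ndarray        # integer X units per compartment, x+y >= 2
    y: np.ndarray

    def check_conservation(self, params: MicroParams) -> None:
        if int(self.nX + self.x.sum()) != params.xtot:
            raise AssertionError("X is not conserved")
        if int(self.nY + self.y.sum()) != params.ytot:
            raise AssertionError("Y is not conserved")


def reaction_rates(state: MicroState, params: MicroParams):
    """Propensity of every reaction channel.

    Returns ``(homotypic, bud_x, bud_y, fuse_x, fuse_y)`` where the first is
    a scalar and the rest are per-compartment arrays.
    """
    x = state.x.astype(float)
    y = state.y.astype(float)
    homotypic = params.A * state.nX * (state.nX - 1)
    bud_x = params.B * x
    bud_y = params.D * y
    size2 = np.where(x + y > 0, (x + y) ** 2, 1.0)
    fuse_x = params.A * (x ** 2) / size2 * state.nX
    fuse_y = params.C * x * state.nY
    return homotypic, bud_x, bud_y, fuse_x, fuse_y


@dataclass
class MicroTrajectory:
    params: MicroParams
    t_end: float
    burn_in: float
    nX_mean: float
    nY_mean: float
    n_events: int
    sample_times: np.ndarray
    nX_samples: np.ndarray
    nY_samples: np.ndarray
    n_compartments_samples: np.ndarray
    census: dict                      # final (x, y) -> count
    compartment_paths: list = field(default_factory=list)


def gillespie_run(params: MicroParams, t_end: float, seed=None,
                  burn_in_fraction: float = 0.2, n_samples: int = 2000,
                  track_compartments: int = 0) -> MicroTrajectory:
    """Exact stochastic simulation (Gillespie direct method).

    Starts with all mass as free vesicles. Time-averaged pools are computed
    over the window after ``burn_in_fraction * t_end``. ``track_compartments``
    keeps full (t, x, y) histories for the first so many compartments created
    after burn-in. Conservation of both totals is asserted throughout.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nX, nY = params.xtot, params.ytot
    cap = 256
    x = np.zeros(cap, dtype=np.int64)
    y = np.zeros(cap, dtype=np.int64)
    m = 0                                        # live compartment count
    A, B, C, D = params.A, params.B, params.C, params.D

    t = 0.0
    t_burn = burn_in_fraction * t_end
    acc_x = acc_y = acc_t = 0.0
    n_events = 0
    sample_times = np.linspace(0.0, t_end, n_samples)
    s_nX = np.zeros(n_samples)
    s_nY = np.zeros(n_samples)
    s_m = np.zeros(n_samples, dtype=np.int64)
    next_sample = 0
    paths: list[dict] = []
    path_of = {}                                 # compartment slot -> path dict

    def retire(k: int):
        nonlocal m
        if k in path_of:
            path_of[k]["alive"] = False
            del path_of[k]
        last = m - 1
        if k != last:
            x[k] = x[last]
            y[k] = y[last]
            if last in path_of:
                path_of[k] = path_of.pop(last)
        x[last] = y[last] = 0
        m -= 1

    while t < t_end:
        xs = x[:m].astype(float)
        ys = y[:m].astype(float)
        r0 = A * nX * (nX - 1)
        if m:
            bud_x = B * xs
            bud_y = D * ys
            fuse_x = A * xs * xs / ((xs + ys) ** 2) * nX
            fuse_y = C * xs * nY
            per = bud_x + bud_y + fuse_x + fuse_y
            total = r0 + per.sum()
        else:
            per = None
            total = r0
        if total <= 0.0:
            t_next = t_end
        else:
            t_next = t + rng.exponential(1.0 / total)
        t_step_end = min(t_next, t_end)
        while next_sample < n_samples and sample_times[next_sample] <= t_step_end:
            s_nX[next_sample] = nX
            s_nY[next_sample] = nY
            s_m[next_sample] = m
            next_sample += 1
        if t < t_end and t_step_end > t_burn:
            dt = t_step_end - max(t, t_burn)
            acc_x += nX * dt
            acc_y += nY * dt
            acc_t += dt
        t = t_next
        if t >= t_end or total <= 0.0:
            break

        u = rng.random() * total
        if u < r0:
            nX -= 2
            if m == cap:
                cap *= 2
                x = np.resize(x, cap)
                y = np.resize(y, cap)
                x[m:] = 0
                y[m:] = 0
            x[m] = 2
            y[m] = 0
            if len(paths) < track_compartments and t > t_burn:
                rec = {"t": [t], "x": [2], "y": [0], "alive": True}
                paths.append(rec)
                path_of[m] = rec
            m += 1
        else:
            u -= r0
            cum = np.cumsum(per)
            k = int(np.searchsorted(cum, u, side="right"))
            k = min(k, m - 1)
            base = u - (cum[k - 1] if k else 0.0)
            bx, by = B * xs[k], D * ys[k]
            fx = A * xs[k] * xs[k] / ((xs[k] + ys[k]) ** 2) * nX
            if base < bx:
                x[k] -= 1
                nX += 1
            elif base < bx + by:
                y[k] -= 1
                nY += 1
            elif base < bx + by + fx:
                x[k] += 1
                nX -= 1
            else:
                y[k] += 1
                nY -= 1
            if k in path_of:
                rec = path_of[k]
                rec["t"].append(t)
                rec["x"].append(int(x[k]))
                rec["y"].append(int(y[k]))
            if x[k] + y[k] <= 1:                 # shrank to a single vesicle
                if x[k] == 1:
                    nX += 1
                elif y[k] == 1:
                    nY += 1
                retire(k)
        n_events += 1
        if n_events % 4096 == 0:
            state = MicroState(nX=nX, nY=nY, x=x[:m], y=y[:m])
            state.check_conservation(params)

    state = MicroState(nX=nX, nY=nY, x=x[:m], y=y[:m])
    state.check_conservation(params)
    while next_sample < n_samples:
        s_nX[next_sample] = nX
        s_nY[next_sample] = nY
        s_m[next_sample] = m
        next_sample += 1
    census: dict = {}
    for k in range(m):
        key = (int(x[k]), int(y[k]))
        census[key] = census.get(key, 0) + 1
    return MicroTrajectory(
        params=params, t_end=t_end, burn_in=t_burn,
        nX_mean=acc_x / acc_t if acc_t else float("nan"),
        nY_mean=acc_y / acc_t if acc_t else float("nan"),
        n_events=n_events, sample_times=sample_times,
        nX_samples=s_nX, nY_samples=s_nY, n_compartments_samples=s_m,
        census=census,
        compartment_paths=[{k: np.asarray(v) for k, v in p.items() if k != "alive"}
                           for p in paths])


# ----------------------------- mean-field ODE -----------------------------

def ode_field(x: float, y: float, params: MicroParams,
              nXbar: float, nYbar: float):
    """Mean-field derivatives for one compartment, given the free pools."""
    if x + y <= 0:
        raise ValueError("the fusion factor is undefined at x = y = 0")
    dx = params.A * nXbar * x * x / (x + y) ** 2 - params.B * x
    dy = params.C * nYbar * x - params.D * y
    return dx, dy


def interior_fixed_point(params: MicroParams, nXbar: float, nYbar: float):
    """The nonzero fixed point of the mean-field equations, in closed form."""
    k = params.C * nYbar / params.D
    x = params.A * nXbar / (params.B * (1.0 + k) ** 2)
    return x, k * x


def jacobian(x: float, y: float, params: MicroParams,
             nXbar: float, nYbar: float) -> np.ndarray:
    s = x + y
    a = params.A * nXbar
    j11 = a * (2 * x * s ** 2 - 2 * s * x * x) / s ** 4 - params.B
    j12 = -2 * a * x * x / s ** 3
    return np.array([[j11, j12],
                     [params.C * nYbar, -params.D]])


def stability_condition(params: MicroParams, nYbar: float) -> bool:
    """True when the interior fixed point is unstable (limit-cycle regime)."""
    cn = params.C * nYbar
    lhs = params.B / (params.B + params.D) * cn / (cn + params.D)
    return lhs > 0.5


@dataclass
class LimitCycle:
    """One period of the maturation cycle, or the fixed point reached.

    In the unstable regime the mean-field trajectory is a relaxation cycle
    closed by renucleation: a compartment nucleates at vesicle-pair size,
    grows by X fusion, matures as Y fuses in and X buds out, and finally
    collapses back below vesicle scale (vesiculation), whereupon homotypic
    fusion starts the next, identical excursion. ``period`` is the
    nucleation-to-vesiculation time; ``x``/``y`` trace the excursion, whose
    extrema are the mean-field analogs of the Boolean compositions.
    """

    found: bool
    period: float | None
    t: np.ndarray | None
    x: np.ndarray | None
    y: np.ndarray | None
    fixed_point: tuple | None = None


def limit_cycle(params: MicroParams, nXbar: float, nYbar: float,
                x0: tuple = (2.0, 0.01), nucleation_size: float = 2.0,
                t_max: float = 60.0, rtol: float = 1e-8) -> LimitCycle:
    """Integrate the mean-field equations from a nucleation state.

    Returns the maturation excursion terminated where total content x+y
    falls back below ``nucleation_size`` (the compartment/vesicle boundary);
    when the interior fixed point is stable the trajectory converges instead
    and no cycle is reported.
    """

    def rhs(_t, z):
        x, y = z
        s = x + y
        if s <= 0:
            return [0.0, 0.0]
        return [params.A * nXbar * x * x / s ** 2 - params.B * x,
                params.C * nYbar * x - params.D * y]

    fp = interior_fixed_point(params, nXbar, nYbar)

    def vesiculation(_t, z):          # total content back at vesicle scale
        return z[0] + z[1] - nucleation_size
    vesiculation.direction = -1.0
    vesiculation.terminal = True

    sol = solve_ivp(rhs, (0.0, t_max), list(x0), method="LSODA",
                    rtol=rtol, atol=1e-12, events=vesiculation,
                    dense_output=True, max_step=0.05)
    crossings = sol.t_events[0]
    if len(crossings) == 0:
        return LimitCycle(found=False, period=None, t=None, x=None, y=None,
                          fixed_point=fp)
    period = float(crossings[0])
    ts = np.linspace(0.0, period, 512)
    zs = sol.sol(ts)
    return LimitCycle(found=True, period=period, t=ts,
                      x=zs[0], y=zs[1], fixed_point=fp)
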
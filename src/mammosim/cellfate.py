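"""Hypoxic death, the estrogen-paced cell-cycle clock, and division.

Cell death under hypoxia follows a Gaussian law in the ratio of local
oxygen to the local piled-cancer count.  The division clock is a
non-dimensional Lotka-Volterra oscillator for the antagonistic cyclin-E
(u) / cyclin-B (v) pair,

    du/dt = u (1 - v),        dv/dt = eps v (u - 1),

whose local rate parameter eps couples the cycle duration to the local
estrogen concentration.  One full oscillation (phase return to the
starting Poincare section) marks one biological cell cycle; on division
the clock is reset.

A note on the period: linearizing around the (1,1) equilibrium gives
T = 2*pi/sqrt(eps), which is dimensionally consistent with eps being a
squared rate.  The clock therefore uses the *measured* phase-return
period of the actual orbit (exact at any amplitude), and the analytic
small-amplitude check targets 2*pi/sqrt(eps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core import CellGrid, CellPopulation, CellRecord, SimulationConfig


# ---------------------------------------------------------------------------
# Death (hypoxia)
# ---------------------------------------------------------------------------

def death_probability(C2_local, sigma_c_local, theta_d):
    """Gaussian hypoxic-death probability exp[-(C2/(theta_d*sigma_c))^2].

    Vanishes when no cancer cell is present (the argument diverges).
    Accepts scalars or arrays.
    """
    C2 = np.asarray(C2_local, dtype=float)
    sc = np.asarray(sigma_c_local, dtype=float)
    if (C2 < 0).any():
        raise ValueError("oxygen concentration must be nonnegative")
    if (sc < 0).any():
        raise ValueError("cancer count must be nonnegative")
    if theta_d <= 0:
        raise ValueError("theta_d must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.where(sc >= 1, C2 / (theta_d * np.maximum(sc, 1)), np.inf)
    out = np.where(sc >= 1, np.exp(-arg ** 2), 0.0)
    if np.isscalar(C2_local) and np.isscalar(sigma_c_local):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Cycle clock
# ---------------------------------------------------------------------------

def epsilon_local(sigma_n, sigma_c, alpha3, lam3, C3_local):
    """Local cycle rate eps = (alpha3^2 [sigma_n + lam3 sigma_c] C3)^2.

    Distinguishes normal from cancer cell cycle duration; zero estrogen
    arrests the cycle.  Accepts scalars or arrays.
    """
    sn = np.asarray(sigma_n, dtype=float)
    sc = np.asarray(sigma_c, dtype=float)
    C3 = np.asarray(C3_local, dtype=float)
    eps = (alpha3 ** 2 * (sn + lam3 * sc) * C3) ** 2
    if np.isscalar(C3_local):
        return float(eps)
    return eps


def lv_rhs(t, y, eps):
    u, v = y
    return (u * (1.0 - v), eps * v * (u - 1.0))


def lv_invariant(u, v, eps):
    """Conserved quantity V = eps (u - ln u) + (v - ln v)."""
    return eps * (u - np.log(u)) + (v - np.log(v))


@dataclass
class CycleClock:
    """Cyclin pair (u, v), local rate eps, elapsed time in this cycle."""

    u: float
    v: float
    eps: float
    t_elapsed: float = 0.0


def _section_event(u0, v0, eps):
    """Poincare section through (u0, v0) transverse to the flow."""
    du0, dv0 = lv_rhs(0.0, (u0, v0), eps)
    if abs(dv0) > abs(du0) * eps:   # prefer the v-section when transverse
        def ev(t, y, *_):
            return y[1] - v0
        ev.direction = math.copysign(1.0, dv0)
    else:
        def ev(t, y, *_):
            return y[0] - u0
        ev.direction = math.copysign(1.0, du0)
    return ev


def lv_period(eps, u0=1.2, v0=1.0, rtol=1e-10) -> float:
    """Measured phase-return period of the orbit through (u0, v0).

    Integrates until the trajectory re-crosses its starting Poincare
    section in the starting direction.
    """
    if eps <= 0:
        return math.inf
    if u0 <= 0 or v0 <= 0:
        raise ValueError("cyclin concentrations must be positive")
    if abs(u0 - 1.0) < 1e-12 and abs(v0 - 1.0) < 1e-12:
        return math.inf   # fixed point: no oscillation, never divides
    guess = 2.0 * math.pi / math.sqrt(eps)
    # burn in past the start (the state begins exactly on the section,
    # which would otherwise register a spurious t=0 event)
    t_burn = 0.25 * guess
    leg1 = solve_ivp(lv_rhs, (0.0, t_burn), (u0, v0), args=(eps,),
                     rtol=rtol, atol=1e-12, method="RK45")
    ev = _section_event(u0, v0, eps)
    ev.terminal = True
    sol = solve_ivp(lv_rhs, (t_burn, t_burn + 10.0 * guess),
                    leg1.y[:, -1], args=(eps,),
                    events=ev, rtol=rtol, atol=1e-12, method="RK45")
    if not sol.t_events[0].size:
        raise RuntimeError(f"no phase return found for eps={eps}")
    # the first crossing in the starting direction is one full period:
    # the section is crossed in that direction exactly once per loop
    return float(sol.t_events[0][0])


class PeriodTable:
    """Log-log interpolant of the measured period over a lazy eps grid.

    T(eps) is smooth and close to 2*pi/sqrt(eps); log T is interpolated
    linearly in log eps on a 1/4-decade grid spanning [1e-14, 10].
    """

    def __init__(self, u0=1.2, v0=1.0):
        self.u0, self.v0 = u0, v0
        self._log_eps = None
        self._log_T = None

    def _build(self):
        log_eps = np.arange(-14.0, 1.01, 0.25)
        periods = [lv_period(10.0 ** le, self.u0, self.v0, rtol=1e-9)
                   for le in log_eps]
        self._log_eps = log_eps
        self._log_T = np.log10(periods)

    def __call__(self, eps):
        eps = np.asarray(eps, dtype=float)
        if self._log_T is None:
            self._build()
        out = np.full(eps.shape, np.inf)
        ok = eps >= 10.0 ** self._log_eps[0]
        le = np.log10(np.clip(eps, 1e-300, None))
        out[ok] = 10.0 ** np.interp(le[ok], self._log_eps, self._log_T)
        return out


def step_cycle(clock: CycleClock, dt: float, rtol=1e-9):
    """Advance the cyclin oscillator by dt; flag a completed cycle.

    Division triggers when the trajectory re-crosses its starting
    Poincare section in the starting direction (one full period).  On
    division the clock resets (t_elapsed back to zero, phase kept).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if clock.eps == 0:
        return CycleClock(clock.u, clock.v, clock.eps,
                          clock.t_elapsed + dt), False
    if abs(clock.u - 1.0) < 1e-12 and abs(clock.v - 1.0) < 1e-12:
        return CycleClock(clock.u, clock.v, clock.eps,
                          clock.t_elapsed + dt), False
    ev = _section_event(clock.u, clock.v, clock.eps)
    ev.terminal = False
    sol = solve_ivp(lv_rhs, (0.0, dt), (clock.u, clock.v), args=(clock.eps,),
                    events=ev, rtol=rtol, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"cycle integration failed: {sol.message}")
    u, v = sol.y[:, -1]
    # ignore a spurious event at the very start (state on the section)
    events = sol.t_events[0]
    events = events[events > 1e-8 * dt]
    divided = bool(events.size)
    t_new = 0.0 if divided else clock.t_elapsed + dt
    return CycleClock(float(u), float(v), clock.eps, t_new), divided


# ---------------------------------------------------------------------------
# Division placement
# ---------------------------------------------------------------------------

def place_daughter(parent: CellRecord, grid: CellGrid, cells: CellPopulation,
                   config: SimulationConfig, rng: np.random.Generator):
    """Place a daughter on a uniformly random nearest-neighbor site.

    A normal occupant is replaced by the cancer daughter; cancer
    occupants pile up; a necrotic site blocks the division (unless
    configured replaceable).  Returns the new record, or None when the
    division was blocked.  The daughter inherits the parent genotype,
    thresholds, GRN state and phenotype, with a fresh clock.
    """
    from .core import neighbors
    nbs = neighbors(parent.pos, config)
    site = nbs[int(rng.integers(len(nbs)))]
    if site[-1] == config.L - 1:
        # the capillary face is vessel wall: not colonizable
        return None
    if grid.sigma_d[site] == 1 and grid.sigma_c[site] == 0:
        if not config.necrotic_replaceable:
            return None
        grid.sigma_d[site] = 0
    if grid.sigma_n[site] == 1:
        grid.sigma_n[site] = 0        # normal cell replaced by the daughter
    grid.sigma_c[site] += 1
    daughter = parent.copy()
    daughter.pos = site
    daughter.phase = tuple(config.lv_init)
    daughter.clock = 0.0
    cells.add(daughter)
    return daughter
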
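"""Monte-Carlo synaptic rewiring.

Synapse survival is modelled as winner-take-all competition: a competitive
Lotka-Volterra system whose steady state keeps only the contact with the
largest growth rate.  The Monte-Carlo scheme replaces the continuous
dynamics by stochastic swaps: each trial picks a random synaptic site,
proposes a random candidate afferent from the site's retinotopic pool,
passes it through the age-dependent spine-contact gate (the p75^NTR
closure of the sensitive period), and then accepts the swap with a
logistic probability in the growth-rate difference, with inverse
fictitious temperature ``beta``.

One Monte-Carlo step (MC step, the model's unit of developmental time) is
``n_neurons * n_sites`` trials -- on average one update attempt per site.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from . import cortex as _cortex
from ._kernels import DRAWS_PER_TRIAL, sweep_kernel
from .cortex import (CortexGeometry, LateralKernelParams, POOL_HALF_WIDTH,
                     SynapseState, random_initial_state)
from .stimulus_lgn import LGNResponseTable

__all__ = [
    "RewiringConfig", "PlasticityClock", "lv_steady_state",
    "spine_contact_prob", "rewiring_prob", "mc_trial", "Simulation",
]


@dataclass(frozen=True)
class RewiringConfig:
    """Parameters of the rewiring probabilities and the plasticity gate."""

    beta: float = 250.0    # inverse fictitious temperature
    c_dp: float = 2.0      # depression/potentiation efficiency ratio
    xi_max: float = 0.8    # maximal p75^NTR expression level
    t_p: float = 15.75     # plasticity time constant (MC steps)
    v: float = 0.045       # afferent coupling to membrane potential
    abar: float = 1.0      # activity-independent mean growth rate (normalized)

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.t_p <= 0:
            raise ValueError("t_p must be positive")
        if self.xi_max < 0:
            raise ValueError("xi_max must be non-negative")


@dataclass
class PlasticityClock:
    """Developmental time in MC steps; advances by 1/n_trials per trial."""

    t: float = 0.0
    trial_count: int = 0

    def advance(self, n_trials: int, trials_per_step: int) -> None:
        self.t += n_trials / trials_per_step
        self.trial_count += n_trials


# ---------------------------------------------------------------------------
# competitive Lotka-Volterra demonstration

def lv_steady_state(a, verify: bool = False, rng=None) -> np.ndarray:
    """Stable fixed point of the competitive Lotka-Volterra system.

    ``d rho_k/dt = a_k rho_k - (sum_k' rho_k') rho_k`` with distinct growth
    rates has a single stable fixed point: the winner ``k0 = argmax a``
    survives at ``rho_k0 = a_k0`` and every other species dies out.

    With ``verify=True`` the fixed point is checked by numerically
    integrating the ODE from random positive initial conditions.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("a must be a non-empty vector")
    k0 = int(np.argmax(a))
    if np.sum(a == a[k0]) > 1:
        raise ValueError("degenerate input: growth-rate maximum is tied")
    rho = np.zeros_like(a)
    rho[k0] = a[k0]
    if verify:
        from scipy.integrate import solve_ivp

        rng = np.random.default_rng(rng)
        rho0 = rng.uniform(0.1, 1.0, size=a.size)

        def rhs(_t, r):
            return a * r - r.sum() * r

        # losers decay at the rate of the growth-rate gap to the winner
        others = np.delete(a, k0)
        gap = a[k0] - others.max() if others.size else a[k0]
        span = 40.0 / max(gap, 1e-6) + 20.0 / max(abs(a[k0]), 1e-6)
        sol = solve_ivp(rhs, (0.0, span), rho0, rtol=1e-10, atol=1e-12)
        if not np.allclose(sol.y[:, -1], rho, atol=1e-6):
            raise RuntimeError("ODE integration did not converge to the "
                               "winner-take-all fixed point")
    return rho


# ---------------------------------------------------------------------------
# transition probabilities

def plasticity_gate(t, config: RewiringConfig):
    """Spine growth rate ``g(t) = -xi_max (t/(T_p+t))^4`` (age gate)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return -config.xi_max * (t / (config.t_p + t)) ** 4


def spine_contact_prob(t, config: RewiringConfig):
    """Probability that a proposed candidate makes a transient contact.

    Logistic in ``beta * g(t)``: 1/2 at t=0, monotonically closing toward
    ``1/(1+exp(beta*xi_max))`` -- the end of the sensitive period.
    """
    return expit(config.beta * plasticity_gate(t, config))


def rewiring_prob(b_new, b_old, beta: float):
    """Probability that the candidate contact replaces the current one."""
    return expit(beta * (np.asarray(b_new) - np.asarray(b_old)))


# ---------------------------------------------------------------------------
# simulation engine

class Simulation:
    """Monte-Carlo rewiring run bound to one stimulus ensemble.

    Holds the wiring state, the response table of the active ensemble, and
    the per-sweep activation caches (thresholds and lateral drive are
    refreshed once per sweep -- threshold adaptation is slow compared with
    single trials).  ``switch_table`` swaps the exposure regimen while the
    plasticity clock keeps running, which is how protocols chain segments.
    """

    def __init__(self, geometry: CortexGeometry, table: LGNResponseTable,
                 config: RewiringConfig | None = None,
                 lateral: LateralKernelParams | None = None,
                 state: SynapseState | None = None,
                 seed: int | np.random.Generator = 0):
        self.geometry = geometry
        self.config = config or RewiringConfig()
        self.lateral_params = lateral or LateralKernelParams()
        self.rng = (seed if isinstance(seed, np.random.Generator)
                    else np.random.default_rng(seed))
        self.u_lateral = _cortex.lateral_kernel(geometry, self.lateral_params)
        self.clock = PlasticityClock()
        self.state = state if state is not None else random_initial_state(
            geometry, self.rng)
        self._pool_cx = np.ascontiguousarray(geometry.pool_centers[..., 0])
        self._pool_cy = np.ascontiguousarray(geometry.pool_centers[..., 1])
        self.table: LGNResponseTable | None = None
        self.switch_table(table)

    # -- activation caches ---------------------------------------------------

    def switch_table(self, table: LGNResponseTable) -> None:
        """Bind a new stimulus ensemble and rebuild the potential cache.

        A no-op when the table is already active, so protocol segmentation
        does not perturb the per-sweep adaptation schedule.
        """
        if table is self.table:
            return
        if table.n_cells != self.state.n_cells:
            raise ValueError("table does not match the LGN grid")
        self.table = table
        self._eta = np.ascontiguousarray(table.flat)
        self.s_aff = _cortex.afferent_potential(self.state, table,
                                                self.config.v)
        self.refresh()

    def refresh(self) -> None:
        """Recompute thresholds and lateral drive from current potentials."""
        self.theta = _cortex.update_thresholds(self.s_aff)
        eta_aff, _ = _cortex.firing_rates(self.s_aff, self.theta)
        self.lateral = _cortex.lateral_drive(eta_aff, self.u_lateral)

    def rebuild_potentials(self) -> None:
        """Recompute potentials from scratch (checkpoint restore / checks)."""
        self.s_aff = _cortex.afferent_potential(self.state, self.table,
                                                self.config.v)
        self.refresh()

    # -- running -------------------------------------------------------------

    def run_trials(self, n_trials: int) -> int:
        """Run ``n_trials`` rewiring trials with frozen per-sweep caches."""
        cfg = self.config
        u = self.rng.random((n_trials, DRAWS_PER_TRIAL))
        accepted = sweep_kernel(
            self.state.assignment, self.state.counts, self.s_aff,
            self.theta, self.lateral, self._eta,
            self._pool_cx, self._pool_cy, POOL_HALF_WIDTH,
            self.geometry.lgn.nx, self.geometry.lgn.ny,
            self.geometry.lgn.n_layers,
            cfg.v, cfg.beta, cfg.c_dp, cfg.xi_max, cfg.t_p,
            self.clock.t, 1.0 / self.geometry.n_trials_per_step, u)
        self.clock.advance(n_trials, self.geometry.n_trials_per_step)
        return int(accepted)

    def run_sweep(self) -> int:
        """One full MC step: refresh caches, then one trial per site."""
        self.refresh()
        return self.run_trials(self.geometry.n_trials_per_step)

    def run(self, duration: float) -> int:
        """Advance the clock by ``duration`` MC steps (fractional allowed).

        Thresholds and lateral drive adapt on a canonical per-sweep
        schedule (at every whole-MC-step boundary of the global clock), so
        a run split into consecutive calls follows the same trajectory as
        one uninterrupted call.
        """
        if duration < 0:
            raise ValueError("duration must be non-negative")
        total = 0
        remaining = int(round(duration * self.geometry.n_trials_per_step))
        per_step = self.geometry.n_trials_per_step
        while remaining > 0:
            phase = self.clock.trial_count % per_step
            if phase == 0:
                self.refresh()
            batch = min(per_step - phase, remaining)
            total += self.run_trials(batch)
            remaining -= batch
        return total


def mc_trial(sim: Simulation, rng: np.random.Generator | None = None) -> bool:
    """One rewiring trial, in pure Python (reference implementation).

    Consumes exactly six uniforms from ``rng`` (default: the simulation's
    own generator) in the same order as the compiled sweep kernel, so a
    sequence of ``mc_trial`` calls reproduces ``run_trials`` bit for bit.
    Returns True when a swap was accepted.  The per-sweep caches are *not*
    refreshed here; callers control when thresholds adapt.
    """
    rng = rng or sim.rng
    geo = sim.geometry
    cfg = sim.config
    u = rng.random(DRAWS_PER_TRIAL)

    gidx = min(int(u[0] * (geo.n_neurons * geo.n_sites)),
               geo.n_neurons * geo.n_sites - 1)
    i, j = divmod(gidx, geo.n_sites)

    side = 2 * POOL_HALF_WIDTH + 1
    dx = int(u[1] * side) - POOL_HALF_WIDTH
    dy = int(u[2] * side) - POOL_HALF_WIDTH
    layer = min(int(u[3] * geo.lgn.n_layers), geo.lgn.n_layers - 1)
    cx = (sim.geometry.pool_centers[i, j, 0] + dx) % geo.lgn.nx
    cy = (sim.geometry.pool_centers[i, j, 1] + dy) % geo.lgn.ny
    cand = int(layer * geo.lgn.nx * geo.lgn.ny + cx * geo.lgn.ny + cy)

    accepted = False
    t = sim.clock.t
    if u[4] < spine_contact_prob(t, cfg):
        cur = int(sim.state.assignment[i, j])
        if cand != cur:
            eta = sim._eta
            # plasticity products use the deviation of the potential from
            # its homeostatic set point (threshold = long-time mean), so the
            # general growth-rate expression is evaluated at zero threshold
            # on the centered potential
            d = sim.s_aff[i] - sim.theta[i]
            b_old = _cortex.growth_rate(eta[cur], d, 0.0,
                                        sim.lateral[i], cfg.c_dp)
            d_new = d + cfg.v * (eta[cand] - eta[cur])
            b_new = _cortex.growth_rate(eta[cand], d_new, 0.0,
                                        sim.lateral[i], cfg.c_dp)
            if u[5] < rewiring_prob(b_new, b_old, cfg.beta):
                sim.state.apply_swap(i, j, cand)
                sim.s_aff[i] += cfg.v * (eta[cand] - eta[cur])
                accepted = True
    sim.clock.advance(1, geo.n_trials_per_step)
    return accepted
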
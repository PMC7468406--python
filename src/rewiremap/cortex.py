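"""Cortical lattice, lateral interactions, and the synapse growth rate.

The model cortex is a periodic square lattice of neurons, each carrying a
disk-shaped dendritic field of a fixed number of synaptic sites.  Every
site hosts exactly one afferent synapse from one LGN cell; rewiring swaps
the presynaptic identity of a site, so the per-neuron synapse count is
conserved by construction.

Afferent membrane potentials are linear in the synapse counts
(``s_aff = v * n . eta_LGN``, electrotonically compact dendrite), firing is
half-rectified about a slowly adapting threshold (the long-time mean of the
potential), and lateral interactions follow a short-range-excitation /
long-range-inhibition difference of Gaussians.  The stimulus-averaged
synapse growth rate combines a potentiating term gated by suprathreshold
episodes (coincident backpropagating spikes) with a depressing term
proportional to subthreshold correlation, plus their first-order lateral
corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .stimulus_lgn import LGNGrid, LGNResponseTable

__all__ = [
    "LateralKernelParams", "CortexGeometry", "SynapseState",
    "lateral_kernel", "afferent_potential", "update_thresholds",
    "firing_rates", "growth_rate", "random_initial_state",
]

#: half-width of the square retinotopic candidate pool (9 x 9 offsets)
POOL_HALF_WIDTH = 4


@dataclass(frozen=True)
class LateralKernelParams:
    """Short-range excitatory / long-range inhibitory lateral interaction."""

    lambda_ex: float = 82.0     # excitatory extent (model length units)
    lambda_inh: float = 328.0   # inhibitory extent
    q: float = 4.0              # interaction strength
    kappa_ie: float = 1.0       # inhibition/excitation ratio
    cutoff_factor: float = 3.0  # truncation radius in units of lambda_inh

    def __post_init__(self) -> None:
        if not (self.lambda_inh > self.lambda_ex > 0):
            raise ValueError("require lambda_inh > lambda_ex > 0")


def _disk_site_offsets(n_sites: int, a_spine: float) -> np.ndarray:
    """Square-packed dendritic sites: the ``n_sites`` lattice points closest
    to the soma, spaced ``a_spine`` apart (deterministic tie-break)."""
    m = int(np.ceil(np.sqrt(n_sites))) + 2
    ii, jj = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    r2 = ii**2 + jj**2
    order = np.lexsort((jj, ii, r2))
    sel = order[:n_sites]
    return np.stack([ii[sel], jj[sel]], axis=1) * float(a_spine)


@dataclass(frozen=True)
class CortexGeometry:
    """Periodic cortical lattice with dendritic sites and retinotopy.

    The cortex maps onto the LGN lattice with a fixed magnification
    (2:1 downscaling at default sizes).  Each synaptic site draws rewiring
    candidates from a 9 x 9 window of LGN positions (x 4 cell types)
    centered on the LGN position that retinotopically corresponds to the
    site, i.e. the neuron's retinotopic position plus the site offset
    scaled by the cortex-to-LGN magnification.
    """

    nx: int = 48
    ny: int = 48
    a_cell: float = 50.0        # inter-neuron spacing (model length units)
    n_sites: int = 254
    a_spine: float = 15.0       # inter-site spacing
    lgn: LGNGrid = field(default_factory=LGNGrid)

    @classmethod
    def full(cls) -> "CortexGeometry":
        return cls()

    @classmethod
    def reduced(cls) -> "CortexGeometry":
        """Desk-scale geometry: 16 x 16 cortex, 8 x 8 LGN, 64 sites."""
        return cls(nx=16, ny=16, n_sites=64, lgn=LGNGrid(nx=8, ny=8))

    @classmethod
    def tiny(cls) -> "CortexGeometry":
        """Minimal geometry for fast unit tests."""
        return cls(nx=4, ny=4, n_sites=8, lgn=LGNGrid(nx=2, ny=2))

    @property
    def n_neurons(self) -> int:
        return self.nx * self.ny

    @property
    def n_trials_per_step(self) -> int:
        """Trials per Monte-Carlo step: one per synaptic site on average."""
        return self.nx * self.ny * self.n_sites

    @property
    def pool_size(self) -> int:
        side = 2 * POOL_HALF_WIDTH + 1
        return side * side * self.lgn.n_layers

    @cached_property
    def site_offsets(self) -> np.ndarray:
        """(n_sites, 2) site positions relative to the soma (length units)."""
        return _disk_site_offsets(self.n_sites, self.a_spine)

    @cached_property
    def positions(self) -> np.ndarray:
        """(n_neurons, 2) neuron positions (length units)."""
        ix, iy = np.divmod(np.arange(self.n_neurons), self.ny)
        return np.stack([ix * self.a_cell, iy * self.a_cell], axis=1)

    @cached_property
    def pool_centers(self) -> np.ndarray:
        """(n_neurons, n_sites, 2) int LGN-lattice pool centers per site."""
        mag_x = self.lgn.nx / self.nx            # LGN cells per cortical cell
        mag_y = self.lgn.ny / self.ny
        ix, iy = np.divmod(np.arange(self.n_neurons), self.ny)
        base = np.stack([ix * mag_x, iy * mag_y], axis=1)          # (N, 2)
        off = self.site_offsets / self.a_cell * np.array([mag_x, mag_y])
        centers = np.rint(base[:, None, :] + off[None, :, :]).astype(np.int64)
        centers[..., 0] %= self.lgn.nx
        centers[..., 1] %= self.lgn.ny
        return centers

    def candidate_pool(self, neuron: int, site: int) -> np.ndarray:
        """All pool_size candidate cell indices for one synaptic site."""
        cx, cy = self.pool_centers[neuron, site]
        hw = POOL_HALF_WIDTH
        d = np.arange(-hw, hw + 1)
        gx = (cx + d[:, None]) % self.lgn.nx
        gy = (cy + d[None, :]) % self.lgn.ny
        plane = self.lgn.nx * self.lgn.ny
        cells = (gx * self.lgn.ny + gy).ravel()
        return (np.arange(self.lgn.n_layers)[:, None] * plane + cells[None, :]).ravel()


def lateral_kernel_density(distance, params: LateralKernelParams | None = None):
    """Continuum lateral-interaction density (1/length^2) at ``distance``.

    The difference of two normalized Gaussians scaled by ``q``; integrates
    to ``q (1 - kappa_ie)`` over the plane (zero for the balanced kernel).
    """
    params = params or LateralKernelParams()
    d2 = np.square(np.asarray(distance, dtype=float))
    le2, li2 = params.lambda_ex**2, params.lambda_inh**2
    return params.q * (np.exp(-d2 / (2 * le2)) / (2 * np.pi * le2)
                       - params.kappa_ie * np.exp(-d2 / (2 * li2))
                       / (2 * np.pi * li2))


def lateral_kernel(geometry: CortexGeometry,
                   params: LateralKernelParams | None = None) -> np.ndarray:
    """Dense (N, N) lateral interaction matrix on the periodic lattice.

    Entries are the continuum density integrated over one lattice cell
    (density times ``a_cell^2``), so the discrete sum over neurons inherits
    the continuum properties: the balanced kernel sums to ~0 while its
    band-pass transfer keeps an O(1) peak gain ``~q(e1 - e2)`` at the map
    wavelength -- the coupling that organizes neighboring neurons into
    smooth orientation domains.  Symmetric, zero on the diagonal (the
    membrane-potential sum excludes the neuron itself), truncated beyond
    ``cutoff_factor * lambda_inh`` in minimum-image distance.
    """
    params = params or LateralKernelParams()
    pos = geometry.positions
    lx = geometry.nx * geometry.a_cell
    ly = geometry.ny * geometry.a_cell
    dx = np.abs(pos[:, None, 0] - pos[None, :, 0])
    dy = np.abs(pos[:, None, 1] - pos[None, :, 1])
    dx = np.minimum(dx, lx - dx)
    dy = np.minimum(dy, ly - dy)
    d2 = dx**2 + dy**2
    u = lateral_kernel_density(np.sqrt(d2), params) * geometry.a_cell**2
    u[d2 > (params.cutoff_factor * params.lambda_inh) ** 2] = 0.0
    np.fill_diagonal(u, 0.0)
    return u


# ---------------------------------------------------------------------------
# synapse state

class SynapseState:
    """Wiring of afferent synapses: per (neuron, site) one LGN cell.

    ``assignment`` is (n_neurons, n_sites) int32 of LGN cell indices;
    ``counts`` is the (n_neurons, n_cells) tally ``n_{i,k,mu1,mu2}`` kept
    consistent incrementally.
    """

    def __init__(self, assignment: np.ndarray, n_cells: int):
        assignment = np.ascontiguousarray(assignment, dtype=np.int32)
        if assignment.min() < 0 or assignment.max() >= n_cells:
            raise ValueError("assignment indices out of range")
        self.assignment = assignment
        self.n_cells = int(n_cells)
        self.counts = self._tally()

    def _tally(self) -> np.ndarray:
        n, s = self.assignment.shape
        counts = np.zeros((n, self.n_cells), dtype=np.int32)
        for i in range(n):
            counts[i] = np.bincount(self.assignment[i], minlength=self.n_cells)
        return counts

    @property
    def n_neurons(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_sites(self) -> int:
        return self.assignment.shape[1]

    def apply_swap(self, neuron: int, site: int, new_cell: int) -> int:
        """Replace one site's presynaptic cell; returns the old cell."""
        old = int(self.assignment[neuron, site])
        self.assignment[neuron, site] = new_cell
        self.counts[neuron, old] -= 1
        self.counts[neuron, new_cell] += 1
        return old

    def copy(self) -> "SynapseState":
        return SynapseState(self.assignment.copy(), self.n_cells)

    def validate(self, geometry: CortexGeometry | None = None) -> None:
        """Check count consistency, conservation, and pool closure."""
        if not np.array_equal(self.counts, self._tally()):
            raise AssertionError("counts inconsistent with assignment")
        if not np.all(self.counts.sum(axis=1) == self.n_sites):
            raise AssertionError("per-neuron synapse count not conserved")
        if geometry is not None:
            for i in range(self.n_neurons):
                for j in range(self.n_sites):
                    if self.assignment[i, j] not in geometry.candidate_pool(i, j):
                        raise AssertionError(
                            f"synapse ({i},{j}) outside its candidate pool")


def random_initial_state(geometry: CortexGeometry,
                         rng: np.random.Generator) -> SynapseState:
    """Rough retinotopic wiring: each site uniform over its candidate pool."""
    hw = POOL_HALF_WIDTH
    side = 2 * hw + 1
    n, s = geometry.n_neurons, geometry.n_sites
    lgn = geometry.lgn
    dx = rng.integers(-hw, hw + 1, size=(n, s))
    dy = rng.integers(-hw, hw + 1, size=(n, s))
    layer = rng.integers(0, lgn.n_layers, size=(n, s))
    cx = (geometry.pool_centers[..., 0] + dx) % lgn.nx
    cy = (geometry.pool_centers[..., 1] + dy) % lgn.ny
    assignment = layer * (lgn.nx * lgn.ny) + cx * lgn.ny + cy
    return SynapseState(assignment.astype(np.int32), lgn.n_cells)


# ---------------------------------------------------------------------------
# activations

def afferent_potential(state: SynapseState, table: LGNResponseTable,
                       v: float = 0.045) -> np.ndarray:
    """(n_neurons, n_stimuli*n_t) afferent membrane potential.

    Linear in the synapse counts; incremental updates after a single swap
    are ``s_aff[i] += v * (eta[new] - eta[old])`` (done in the MC engine).
    """
    if state.n_cells != table.n_cells:
        raise ValueError("state and table disagree on the number of LGN cells")
    if not np.all(state.counts.sum(axis=1) == state.n_sites):
        raise ValueError("inconsistent synapse counts")
    return v * (state.counts.astype(np.float64) @ table.flat)


def update_thresholds(s_aff: np.ndarray) -> np.ndarray:
    """Firing thresholds: long-time mean of the membrane potential, i.e.
    the average over all stimuli and time samples of the active ensemble."""
    return s_aff.mean(axis=1)


def firing_rates(s_aff: np.ndarray, theta: np.ndarray,
                 u_lateral: np.ndarray | None = None):
    """Rectified afferent rate and its first-order lateral correction.

    ``eta_aff = (s_aff - theta) Theta(s_aff - theta)``; the lateral term is
    added only where the neuron is itself suprathreshold (the gate carried
    over from linearizing the rectification).
    """
    gate = s_aff > theta[:, None]
    eta_aff = np.where(gate, s_aff - theta[:, None], 0.0)
    if u_lateral is None:
        return eta_aff, eta_aff.copy()
    # first-order lateral correction; rates are physically non-negative, so
    # clip where strong inhibition drives the linearized rate below zero
    eta_cx = np.maximum(eta_aff + gate * (u_lateral @ eta_aff), 0.0)
    return eta_aff, eta_cx


def lateral_drive(eta_aff: np.ndarray, u_lateral: np.ndarray) -> np.ndarray:
    """(N, ST) summed lateral input ``sum_i' U_{i,i'} eta_aff_{i'}``."""
    return u_lateral @ eta_aff


def growth_rate(eta_cand: np.ndarray, s_aff_i: np.ndarray, theta_i: float,
                lateral_i: np.ndarray | None, c_dp: float) -> float:
    """Stimulus-averaged synapse growth rate for one candidate afferent.

    Implements the first-order-in-lateral expansion

        <b> = (1+c)[<eta_aff eta> + theta <Theta eta>] - c <s_aff eta>
              + (1+c) <Theta L eta> - c <L eta>

    with Theta the suprathreshold indicator of the postsynaptic neuron, L
    the summed lateral drive, and <.> the mean over stimuli and time.
    Deterministic given the activation state; every term carries the
    candidate's response, so a silent candidate has <b> = 0.
    """
    s = np.asarray(s_aff_i, dtype=np.float64)
    e = np.asarray(eta_cand, dtype=np.float64)
    gate = s > theta_i
    eta_aff = np.where(gate, s - theta_i, 0.0)
    w = (1.0 + c_dp) * (eta_aff + theta_i * gate) - c_dp * s
    if lateral_i is not None:
        lat = np.asarray(lateral_i, dtype=np.float64)
        w = w + (1.0 + c_dp) * gate * lat - c_dp * lat
    return float(np.mean(w * e))
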
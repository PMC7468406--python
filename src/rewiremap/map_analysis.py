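"""Orientation-map metrics and receptive-field reconstruction.

Preferred orientation and orientation magnitude follow the vector-sum
method: the tuning curve is treated as weights on unit vectors at twice
the stimulus orientation (orientation is a 180-degree-periodic quantity),
so ``pref = arg(sum r exp(2i theta))/2`` and ``mag = |sum r exp(2i theta)|``
-- the modulation amplitude of the second harmonic.

The over-representation index (ORI) quantifies how much cortical area
prefers the exposed (vertical) orientation in a 6-bin histogram:
``ORI = (area@90% - 100/6) / (100 - 100/6)``, 0 for a uniform histogram,
1 for complete over-representation.

The orientation selectivity index (OSI) multiplies tuning depth by tuning
sharpness: ``OSI = (1 - r_min/r_max)(1 - FWHH/180)``, and is defined to be
zero when the tuning curve crosses its half-height line more than three
times (no unique preferred orientation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cortex as _cortex
from .cortex import CortexGeometry, SynapseState
from .stimulus_lgn import (LGNGrid, LGNResponseTable, LGNRFParams,
                           spatial_kernel, temporal_kernel)

__all__ = [
    "TuningCurves", "OrientationMap",
    "vector_sum", "orientation_histogram", "ori", "osi", "fwhh",
    "probe_tuning", "compute_orientation_map", "reconstruct_rf",
    "power_spectrum", "band_power_fraction", "expected_map_wavenumber",
    "nonselective_mask", "render_polar_map",
]


@dataclass(frozen=True)
class TuningCurves:
    """Per-neuron orientation tuning: responses (n_neurons, n_orientations)."""

    orientations: np.ndarray     # probe orientations (deg, [0, 180))
    responses: np.ndarray        # time-averaged rate, >= 0

    def __post_init__(self) -> None:
        if self.responses.shape[1] != self.orientations.size:
            raise ValueError("responses do not match orientations")


@dataclass(frozen=True)
class OrientationMap:
    """Vector-sum preferred orientation (deg, [0,180)) and magnitude."""

    pref: np.ndarray
    mag: np.ndarray
    shape: tuple[int, int]

    def pref_grid(self) -> np.ndarray:
        return self.pref.reshape(self.shape)

    def mag_grid(self) -> np.ndarray:
        return self.mag.reshape(self.shape)


# ---------------------------------------------------------------------------
# vector-sum method

def vector_sum(responses: np.ndarray, orientations: np.ndarray):
    """Preferred orientation and magnitude from the second-harmonic sum.

    Works on a single curve (1-D) or a stack (n, n_orientations).  An
    all-zero curve has magnitude 0 and undefined preference (NaN).
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    orientations = np.asarray(orientations, dtype=float)
    if orientations.size < 2:
        raise ValueError("need at least two distinct probe orientations")
    z = responses @ np.exp(2j * np.deg2rad(orientations))
    mag = np.abs(z)
    pref = np.where(mag > 0, np.rad2deg(np.angle(z)) / 2.0 % 180.0, np.nan)
    if pref.shape[0] == 1 and np.ndim(responses) == 2 and responses.shape[0] == 1:
        return float(pref[0]), float(mag[0])
    return pref, mag


def orientation_histogram(pref: np.ndarray, n_bins: int = 6,
                          weights: np.ndarray | None = None):
    """Relative-area histogram of preferred orientations.

    Bins are centered on the stimulus orientations (0, 180/n_bins, ...);
    each preference is assigned to the nearest bin center modulo 180.
    Returns ``(bin_centers_deg, rel_area_percent)`` with the areas summing
    to 100.  NaN preferences (undefined) are excluded.
    """
    pref = np.asarray(pref, dtype=float).ravel()
    ok = np.isfinite(pref)
    pref = pref[ok]
    if weights is not None:
        weights = np.asarray(weights, dtype=float).ravel()[ok]
    else:
        weights = np.ones(pref.size)
    if pref.size == 0:
        raise ValueError("no defined preferred orientations to histogram")
    width = 180.0 / n_bins
    idx = np.rint(pref / width).astype(int) % n_bins
    area = np.bincount(idx, weights=weights, minlength=n_bins)
    centers = np.arange(n_bins) * width
    return centers, 100.0 * area / area.sum()


def ori(rel_area: np.ndarray, bin_centers: np.ndarray | None = None) -> float:
    """Over-representation index of the 90-degree bin of a 6-bin histogram.

    ``(area@90 - 100/6)/(100 - 100/6)``: 1 for complete over-representation,
    0 for the unbiased histogram, negative for under-representation.
    """
    rel_area = np.asarray(rel_area, dtype=float)
    if rel_area.size != 6:
        raise ValueError("ORI is defined on a 6-bin orientation histogram")
    if not np.isclose(rel_area.sum(), 100.0):
        raise ValueError("relative areas must sum to 100%")
    if bin_centers is None:
        bin_centers = np.arange(6) * 30.0
    i90 = np.flatnonzero(np.isclose(np.asarray(bin_centers, float), 90.0))
    if i90.size != 1:
        raise ValueError("histogram must have exactly one bin centered at 90")
    uniform = 100.0 / 6.0
    return float((rel_area[i90[0]] - uniform) / (100.0 - uniform))


# ---------------------------------------------------------------------------
# orientation selectivity index

def _half_crossings(theta: np.ndarray, r: np.ndarray, half: float):
    """Crossing positions of the 180-periodic piecewise-linear curve with
    the horizontal half-height line.  Points on the line count as above."""
    n = theta.size
    cross = []
    above = r >= half
    for k in range(n):
        k2 = (k + 1) % n
        if above[k] == above[k2]:
            continue
        th1, th2 = theta[k], theta[k] + (theta[k2] - theta[k]) % 180.0
        if th2 == th1:
            th2 = th1 + 180.0 / n
        frac = (half - r[k]) / (r[k2] - r[k])
        cross.append(((th1 + frac * (th2 - th1)) % 180.0, bool(above[k2])))
    return cross


def fwhh(responses: np.ndarray, orientations: np.ndarray) -> float:
    """Full width at half height of a periodic orientation tuning curve.

    Half height is measured between the curve's floor and peak
    (``r_min + (r_max - r_min)/2``); crossings are located by linear
    interpolation on the 180-degree-periodic curve.  Returns the width of
    the above-half interval containing the peak, in degrees; a curve that
    never drops below half height has width 180.
    """
    r = np.asarray(responses, dtype=float)
    theta = np.asarray(orientations, dtype=float)
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    r_max, r_min = r.max(), r.min()
    if r_max == r_min:
        return 180.0
    half = r_min + (r_max - r_min) / 2.0
    if np.all(r >= half):
        return 180.0
    peak = theta[int(np.argmax(r))]
    cross = _half_crossings(theta, r, half)
    ups = sorted(c[0] for c in cross if c[1])        # upward crossings
    downs = sorted(c[0] for c in cross if not c[1])  # downward crossings
    # interval containing the peak: nearest upward crossing at or below the
    # peak (cyclically) to the nearest downward crossing above it
    up = max((u for u in ups if u <= peak), default=max(ups) - 180.0)
    down = min((d for d in downs if d >= peak), default=min(downs) + 180.0)
    return float((down - up) % 180.0 or 180.0)


def osi(responses: np.ndarray, orientations: np.ndarray) -> float:
    """Orientation selectivity index of one tuning curve, in [0, 1].

    Product of tuning depth ``1 - r_min/r_max`` and sharpness
    ``1 - FWHH/180``.  Zero for a flat curve, and zero by definition when
    the curve crosses its half-height line more than three times (e.g. a
    bimodal curve with two comparable peaks).
    """
    r = np.asarray(responses, dtype=float)
    theta = np.asarray(orientations, dtype=float)
    if np.any(r < 0):
        raise ValueError("tuning responses must be non-negative")
    r_max, r_min = r.max(), r.min()
    if r_max <= 0 or r_max == r_min:
        return 0.0
    half = r_min + (r_max - r_min) / 2.0
    if len(_half_crossings(theta, r, half)) > 3:
        return 0.0
    return float((1.0 - r_min / r_max) * (1.0 - fwhh(r, theta) / 180.0))


# ---------------------------------------------------------------------------
# probing the model cortex

def probe_tuning(state: SynapseState, table: LGNResponseTable,
                 u_lateral: np.ndarray | None = None,
                 v: float = 0.045) -> TuningCurves:
    """Orientation tuning curves with frozen synapses.

    The probe ensemble must pair both drift directions of each orientation;
    responses are the time-averaged first-order-corrected cortical rates
    (``eta_cx``), averaged over the two directions.  Probing never rewires:
    the state is read-only here.
    """
    dirs = np.array([s.theta_dr % 360.0 for s in table.stimuli])
    orientations = np.unique(np.round(dirs % 180.0, 9))
    s_aff = _cortex.afferent_potential(state, table, v)
    theta = _cortex.update_thresholds(s_aff)
    _, eta_cx = _cortex.firing_rates(s_aff, theta, u_lateral)
    per_stim = eta_cx.reshape(state.n_neurons, table.n_stimuli,
                              table.n_t).mean(axis=2)
    responses = np.zeros((state.n_neurons, orientations.size))
    for k, o in enumerate(orientations):
        sel = np.isclose(dirs % 180.0, o)
        if sel.sum() != 2:
            raise ValueError("probe ensemble must contain exactly two drift "
                             f"directions for orientation {o}")
        responses[:, k] = per_stim[:, sel].mean(axis=1)
    return TuningCurves(orientations=orientations, responses=responses)


def compute_orientation_map(curves: TuningCurves,
                            shape: tuple[int, int]) -> OrientationMap:
    pref, mag = vector_sum(curves.responses, curves.orientations)
    return OrientationMap(pref=np.asarray(pref), mag=np.asarray(mag),
                          shape=shape)


def nonselective_mask(curves: TuningCurves, omap: OrientationMap) -> np.ndarray:
    """Orientation-nonselective neurons: OSI = 0 and vector-sum magnitude
    below half the magnitude averaged over the model cortex."""
    osi_vals = np.array([osi(r, curves.orientations) for r in curves.responses])
    return (osi_vals == 0.0) & (omap.mag < 0.5 * omap.mag.mean())


# ---------------------------------------------------------------------------
# receptive-field reconstruction

def reconstruct_rf(state: SynapseState, neuron: int, grid: LGNGrid,
                   params: LGNRFParams | None = None,
                   times: np.ndarray | None = None,
                   pixel: float = 0.05, half_width: float = 1.5,
                   center: tuple[float, float] | None = None):
    """Spatiotemporal receptive field of one cortical neuron.

    The field is the synapse-count-weighted sum of the LGN receptive
    fields: ``R_cx(x, t) = sum_cells n_c * S_c(x) * T_c(t)``, rendered on a
    pixel grid centered on the neuron's afferent center of mass, sampled
    every 10 ms by default.  Exactly linear in the counts.
    """
    params = params or LGNRFParams()
    if times is None:
        times = np.arange(0.0, params.t_window + params.tau_latency + 1e-9,
                          0.010)
    counts = state.counts[neuron]
    cells = np.flatnonzero(counts)
    pos = grid.positions()
    mu1, mu2 = grid.mu_arrays()

    if center is not None:
        cx, cy = center
    elif cells.size:
        wsum = counts[cells].sum()
        cx, cy = (counts[cells] @ pos[cells]) / wsum
    else:
        cx = cy = 0.0
    ax = cx + np.arange(-half_width, half_width + pixel / 2, pixel)
    ay = cy + np.arange(-half_width, half_width + pixel / 2, pixel)
    xs, ys = np.meshgrid(ax, ay, indexing="ij")

    frames = np.zeros((times.size, ax.size, ay.size))
    ex, ey = grid.extent
    for c in cells:
        dx = np.abs(xs - pos[c, 0])
        dy = np.abs(ys - pos[c, 1])
        dx = np.minimum(dx, ex - dx)      # periodic LGN lattice
        dy = np.minimum(dy, ey - dy)
        s = spatial_kernel(mu1[c], np.hypot(dx, dy), params)
        tk = temporal_kernel(mu2[c], times, params)
        frames += counts[c] * tk[:, None, None] * s[None, :, :]
    return times, (ax, ay), frames


# ---------------------------------------------------------------------------
# map power spectra

def power_spectrum(omap: OrientationMap):
    """Radially averaged power spectrum of the complex orientation field.

    The field ``mag * exp(2i pref)`` is Fourier transformed over the
    periodic lattice; power is averaged in integer radial wavenumber bins
    (cycles per lattice, bin 0 = DC).
    """
    z = (omap.mag * np.exp(2j * np.deg2rad(np.where(np.isfinite(omap.pref),
                                                    omap.pref, 0.0))))
    z = z.reshape(omap.shape)
    power = np.abs(np.fft.fft2(z)) ** 2
    ky, kx = np.meshgrid(np.fft.fftfreq(omap.shape[1]) * omap.shape[1],
                         np.fft.fftfreq(omap.shape[0]) * omap.shape[0],
                         indexing="xy")
    k = np.hypot(kx, ky).T
    bins = np.rint(k).astype(int)
    n_bins = bins.max() + 1
    radial = np.bincount(bins.ravel(), weights=power.ravel(), minlength=n_bins)
    counts = np.bincount(bins.ravel(), minlength=n_bins)
    return np.arange(n_bins), radial / np.maximum(counts, 1)


def band_power_fraction(omap: OrientationMap,
                        k_band: tuple[float, float] = (0.5, 2.5)) -> float:
    """Fraction of non-DC spectral power inside a radial wavenumber band.

    The statistic that separates structured (band-pass) orientation maps
    from spatially random ones: a random map spreads power over all radii,
    a self-organized map concentrates it in an annulus near the lateral
    interaction's characteristic wavenumber.
    """
    k, p = power_spectrum(omap)
    nz = k > 0
    total = p[nz].sum()
    if total == 0:
        return 0.0
    sel = nz & (k >= k_band[0]) & (k <= k_band[1])
    return float(p[sel].sum() / total)


def expected_map_wavenumber(geometry: CortexGeometry,
                            params=None) -> float:
    """Characteristic map wavenumber (cycles per lattice) from the peak of
    the lateral difference-of-Gaussians transfer function."""
    from .cortex import LateralKernelParams

    params = params or LateralKernelParams()
    le2, li2 = params.lambda_ex**2, params.lambda_inh**2
    k_peak = np.sqrt(2 * np.log(li2 / le2) / (li2 - le2))   # rad / length
    domain = geometry.nx * geometry.a_cell
    return float(k_peak * domain / (2 * np.pi))


# ---------------------------------------------------------------------------
# rendering

def render_polar_map(omap: OrientationMap, path, mag_percentile: float = 99.0):
    """Write the polar map as PNG: hue = preferred orientation, value =
    magnitude normalized to its ``mag_percentile`` percentile."""
    from matplotlib import pyplot as plt
    from matplotlib.colors import hsv_to_rgb

    pref = np.where(np.isfinite(omap.pref), omap.pref, 0.0).reshape(omap.shape)
    mag = omap.mag_grid()
    scale = np.percentile(mag, mag_percentile) or 1.0
    hsv = np.stack([pref / 180.0, np.ones_like(mag),
                    np.clip(mag / scale, 0, 1)], axis=-1)
    fig, ax_ = plt.subplots(figsize=(4, 4))
    ax_.imshow(hsv_to_rgb(hsv), origin="lower")
    ax_.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
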
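"""Drifting-grating stimuli and model LGN responses.

The model LGN is a periodic lattice of concentric-receptive-field relay
cells in four flavours: ON/OFF center (``mu1 = +1/-1``) crossed with
non-lagged/lagged timing (``mu2 = +1/-1``).  Each cell's spatiotemporal
receptive field is separable: a difference-of-Gaussians (DOG) spatial
kernel times a windowed, exponentially damped sinusoid in time.  The
response to a stimulus is the half-rectified spatiotemporal convolution of
that kernel with the luminance pattern.

For drifting sinusoidal gratings the pre-rectification drive is, at
periodic steady state, a pure sinusoid in time whose complex amplitude
factorizes into (i) the DOG transfer function at the grating's spatial
frequency, (ii) the discrete temporal transfer of the sampled temporal
kernel at the grating's temporal frequency, and (iii) a spatial phase set
by the cell's receptive-field center.  ``lgn_response`` evaluates that
closed form by default, which makes the time-averaged response exactly
independent of drift direction (concentric receptive fields carry no
orientation preference); a pixel-grid quadrature route is provided as an
independent numerical cross-check.

Units: visual-field positions and extents in degrees, time in seconds,
temporal frequencies in Hz, spatial frequencies in cycles/degree.  The
temporal convolution is a plain sum over 5-ms samples (rectangle rule with
time in units of the sampling bin), which fixes the overall response scale
the rest of the model (``v``, ``beta``) is calibrated against.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ON", "OFF", "NONLAGGED", "LAGGED",
    "LGNRFParams", "GratingStimulus", "LGNGrid", "LGNResponseTable",
    "spatial_kernel", "temporal_kernel", "dog_transfer", "temporal_transfer",
    "grating_frame", "lgn_response", "build_response_table",
    "twelve_orientation_ensemble", "single_orientation_ensemble",
    "rectified_sine_mean",
]

ON, OFF = +1, -1
NONLAGGED, LAGGED = +1, -1

#: default temporal sampling step (s); the stimulus grid must resolve both
#: the grating and receptive-field frequencies, 5 ms is the coarsest allowed
DEFAULT_DT = 0.005


@dataclass(frozen=True)
class LGNRFParams:
    """Parameters of the LGN spatiotemporal receptive field.

    Defaults are least-squares fits to cat LGN reverse-correlation data.
    """

    lambda_c: float = 0.225       # center subfield extent (deg)
    lambda_s: float = 0.9         # surround subfield extent (deg)
    kappa_sc: float = 1.0         # surround/center strength ratio
    amplitude: float = 1.0        # temporal kernel coefficient A
    tau_decay: float = 0.100      # temporal decay constant (s)
    f_rf: float = 5.0             # receptive-field temporal frequency (Hz)
    t_window: float = 0.200       # temporal kernel window (s)
    tau_latency: float = 0.057    # latency of the lagged response (s)

    def __post_init__(self) -> None:
        if not (self.lambda_s > self.lambda_c > 0):
            raise ValueError("require lambda_s > lambda_c > 0")
        if self.t_window <= 0:
            raise ValueError("require t_window > 0")


@dataclass(frozen=True)
class GratingStimulus:
    """A full-field drifting sinusoidal grating.

    ``theta_dr`` is the drift direction in degrees; ``theta_dr`` and
    ``theta_dr + 180`` share the same orientation ``theta_dr % 180`` and
    drift oppositely.
    """

    theta_dr: float               # drift direction (deg)
    f_spat: float = 0.4           # spatial frequency (cycles/deg)
    f_temp: float = 4.0           # temporal frequency (Hz)
    contrast: float = 1.0

    @property
    def orientation(self) -> float:
        return self.theta_dr % 180.0

    @property
    def period(self) -> float:
        return 1.0 / self.f_temp

    def wave_vector(self) -> tuple[float, float]:
        th = np.deg2rad(self.theta_dr)
        return (self.f_spat * np.cos(th), self.f_spat * np.sin(th))


def twelve_orientation_ensemble(f_spat: float = 0.4, f_temp: float = 4.0,
                                contrast: float = 1.0) -> tuple[GratingStimulus, ...]:
    """Balanced battery of 24 drift directions (12 orientations x 2)."""
    return tuple(GratingStimulus(15.0 * k, f_spat, f_temp, contrast)
                 for k in range(24))


def single_orientation_ensemble(orientation: float = 90.0, f_spat: float = 0.4,
                                f_temp: float = 4.0,
                                contrast: float = 1.0) -> tuple[GratingStimulus, ...]:
    """One orientation drifting in both directions (goggle-rearing stimulus)."""
    return (GratingStimulus(orientation, f_spat, f_temp, contrast),
            GratingStimulus(orientation + 180.0, f_spat, f_temp, contrast))


# ---------------------------------------------------------------------------
# receptive-field kernels

def spatial_kernel(mu1, d, params: LGNRFParams):
    """Signed DOG density (1/deg^2) at visual-field distance ``d`` (deg)."""
    d2 = np.square(np.asarray(d, dtype=float))
    center = np.exp(-d2 / (2 * params.lambda_c**2)) / (2 * np.pi * params.lambda_c**2)
    surround = np.exp(-d2 / (2 * params.lambda_s**2)) / (2 * np.pi * params.lambda_s**2)
    return mu1 * (center - params.kappa_sc * surround)


def temporal_kernel(mu2, t, params: LGNRFParams):
    """Windowed damped-sinusoid temporal kernel (non-lagged or lagged).

    The non-lagged kernel is supported on ``[0, t_window]``; the lagged one
    is sign-inverted, time-reversed in its envelope, and supported on
    ``[tau_latency, t_window + tau_latency]``.
    """
    t = np.asarray(t, dtype=float)
    w, lat, tau, f = params.t_window, params.tau_latency, params.tau_decay, params.f_rf
    if mu2 == NONLAGGED:
        inside = (t >= 0) & (t <= w)
        out = params.amplitude * np.exp(-t / tau) * np.sin(2 * np.pi * f * t)
        return np.where(inside, out, 0.0)
    if mu2 == LAGGED:
        inside = (t >= lat) & (t <= w + lat)
        out = (-params.amplitude
               * np.exp(-(w + lat - t) / tau)
               * np.sin(2 * np.pi * f * (t - lat)))
        return np.where(inside, out, 0.0)
    raise ValueError(f"mu2 must be +1 or -1, got {mu2}")


def dog_transfer(f_spat: float, params: LGNRFParams) -> float:
    """Fourier transform of the unit-sign DOG at radial frequency ``f_spat``.

    Radially symmetric, hence independent of drift direction.
    """
    gc = np.exp(-2 * np.pi**2 * params.lambda_c**2 * f_spat**2)
    gs = np.exp(-2 * np.pi**2 * params.lambda_s**2 * f_spat**2)
    return gc - params.kappa_sc * gs


def _temporal_transfer_raw(mu2: int, f_temp: float, params: LGNRFParams,
                           dt: float = DEFAULT_DT) -> complex:
    """Unnormalized discrete transfer ``sum_n T(n dt) exp(i w n dt)``."""
    n = int(np.ceil((params.t_window + params.tau_latency) / dt)) + 1
    ts = np.arange(n) * dt
    k = temporal_kernel(mu2, ts, params)
    return complex(np.sum(k * np.exp(2j * np.pi * f_temp * ts)))


def temporal_gain_norm(params: LGNRFParams, dt: float = DEFAULT_DT) -> float:
    """Normalization constant of the temporal transfer.

    The response scale of the discrete convolution is otherwise arbitrary
    (it depends on the sampling step); responses are expressed in units of
    the modulation a unit-contrast stimulus at the receptive field's own
    characteristic frequency ``f_rf`` evokes through the non-lagged kernel.
    This puts LGN firing-rate modulations at O(1) and places the rewiring
    phase transition at the intended inverse-temperature scale.
    """
    return 1.0 / abs(_temporal_transfer_raw(NONLAGGED, params.f_rf, params, dt))


def temporal_transfer(mu2: int, f_temp: float, params: LGNRFParams,
                      dt: float = DEFAULT_DT) -> complex:
    """Normalized discrete transfer of the sampled temporal kernel.

    The discrete convolution of the sampled kernel with ``cos(phi - w t)``
    equals ``Re[H exp(i (phi - w t))]`` with ``H`` this transfer (times the
    gain normalization of :func:`temporal_gain_norm`).
    """
    return (_temporal_transfer_raw(mu2, f_temp, params, dt)
            * temporal_gain_norm(params, dt))


# ---------------------------------------------------------------------------
# stimulus rendering

def grating_frame(stim: GratingStimulus, t, xs, ys):
    """Luminance of the grating at pixel positions (deg) and time ``t`` (s)."""
    fx, fy = stim.wave_vector()
    phase = 2 * np.pi * (fx * np.asarray(xs) + fy * np.asarray(ys))
    return stim.contrast * np.cos(phase - 2 * np.pi * stim.f_temp * np.asarray(t))


# ---------------------------------------------------------------------------
# LGN lattice

_LAYER_MU = ((ON, NONLAGGED), (OFF, NONLAGGED), (ON, LAGGED), (OFF, LAGGED))


@dataclass(frozen=True)
class LGNGrid:
    """Periodic lattice of LGN cells: four type layers over an nx x ny grid.

    Cells are indexed ``c = layer * nx * ny + kx * ny + ky`` with layers
    ordered (ON,non-lagged), (OFF,non-lagged), (ON,lagged), (OFF,lagged).
    """

    nx: int = 24
    ny: int = 24
    spacing: float = 0.25   # retinotopic spacing (deg between adjacent cells)

    @property
    def n_layers(self) -> int:
        return len(_LAYER_MU)

    @property
    def n_cells(self) -> int:
        return self.n_layers * self.nx * self.ny

    def cell_index(self, layer: int, kx: int, ky: int) -> int:
        return layer * self.nx * self.ny + (kx % self.nx) * self.ny + (ky % self.ny)

    def cell_mu(self, c: int) -> tuple[int, int]:
        return _LAYER_MU[c // (self.nx * self.ny)]

    def cell_position(self, c: int) -> tuple[float, float]:
        plane = c % (self.nx * self.ny)
        return ((plane // self.ny) * self.spacing, (plane % self.ny) * self.spacing)

    def positions(self) -> np.ndarray:
        """(n_cells, 2) receptive-field centers in degrees."""
        kx, ky = np.divmod(np.arange(self.nx * self.ny), self.ny)
        xy = np.stack([kx * self.spacing, ky * self.spacing], axis=1)
        return np.tile(xy, (self.n_layers, 1))

    def mu_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        plane = self.nx * self.ny
        mu1 = np.repeat([m1 for m1, _ in _LAYER_MU], plane)
        mu2 = np.repeat([m2 for _, m2 in _LAYER_MU], plane)
        return mu1, mu2

    @property
    def extent(self) -> tuple[float, float]:
        return (self.nx * self.spacing, self.ny * self.spacing)


# ---------------------------------------------------------------------------
# responses

def rectified_sine_mean(amplitude: float, dc: float = 0.0) -> float:
    """Exact time average of ``max(dc + amplitude*cos(wt), 0)`` over a period."""
    a = abs(amplitude)
    if a == 0.0:
        return max(dc, 0.0)
    x = dc / a
    if x >= 1.0:
        return dc
    if x <= -1.0:
        return 0.0
    alpha = np.arccos(-x)
    return (dc * alpha + a * np.sin(alpha)) / np.pi


def _steady_state_amplitude(cell_xy, mu1, mu2, stim: GratingStimulus,
                            params: LGNRFParams, dt: float) -> complex:
    """Complex amplitude of the pre-rectification drive at steady state."""
    fx, fy = stim.wave_vector()
    psi = 2 * np.pi * (fx * cell_xy[0] + fy * cell_xy[1])
    return (mu1 * stim.contrast * dog_transfer(stim.f_spat, params)
            * np.exp(1j * psi) * temporal_transfer(mu2, stim.f_temp, params, dt))


def _check_dt(stim: GratingStimulus, params: LGNRFParams, dt: float) -> None:
    if dt > DEFAULT_DT + 1e-12:
        raise ValueError(
            f"temporal step {dt} s too coarse to resolve f_temp={stim.f_temp} Hz "
            f"and f_rf={params.f_rf} Hz; need dt <= {DEFAULT_DT} s")


def lgn_response(cell_xy, mu1: int, mu2: int, stim: GratingStimulus,
                 params: LGNRFParams, dt: float = DEFAULT_DT,
                 method: str = "analytic"):
    """Half-rectified response of one LGN cell to a drifting grating.

    Returns ``(t_grid, eta, eta_mean)`` where ``eta`` samples one full
    temporal period of the periodic steady state and ``eta_mean`` is the
    exact continuous-time average of the rectified drive.

    ``method="analytic"`` evaluates the closed-form sinusoidal steady state;
    ``method="quadrature"`` renders the grating on a pixel grid and performs
    the discrete space-time convolution (slower; used as a cross-check).
    """
    _check_dt(stim, params, dt)
    n_t = int(round(stim.period / dt))
    if abs(n_t * dt - stim.period) > 1e-9:
        raise ValueError("temporal step must divide the stimulus period")
    t_grid = np.arange(n_t) * dt

    if method == "analytic":
        amp = _steady_state_amplitude(cell_xy, mu1, mu2, stim, params, dt)
        drive = np.real(amp * np.exp(-2j * np.pi * stim.f_temp * t_grid))
        eta = np.maximum(drive, 0.0)
        return t_grid, eta, rectified_sine_mean(abs(amp))
    if method == "quadrature":
        drive = _quadrature_drive(cell_xy, mu1, mu2, stim, params, dt, t_grid)
        eta = np.maximum(drive, 0.0)
        return t_grid, eta, float(eta.mean())
    raise ValueError(f"unknown method {method!r}")


def _quadrature_drive(cell_xy, mu1, mu2, stim, params, dt, t_grid,
                      pixel: float = 0.125, half_width_factor: float = 4.0):
    """Discrete space-time convolution on a pixel window around the cell.

    The window spans ``half_width_factor`` surround extents; the pixel sum
    carries the pixel-area factor so it approximates the continuum integral.
    """
    hw = half_width_factor * params.lambda_s
    n_pix = int(np.ceil(2 * hw / pixel))
    ax = cell_xy[0] + (np.arange(n_pix) - (n_pix - 1) / 2) * pixel
    ay = cell_xy[1] + (np.arange(n_pix) - (n_pix - 1) / 2) * pixel
    xs, ys = np.meshgrid(ax, ay, indexing="ij")
    d = np.hypot(xs - cell_xy[0], ys - cell_xy[1])
    s_weights = spatial_kernel(mu1, d, params) * pixel**2

    # spatial projection at each sample time of one period
    frames = grating_frame(stim, t_grid[:, None, None], xs[None], ys[None])
    spatial_drive = np.tensordot(frames, s_weights, axes=([1, 2], [0, 1]))

    # periodic steady state: circular convolution with the kernel folded
    # into one stimulus period (plain sum over samples, no dt factor)
    n_t = t_grid.size
    n_k = int(np.ceil((params.t_window + params.tau_latency) / dt)) + 1
    kern = (temporal_kernel(mu2, np.arange(n_k) * dt, params)
            * temporal_gain_norm(params, dt))
    folded = np.zeros(n_t)
    np.add.at(folded, np.arange(n_k) % n_t, kern)
    return np.real(np.fft.ifft(np.fft.fft(spatial_drive) * np.fft.fft(folded)))


@dataclass(frozen=True)
class LGNResponseTable:
    """Precomputed rectified responses of every LGN cell to an ensemble.

    ``eta`` has shape (n_cells, n_stimuli, n_t): one temporal period of the
    periodic steady state per stimulus.  ``eta_mean`` (n_cells, n_stimuli)
    is the exact time average.  ``flat`` is the (n_cells, n_stimuli*n_t)
    view the Monte-Carlo engine correlates against.
    """

    eta: np.ndarray
    eta_mean: np.ndarray
    amplitude: np.ndarray            # complex steady-state amplitudes
    stimuli: tuple[GratingStimulus, ...]
    grid: LGNGrid
    params: LGNRFParams
    dt: float

    @property
    def n_cells(self) -> int:
        return self.eta.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.eta.shape[1]

    @property
    def n_t(self) -> int:
        return self.eta.shape[2]

    @property
    def flat(self) -> np.ndarray:
        return self.eta.reshape(self.n_cells, -1)

    def orientations(self) -> np.ndarray:
        return np.array([s.orientation for s in self.stimuli])

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(repr((self.stimuli, self.grid, self.params, self.dt)).encode())
        return h.hexdigest()[:16]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("eta", data=self.eta, compression="gzip")
            fh.create_dataset("eta_mean", data=self.eta_mean)
            fh.create_dataset("amplitude", data=self.amplitude)
            fh.attrs["content_hash"] = self.content_hash()
            fh.attrs["dt"] = self.dt
            fh.attrs["grid"] = repr(self.grid)
            fh.attrs["params"] = repr(self.params)
            fh.attrs["stimuli"] = repr(self.stimuli)

    @classmethod
    def from_hdf5(cls, path, ensemble, grid: "LGNGrid",
                  params: "LGNRFParams", dt: float) -> "LGNResponseTable":
        import h5py

        table = cls(eta=np.empty((0, 0, 0)), eta_mean=np.empty((0, 0)),
                    amplitude=np.empty((0, 0)), stimuli=tuple(ensemble),
                    grid=grid, params=params, dt=dt)
        with h5py.File(path, "r") as fh:
            if fh.attrs["content_hash"] != table.content_hash():
                raise ValueError("cached table does not match the request")
            object.__setattr__(table, "eta", fh["eta"][...])
            object.__setattr__(table, "eta_mean", fh["eta_mean"][...])
            object.__setattr__(table, "amplitude", fh["amplitude"][...])
        return table


def build_response_table(ensemble, grid: LGNGrid, params: LGNRFParams | None = None,
                         dt: float = DEFAULT_DT) -> LGNResponseTable:
    """Tabulate rectified steady-state responses for all cells x stimuli.

    Deterministic given its inputs; responses do not depend on cortical
    state, so one table serves an entire exposure segment.
    """
    params = params or LGNRFParams()
    ensemble = tuple(ensemble)
    pos = grid.positions()
    mu1, mu2 = grid.mu_arrays()
    n_c = grid.n_cells

    n_t = int(round(ensemble[0].period / dt))
    for s in ensemble:
        _check_dt(s, params, dt)
        if int(round(s.period / dt)) != n_t:
            raise ValueError("all stimuli in an ensemble must share f_temp")
    t_grid = np.arange(n_t) * dt

    amp = np.zeros((n_c, len(ensemble)), dtype=complex)
    for si, stim in enumerate(ensemble):
        dog = dog_transfer(stim.f_spat, params)
        fx, fy = stim.wave_vector()
        psi = 2 * np.pi * (fx * pos[:, 0] + fy * pos[:, 1])
        h = np.where(mu2 == NONLAGGED,
                     temporal_transfer(NONLAGGED, stim.f_temp, params, dt),
                     temporal_transfer(LAGGED, stim.f_temp, params, dt))
        amp[:, si] = mu1 * stim.contrast * dog * np.exp(1j * psi) * h

    phases = np.exp(-2j * np.pi * ensemble[0].f_temp * t_grid)
    drive = np.real(amp[:, :, None] * phases[None, None, :])
    eta = np.maximum(drive, 0.0)
    a = np.abs(amp)
    with np.errstate(invalid="ignore"):
        eta_mean = a / np.pi
    return LGNResponseTable(eta=eta, eta_mean=eta_mean, amplitude=amp,
                            stimuli=ensemble, grid=grid, params=params, dt=dt)


def cached_response_table(cache_dir, ensemble, grid: LGNGrid,
                          params: LGNRFParams | None = None,
                          dt: float = DEFAULT_DT) -> LGNResponseTable:
    """Build (or reload) a response table cached by content hash."""
    from pathlib import Path

    params = params or LGNRFParams()
    probe = LGNResponseTable(eta=np.empty((0, 0, 0)), eta_mean=np.empty((0, 0)),
                             amplitude=np.empty((0, 0)),
                             stimuli=tuple(ensemble), grid=grid,
                             params=params, dt=dt)
    path = Path(cache_dir) / f"lgn_table_{probe.content_hash()}.h5"
    if path.exists():
        return LGNResponseTable.from_hdf5(path, ensemble, grid, params, dt)
    table = build_response_table(ensemble, grid, params, dt)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_hdf5(path)
    return table
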
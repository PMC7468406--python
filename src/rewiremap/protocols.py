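"""Exposure protocols: orchestrated rewiring experiments.

A protocol is a sequence of exposure segments -- balanced 12-orientation
exposure (normal vision) or single-orientation exposure (goggle rearing)
-- executed on one continuous plasticity clock.  The clock's origin t=0 is
the onset of map formation, identified with postnatal day P24 in kittens;
2.25 MC steps correspond to 10 days, so a 2-week goggle-rearing episode is
3.15 MC steps.

Protocols probe the frozen wiring with a balanced 12-orientation battery
at segment boundaries (and any extra probe times), recording the
orientation map, its 6- and 12-bin histograms, the over-representation
index of the vertical orientation (ORI), the mean orientation selectivity
index (OSI), and the band-pass power statistic of the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import map_analysis as ma
from .config import ModelConfig
from .cortex import CortexGeometry
from .rewiring import Simulation
from .stimulus_lgn import (build_response_table, single_orientation_ensemble,
                           twelve_orientation_ensemble)

__all__ = [
    "Segment", "ProtocolSchedule", "AgeMapping", "RunSummary",
    "twelve", "single", "run_protocol", "sensitive_period_sweep",
    "mcs_to_postnatal_day", "postnatal_day_to_mcs", "beta_sweep",
    "recovery_experiment",
]


@dataclass(frozen=True)
class Segment:
    """One exposure segment: ensemble kind and duration in MC steps."""

    kind: str                      # "twelve" | "single"
    duration: float                # MC steps, > 0
    orientation: float = 90.0      # exposed orientation for "single"

    def __post_init__(self) -> None:
        if self.kind not in ("twelve", "single"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("segment durations must be positive")

    def ensemble_key(self):
        return (self.kind, self.orientation if self.kind == "single" else None)


def twelve(duration: float) -> Segment:
    return Segment("twelve", duration)


def single(duration: float, orientation: float = 90.0) -> Segment:
    return Segment("single", duration, orientation)


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered exposure segments plus optional extra probe times (MC)."""

    segments: tuple[Segment, ...]
    probe_points: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        total = self.total_duration
        for p in self.probe_points:
            if not (0.0 <= p <= total + 1e-9):
                raise ValueError(f"probe point {p} outside the protocol")

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)


@dataclass(frozen=True)
class AgeMapping:
    """Affine map between MC steps and kitten postnatal days."""

    mcs_per_10days: float = 2.25
    onset_day: float = 24.0

    def day(self, t) -> np.ndarray | float:
        return self.onset_day + 10.0 * np.asarray(t, dtype=float) / self.mcs_per_10days

    def mcs(self, day) -> np.ndarray | float:
        return (np.asarray(day, dtype=float) - self.onset_day) * self.mcs_per_10days / 10.0


def mcs_to_postnatal_day(t, mapping: AgeMapping | None = None) -> int:
    """Postnatal day corresponding to MC time ``t`` (nearest integer day)."""
    mapping = mapping or AgeMapping()
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be non-negative")
    return int(np.rint(mapping.day(t)))


def postnatal_day_to_mcs(day, mapping: AgeMapping | None = None) -> float:
    mapping = mapping or AgeMapping()
    return float(mapping.mcs(day))


@dataclass
class RunSummary:
    """Per-probe metrics of one protocol run; reproducible from (config, seed)."""

    seed: int
    config_hash: str
    records: list[dict] = field(default_factory=list)
    final_assignment: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        scalars = ["t", "postnatal_day", "segment", "ori", "mean_osi",
                   "nonselective_frac", "band_fraction", "band_fraction_aff",
                   "accepted"]
        return pd.DataFrame([{k: r[k] for k in scalars} for r in self.records])

    @property
    def final(self) -> dict:
        return self.records[-1]


# ---------------------------------------------------------------------------

def _build_tables(schedule: ProtocolSchedule, geometry: CortexGeometry,
                  config: ModelConfig):
    """One response table per distinct ensemble, plus the probe table."""
    tables = {}
    probe = build_response_table(
        twelve_orientation_ensemble(config.f_spat, config.f_temp),
        geometry.lgn, config.rf, config.dt)
    tables[("twelve", None)] = probe
    for seg in schedule.segments:
        key = seg.ensemble_key()
        if key not in tables:
            tables[key] = build_response_table(
                single_orientation_ensemble(seg.orientation, config.f_spat,
                                            config.f_temp),
                geometry.lgn, config.rf, config.dt)
    return tables, probe


def _probe_record(sim: Simulation, probe_table, segment: str, accepted: int,
                  k_band, keep_state: bool) -> dict:
    curves = ma.probe_tuning(sim.state, probe_table, sim.u_lateral,
                             sim.config.v)
    omap = ma.compute_orientation_map(curves,
                                      (sim.geometry.nx, sim.geometry.ny))
    c6, h6 = ma.orientation_histogram(omap.pref, n_bins=6)
    c12, h12 = ma.orientation_histogram(omap.pref, n_bins=12)
    osi_vals = np.array([ma.osi(r, curves.orientations)
                         for r in curves.responses])
    nonsel = ma.nonselective_mask(curves, omap)
    # afferent-only map: the wiring's own organization, free of the
    # band-pass imprint the lateral readout leaves on any map
    omap_aff = ma.compute_orientation_map(
        ma.probe_tuning(sim.state, probe_table, None, sim.config.v),
        (sim.geometry.nx, sim.geometry.ny))
    rec = {
        "t": sim.clock.t,
        "postnatal_day": mcs_to_postnatal_day(sim.clock.t),
        "segment": segment,
        "ori": ma.ori(h6, c6),
        "mean_osi": float(osi_vals.mean()),
        "nonselective_frac": float(nonsel.mean()),
        "band_fraction": ma.band_power_fraction(omap, k_band),
        "band_fraction_aff": ma.band_power_fraction(omap_aff, k_band),
        "accepted": accepted,
        "hist6": (c6, h6),
        "hist12": (c12, h12),
        "pref": omap.pref.copy(),
        "mag": omap.mag.copy(),
        "osi": osi_vals,
    }
    if keep_state:
        rec["assignment"] = sim.state.assignment.copy()
    return rec


def _default_band(geometry: CortexGeometry, config: ModelConfig):
    k_exp = ma.expected_map_wavenumber(geometry, config.lateral)
    return (max(0.5, 0.5 * k_exp), 2.5 * k_exp)


def run_protocol(schedule: ProtocolSchedule,
                 geometry: CortexGeometry | None = None,
                 config: ModelConfig | None = None,
                 seed: int = 0,
                 keep_states: bool = False,
                 checkpoint_dir=None) -> RunSummary:
    """Execute a protocol and return its probe records.

    Segments run sequentially on a continuous plasticity clock; probes are
    taken at t=0, at every segment boundary, and at ``schedule.probe_points``.
    Deterministic given (schedule, geometry, config, seed).
    """
    geometry = geometry or CortexGeometry.reduced()
    config = config or ModelConfig()
    tables, probe_table = _build_tables(schedule, geometry, config)
    k_band = _default_band(geometry, config)
    chash = config.content_hash(geometry, extra=repr((schedule, seed)))

    sim = Simulation(geometry, tables[schedule.segments[0].ensemble_key()],
                     config=config.rewiring, lateral=config.lateral, seed=seed)
    summary = RunSummary(seed=seed, config_hash=chash)
    summary.records.append(
        _probe_record(sim, probe_table, "initial", 0, k_band, keep_states))

    t_cursor = 0.0
    for seg_idx, seg in enumerate(schedule.segments):
        sim.switch_table(tables[seg.ensemble_key()])
        seg_end = t_cursor + seg.duration
        stops = sorted({p for p in schedule.probe_points
                        if t_cursor < p < seg_end - 1e-9} | {seg_end})
        for stop in stops:
            accepted = sim.run(stop - sim.clock.t)
            summary.records.append(
                _probe_record(sim, probe_table, seg.kind, accepted,
                              k_band, keep_states))
        t_cursor = seg_end
        if checkpoint_dir is not None:
            from .io import save_checkpoint
            save_checkpoint(
                f"{checkpoint_dir}/segment_{seg_idx}.h5", sim, chash)

    summary.final_assignment = sim.state.assignment.copy()
    return summary


# ---------------------------------------------------------------------------
# experiments

def sensitive_period_sweep(onsets, exposure_len: float = 3.15,
                           geometry: CortexGeometry | None = None,
                           config: ModelConfig | None = None,
                           n_seeds: int = 5, base_seed: int = 0) -> pd.DataFrame:
    """ORI after single-orientation exposure as a function of its onset.

    For each onset t0: run 12-orientation exposure until t0, then
    single-orientation exposure for ``exposure_len`` MC steps, and record
    the final ORI.  Negative onsets model goggle rearing that begins before
    map formation starts (t=0): plasticity is absent before t=0, so only
    the part of the exposure falling after t=0 is effective -- the
    truncation that produces the rising phase of the sensitive-period
    profile.  Seeds are paired across onsets (the same initial random
    wiring per seed), matching how error bars are estimated over repeated
    simulations with different initial afferent patterns.
    """
    rows = []
    for s in range(n_seeds):
        seed = base_seed + s
        for t0 in onsets:
            effective = t0 + exposure_len          # exposure ends here
            segs = []
            if t0 > 0:
                segs.append(twelve(t0))
            if effective > 0:
                segs.append(single(effective - max(t0, 0.0)))
            if segs:
                res = run_protocol(ProtocolSchedule(tuple(segs)),
                                   geometry, config, seed=seed)
                final = res.final
            else:                                   # exposure entirely pre-plasticity
                res = run_protocol(ProtocolSchedule((twelve(1e-9),)),
                                   geometry, config, seed=seed)
                final = res.records[0]
            rows.append({"onset": t0, "seed": seed,
                         "t_final": final["t"],
                         "postnatal_day": mcs_to_postnatal_day(max(t0, 0.0)),
                         "ori": final["ori"],
                         "mean_osi": final["mean_osi"]})
    df = pd.DataFrame(rows)
    g = df.groupby("onset")["ori"]
    df = df.merge(g.agg(ori_mean="mean",
                        ori_se=lambda x: x.std(ddof=1) / np.sqrt(len(x))
                        if len(x) > 1 else 0.0).reset_index(), on="onset")
    return df


def beta_sweep(betas, duration: float = 6.0,
               geometry: CortexGeometry | None = None,
               config: ModelConfig | None = None,
               n_seeds: int = 3, base_seed: int = 0,
               threshold: float = 0.5):
    """Map-formation indicator versus inverse temperature.

    Runs 12-orientation exposure for ``duration`` MC steps at each beta and
    classifies map formation by the band-pass power fraction of the final
    afferent-only orientation map exceeding ``threshold`` (an unstructured
    map scores ~0.2 on this statistic, a mature map >~0.75; the midpoint
    0.5 separates the two regimes).  Returns the per-run table and
    a bracketing estimate of the critical beta (largest non-forming /
    smallest forming beta of the seed-averaged indicator); a non-monotone
    classification widens the bracket with a warning.
    """
    geometry = geometry or CortexGeometry.reduced()
    config = config or ModelConfig()
    from dataclasses import replace

    rows = []
    for beta in sorted(betas):
        cfg = ModelConfig(rewiring=replace(config.rewiring, beta=float(beta)),
                          lateral=config.lateral, rf=config.rf,
                          f_spat=config.f_spat, f_temp=config.f_temp,
                          dt=config.dt)
        for s in range(n_seeds):
            res = run_protocol(ProtocolSchedule((twelve(duration),)),
                               geometry, cfg, seed=base_seed + s)
            rows.append({"beta": float(beta), "seed": base_seed + s,
                         "band_fraction": res.final["band_fraction_aff"],
                         "ori": res.final["ori"]})
    df = pd.DataFrame(rows)
    mean_frac = df.groupby("beta")["band_fraction"].mean()
    formed = mean_frac > threshold
    bs = np.array(sorted(mean_frac.index))
    flags = formed.loc[bs].to_numpy()
    changes = np.flatnonzero(np.diff(flags.astype(int)))
    if flags.all() or not flags.any():
        bracket = (None, None)
    elif changes.size == 1 and flags[-1]:
        bracket = (float(bs[changes[0]]), float(bs[changes[0] + 1]))
    else:
        warnings.warn("non-monotone map-formation classification; "
                      "widening the bracket")
        lo = bs[~flags].max()
        hi = bs[flags].min()
        bracket = (float(min(lo, hi)), float(max(lo, hi)))
    return df, {"bracket": bracket, "mean_band_fraction": mean_frac.to_dict(),
                "threshold": threshold}


def recovery_experiment(geometry: CortexGeometry | None = None,
                        config: ModelConfig | None = None,
                        seed: int = 0, keep_states: bool = True):
    """Short and prolonged goggle rearing followed by normal vision.

    Short arm: 1.57 MCs of 12-orientation exposure, 1.57 MCs of
    single-orientation exposure, 1.57 MCs of 12-orientation recovery.
    Long arm: 1.57 MCs, then 7.85 MCs of single-orientation exposure and
    7.09 MCs of 12-orientation recovery.  Both arms share the same seed, so
    their first segments (and hence the 1.57-MC states they branch from)
    are identical.
    """
    short_sched = ProtocolSchedule((twelve(1.57), single(1.57), twelve(1.57)))
    long_sched = ProtocolSchedule((twelve(1.57), single(7.85), twelve(7.09)))
    return {
        "short": run_protocol(short_sched, geometry, config, seed=seed,
                              keep_states=keep_states),
        "long": run_protocol(long_sched, geometry, config, seed=seed,
                             keep_states=keep_states),
    }
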
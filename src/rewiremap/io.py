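"""HDF5 checkpointing of simulation runs.

A checkpoint stores the wiring assignment, the plasticity clock, the RNG
bit-generator state, and a configuration hash, so that an exposure
protocol can be resumed mid-run and reproduce the uninterrupted run bit
for bit.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .cortex import SynapseState
from .rewiring import Simulation

__all__ = ["save_checkpoint", "load_checkpoint", "ConfigHashError"]


class ConfigHashError(RuntimeError):
    """Checkpoint was produced under a different configuration."""


def save_checkpoint(path, sim: Simulation, config_hash: str = "") -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("state")
        g.create_dataset("assignment", data=sim.state.assignment,
                         compression="gzip")
        g.attrs["n_cells"] = sim.state.n_cells
        fh.attrs["t"] = sim.clock.t
        fh.attrs["trial_count"] = sim.clock.trial_count
        fh.attrs["config_hash"] = config_hash
        fh.attrs["rng_state"] = json.dumps(
            sim.rng.bit_generator.state,
            default=lambda o: int(o) if isinstance(o, np.integer) else o)


def load_checkpoint(path, geometry, table, config=None, lateral=None,
                    expected_hash: str | None = None) -> Simulation:
    """Rebuild a :class:`Simulation` from a checkpoint.

    Raises :class:`ConfigHashError` when ``expected_hash`` is given and does
    not match the stored hash.
    """
    with h5py.File(path, "r") as fh:
        stored = fh.attrs.get("config_hash", "")
        if expected_hash is not None and stored != expected_hash:
            raise ConfigHashError(
                f"checkpoint hash {stored!r} != expected {expected_hash!r}")
        assignment = fh["state/assignment"][...]
        n_cells = int(fh["state"].attrs["n_cells"])
        t = float(fh.attrs["t"])
        trial_count = int(fh.attrs["trial_count"])
        rng_state = json.loads(fh.attrs["rng_state"])

    state = SynapseState(assignment, n_cells)
    rng = np.random.default_rng(0)
    rng.bit_generator.state = rng_state
    sim = Simulation(geometry, table, config=config, lateral=lateral,
                     state=state, seed=rng)
    sim.clock.t = t
    sim.clock.trial_count = trial_count
    return sim
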
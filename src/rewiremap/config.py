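"""Bundled model configuration and YAML (de)serialization."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .cortex import CortexGeometry, LateralKernelParams
from .rewiring import RewiringConfig
from .stimulus_lgn import LGNGrid, LGNRFParams

__all__ = ["ModelConfig"]


@dataclass(frozen=True)
class ModelConfig:
    """All tunable model parameters in one place (defaults = operating point)."""

    rewiring: RewiringConfig = field(default_factory=RewiringConfig)
    lateral: LateralKernelParams = field(default_factory=LateralKernelParams)
    rf: LGNRFParams = field(default_factory=LGNRFParams)
    f_spat: float = 0.4     # grating spatial frequency (cycles/deg)
    f_temp: float = 4.0     # grating temporal frequency (Hz)
    dt: float = 0.005       # temporal sampling step (s)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(rewiring=RewiringConfig(**d.get("rewiring", {})),
                   lateral=LateralKernelParams(**d.get("lateral", {})),
                   rf=LGNRFParams(**d.get("rf", {})),
                   f_spat=d.get("f_spat", 0.4),
                   f_temp=d.get("f_temp", 4.0),
                   dt=d.get("dt", 0.005))

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def content_hash(self, geometry: CortexGeometry | None = None,
                     extra: str = "") -> str:
        h = hashlib.sha256()
        h.update(yaml.safe_dump(self.to_dict(), sort_keys=True).encode())
        if geometry is not None:
            h.update(repr((geometry.nx, geometry.ny, geometry.n_sites,
                           geometry.a_cell, geometry.a_spine,
                           geometry.lgn.nx, geometry.lgn.ny,
                           geometry.lgn.spacing)).encode())
        h.update(extra.encode())
        return h.hexdigest()[:16]


def geometry_from_dict(d: dict) -> CortexGeometry:
    lgn = LGNGrid(**d.pop("lgn", {}))
    return CortexGeometry(lgn=lgn, **d)
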
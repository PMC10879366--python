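"""Pipeline configuration: every analysis parameter in one serializable object.

The defaults reproduce the reference analysis settings exactly: ordinal
encoding with m = 5, tau = 1; 30 s windows shifted by 1 s; transfer delays
7..12 pattern steps; time points at -15 s and +30 s around LoR and RoR;
10,000-fold percentile bootstrap at the 95% level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .core import ConfigurationError
from .entropy import EntropyConfig
from .synth import SimulationConfig


def _listify(obj):
    """Tuples -> lists, recursively, so the dict is plain-YAML serializable."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


@dataclass
class PipelineConfig:
    filter_order: int = 1000
    filter_cutoff_hz: float = 30.0
    m: int = 5
    tau: int = 1
    window_s: float = 30.0
    shift_s: float = 1.0
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    pre_offset_s: float = -15.0
    post_offset_s: float = 30.0
    bootstrap_n: int = 10_000
    bootstrap_level: float = 0.95
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_dict(self) -> dict:
        return _listify(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        try:
            if "entropy" in d:
                ent = dict(d["entropy"])
                for key in ("delays", "pe_channels"):
                    if key in ent:
                        ent[key] = tuple(ent[key])
                if "fp_pairs" in ent:
                    ent["fp_pairs"] = tuple(tuple(p) for p in ent["fp_pairs"])
                d["entropy"] = EntropyConfig(**ent)
            if "simulation" in d:
                sim = dict(d["simulation"])
                for key in ("lor_range_s", "ror_margin_s"):
                    if key in sim:
                        sim[key] = tuple(sim[key])
                d["simulation"] = SimulationConfig(**sim)
            return cls(**d)
        except TypeError as exc:
            raise ConfigurationError(f"bad configuration: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
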
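"""Run configuration: nested stage configs, YAML round trip, content hash."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace

import yaml

from ..synth import CONDITIONS, SynthConfig
from ..tracker import TrackerConfig

__all__ = ["RunConfig", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run the full synthetic closed-loop pipeline."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    condition: str = "FPS"
    seed: int = 0
    channel: str = "C4"
    refractory_ms: float = 100.0
    max_out_fraction: float = 0.5
    rose_bins: int = 24
    m_pairs: int = 3
    cv_repeats: int = 10
    cv_folds: int = 10
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        # master seed/condition propagate into the generator config
        object.__setattr__(
            self, "synth", replace(self.synth, seed=self.seed,
                                   condition=self.condition)
        )
        if self.tracker.fs != self.synth.fs:
            object.__setattr__(
                self, "tracker", replace(self.tracker, fs=self.synth.fs)
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d:
            s = dict(d["synth"])
            if "task_window" in s:
                s["task_window"] = tuple(s["task_window"])
            d["synth"] = SynthConfig(**s)
        if "tracker" in d:
            t = dict(d["tracker"])
            if "band" in t:
                t["band"] = tuple(t["band"])
            d["tracker"] = TrackerConfig(**t)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _plain(obj):
    """Coerce tuples to lists recursively so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def config_hash(cfg: RunConfig) -> str:
    """Short stable content hash of a run configuration."""
    blob = json.dumps(_plain(cfg.to_dict()), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
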
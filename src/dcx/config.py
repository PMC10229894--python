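"""Run configuration: every stage's toggles and parameters, YAML-loadable,
with unknown keys rejected and a provenance hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .simulate import BehaviorTargets, SimConfig

__all__ = ["RunConfig", "load_config", "config_hash"]

VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Parameters for an end-to-end pipeline run.

    Section dicts mirror the module parameters: `simulate` feeds
    :class:`~dcx.simulate.SimConfig`; `preprocess` carries drop count,
    band edges and FWHM; `dc` the threshold and edge kind; `classify`
    alpha, C and mode; `stats` the analysis group and FDR level.
    """

    seed: int = 0
    mode: str = "roi"  # roi | voxel
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(
        default_factory=lambda: {"n_drop": 10, "low_hz": 0.01, "high_hz": 0.08, "fwhm_mm": 0.0}
    )
    dc: dict = field(default_factory=lambda: {"threshold_r": 0.2, "edge_kind": "weighted_z"})
    classify: dict = field(
        default_factory=lambda: {"alpha": 0.05, "C": 1.0, "mode": "nested", "strategy": "contribution"}
    )
    stats: dict = field(default_factory=lambda: {"group": "expertise", "alpha": 0.05})

    _SECTION_KEYS = {
        "preprocess": {"n_drop", "low_hz", "high_hz", "fwhm_mm"},
        "dc": {"threshold_r", "edge_kind"},
        "classify": {"alpha", "C", "mode", "strategy"},
        "stats": {"group", "alpha"},
    }

    def __post_init__(self):
        if self.mode not in ("roi", "voxel"):
            raise ValueError("mode must be 'roi' or 'voxel'")
        for section, allowed in self._SECTION_KEYS.items():
            given = set(getattr(self, section))
            unknown = given - allowed
            if unknown:
                raise ValueError(f"unknown keys in {section!r}: {sorted(unknown)}")
        sim_fields = {f.name for f in fields(SimConfig)}
        unknown = set(self.simulate) - sim_fields
        if unknown:
            raise ValueError(f"unknown keys in 'simulate': {sorted(unknown)}")

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.simulate)
        if isinstance(kwargs.get("behavior_targets"), dict):
            kwargs["behavior_targets"] = BehaviorTargets(**kwargs["behavior_targets"])
        kwargs.setdefault("seed", self.seed)
        return SimConfig(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: RunConfig) -> str:
    """Stable hash of the configuration (canonical JSON, sha256, short)."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read a YAML config file; unknown top-level or section keys are
    rejected with a descriptive error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return RunConfig(**raw)
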
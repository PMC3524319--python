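"""Structured run configuration loaded from YAML.

One file carries the thresholds of the priming definition, the
screening-comparison settings, protocol timings/doses for the generic
motif model, and (optionally) Jak/STAT parameter overrides.  Unknown
keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .features import PrimingThresholds


@dataclass
class ScreenConfig:
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    relaxed_readout_fc: float = 1.5


@dataclass
class TrinodeProtocolConfig:
    ld_dose: float = 0.03
    hd_dose: float = 1.0
    ld_duration: float = 50.0
    hd_duration: float = 50.0
    wash_duration: float = 0.0


@dataclass
class RunConfig:
    thresholds: PrimingThresholds = field(default_factory=PrimingThresholds)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    trinode_protocol: TrinodeProtocolConfig = field(
        default_factory=TrinodeProtocolConfig
    )
    jakstat_params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "thresholds": PrimingThresholds,
    "screen": ScreenConfig,
    "trinode_protocol": TrinodeProtocolConfig,
}


def _build(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {context!r}; "
            f"allowed: {sorted(allowed)}"
        )
    return cls(**data)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults if None)."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    top_allowed = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ValueError(
            f"{path}: unknown top-level key(s) {sorted(unknown)}; "
            f"allowed: {sorted(top_allowed)}"
        )
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"{path}: section {key!r} must be a mapping")
            kwargs[key] = _build(_SECTIONS[key], value, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)
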
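"""Structured configuration mirroring every tunable constant.

A config file is YAML with the same field names; unknown keys are
rejected so typos fail loudly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .preprocess import BandpassSpec, ICACleanSpec, SGKernel
from .simulate import SubjectProfile


@dataclass(frozen=True)
class DecoderConfig:
    """All pipeline constants in one place."""

    profile: SubjectProfile = field(default_factory=SubjectProfile)
    bandpass: BandpassSpec = field(default_factory=BandpassSpec)
    sg: SGKernel = field(default_factory=SGKernel)
    ica: ICACleanSpec = field(default_factory=ICACleanSpec)
    eog_removal: bool = False
    k_folds: int = 10
    resamples: int | None = None      # None -> k_folds
    with_replacement: bool = False
    threshold: float = 0.5
    carry_ms: int = 100

    def config_hash(self) -> str:
        return hashlib.sha1(json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()).hexdigest()[:12]


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> DecoderConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    nested = {"profile": SubjectProfile, "bandpass": BandpassSpec,
              "sg": SGKernel, "ica": ICACleanSpec}
    kwargs = {}
    for key, value in raw.items():
        if key in nested:
            kwargs[key] = _build(nested[key], value or {})
        else:
            kwargs[key] = value
    return _build(DecoderConfig, kwargs)


def save_config(config: DecoderConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
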
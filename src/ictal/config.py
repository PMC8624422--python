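"""Run configuration: one YAML document covering every stage.

Unknown keys are rejected so typos fail loudly; every output artifact embeds
the configuration hash so runs are traceable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classify import CVConfig
from .fusion import FusionModelSpec
from .io import FilterSpec, WindowSpec
from .pipeline import FeatureConfig, config_hash
from .synth import SyntheticSpec
from .tqwt import TQWTParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    sampling_rate: float = 173.6
    window: WindowSpec = field(default_factory=lambda: WindowSpec(5.0))
    filter: FilterSpec = field(default_factory=FilterSpec)
    tqwt: TQWTParams = field(default_factory=TQWTParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    fusion: FusionModelSpec = field(default_factory=FusionModelSpec)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    cnn_sub_len: int = 50
    cnn_step: int = 25

    @property
    def hash(self) -> str:
        return config_hash(self.sampling_rate, self.window, self.filter,
                           self.tqwt, self.features, self.cv, self.fusion,
                           self.synthetic, self.cnn_sub_len, self.cnn_step)


_SECTIONS = {
    "window": WindowSpec,
    "filter": FilterSpec,
    "tqwt": TQWTParams,
    "features": FeatureConfig,
    "cv": CVConfig,
    "fusion": FusionModelSpec,
    "synthetic": SyntheticSpec,
}
_SCALARS = {"sampling_rate", "cnn_sub_len", "cnn_step"}


def _build(cls, data: dict):
    fields = cls.__dataclass_fields__
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML, applying flat overrides afterwards."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    unknown = set(data) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for key, cls in _SECTIONS.items():
        if key in data:
            kwargs[key] = _build(cls, data[key] or {})
    for key in _SCALARS:
        if key in data:
            kwargs[key] = data[key]
    cfg = RunConfig(**kwargs)
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        section, _, attr = key.partition(".")
        if not attr:
            setattr(cfg, section, value)
        else:
            current = getattr(cfg, section)
            setattr(cfg, section, _build(type(current),
                                         {**_fields_dict(current), attr: value}))
    return cfg


def _fields_dict(obj) -> dict:
    return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
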
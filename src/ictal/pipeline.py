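"""Assemble per-window feature vectors across TQWT sub-bands.

Each analysis window is decomposed into J+1 sub-bands; every enabled feature
is applied to every sub-band and (by default) to the raw window as well,
giving column names ``{feature}__band{j}`` (band 1 = highest frequency) and
``{feature}__raw``.  Column order is a pure function of the feature
configuration and the TQWT parameters.  A feature that fails on a degenerate
sub-band (for example a near-zero-energy high band) contributes 0 for that
cell and is counted, never aborting the row.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import FilterSpec, SignalRecord, WindowSpec, bandpass, segment_windows
from .tqwt import TQWTParams, decompose
from .features import entropy as ent
from .features import fractal as frac
from .features import linear as lin

log = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "FeatureTable",
    "registered_feature_names",
    "extract_features",
    "build_feature_table",
]


def _stat(name: str):
    def f(x: np.ndarray, fs: float) -> float:
        return lin.stat_features(x).as_dict()[name]
    return f


def _psd_feature(fn):
    def f(x: np.ndarray, fs: float) -> float:
        return fn(lin.normalized_psd(x, fs))
    return f


def _wavelet_avg(kind: str):
    def f(x: np.ndarray, fs: float) -> float:
        half = x.size // 2
        se_a = ent.SubbandEnergies.from_signal(x[:half])
        se_b = ent.SubbandEnergies.from_signal(x[half:])
        return ent.wavelet_entropy_avg(se_a, se_b, kind=kind, alpha=2.0)
    return f


# Registered feature order is fixed; the default configuration enables all
# 27 scalar features (so the default Bonn vector has 27 * (J+1) + 27 = 270
# entries at Q=1, r=3, J=8).
_REGISTRY: dict[str, Callable[[np.ndarray, float], float]] = {
    "mean": _stat("mean"),
    "var": _stat("var"),
    "kurt": _stat("kurt"),
    "skew": _stat("skew"),
    "std": _stat("std"),
    "max": _stat("max"),
    "iwmf": _psd_feature(lin.iwmf),
    "iwbw": _psd_feature(lin.iwbw),
    "higuchi": lambda x, fs: frac.higuchi_fd(x),
    "katz": lambda x, fs: frac.katz_fd(x),
    "petrosian": lambda x, fs: frac.petrosian_fd(x),
    "dfa": lambda x, fs: frac.dfa(x),
    "shannon": lambda x, fs: ent.shannon_entropy(x),
    "logen": lambda x, fs: ent.log_energy_entropy(x),
    "spectral": lambda x, fs: ent.spectral_entropy(x, fs),
    "sampen": lambda x, fs: ent.sample_entropy(x),
    "pe": lambda x, fs: ent.permutation_entropy(x)[0],
    "pe_renyi": lambda x, fs: ent.permutation_renyi_entropy(x),
    "wshannon_avg": _wavelet_avg("shannon"),
    "wrenyi_avg": _wavelet_avg("renyi"),
    "wtsallis_avg": _wavelet_avg("tsallis"),
    "graphen": lambda x, fs: ent.graph_entropy(x),
    "fuzzen": lambda x, fs: ent.fuzzy_entropy(x),
    "rcmfe_mu_s2": lambda x, fs: float(ent.rcmfe(x, scales=(2,))[0]),
    "ifuzzen_s2": lambda x, fs: float(ent.inherent_fuzzy_entropy(x, scales=(2,))[0]),
    "afuzzen": lambda x, fs: ent.averaged_fuzzy_entropy(x),
    "ffuzzen": lambda x, fs: ent.fractional_fuzzy_entropy(x),
}

#: Cheap subset used for large runs: statistics, spectral moments and the
#: light-weight fractal/entropy estimators (no O(N^2) fuzzy family, no EMD).
FAST_FEATURES: tuple[str, ...] = (
    "mean", "var", "kurt", "skew", "std", "max", "iwmf", "iwbw",
    "higuchi", "katz", "petrosian", "shannon", "logen", "spectral", "pe",
)


def registered_feature_names() -> tuple[str, ...]:
    return tuple(_REGISTRY)


@dataclass(frozen=True)
class FeatureConfig:
    """Which features to compute, and where (sub-bands and/or raw window)."""

    features: tuple[str, ...] = tuple(_REGISTRY)
    on_bands: bool = True
    on_raw: bool = True

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("feature configuration is empty")
        unknown = [f for f in self.features if f not in _REGISTRY]
        if unknown:
            raise ValueError(f"unknown features: {unknown}")
        if not (self.on_bands or self.on_raw):
            raise ValueError("enable sub-band features, raw features, or both")

    @classmethod
    def fast(cls, **kw) -> "FeatureConfig":
        return cls(features=FAST_FEATURES, **kw)

    def column_names(self, tqwt_params: TQWTParams) -> list[str]:
        names: list[str] = []
        for feat in self.features:
            if self.on_bands:
                names.extend(f"{feat}__band{j}"
                             for j in range(1, tqwt_params.J + 2))
            if self.on_raw:
                names.append(f"{feat}__raw")
        return names


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list[str]
    window_id: str
    label: str | int | None
    n_imputed: int = 0  # non-finite / failed cells replaced by 0


@dataclass
class FeatureTable:
    """Rectangular window-by-feature table with labels and provenance."""

    frame: pd.DataFrame  # feature columns + window_id + label
    config_hash: str
    n_imputed: int = 0

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("window_id", "label")]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(frame=pd.read_csv(path), config_hash="")


def config_hash(*objs) -> str:
    """Stable short hash of configuration dataclasses/dicts."""
    def enc(o):
        if hasattr(o, "__dataclass_fields__"):
            return {k: enc(getattr(o, k)) for k in o.__dataclass_fields__}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        if isinstance(o, dict):
            return {k: enc(v) for k, v in o.items()}
        if isinstance(o, np.ndarray):
            return o.tolist()
        return o
    payload = json.dumps([enc(o) for o in objs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def extract_features(window: SignalRecord,
                     tqwt_params: TQWTParams = TQWTParams(),
                     feature_config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Feature vector of one analysis window (sub-bands and/or raw)."""
    fs = window.sampling_rate
    signals: list[tuple[str, np.ndarray]] = []
    if feature_config.on_bands:
        bands = decompose(window, tqwt_params).bands
        signals.extend((f"band{j + 1}", b) for j, b in enumerate(bands))
    if feature_config.on_raw:
        signals.append(("raw", window.samples))

    values: list[float] = []
    names: list[str] = []
    n_imputed = 0
    for feat in feature_config.features:
        for tag, sig in signals:
            try:
                v = float(_REGISTRY[feat](sig, fs))
            except Exception:
                v = float("nan")
            if not np.isfinite(v):
                v = 0.0
                n_imputed += 1
            values.append(v)
            names.append(f"{feat}__{tag}")
    if n_imputed:
        log.debug("window %s: %d feature cells imputed to 0",
                  window.source_id, n_imputed)
    return FeatureVector(np.array(values), names, window.source_id,
                         window.label, n_imputed)


def build_feature_table(records: Sequence[SignalRecord],
                        window_spec: WindowSpec = WindowSpec(5.0),
                        filter_spec: FilterSpec | None = FilterSpec(),
                        tqwt_params: TQWTParams = TQWTParams(),
                        feature_config: FeatureConfig = FeatureConfig()) -> FeatureTable:
    """Filter -> window -> extract for every record; deterministic row order."""
    if not records:
        raise ValueError("no input records")
    rates = {r.sampling_rate for r in records}
    if len(rates) > 1:
        raise ValueError(f"inconsistent sampling rates: {sorted(rates)}")
    rows, meta = [], []
    names: list[str] | None = None
    n_imputed = 0
    for rec in records:
        filtered = bandpass(rec, filter_spec) if filter_spec else rec
        for window in segment_windows(filtered, window_spec):
            fv = extract_features(window, tqwt_params, feature_config)
            rows.append(fv.values)
            meta.append((fv.window_id, fv.label))
            n_imputed += fv.n_imputed
            names = names or fv.names
    if not rows:
        raise ValueError("no windows produced (all records too short?)")
    frame = pd.DataFrame(np.vstack(rows), columns=names)
    frame["window_id"] = [m[0] for m in meta]
    frame["label"] = [m[1] for m in meta]
    if n_imputed:
        log.info("feature table: %d cells imputed to 0", n_imputed)
    return FeatureTable(frame=frame,
                        config_hash=config_hash(window_spec, filter_spec or {},
                                                tqwt_params, feature_config),
                        n_imputed=n_imputed)
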
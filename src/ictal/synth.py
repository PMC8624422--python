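"""Synthetic EEG-like datasets with Bonn/Freiburg geometry.

The generator is a statistical fixture, not a simulator of epilepsy: every
segment is a stationary AR(2) background (resonant, so band-pass filtering
and sub-band decomposition are non-trivial), and ictal-like classes add
Poisson-timed spike-wave bursts — rectified sinusoids at ~3 Hz, the classic
spike-wave discharge rate — whose amplitude relative to the background
standard deviation is the single separability dial.  At separability 0 the
classes are distributionally identical (the chance-level control); the
default burst rate and duration keep discharges present through nearly all
of an ictal-like segment, mirroring the fact that ictal reference segments
are recorded during ongoing seizure activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import SignalRecord

__all__ = [
    "ClassRecipe",
    "SyntheticSpec",
    "generate_dataset",
    "generate_freiburg_like",
    "default_two_class_spec",
    "write_ascii_dataset",
]


@dataclass(frozen=True)
class ClassRecipe:
    """Recipe for one class: AR(2) background plus optional burst process."""

    label: str
    ar: tuple[float, float] = (1.0, -0.81)  # resonance near 10 Hz at 173.6 Hz
    noise_sd: float = 1.0
    burst_rate: float = 0.0        # events per minute
    burst_freq: float = 3.0        # Hz, spike-wave repetition rate
    burst_amplitude: float = 0.0   # multiples of background sd (scaled by separability)
    burst_duration: float = 6.0    # seconds

    def __post_init__(self) -> None:
        a1, a2 = self.ar
        # stationarity triangle of the AR(2) process
        if not (abs(a2) < 1 and a2 + a1 < 1 and a2 - a1 < 1):
            raise ValueError(f"AR coefficients {self.ar} are not stationary")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Dataset geometry and class recipes; `seed` fixes every draw."""

    sampling_rate: float = 173.6
    segment_samples: int = 4097
    n_per_class: int = 50
    separability: float = 2.0
    seed: int = 0
    classes: tuple[ClassRecipe, ...] = ()

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")
        if not self.classes:
            object.__setattr__(self, "classes", _default_recipes(2, self.sampling_rate))
        for rec in self.classes:
            if rec.burst_freq >= self.sampling_rate / 2:
                raise ValueError("burst frequency above Nyquist")


def _ar_for_resonance(freq_hz: float, fs: float, rho: float = 0.9) -> tuple[float, float]:
    """AR(2) coefficients with a spectral peak near freq_hz."""
    w = 2 * np.pi * freq_hz / fs
    return (2 * rho * np.cos(w), -rho * rho)


def _default_recipes(n_classes: int, fs: float) -> tuple[ClassRecipe, ...]:
    interictal = ClassRecipe(label="interictal", ar=_ar_for_resonance(10.0, fs))
    ictal = ClassRecipe(label="ictal", ar=_ar_for_resonance(10.0, fs),
                        burst_rate=30.0, burst_amplitude=1.0,
                        burst_duration=8.0)
    if n_classes == 2:
        return (interictal, ictal)
    healthy = ClassRecipe(label="healthy", ar=_ar_for_resonance(6.0, fs))
    if n_classes == 3:
        return (healthy, interictal, ictal)
    raise ValueError("default recipes exist for 2 or 3 classes")


def default_two_class_spec(n_per_class: int = 50, separability: float = 2.0,
                           seed: int = 0) -> SyntheticSpec:
    return SyntheticSpec(n_per_class=n_per_class, separability=separability,
                         seed=seed)


def _ar2_segment(rng: np.random.Generator, recipe: ClassRecipe,
                 n: int) -> np.ndarray:
    a1, a2 = recipe.ar
    burn = 200
    e = rng.normal(0.0, recipe.noise_sd, size=n + burn)
    x = np.empty(n + burn)
    x[0], x[1] = e[0], e[1]
    for t in range(2, n + burn):
        x[t] = a1 * x[t - 1] + a2 * x[t - 2] + e[t]
    return x[burn:]


def ar2_theoretical_psd(recipe: ClassRecipe, freqs: np.ndarray,
                        fs: float) -> np.ndarray:
    """Theoretical AR(2) power spectral density (one-sided shape)."""
    a1, a2 = recipe.ar
    w = 2 * np.pi * freqs / fs
    denom = np.abs(1 - a1 * np.exp(-1j * w) - a2 * np.exp(-2j * w)) ** 2
    return recipe.noise_sd**2 / denom


def _spike_wave(rng: np.random.Generator, n: int, fs: float,
                recipe: ClassRecipe, amplitude: float) -> np.ndarray:
    """Poisson-timed rectified-sinusoid bursts, amplitude in signal units."""
    out = np.zeros(n)
    if recipe.burst_rate <= 0 or amplitude == 0:
        return out
    rate_per_sample = recipe.burst_rate / 60.0 / fs
    dur = int(round(recipe.burst_duration * fs))
    # onsets extend `dur` before t=0 so coverage is stationary at the start
    n_events = rng.poisson(rate_per_sample * (n + dur))
    onsets = rng.integers(-dur, n, size=n_events)
    t = np.arange(n) / fs
    for onset in onsets:
        start, stop = max(onset, 0), min(onset + dur, n)
        seg = t[start:stop]
        out[start:stop] += amplitude * np.abs(
            np.sin(2 * np.pi * recipe.burst_freq * seg))
    return out


def _background_sd(recipe: ClassRecipe) -> float:
    """Stationary standard deviation of the AR(2) background."""
    a1, a2 = recipe.ar
    var = recipe.noise_sd**2 * (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1**2))
    return float(np.sqrt(var))


def generate_dataset(spec: SyntheticSpec = SyntheticSpec()) -> list[SignalRecord]:
    """Generate n_per_class segments per class recipe; deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    records: list[SignalRecord] = []
    for recipe in spec.classes:
        sd = _background_sd(recipe)
        amp = spec.separability * recipe.burst_amplitude * sd
        for i in range(spec.n_per_class):
            x = _ar2_segment(rng, recipe, spec.segment_samples)
            x = x + _spike_wave(rng, spec.segment_samples, spec.sampling_rate,
                                recipe, amp)
            records.append(SignalRecord(
                x, spec.sampling_rate, label=recipe.label,
                source_id=f"{recipe.label}_{i:03d}"))
    return records


def generate_freiburg_like(spec: SyntheticSpec | None = None) -> list[SignalRecord]:
    """Same recipes at Freiburg geometry: 256 Hz, 4 s windows (1024 samples)."""
    if spec is None:
        spec = SyntheticSpec(sampling_rate=256.0, segment_samples=4096)
    if spec.sampling_rate != 256.0:
        spec = replace(spec, sampling_rate=256.0,
                       classes=_default_recipes(len(spec.classes) or 2, 256.0))
    return generate_dataset(spec)


def write_ascii_dataset(records: list[SignalRecord], out_dir: str | Path) -> Path:
    """Write one single-column ASCII file per record plus labels.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        name = f"{rec.source_id}.txt"
        np.savetxt(out_dir / name, rec.samples, fmt="%.10g")
        rows.append(f"{name},{rec.label}")
    manifest = out_dir / "labels.csv"
    manifest.write_text("filename,label\n" + "\n".join(rows) + "\n",
                        encoding="utf-8")
    return manifest
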
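"""Reading, band-pass filtering and windowing of single-channel EEG segments.

The canonical input is a Bonn-style segment: one ASCII file holding a single
column of numbers, 4097 samples recorded at 173.6 Hz.  Any sampled 1-D signal
with a declared sampling rate is accepted.  Segments are band-pass filtered
(0.5-40 Hz by default) and cut into fixed-length analysis windows (5 s for
Bonn geometry, 4 s for Freiburg geometry); each analysis window is further
split into short overlapping sub-windows that feed the convolutional branch
of the fusion classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as _sig

__all__ = [
    "SignalRecord",
    "WindowSpec",
    "FilterSpec",
    "read_ascii_segment",
    "read_multicolumn_segment",
    "bandpass",
    "segment_windows",
    "subwindow_for_cnn",
]


@dataclass(frozen=True)
class SignalRecord:
    """A sampled 1-D signal with sampling rate and optional class label."""

    samples: np.ndarray
    sampling_rate: float
    label: str | int | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return len(self) / self.sampling_rate


@dataclass(frozen=True)
class WindowSpec:
    """Analysis-window geometry.

    ``window_samples`` is derived as round(window_seconds * sampling_rate) so
    that 5 s at 173.6 Hz gives 868 samples and 4 s at 256 Hz gives 1024.
    ``step_samples`` defaults to the window length (non-overlapping).
    """

    window_seconds: float
    step_samples: int | None = None

    def __post_init__(self) -> None:
        if not self.window_seconds > 0:
            raise ValueError("window_seconds must be > 0")

    def window_samples(self, sampling_rate: float) -> int:
        n = int(round(self.window_seconds * sampling_rate))
        if n < 2:
            raise ValueError("window shorter than 2 samples at this rate")
        return n

    def step(self, sampling_rate: float) -> int:
        w = self.window_samples(sampling_rate)
        s = self.step_samples if self.step_samples is not None else w
        if not 1 <= s <= w:
            raise ValueError("step_samples must be in [1, window_samples]")
        return s


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass configuration (zero-phase application)."""

    low_hz: float = 0.5
    high_hz: float = 40.0
    order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def validate_for(self, sampling_rate: float) -> None:
        if self.high_hz >= sampling_rate / 2:
            raise ValueError(
                f"high_hz={self.high_hz} must be below the Nyquist frequency "
                f"{sampling_rate / 2} Hz"
            )


def read_ascii_segment(
    path: str | Path,
    sampling_rate: float,
    label: str | int | None = None,
) -> SignalRecord:
    """Read a single-column numeric text file (Bonn dialect).

    Blank lines are skipped; a non-numeric line raises ``ValueError`` naming
    the offending line number.
    """
    path = Path(path)
    values: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno} is not numeric: {text!r}"
                ) from None
    if not values:
        raise ValueError(f"{path}: file contains no samples")
    return SignalRecord(np.array(values), sampling_rate, label=label,
                        source_id=path.name)


def read_multicolumn_segment(
    path: str | Path,
    sampling_rate: float,
    channel: int = 0,
    label: str | int | None = None,
) -> SignalRecord:
    """Read one channel from whitespace/comma-separated multi-column text."""
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter=None, ndmin=2)
    except ValueError:
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    if data.size == 0:
        raise ValueError(f"{path}: file contains no samples")
    if not 0 <= channel < data.shape[1]:
        raise ValueError(f"{path}: channel {channel} out of range "
                         f"(file has {data.shape[1]} columns)")
    return SignalRecord(data[:, channel], sampling_rate, label=label,
                        source_id=f"{path.name}#ch{channel}")


def bandpass(record: SignalRecord, spec: FilterSpec = FilterSpec()) -> SignalRecord:
    """Zero-phase Butterworth band-pass; length and sampling rate preserved."""
    spec.validate_for(record.sampling_rate)
    sos = _sig.butter(spec.order, [spec.low_hz, spec.high_hz],
                      btype="bandpass", fs=record.sampling_rate, output="sos")
    # pad by ~3 periods of the low cut-off so edge transients of the
    # zero-phase pass settle (the 0.5 Hz corner has a long time constant)
    padlen = min(len(record) - 1,
                 int(3 * record.sampling_rate / spec.low_hz))
    filtered = _sig.sosfiltfilt(sos, record.samples, padlen=padlen)
    return replace(record, samples=filtered)


def _slide(x: np.ndarray, length: int, step: int) -> np.ndarray:
    """Strided view (n_windows, length); trailing partial window dropped."""
    if x.size < length:
        raise ValueError(f"signal of length {x.size} shorter than one "
                         f"window of {length} samples")
    n = (x.size - length) // step + 1
    idx = step * np.arange(n)[:, None] + np.arange(length)[None, :]
    return x[idx]


def segment_windows(record: SignalRecord, spec: WindowSpec) -> list[SignalRecord]:
    """Cut a segment into fixed-length analysis windows; labels inherited."""
    length = spec.window_samples(record.sampling_rate)
    step = spec.step(record.sampling_rate)
    chunks = _slide(record.samples, length, step)
    return [
        SignalRecord(chunk.copy(), record.sampling_rate, label=record.label,
                     source_id=f"{record.source_id}[w{i}]")
        for i, chunk in enumerate(chunks)
    ]


def subwindow_for_cnn(
    window: SignalRecord | np.ndarray, sub_len: int = 50, step: int = 25
) -> np.ndarray:
    """Split one analysis window into overlapping sub-windows.

    Returns an array of shape (n_sub, sub_len); an 868-sample window with the
    default 50/25 geometry yields 33 sub-windows.  Trailing samples that do
    not fill a sub-window are dropped.
    """
    x = window.samples if isinstance(window, SignalRecord) else np.asarray(window, float)
    return _slide(x, sub_len, step).copy()
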
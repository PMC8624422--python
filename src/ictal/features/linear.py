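"""Statistical moments and PSD-weighted frequency features.

The statistical battery follows the epilepsy-detection convention of using
the N-1 denominator throughout, including for the shape moments: kurtosis is
the *non-excess* sum((x-mean)^4) / ((N-1) * sd^4) and skewness the analogous
third moment.  This differs from the common N-normalised excess kurtosis
returned by scipy.stats.kurtosis.

The frequency features are the intensity-weighted mean frequency (IWMF, the
first moment of the normalised power spectral density) and the
intensity-weighted bandwidth (IWBW, the weighted standard deviation of
frequency around the IWMF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

__all__ = [
    "StatFeatures",
    "PSDEstimate",
    "stat_features",
    "normalized_psd",
    "iwmf",
    "iwbw",
]


@dataclass(frozen=True)
class StatFeatures:
    mean: float
    variance: float
    kurtosis: float
    skewness: float
    std: float
    max: float
    degenerate: bool = False  # constant input: shape moments reported as 0

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean, "var": self.variance, "kurt": self.kurtosis,
            "skew": self.skewness, "std": self.std, "max": self.max,
        }


@dataclass(frozen=True)
class PSDEstimate:
    """Normalised power spectral density: power sums to one."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, float)
        p = np.asarray(self.power, float)
        if f.shape != p.shape:
            raise ValueError("freqs and power must have the same length")
        if np.any(np.diff(f) <= 0) or np.any(f < 0):
            raise ValueError("freqs must be non-negative and increasing")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("power must be non-negative and sum to 1")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)


def stat_features(x: np.ndarray) -> StatFeatures:
    """Mean, variance, kurtosis, skewness, standard deviation and maximum."""
    x = np.asarray(x, float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    am = float(np.mean(x))
    dev = x - am
    var = float(np.sum(dev**2) / (n - 1))
    sd = float(np.sqrt(var))
    if sd == 0.0:
        return StatFeatures(am, 0.0, 0.0, 0.0, 0.0, float(np.max(x)),
                            degenerate=True)
    kurt = float(np.sum(dev**4) / ((n - 1) * sd**4))
    skew = float(np.sum(dev**3) / ((n - 1) * sd**3))
    return StatFeatures(am, var, kurt, skew, sd, float(np.max(x)))


def normalized_psd(x: np.ndarray, sampling_rate: float) -> PSDEstimate:
    """Single-taper periodogram of the zero-mean signal, scaled to sum 1."""
    x = np.asarray(x, float)
    if x.size < 8:
        raise ValueError("need at least 8 samples for a spectrum")
    freqs, power = _sig.periodogram(x - np.mean(x), fs=sampling_rate,
                                    window="boxcar", detrend=False)
    total = power.sum()
    if total <= 0:
        raise ValueError("signal has no spectral power (constant input)")
    return PSDEstimate(freqs, power / total)


def iwmf(psd: PSDEstimate) -> float:
    """Intensity-weighted mean frequency: sum_k x[k] * f_k (Hz)."""
    return float(np.dot(psd.power, psd.freqs))


def iwbw(psd: PSDEstimate) -> float:
    """Intensity-weighted bandwidth: weighted std of frequency (Hz)."""
    mu = iwmf(psd)
    return float(np.sqrt(np.dot(psd.power, (psd.freqs - mu) ** 2)))


def iwbw_raw_second_moment(psd: PSDEstimate) -> float:
    """The un-rooted weighted second moment (Hz^2), kept as an optional
    feature alongside the standard-deviation form."""
    mu = iwmf(psd)
    return float(np.dot(psd.power, (psd.freqs - mu) ** 2))
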
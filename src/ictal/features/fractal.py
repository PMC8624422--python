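"""Fractal-dimension estimators: Higuchi, Katz, Petrosian and DFA.

All four quantify waveform irregularity on a dimensionless scale where a
smooth curve sits near 1 and a noise-like curve approaches 2 (for DFA the
output is the scaling exponent alpha instead: ~0.5 for white noise, ~1.5 for
integrated white noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HiguchiParams",
    "DFAParams",
    "higuchi_fd",
    "katz_fd",
    "petrosian_fd",
    "dfa",
    "dyadic_scales",
]


@dataclass(frozen=True)
class HiguchiParams:
    k_max: int = 10

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")


@dataclass(frozen=True)
class DFAParams:
    scales: tuple[int, ...]
    detrend_order: int = 1

    def __post_init__(self) -> None:
        s = tuple(int(v) for v in self.scales)
        if len(s) < 2 or any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("scales must be an increasing sequence")
        if s[0] < 4:
            raise ValueError("minimum scale is 4")
        if self.detrend_order < 1:
            raise ValueError("detrend_order must be >= 1")
        object.__setattr__(self, "scales", s)


def dyadic_scales(n: int, lo: int = 8) -> tuple[int, ...]:
    """Powers of two from lo up to n//4 (default DFA scale set)."""
    scales = []
    s = lo
    while s <= n // 4:
        scales.append(s)
        s *= 2
    if len(scales) < 2:
        raise ValueError(f"signal of length {n} too short for DFA scales")
    return tuple(scales)


def higuchi_fd(x: np.ndarray, params: HiguchiParams = HiguchiParams()) -> float:
    """Higuchi fractal dimension.

    For each delay k in 1..k_max and each offset m in 1..k, the curve length
    of the decimated series x[m-1::k] is

        L_m(k) = (N-1) / (floor((N-m)/k) * k) * sum |x[m+ik] - x[m+(i-1)k]|

    averaged over m to L(k); the FD is the slope of the least-squares fit of
    ln L(k) against ln(1/k).
    """
    x = np.asarray(x, float)
    n = x.size
    if n < 4 * params.k_max:
        raise ValueError("need N >= 4*k_max samples")
    ks = np.arange(1, params.k_max + 1)
    lk = np.empty(ks.size)
    for i, k in enumerate(ks):
        lengths = []
        for m in range(1, k + 1):
            idx = np.arange(m - 1, n, k)
            nseg = idx.size - 1
            if nseg < 1:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (nseg * k)
            lengths.append(dist * norm / k)
        lk[i] = np.mean(lengths)
    if np.all(lk == 0):  # constant signal: no curve length at any scale
        return 1.0
    slope = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)[0]
    return float(slope)


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension, D = log10(n) / (log10(d/L) + log10(n)).

    Computed on the planar waveform curve (i, x_i): the curve length L is
    the summed Euclidean distance between successive points, the diameter d
    the largest distance from the first point, and n = N - 1 the number of
    steps.  D = 1 exactly for any uniformly sampled monotone line (then
    d = L); like the original construction, D is not invariant under
    amplitude scaling because the abscissa carries its own unit.
    """
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    dx = np.diff(x)
    length = float(np.sum(np.sqrt(1.0 + dx * dx)))
    idx = np.arange(1, x.size, dtype=float)
    diameter = float(np.max(np.sqrt(idx**2 + (x[1:] - x[0]) ** 2)))
    if np.ptp(x) == 0:  # constant signal: straight horizontal line
        return 1.0
    n_steps = x.size - 1
    return float(np.log10(n_steps)
                 / (np.log10(diameter / length) + np.log10(n_steps)))


def petrosian_fd(x: np.ndarray) -> float:
    """Petrosian fractal dimension from the sign-change count of the first
    difference: D = log10(n) / (log10(n) + log10(n / (n + 0.4*N_delta)))."""
    x = np.asarray(x, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    diff = np.diff(x)
    signs = np.sign(diff)
    # zeros in the difference break toward "no sign change"
    nz = signs != 0
    s = signs[nz]
    n_delta = int(np.count_nonzero(s[1:] * s[:-1] < 0))
    return float(np.log10(n) / (np.log10(n)
                 + np.log10(n / (n + 0.4 * n_delta))))


def _dfa_fluctuation(y: np.ndarray, scale: int, order: int) -> float:
    """RMS residual of per-segment polynomial detrending of the profile y."""
    n_seg = y.size // scale
    segs = y[: n_seg * scale].reshape(n_seg, scale)
    t = np.arange(scale, dtype=float)
    # Vandermonde least squares shared across segments
    V = np.vander(t, order + 1)
    coef, *_ = np.linalg.lstsq(V, segs.T, rcond=None)
    resid = segs.T - V @ coef
    return float(np.sqrt(np.mean(resid**2)))


def dfa(x: np.ndarray, params: DFAParams | None = None) -> float:
    """Detrended fluctuation analysis scaling exponent.

    The mean-subtracted signal is integrated to a profile y; for each
    segment length n the profile is split into floor(N/n) non-overlapping
    segments, each detrended by a least-squares polynomial, and
    F(n) = sqrt(mean squared residual).  The exponent is the slope of
    log F(n) versus log n.
    """
    x = np.asarray(x, float)
    if params is None:
        params = DFAParams(scales=dyadic_scales(x.size))
    if x.size < 4 * params.scales[-1]:
        raise ValueError("need N >= 4*max(scale) samples")
    y = np.cumsum(x - np.mean(x))
    f = np.array([_dfa_fluctuation(y, s, params.detrend_order)
                  for s in params.scales])
    if np.any(f == 0):
        raise ValueError("zero fluctuation (constant signal): "
                         "DFA exponent undefined")
    slope = np.polyfit(np.log(np.asarray(params.scales, float)), np.log(f), 1)[0]
    return float(slope)
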
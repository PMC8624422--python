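"""Tunable-Q wavelet transform (TQWT) analysis/synthesis filter bank.

The TQWT is an iterated two-channel, oversampled filter bank parameterised by
a quality factor Q, a redundancy r and a level count J.  Each level splits the
current low-pass branch with a pair of frequency-domain filters whose
responses are

    T0(w) = 1                        for |w| <  (1-beta)*pi
            theta((w+(beta-1)pi)/(alpha+beta-1))    on the transition band
            0                        for |w| >= alpha*pi

    T1(w) = 0                        below (1-beta)*pi
            theta((alpha*pi-w)/(alpha+beta-1))      on the transition band
            1                        for |w| >= alpha*pi

with theta(w) = 0.5*(1+cos w)*sqrt(2-cos w), the Daubechies-like transition
function for which T0^2 + T1^2 = 1 (perfect reconstruction).  The scale
factors are beta = 2/(Q+1) and alpha = 1 - beta/r; alpha + beta > 1 makes the
bank oversampled.  The low-pass branch is rate-reduced by alpha (its support
ends at alpha*pi) and the high-pass branch by beta (its support starts at
(1-beta)*pi), which is what makes the iterated bank invertible.  Decomposing J levels yields J+1 sub-bands: band 1 is the
highest-frequency (level-1 high-pass) output and band J+1 the final low-pass
residue.

The implementation works on the unitary DFT with band lengths rounded to even
integers per level, so analysis followed by synthesis is exact to rounding
error and sub-band energies sum exactly to the signal energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SignalRecord

__all__ = [
    "TQWTParams",
    "SubbandSet",
    "lowpass_response",
    "highpass_response",
    "decompose",
    "reconstruct",
    "subband_center_frequencies",
    "max_feasible_levels",
]


@dataclass(frozen=True)
class TQWTParams:
    """Filter-bank configuration: quality factor, redundancy, level count."""

    Q: float = 1.0
    r: float = 3.0
    J: int = 8

    def __post_init__(self) -> None:
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        if self.r <= 1:
            raise ValueError("r must be > 1")
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if not (0 < self.alpha < 1 and 0 < self.beta <= 1):
            raise ValueError("scale factors out of range")
        if self.alpha + self.beta <= 1:
            raise ValueError("oversampling condition alpha + beta > 1 violated")

    @property
    def beta(self) -> float:
        """High-pass scale factor, 2/(Q+1)."""
        return 2.0 / (self.Q + 1.0)

    @property
    def alpha(self) -> float:
        """Low-pass scale factor, 1 - beta/r."""
        return 1.0 - self.beta / self.r


@dataclass
class SubbandSet:
    """The J+1 coefficient sequences produced by :func:`decompose`."""

    bands: list[np.ndarray]
    params: TQWTParams
    original_length: int
    padded_length: int

    def __post_init__(self) -> None:
        if len(self.bands) != self.params.J + 1:
            raise ValueError("expected J+1 bands")

    def energies(self) -> np.ndarray:
        """Per-band energy sum(w^2); sums exactly to the signal energy."""
        return np.array([float(np.sum(b * b)) for b in self.bands])


def _theta(v: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.cos(v)) * np.sqrt(2.0 - np.cos(v))


def lowpass_response(omega: float | np.ndarray, params: TQWTParams) -> np.ndarray:
    """Low-pass frequency response T0 on [0, pi]."""
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0) or np.any(w > np.pi):
        raise ValueError("omega must lie in [0, pi]")
    a, b = params.alpha, params.beta
    out = np.zeros_like(w)
    out[w < (1 - b) * np.pi] = 1.0
    trans = (w >= (1 - b) * np.pi) & (w < a * np.pi)
    out[trans] = _theta((w[trans] + (b - 1) * np.pi) / (a + b - 1))
    return out if out.ndim else float(out)


def highpass_response(omega: float | np.ndarray, params: TQWTParams) -> np.ndarray:
    """High-pass frequency response T1 on [0, pi]."""
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0) or np.any(w > np.pi):
        raise ValueError("omega must lie in [0, pi]")
    a, b = params.alpha, params.beta
    out = np.zeros_like(w)
    out[w >= a * np.pi] = 1.0
    trans = (w >= (1 - b) * np.pi) & (w < a * np.pi)
    out[trans] = _theta((a * np.pi - w[trans]) / (a + b - 1))
    return out if out.ndim else float(out)


def _level_lengths(params: TQWTParams, n: int) -> list[tuple[int, int]]:
    """(low-pass, high-pass) output lengths for levels 1..J on an even n."""
    a, b = params.alpha, params.beta
    out = []
    for j in range(1, params.J + 1):
        n0 = 2 * int(round(a**j * n / 2))
        n1 = 2 * int(round(b * a ** (j - 1) * n / 2))
        out.append((n0, n1))
    return out


def _level_ok(n_cur: int, n0: int, n1: int) -> bool:
    if n0 < 4 or n1 < 4:
        return False
    p = (n_cur - n1) // 2
    s = (n_cur - n0) // 2
    t = (n0 + n1 - n_cur) // 2 - 1
    return p >= 0 and s >= 0 and t >= 0


def max_feasible_levels(params: TQWTParams, n_samples: int) -> int:
    """Largest J for which every level keeps a valid, non-empty band."""
    n = n_samples + (n_samples % 2)
    probe = TQWTParams(params.Q, params.r, max(params.J, 64))
    n_cur, jmax = n, 0
    for j, (n0, n1) in enumerate(_level_lengths(probe, n), start=1):
        if not _level_ok(n_cur, n0, n1):
            break
        jmax, n_cur = j, n0
    return jmax


def _afb(X: np.ndarray, n0: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """One analysis split of a unitary DFT vector X (even length)."""
    n = X.size
    p = (n - n1) // 2
    t = (n0 + n1 - n) // 2 - 1
    v = np.arange(1, t + 1) * np.pi / (t + 1)
    trans = _theta(v)

    V0 = np.zeros(n0, dtype=complex)
    V0[0] = X[0]
    V0[1:p + 1] = X[1:p + 1]
    V0[p + 1:p + t + 1] = X[p + 1:p + t + 1] * trans
    # V0[n0//2] (Nyquist of the low-pass band) stays 0
    V0[n0 // 2 + 1:] = np.conj(V0[1:n0 // 2][::-1])

    V1 = np.zeros(n1, dtype=complex)
    V1[1:t + 1] = X[p + 1:p + t + 1] * trans[::-1]
    V1[t + 1:n1 // 2] = X[p + t + 1:n // 2]
    V1[n1 // 2] = X[n // 2]
    V1[n1 // 2 + 1:] = np.conj(V1[1:n1 // 2][::-1])
    return V0, V1


def _sfb(V0: np.ndarray, V1: np.ndarray, n: int) -> np.ndarray:
    """Synthesis dual of :func:`_afb`; rebuilds the parent DFT vector."""
    n0, n1 = V0.size, V1.size
    p = (n - n1) // 2
    t = (n0 + n1 - n) // 2 - 1
    v = np.arange(1, t + 1) * np.pi / (t + 1)
    trans = _theta(v)

    Y = np.zeros(n, dtype=complex)
    Y[0] = V0[0]
    Y[1:p + 1] = V0[1:p + 1]
    Y[p + 1:p + t + 1] = V0[p + 1:p + t + 1] * trans + V1[1:t + 1] * trans[::-1]
    Y[p + t + 1:n // 2] = V1[t + 1:n1 // 2]
    Y[n // 2] = V1[n1 // 2]
    Y[n // 2 + 1:] = np.conj(Y[1:n // 2][::-1])
    return Y


def _udft(x: np.ndarray) -> np.ndarray:
    return np.fft.fft(x) / np.sqrt(x.size)


def _iudft(X: np.ndarray) -> np.ndarray:
    return np.real(np.fft.ifft(X) * np.sqrt(X.size))


def decompose(record: SignalRecord | np.ndarray, params: TQWTParams = TQWTParams()) -> SubbandSet:
    """Decompose a signal into J+1 TQWT sub-bands.

    Band ordering: band 1 = highest frequency, band J+1 = low-pass residue.
    Odd-length inputs are zero-padded by one sample internally; the original
    length is recorded and restored by :func:`reconstruct`.
    """
    x = record.samples if isinstance(record, SignalRecord) else np.asarray(record, float)
    n_orig = x.size
    if n_orig % 2:
        x = np.concatenate([x, [0.0]])
    n = x.size

    jmax = max_feasible_levels(params, n)
    if params.J > jmax:
        raise ValueError(
            f"signal of length {n_orig} supports at most J={jmax} levels "
            f"for Q={params.Q}, r={params.r} (requested J={params.J})"
        )

    X = _udft(x)
    bands: list[np.ndarray] = []
    for n0, n1 in _level_lengths(params, n):
        X, V1 = _afb(X, n0, n1)
        bands.append(_iudft(V1))
    bands.append(_iudft(X))
    return SubbandSet(bands=bands, params=params, original_length=n_orig,
                      padded_length=n)


def reconstruct(subbands: SubbandSet) -> np.ndarray:
    """Invert :func:`decompose`; exact up to floating-point rounding."""
    params, n = subbands.params, subbands.padded_length
    lengths = _level_lengths(params, n)
    expected = [n1 for (_, n1) in lengths] + [lengths[-1][0]]
    got = [b.size for b in subbands.bands]
    if got != expected:
        raise ValueError(f"band lengths {got} inconsistent with params "
                         f"(expected {expected})")

    X = _udft(subbands.bands[-1])
    parents = [n] + [n0 for (n0, _) in lengths[:-1]]
    for j in range(params.J - 1, -1, -1):
        V1 = _udft(subbands.bands[j])
        X = _sfb(X, V1, parents[j])
    x = _iudft(X)
    return x[:subbands.original_length]


def subband_center_frequencies(params: TQWTParams, sampling_rate: float) -> np.ndarray:
    """Nominal center frequency (Hz) of each of the J+1 sub-bands.

    Band j (j = 1..J) occupies roughly [(1-beta)*a^(j-1), a^(j-1)] * fs/2
    with a = alpha, so its nominal center is the midpoint
    (2-beta)/4 * alpha^(j-1) * fs; the low-pass residue continues the
    geometric sequence one step further.  Strictly decreasing for all valid
    parameter choices.
    """
    a, b = params.alpha, params.beta
    j = np.arange(params.J + 1)
    return (2.0 - b) / 4.0 * a**j * sampling_rate
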
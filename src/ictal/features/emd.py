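"""Empirical mode decomposition by cubic-spline envelope sifting.

Used by the inherent fuzzy entropy feature: the signal is decomposed into
intrinsic mode functions (IMFs) and re-assembled without the final monotone
residue, which removes the slow trend before entropy estimation.

Sifting loop per IMF: upper and lower envelopes are cubic splines through
the local maxima/minima (signal endpoints are appended to both extrema sets
to anchor the splines), the envelope mean is subtracted, and sifting stops
when the normalised change between successive candidates falls below
``sd_stop`` or after ``max_sifts`` passes.  Decomposition stops when the
residue has fewer than two interior extrema of either kind (monotone-like)
or after ``max_imfs`` components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["EMDParams", "emd", "trend_removed"]


@dataclass(frozen=True)
class EMDParams:
    sd_stop: float = 0.2
    max_sifts: int = 10
    max_imfs: int = 12


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    minima = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    # anchor with the endpoints so the spline spans the whole signal
    t = np.concatenate([[0], idx, [x.size - 1]])
    t, keep = np.unique(t, return_index=True)
    v = np.concatenate([[x[0]], x[idx], [x[-1]]])[keep]
    return CubicSpline(t, v)(np.arange(x.size))


def emd(x: np.ndarray, params: EMDParams = EMDParams()) -> list[np.ndarray]:
    """Decompose x into [imf_1, ..., imf_K, residue]; the parts sum to x."""
    x = np.asarray(x, float)
    if x.size < 64:
        raise ValueError("need at least 64 samples for EMD")
    residue = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(params.max_imfs):
        maxima, minima = _local_extrema(residue)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residue.copy()
        for _ in range(params.max_sifts):
            mx, mn = _local_extrema(h)
            if mx.size < 2 or mn.size < 2:
                break
            m = 0.5 * (_envelope(h, mx) + _envelope(h, mn))
            h_new = h - m
            denom = float(np.sum(h * h))
            sd = float(np.sum((h - h_new) ** 2) / denom) if denom > 0 else 0.0
            h = h_new
            if sd < params.sd_stop:
                break
        imfs.append(h)
        residue = residue - h
    if not imfs:
        raise ValueError("no oscillatory component: input has too few extrema")
    return imfs + [residue]


def trend_removed(x: np.ndarray, params: EMDParams = EMDParams()) -> np.ndarray:
    """Sum of all IMFs excluding the final residue (the de-trended signal)."""
    parts = emd(x, params)
    return np.sum(parts[:-1], axis=0)
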
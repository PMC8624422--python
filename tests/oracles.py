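"""Brute-force reference implementations used as independent oracles.

Every function here follows the defining double/triple loops literally and
is deliberately independent of the vectorised implementations in the
package.  They are only practical for short inputs (N <= ~40).
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sample_entropy(x, m, r_frac):
    x = np.asarray(x, float)
    n = len(x)
    tol = r_frac * float(np.std(x))
    a = b = 0
    for i in range(n - m):
        for j in range(n - m):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= tol:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= tol:
                a += 1
    if a == 0 or b == 0:
        return float("inf")
    return -math.log(a / b)


def _fuzzy_phi(x, m_templates, mm, n, tol):
    """Phi at template length mm using m_templates start positions."""
    total = 0.0
    for i in range(m_templates):
        s = 0.0
        for j in range(m_templates):
            if j == i:
                continue
            ti = x[i:i + mm] - np.mean(x[i:i + mm])
            tj = x[j:j + mm] - np.mean(x[j:j + mm])
            d = np.max(np.abs(ti - tj))
            s += math.exp(-(d**n) / tol)
        total += s / (m_templates - 1)
    return total / m_templates


def fuzzy_entropy(x, m, n, r_frac):
    x = np.asarray(x, float)
    tol = r_frac * float(np.std(x))
    mt = len(x) - m
    return -math.log(_fuzzy_phi(x, mt, m + 1, n, tol)
                     / _fuzzy_phi(x, mt, m, n, tol))


def rcmfe_mu(x, m, n, r_frac, tau):
    """Refined composite multiscale fuzzy entropy, mean coarse-graining."""
    x = np.asarray(x, float)
    tol = r_frac * float(np.std(x))
    phis_m, phis_m1 = [], []
    for k in range(tau):
        nb = (len(x) - k) // tau
        z = np.array([np.mean(x[k + i * tau:k + (i + 1) * tau])
                      for i in range(nb)])
        mt = len(z) - m
        phis_m.append(_fuzzy_phi(z, mt, m, n, tol))
        phis_m1.append(_fuzzy_phi(z, mt, m + 1, n, tol))
    return -math.log(np.mean(phis_m1) / np.mean(phis_m))


def averaged_fuzzy_entropy(x, m, n, r_frac, shift=1):
    """Four-transform averaged fuzzy entropy (T, R, I, G).

    T translates the compared template index by `shift`, G additionally
    negates; R reflects the index about the midpoint, I reflects and
    negates.  Pairs whose transformed index leaves the range are skipped.
    """
    x = np.asarray(x, float)
    tol = r_frac * float(np.std(x))
    mt = len(x) - m

    def phi(mm, kind):
        total, count = 0.0, 0
        for j in range(mt):
            if kind in ("T", "G"):
                j2 = j + shift
            else:
                j2 = mt - 1 - j
            if not 0 <= j2 < mt:
                continue
            tj = x[j2:j2 + mm] - np.mean(x[j2:j2 + mm])
            if kind in ("G", "I"):
                tj = -tj
            for i in range(mt):
                if i == j:
                    continue
                ti = x[i:i + mm] - np.mean(x[i:i + mm])
                d = np.max(np.abs(ti - tj))
                total += math.exp(-(d**n) / tol)
                count += 1
        return total / count

    vals = [-math.log(phi(m + 1, k) / phi(m, k)) for k in ("T", "R", "I", "G")]
    return float(np.mean(vals))


def permutation_distribution(x, m, L):
    x = np.asarray(x, float)
    patterns = {}
    n_vec = len(x) - (m - 1) * L
    for t in range(n_vec):
        v = x[t:t + (m - 1) * L + 1:L]
        # stable argsort: ties broken by order of appearance
        order = tuple(sorted(range(m), key=lambda k: (v[k], k)))
        patterns[order] = patterns.get(order, 0) + 1
    return np.array(list(patterns.values())) / n_vec


def permutation_entropy_bits(x, m, L):
    p = permutation_distribution(x, m, L)
    return float(-np.sum(p * np.log2(p)))


def permutation_renyi(x, m, L, alpha):
    p = permutation_distribution(x, m, L)
    return float(math.log(np.sum(p**alpha)) / (1 - alpha))


def dfa_fluctuation(x, scale, order=1):
    """F(n) by per-segment polynomial fits, loop form."""
    x = np.asarray(x, float)
    y = np.cumsum(x - np.mean(x))
    n_seg = len(y) // scale
    residues = []
    t = np.arange(scale, dtype=float)
    for s in range(n_seg):
        seg = y[s * scale:(s + 1) * scale]
        coef = np.polyfit(t, seg, order)
        residues.extend((seg - np.polyval(coef, t)) ** 2)
    return float(np.sqrt(np.mean(residues)))


def katz_fd(x):
    """Planar-curve Katz dimension by literal point-to-point distances."""
    x = np.asarray(x, float)
    L = sum(math.hypot(1.0, x[i + 1] - x[i]) for i in range(len(x) - 1))
    d = max(math.hypot(i, x[i] - x[0]) for i in range(1, len(x)))
    n = len(x) - 1
    return math.log10(n) / (math.log10(d / L) + math.log10(n))


def hvg_edges_naive(x):
    """Horizontal visibility by the O(N^3) definition."""
    x = np.asarray(x, float)
    edges = set()
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if all(x[k] < min(x[i], x[j]) for k in range(i + 1, j)):
                edges.add((i, j))
    return edges


def window_count(n, w, s):
    """Number of full windows by exhaustive enumeration."""
    count = 0
    start = 0
    while start + w <= n:
        count += 1
        start += s
    return count
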
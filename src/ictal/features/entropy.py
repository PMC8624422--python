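"""The entropy feature battery: fifteen estimators of signal irregularity.

Groups:

* histogram / energy: Shannon, log-energy, spectral;
* embedding-based: sample, permutation, permutation-Renyi;
* wavelet sub-band energy: averaged Shannon / Renyi / Tsallis wavelet
  entropies (averaged over two series, by default the two halves of the
  analysis window);
* graph: horizontal-visibility-graph link-weight entropy;
* fuzzy family: fuzzy, refined composite multiscale fuzzy (mean and std
  coarse-graining), inherent (EMD-detrended multiscale), averaged
  (transform-invariant), and fractional fuzzy entropy.

Tolerance convention: the fuzzy/sample tolerance ``r`` is a fraction of the
input's standard deviation and is converted to absolute units internally
(pass ``r_is_fraction=False`` to supply absolute units).

All estimators are deterministic for fixed input and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gamma as _gamma

from .emd import EMDParams, trend_removed
from .linear import normalized_psd

__all__ = [
    "EmbeddingParams",
    "FuzzyParams",
    "SubbandEnergies",
    "shannon_entropy",
    "log_energy_entropy",
    "spectral_entropy",
    "sample_entropy",
    "permutation_entropy",
    "permutation_renyi_entropy",
    "wavelet_entropy",
    "wavelet_entropy_avg",
    "graph_entropy",
    "horizontal_visibility_edges",
    "fuzzy_entropy",
    "rcmfe",
    "inherent_fuzzy_entropy",
    "averaged_fuzzy_entropy",
    "fractional_fuzzy_entropy",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Ordinal-embedding parameters for the permutation entropies."""

    m: int = 3
    L: int = 1
    alpha: float = 2.0

    def __post_init__(self) -> None:
        if self.m < 1 or self.L < 1:
            raise ValueError("m and L must be >= 1")


@dataclass(frozen=True)
class FuzzyParams:
    """Fuzzy-entropy family parameters.

    r is a fraction of the signal standard deviation (default 0.2); n is the
    width/power of the exponential membership exp(-d**n / r).
    """

    m: int = 2
    n: float = 2.0
    r: float = 0.2
    scales: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        if self.m < 1 or self.n <= 0 or self.r <= 0:
            raise ValueError("need m >= 1, n > 0, r > 0")
        if any(s < 1 for s in self.scales):
            raise ValueError("scales must be >= 1")


@dataclass(frozen=True)
class SubbandEnergies:
    """Per-sub-band energies E_i with normalised weights q_i = E_i / E_t."""

    E: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.E, float)
        if np.any(e < 0):
            raise ValueError("energies must be non-negative")
        if e.sum() <= 0:
            raise ValueError("zero total energy")
        object.__setattr__(self, "E", e)

    @property
    def total(self) -> float:
        return float(self.E.sum())

    @property
    def q(self) -> np.ndarray:
        return self.E / self.total

    @classmethod
    def from_signal(cls, x: np.ndarray, tqwt_params=None) -> "SubbandEnergies":
        """Sub-band energies from a TQWT decomposition, reducing J if the
        signal is too short for the requested depth."""
        from .. import tqwt as _tqwt

        params = tqwt_params or _tqwt.TQWTParams()
        jmax = _tqwt.max_feasible_levels(params, np.size(x))
        if jmax < 1:
            raise ValueError("signal too short for any decomposition level")
        if params.J > jmax:
            params = _tqwt.TQWTParams(params.Q, params.r, jmax)
        return cls(_tqwt.decompose(np.asarray(x, float), params).energies())


# ---------------------------------------------------------------------------
# histogram / energy / spectral


def shannon_entropy(x: np.ndarray, bins: int = 64) -> float:
    """Histogram Shannon entropy in bits, -sum p log2 p."""
    x = np.asarray(x, float)
    if x.size < bins:
        raise ValueError("need at least `bins` samples")
    if np.ptp(x) == 0:  # constant: single occupied bin
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def log_energy_entropy(x: np.ndarray, eps: float = 1e-12) -> float:
    """Log-energy entropy sum_i log(x_i**2 + eps), in nats."""
    x = np.asarray(x, float)
    return float(np.sum(np.log(x * x + eps)))


def spectral_entropy(x: np.ndarray, sampling_rate: float) -> float:
    """Normalised spectral Shannon entropy in [0, 1].

    -sum P_f log P_f over the normalised periodogram, divided by log(number
    of frequency bins); near 1 for a flat (noise) spectrum, near 0 for a
    concentrated (tonal) spectrum.
    """
    psd = normalized_psd(x, sampling_rate)
    p = psd.power[psd.power > 0]
    h = -np.sum(p * np.log(p))
    return float(h / np.log(psd.power.size))


# ---------------------------------------------------------------------------
# embedding-based


def _templates(x: np.ndarray, m: int, count: int) -> np.ndarray:
    """First `count` sliding templates of length m as a (count, m) array."""
    idx = np.arange(count)[:, None] + np.arange(m)[None, :]
    return x[idx]


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2,
                   r_is_fraction: bool = True) -> float:
    """Sample entropy -log(A/B) with self-matches excluded.

    B counts ordered pairs (i, j), i != j, of length-m templates within
    Chebyshev distance r; A the same at length m+1.  Both use the N-m
    templates starting at positions 0..N-m-1.  Returns inf when A or B is 0.
    """
    x = np.asarray(x, float)
    n = x.size
    if n < m + 2:
        raise ValueError("need N >= m+2 samples")
    tol = r * float(np.std(x)) if r_is_fraction else r
    if tol <= 0:  # constant signal: every template matches
        return 0.0
    count = n - m
    t_m = _templates(x, m, count)
    t_m1 = _templates(x, m + 1, count)
    d_m = np.max(np.abs(t_m[:, None, :] - t_m[None, :, :]), axis=-1)
    d_m1 = np.max(np.abs(t_m1[:, None, :] - t_m1[None, :, :]), axis=-1)
    off = ~np.eye(count, dtype=bool)
    b = int(np.count_nonzero(d_m[off] <= tol))
    a = int(np.count_nonzero(d_m1[off] <= tol))
    if a == 0 or b == 0:
        return float("inf")
    return float(-math.log(a / b))


def _ordinal_distribution(x: np.ndarray, m: int, L: int) -> np.ndarray:
    x = np.asarray(x, float)
    n_vec = x.size - (m - 1) * L
    if n_vec < 1:
        raise ValueError("need N >= m*L + 1 samples")
    if math.factorial(m) > n_vec:
        import warnings
        warnings.warn(f"ordinal distribution undersampled: m!={math.factorial(m)} "
                      f"patterns but only {n_vec} vectors", stacklevel=3)
    idx = np.arange(n_vec)[:, None] + L * np.arange(m)[None, :]
    # ties broken by order of appearance (stable sort)
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    return counts / n_vec


def permutation_entropy(x: np.ndarray, m: int = 3, L: int = 1) -> tuple[float, float]:
    """Permutation entropy (bits) and its normalised form in [0, 1].

    The normalised form divides the natural-log entropy by ln(m!) — the
    value is base-independent.
    """
    p = _ordinal_distribution(x, m, L)
    h_bits = float(-np.sum(p * np.log2(p)))
    h_norm = float(-np.sum(p * np.log(p)) / math.log(math.factorial(m)))
    return h_bits, h_norm


def permutation_renyi_entropy(x: np.ndarray, m: int = 3, L: int = 1,
                              alpha: float = 2.0) -> float:
    """Renyi entropy of the ordinal-pattern distribution, in nats."""
    if alpha == 1.0:
        raise ValueError("alpha=1 is the Shannon limit: use permutation_entropy")
    p = _ordinal_distribution(x, m, L)
    return float(math.log(np.sum(p**alpha)) / (1.0 - alpha))


# ---------------------------------------------------------------------------
# wavelet sub-band energy entropies


def wavelet_entropy(q: np.ndarray, kind: str = "shannon",
                    alpha: float = 2.0) -> float:
    """Entropy of a normalised sub-band energy distribution q (nats).

    Tsallis uses the (1 - sum q**alpha)/(alpha - 1) form, which recovers the
    Shannon value in the alpha -> 1 limit.
    """
    q = np.asarray(q, float)
    if kind == "shannon":
        qp = q[q > 0]
        return float(-np.sum(qp * np.log(qp)))
    if alpha == 1.0:
        raise ValueError("alpha=1 is the Shannon limit")
    s = float(np.sum(q**alpha))
    if kind == "renyi":
        return float(math.log(s) / (1.0 - alpha))
    if kind == "tsallis":
        return float((1.0 - s) / (alpha - 1.0))
    raise ValueError(f"unknown kind {kind!r}")


def wavelet_entropy_avg(se_x: SubbandEnergies, se_y: SubbandEnergies,
                        kind: str = "shannon", alpha: float = 2.0) -> float:
    """Two-series average of the selected wavelet entropy."""
    return 0.5 * (wavelet_entropy(se_x.q, kind, alpha)
                  + wavelet_entropy(se_y.q, kind, alpha))


# ---------------------------------------------------------------------------
# graph entropy


def horizontal_visibility_edges(x: np.ndarray) -> list[tuple[int, int]]:
    """Edge list of the horizontal visibility graph of x.

    Samples i < j are linked iff every sample strictly between them is lower
    than min(x_i, x_j).
    """
    x = np.asarray(x, float)
    edges: list[tuple[int, int]] = []
    stack: list[int] = []
    for j in range(x.size):
        while stack and x[stack[-1]] < x[j]:
            edges.append((stack.pop(), j))
        if stack:
            edges.append((stack[-1], j))
            if x[stack[-1]] == x[j]:
                stack.pop()
        stack.append(j)
    return edges


def graph_entropy(x: np.ndarray) -> float:
    """Mean per-node entropy of normalised link weights on the horizontal
    visibility graph, with W_ij = |x_i - x_j|.

    Nodes whose links all carry zero weight (constant plateaus) are skipped.
    """
    x = np.asarray(x, float)
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    nbrs: dict[int, list[int]] = {}
    for i, j in horizontal_visibility_edges(x):
        nbrs.setdefault(i, []).append(j)
        nbrs.setdefault(j, []).append(i)
    node_h = []
    for i, js in nbrs.items():
        w = np.abs(x[i] - x[np.array(js)])
        tot = w.sum()
        if tot <= 0:
            continue
        p = w[w > 0] / tot
        node_h.append(float(-np.sum(p * np.log(p))))
    if not node_h:
        return 0.0
    return float(np.mean(node_h))


# ---------------------------------------------------------------------------
# fuzzy family


def _abs_tolerance(x: np.ndarray, params: FuzzyParams,
                   r_is_fraction: bool) -> float:
    return params.r * float(np.std(x)) if r_is_fraction else params.r


def _membership_matrix(x: np.ndarray, m: int, n: float, r: float,
                       count: int) -> np.ndarray:
    """Pairwise membership exp(-d**n / r) of mean-subtracted templates."""
    t = _templates(x, m, count)
    t = t - t.mean(axis=1, keepdims=True)
    d = np.max(np.abs(t[:, None, :] - t[None, :, :]), axis=-1)
    return np.exp(-(d**n) / r)


def _phi(mu: np.ndarray) -> float:
    """Phi of Eq-style double average over i and j != i."""
    count = mu.shape[0]
    off = mu[~np.eye(count, dtype=bool)]
    return float(off.sum() / (count * (count - 1)))


def _phi_pair(x: np.ndarray, m: int, n: float, r: float) -> tuple[float, float]:
    count = x.size - m  # N - m template start positions at both lengths
    if count < 2:
        raise ValueError("need N >= m+2 samples")
    phi_m = _phi(_membership_matrix(x, m, n, r, count))
    phi_m1 = _phi(_membership_matrix(x, m + 1, n, r, count))
    return phi_m, phi_m1


def fuzzy_entropy(x: np.ndarray, params: FuzzyParams = FuzzyParams(),
                  r_is_fraction: bool = True) -> float:
    """Fuzzy entropy -ln(Phi^{m+1} / Phi^m), in nats.

    Templates are baseline-removed (own mean subtracted); the membership of a
    template pair at Chebyshev distance d is exp(-d**n / r).
    """
    x = np.asarray(x, float)
    tol = _abs_tolerance(x, params, r_is_fraction)
    if tol <= 0:
        return 0.0  # constant signal: all memberships 1
    phi_m, phi_m1 = _phi_pair(x, params.m, params.n, tol)
    return float(-math.log(phi_m1 / phi_m))


def _coarse_grain(x: np.ndarray, tau: int, offset: int,
                  variant: str) -> np.ndarray:
    n_blocks = (x.size - offset) // tau
    if n_blocks < 1:
        raise ValueError("scale too large for signal length")
    blocks = x[offset:offset + n_blocks * tau].reshape(n_blocks, tau)
    if variant == "mu":
        return blocks.mean(axis=1)
    if variant == "sigma":
        if tau < 2:
            raise ValueError("sigma coarse-graining needs tau >= 2")
        return blocks.std(axis=1, ddof=1)
    raise ValueError(f"unknown variant {variant!r}")


def rcmfe(x: np.ndarray, params: FuzzyParams = FuzzyParams(),
          variant: str = "mu", scales: tuple[int, ...] | None = None,
          r_is_fraction: bool = True) -> np.ndarray:
    """Refined composite multiscale fuzzy entropy, one value per scale.

    For scale tau, all tau coarse-grained offset series are formed by
    windowed mean (variant "mu") or windowed standard deviation (variant
    "sigma"); Phi is averaged over the offset series at both template
    lengths before taking -ln(mean Phi^{m+1} / mean Phi^m).  The tolerance
    is fixed from the original signal so scales are comparable.
    """
    x = np.asarray(x, float)
    scales = tuple(scales) if scales is not None else params.scales
    tol = _abs_tolerance(x, params, r_is_fraction)
    out = np.empty(len(scales))
    for s_idx, tau in enumerate(scales):
        if x.size < tau * (params.m + 2):
            feasible = [t for t in scales if x.size >= t * (params.m + 2)]
            raise ValueError(f"scale {tau} too large for N={x.size}; "
                             f"feasible scales: {feasible}")
        if tol <= 0:
            out[s_idx] = 0.0
            continue
        phis_m, phis_m1 = [], []
        for k in range(tau):
            z = _coarse_grain(x, tau, k, variant)
            pm, pm1 = _phi_pair(z, params.m, params.n, tol)
            phis_m.append(pm)
            phis_m1.append(pm1)
        out[s_idx] = -math.log(np.mean(phis_m1) / np.mean(phis_m))
    return out


def inherent_fuzzy_entropy(x: np.ndarray, params: FuzzyParams = FuzzyParams(),
                           emd_params: EMDParams = EMDParams(),
                           scales: tuple[int, ...] | None = None,
                           r_is_fraction: bool = True) -> np.ndarray:
    """Inherent fuzzy entropy: EMD-detrended multiscale fuzzy entropy.

    The signal is rebuilt from all IMFs except the final residue (removing
    the slow trend), coarse-grained by windowed mean at each scale, and the
    fuzzy entropy of each coarse-grained series is returned.
    """
    x = np.asarray(x, float)
    scales = tuple(scales) if scales is not None else params.scales
    xh = trend_removed(x, emd_params)
    tol = _abs_tolerance(xh, params, r_is_fraction)
    out = np.empty(len(scales))
    for s_idx, tau in enumerate(scales):
        if xh.size < tau * (params.m + 2):
            raise ValueError(f"scale {tau} too large for N={xh.size}")
        z = _coarse_grain(xh, tau, 0, "mu")
        if tol <= 0:
            out[s_idx] = 0.0
            continue
        pm, pm1 = _phi_pair(z, params.m, params.n, tol)
        out[s_idx] = -math.log(pm1 / pm)
    return out


_AFUZZ_KINDS = ("T", "R", "I", "G")


def _transformed_phi(x: np.ndarray, m: int, n: float, r: float,
                     kind: str, shift: int,
                     count: int | None = None) -> float:
    """Phi comparing templates X_i against transformed templates Gamma X_j.

    T: translation by `shift`; G: glide reflection (translation + negation);
    R: reflection of the template index about the midpoint; I: reflection +
    negation.  Out-of-range (i, j) pairs and i == j are skipped.  `count`
    fixes the number of start positions (shared between template lengths m
    and m+1, as in the plain fuzzy entropy).
    """
    if count is None:
        count = x.size - m
    t = _templates(x, m, count)
    t = t - t.mean(axis=1, keepdims=True)
    total, n_pairs = 0.0, 0
    for j in range(count):
        if kind in ("T", "G"):
            j2 = j + shift
        else:  # R, I: midpoint reflection keeps every index in range
            j2 = count - 1 - j
        if not 0 <= j2 < count:
            continue
        tj = t[j2] if kind in ("T", "R") else -t[j2]
        d = np.max(np.abs(t - tj[None, :]), axis=1)
        mu = np.exp(-(d**n) / r)
        mask = np.ones(count, dtype=bool)
        mask[j] = False
        total += float(mu[mask].sum())
        n_pairs += count - 1
    if n_pairs == 0:
        raise ValueError(f"no valid template pairs for transform {kind}")
    return total / n_pairs


def averaged_fuzzy_entropy(x: np.ndarray, params: FuzzyParams = FuzzyParams(),
                           shift: int = 1, r_is_fraction: bool = True) -> float:
    """Averaged fuzzy entropy over the four template transforms
    (translation, reflection, inversion, glide reflection)."""
    x = np.asarray(x, float)
    tol = _abs_tolerance(x, params, r_is_fraction)
    if tol <= 0:
        return 0.0
    count = x.size - params.m  # shared start positions at both lengths
    vals = []
    for kind in _AFUZZ_KINDS:
        pm = _transformed_phi(x, params.m, params.n, tol, kind, shift, count)
        pm1 = _transformed_phi(x, params.m + 1, params.n, tol, kind, shift,
                               count)
        vals.append(-math.log(pm1 / pm))
    return float(np.mean(vals))


def fractional_fuzzy_entropy(x: np.ndarray,
                             params: FuzzyParams = FuzzyParams(),
                             alpha: float = 0.5,
                             r_is_fraction: bool = True) -> float:
    """Fractional-order fuzzy entropy.

    With rho = Phi^{m+1}/Phi^m:

        FFuEn = -rho**(-alpha) * (ln rho + psi(1) - psi(1-alpha)) / Gamma(1+alpha)

    At alpha = 0 this reduces exactly to the fuzzy entropy.  May be negative
    for alpha > 0 (the fractional correction shifts the zero point).
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1) (digamma pole at 1)")
    x = np.asarray(x, float)
    tol = _abs_tolerance(x, params, r_is_fraction)
    if tol <= 0:
        rho = 1.0
    else:
        pm, pm1 = _phi_pair(x, params.m, params.n, tol)
        rho = pm1 / pm
    val = -(rho ** (-alpha)) * (math.log(rho) + digamma(1.0)
                                - digamma(1.0 - alpha)) / _gamma(1.0 + alpha)
    return float(val)
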
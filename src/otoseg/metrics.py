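"""Denoising and segmentation evaluation metrics.

PSNR scores image restoration; the Rand Index (RI), Global Consistency Error
(GCE) and Variation of Information (VI) score agreement between two label
maps.  RI/GCE/VI follow the standard Unnikrishnan / Martin / Meila
definitions and are computed from the label contingency table, which tests
cross-check against brute-force pair enumeration, per-pixel set arithmetic
and plug-in entropies respectively.

All three clustering metrics are invariant to permuting the label alphabets
of either argument.  VI is reported in bits (base-2 logarithms) and is a
metric on partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError

__all__ = [
    "MetricReport",
    "psnr",
    "rand_index",
    "gce",
    "variation_of_information",
    "contingency_table",
]


@dataclass(frozen=True)
class MetricReport:
    """One row of a benchmark table."""

    image_id: str
    psnr: float = math.inf
    ri: float = 1.0
    gce: float = 0.0
    vi: float = 0.0


def psnr(reference: np.ndarray, test: np.ndarray, L: int = 256) -> float:
    """Peak signal-to-noise ratio, 10*log10((L-1)^2 / MSE), in dB.

    Returns ``math.inf`` when the images are identical (MSE = 0).  MSE is
    taken over all pixels, borders included.
    """
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape:
        raise DomainError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    mse = np.mean((ref - tst) ** 2)
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10((L - 1) ** 2 / mse)


def contingency_table(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Joint label-count matrix N with N[i, j] = #{pixels: s1 = i-th label,
    s2 = j-th label}."""
    a = np.asarray(s1).reshape(-1)
    b = np.asarray(s2).reshape(-1)
    if a.shape != b.shape:
        raise DomainError("label maps must be congruent")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    nb = bi.max() + 1
    return np.bincount(ai * nb + bi, minlength=(ai.max() + 1) * nb) \
             .reshape(-1, nb).astype(np.int64)


def rand_index(s1: np.ndarray, s2: np.ndarray) -> float:
    """Fraction of unordered pixel pairs on which the two labelings agree
    (both co-clustered or both separated).  In [0, 1]; 1 iff the partitions
    coincide."""
    N = contingency_table(s1, s2)
    n = int(N.sum())
    if n < 2:
        raise DomainError("need at least 2 pixels")
    tot = n * (n - 1) // 2

    def c2(x):
        return (x * (x - 1) // 2).sum()

    a = c2(N)  # pairs together in both
    together = a + tot - c2(N.sum(axis=1)) - c2(N.sum(axis=0)) + a
    return float(together) / tot


def gce(s1: np.ndarray, s2: np.ndarray) -> float:
    """Global Consistency Error.

    With R(S, p) the region of S containing pixel p, the local refinement
    error is E(Sa, Sb, p) = |R(Sa,p) \\ R(Sb,p)| / |R(Sa,p)|; GCE averages
    the better of the two directional sums, so a strict mutual refinement
    scores 0.  In [0, 1]; lower is better.
    """
    N = contingency_table(s1, s2).astype(np.float64)
    n = N.sum()
    if n == 0:
        raise DomainError("empty label maps")
    a = N.sum(axis=1, keepdims=True)  # |R(S1,.)| per row
    b = N.sum(axis=0, keepdims=True)
    e12 = (N * (a - N) / np.where(a > 0, a, 1.0)).sum()
    e21 = (N * (b - N) / np.where(b > 0, b, 1.0)).sum()
    return float(min(e12, e21) / n)


def variation_of_information(s1: np.ndarray, s2: np.ndarray) -> float:
    """VI(S1, S2) = H(S1) + H(S2) - 2 I(S1; S2), in bits.

    Zero iff the partitions coincide; symmetric; satisfies the triangle
    inequality.  Bounded by log2(n)."""
    N = contingency_table(s1, s2).astype(np.float64)
    n = N.sum()
    if n == 0:
        raise DomainError("empty label maps")
    p = N / n
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    h1, h2 = ent(pa), ent(pb)
    pj = p[p > 0]
    hj = float(-(pj * np.log2(pj)).sum())
    mi = h1 + h2 - hj
    return max(h1 + h2 - 2.0 * mi, 0.0)
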
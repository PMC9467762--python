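"""Haar wavelet decomposition and multiscale histogram thresholding.

The 2-D transform splits an image into approximation (LL) and detail
(LH/HL/HH) subbands per level, using the orthonormal Haar filters with
periodic extension, so analysis/synthesis round-trips are exact and
coefficient energy equals pixel energy (Parseval).

The segmenter applies a 1-D Haar pyramid to the 256-bin gray histogram:
a rough threshold is found at a coarse scale as the deepest valley between
the two dominant modes, then mapped back scale by scale (bin index doubles
per level) and refined inside a small corridor at each finer level.
Coarse-to-fine tracking makes the threshold robust to histogram noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from ..exceptions import DomainError

__all__ = ["WaveletPyramid", "dwt2", "idwt2", "dwt_threshold_segment"]

_WAVELET = "haar"
_MODE = "periodization"


@dataclass(frozen=True)
class WaveletPyramid:
    """Ordered (LL, LH, HL, HH) coefficient grids, finest first."""

    levels: tuple[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray], ...]
    wavelet: str = _WAVELET

    def __len__(self):
        return len(self.levels)


def dwt2(img: np.ndarray, levels: int = 1) -> WaveletPyramid:
    """Orthonormal Haar analysis of ``img`` over ``levels`` levels."""
    if levels < 1:
        raise DomainError("levels must be >= 1")
    a = np.asarray(img, dtype=np.float64)
    if min(a.shape) < 2 ** levels:
        raise DomainError(
            f"{levels} levels too deep for image of shape {a.shape}")
    out = []
    for _ in range(levels):
        a, (lh, hl, hh) = pywt.dwt2(a, _WAVELET, mode=_MODE)
        out.append((a, lh, hl, hh))
    return WaveletPyramid(tuple(out))


def idwt2(pyr: WaveletPyramid) -> np.ndarray:
    """Exact inverse of :func:`dwt2` (synthesis)."""
    a = pyr.levels[-1][0]
    for _, lh, hl, hh in reversed(pyr.levels):
        a = pywt.idwt2((a, (lh, hl, hh)), pyr.wavelet, mode=_MODE)
    return a


def _local_maxima(a: np.ndarray) -> np.ndarray:
    """Indices i with a[i] >= both neighbours (edges count one-sided)."""
    left = np.r_[-np.inf, a[:-1]]
    right = np.r_[a[1:], -np.inf]
    return np.flatnonzero((a >= left) & (a >= right) & (a > 0))


def _argmin_tiebreak(vals: np.ndarray, cands: np.ndarray, center: float) -> int:
    """Candidate minimizing (value, |cand - center|, cand)."""
    v = vals[cands]
    key = np.lexsort((cands, np.abs(cands - center), v))
    return int(cands[key[0]])


def dwt_threshold_segment(img: np.ndarray, levels: int | None = None,
                          n_classes: int = 2, L: int = 256
                          ) -> tuple[np.ndarray, int]:
    """Binary segmentation by a multiscale histogram threshold.

    The histogram's Haar approximations a_0 (full resolution) .. a_J are
    computed with J chosen so the coarsest approximation keeps >= 8 bins
    (or as given by ``levels``).  At the coarsest level the threshold is the
    deepest interior minimum between the two largest local maxima; it is then
    mapped down (index times 2 per level) and re-localized within a +/-2-bin
    corridor on each finer approximation.  Ties prefer the corridor centre,
    keeping the threshold in the inter-mode valley even when the gap is flat.

    Returns the binary label map (img > threshold) and the threshold (a gray
    level in [0, L-1]).  A histogram unimodal at all usable scales falls back
    to the histogram median with a warning.
    """
    if n_classes != 2:
        raise DomainError("only two-class thresholding is supported")
    img = np.asarray(img)
    hist = np.bincount(img.reshape(-1), minlength=L)[:L].astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DomainError("image must occupy at least 2 gray levels")

    max_levels = int(np.log2(L // 8)) if levels is None else levels
    approxs = [hist]
    a = hist
    for _ in range(max_levels):
        if len(a) // 2 < 2:
            break
        a, _d = pywt.dwt(a, _WAVELET, mode=_MODE)
        approxs.append(a)

    # coarsest level with >= 2 separated modes
    t = None
    for j in range(len(approxs) - 1, -1, -1):
        coarse = approxs[j]
        maxima = _local_maxima(coarse)
        if maxima.size >= 2:
            order = np.lexsort((maxima, -coarse[maxima]))
            m1, m2 = sorted(int(maxima[i]) for i in order[:2])
            if m2 - m1 >= 2:
                between = np.arange(m1 + 1, m2)
                t = _argmin_tiebreak(coarse, between, (m1 + m2) / 2.0)
                start = j
                break
    if t is None:
        warnings.warn("histogram unimodal at all scales; falling back to the "
                      "histogram median", stacklevel=2)
        cdf = np.cumsum(hist)
        t = int(np.searchsorted(cdf, cdf[-1] / 2.0))
        return (img > t).astype(np.uint8), t

    for j in range(start - 1, -1, -1):
        a = approxs[j]
        c = 2 * t
        lo = max(1, c - 2)
        hi = min(len(a) - 2, c + 3)
        cands = np.arange(lo, hi + 1)
        t = _argmin_tiebreak(a, cands, c)

    return (img > t).astype(np.uint8), int(t)
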
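"""Grow Cut: seeded segmentation by a cellular automaton.

Each cell p carries a triplet (label l_p, strength theta_p in [0, 1],
feature C_p = gray value).  Seeded cells start with strength 1, everything
else unlabeled with strength 0.  In every synchronous sweep each neighbour q
"attacks" p with force g(|C_p - C_q|) * theta_q, where the attenuation is
g(d) = 1 - d / d_max with d_max = L - 1 = 255; the strongest attacker (ties:
larger force, then smaller label) conquers p iff its force strictly exceeds
theta_p.  Strengths therefore never decrease, labels only spread from seeds,
and a converged state is a fixed point of the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..exceptions import DomainError
from ..phantoms import UNLABELED

__all__ = ["neighbors", "growcut_segment", "GrowCutResult"]

_OFFS_VN = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFS_MOORE = tuple((dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                    if (dy, dx) != (0, 0))


def neighbors(p: tuple[int, int], kind: str, shape: tuple[int, int]) -> list[tuple[int, int]]:
    """In-bounds neighbours of ``p``: L1-distance-1 for ``"vonneumann"``,
    Linf-distance-1 for ``"moore"``."""
    offs = {"vonneumann": _OFFS_VN, "moore": _OFFS_MOORE}.get(kind)
    if offs is None:
        raise DomainError(f"kind must be 'vonneumann' or 'moore', got {kind!r}")
    y, x = p
    return [(y + dy, x + dx) for dy, dx in offs
            if 0 <= y + dy < shape[0] and 0 <= x + dx < shape[1]]


@dataclass(frozen=True)
class GrowCutResult:
    labels: np.ndarray
    iterations: int
    converged: bool

    def __iter__(self):  # allow (labels, iters) unpacking
        yield self.labels
        yield self.iterations


def growcut_segment(img: np.ndarray, seeds: np.ndarray, kind: str = "moore",
                    max_iters: int = 1000, seed_strength: float = 1.0,
                    unlabeled: int = UNLABELED, L: int = 256) -> GrowCutResult:
    """Evolve the Grow Cut automaton to convergence.

    ``seeds`` is a label map using ``unlabeled`` as the no-seed sentinel.
    Returns the final labels (cells never reached keep the sentinel), the
    number of sweeps that changed at least one cell, and a convergence flag
    (False if ``max_iters`` was exhausted first).  Final labels are invariant
    to rescaling all seed strengths by a common factor in (0, 1].
    """
    offs = {"vonneumann": _OFFS_VN, "moore": _OFFS_MOORE}.get(kind)
    if offs is None:
        raise DomainError(f"kind must be 'vonneumann' or 'moore', got {kind!r}")
    if max_iters < 1:
        raise DomainError("max_iters must be >= 1")
    if not (0.0 < seed_strength <= 1.0):
        raise DomainError("seed_strength must be in (0, 1]")
    seeds = np.asarray(seeds)
    seeded = seeds != unlabeled
    if not seeded.any():
        raise DomainError("seeds must contain at least one labeled pixel")

    H, W = seeds.shape
    C = np.asarray(img, dtype=np.float64)
    lab = np.full((H, W), -1, dtype=np.int64)
    lab[seeded] = seeds[seeded]
    theta = np.where(seeded, seed_strength, 0.0)

    dmax = float(L - 1)
    it = 0
    converged = False
    for it in range(1, max_iters + 1):
        best_f = np.full((H, W), -1.0)
        best_l = np.full((H, W), np.iinfo(np.int64).max, dtype=np.int64)
        for dy, dx in offs:
            ql = np.full((H, W), -1, dtype=np.int64)
            qt = np.zeros((H, W))
            qC = np.zeros((H, W))
            ys = slice(max(dy, 0), H + min(dy, 0))
            yd = slice(max(-dy, 0), H + min(-dy, 0))
            xs = slice(max(dx, 0), W + min(dx, 0))
            xd = slice(max(-dx, 0), W + min(-dx, 0))
            ql[yd, xd] = lab[ys, xs]
            qt[yd, xd] = theta[ys, xs]
            qC[yd, xd] = C[ys, xs]
            g = 1.0 - np.abs(C - qC) / dmax
            f = np.where(ql >= 0, g * qt, -1.0)
            better = (f > best_f) | ((f == best_f) & (ql >= 0) & (ql < best_l))
            best_f = np.where(better, f, best_f)
            best_l = np.where(better, ql, best_l)
        conquer = best_f > theta
        if not conquer.any():
            converged = True
            it -= 1  # this sweep changed nothing
            break
        lab = np.where(conquer, best_l, lab)
        theta = np.where(conquer, best_f, theta)
    else:
        # one extra check: did the last allowed sweep already reach a fixed point?
        converged = False

    out = np.where(lab >= 0, lab, unlabeled).astype(seeds.dtype)
    return GrowCutResult(out, it, converged)
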
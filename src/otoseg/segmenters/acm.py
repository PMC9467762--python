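"""Shape-prior level-set active contour.

The contour is the zero level set of a signed-distance-like field phi
(positive inside).  Segmentation minimizes a weighted energy

    E_T = w1 * E1 + w2 * E2 + w3 * E3

with E1 the Chan-Vese two-phase region term (squared deviation from the
inside/outside means), E2 a shape term penalizing the smoothed-Heaviside
area mismatch between phi and a pose-transformed template phi_T, and E3 an
edge term matching the gradient of H(phi) to the (unit-scaled) image
gradient.  phi descends the energy gradient with step halving so accepted
iterations never increase E_T; the template pose (translation, isotropic
scale, rotation) follows by coordinate descent on E2.  Iteration stops when
the segmented area is stable for several consecutive iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..exceptions import DegenerateContourError, DomainError

__all__ = [
    "ACMParams",
    "heaviside",
    "dirac",
    "signed_distance",
    "transform_template",
    "shape_energy",
    "edge_energy",
    "acm_segment",
]


def heaviside(phi: np.ndarray, eps: float) -> np.ndarray:
    """Smoothed step H_eps(z) = 1/2 (1 + (2/pi) atan(z / eps)).

    Strictly monotone, values in (0, 1), H(0) = 1/2 and H(z) + H(-z) = 1;
    approaches the sharp step as eps -> 0.
    """
    if eps <= 0:
        raise DomainError("eps must be positive")
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(phi, dtype=np.float64) / eps))


def dirac(phi: np.ndarray, eps: float) -> np.ndarray:
    """Derivative of :func:`heaviside`: (eps/pi) / (eps^2 + z^2)."""
    if eps <= 0:
        raise DomainError("eps must be positive")
    z = np.asarray(phi, dtype=np.float64)
    return (eps / np.pi) / (eps ** 2 + z ** 2)


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary, positive inside."""
    mask = np.asarray(mask, dtype=bool)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def transform_template(phi_t: np.ndarray, tx: float = 0.0, ty: float = 0.0,
                       s: float = 1.0, theta: float = 0.0) -> np.ndarray:
    """Resample a template field through translation + isotropic scale + rotation.

    The pose maps template coordinates p (about the grid centre) to image
    coordinates  q = s * R(theta) (p - c) + c + t,  with t = (tx, ty) in
    (col, row) pixels and theta in radians (CCW in the x-right / y-down image
    frame).  Resampling is bilinear through the inverse map; out-of-domain
    samples take the boundary value.  Identity parameters return the input
    up to interpolation epsilon.
    """
    if s <= 0:
        raise DomainError("scale must be positive")
    phi_t = np.asarray(phi_t, dtype=np.float64)
    H, W = phi_t.shape
    c = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    ct, st = np.cos(theta), np.sin(theta)
    # forward matrix on (row, col) vectors; row = y (down), col = x (right)
    F = s * np.array([[ct, st], [-st, ct]])
    Minv = np.linalg.inv(F)
    t = np.array([ty, tx])
    offset = c - Minv @ (c + t)
    return ndimage.affine_transform(phi_t, Minv, offset=offset, order=1,
                                    mode="nearest")


def shape_energy(phi: np.ndarray, phi_tb: np.ndarray, eps: float = 1.5) -> float:
    """E2 = sum (H(phi) - H(phi_T o B_T))^2 over the grid; zero iff the two
    fields induce the same smoothed indicator."""
    if phi.shape != phi_tb.shape:
        raise DomainError("grids must be congruent")
    d = heaviside(phi, eps) - heaviside(phi_tb, eps)
    return float((d * d).sum())


def edge_energy(phi: np.ndarray, img: np.ndarray, eps: float = 1.5) -> float:
    """E3 = sum |grad H(phi) - grad I|^2 (central differences, I scaled to [0,1])."""
    if phi.shape != np.asarray(img).shape:
        raise DomainError("grids must be congruent")
    I = np.asarray(img, dtype=np.float64) / 255.0
    h = heaviside(phi, eps)
    hy, hx = np.gradient(h)
    iy, ix = np.gradient(I)
    return float(((hy - iy) ** 2 + (hx - ix) ** 2).sum())


@dataclass(frozen=True)
class ACMParams:
    """Descent controls: step size (pixels of level-set motion per accepted
    iteration), iteration cap, signed-distance reinitialization cadence,
    area-stability tolerance (pixels) with the required consecutive-stable
    count, Heaviside smoothing width, and line-search acceptance."""

    step: float = 2.0
    max_iters: int = 300
    reinit_every: int = 20
    tol_pixels: float = 2.0
    stable_iters: int = 5
    eps: float = 1.5
    line_search: bool = True
    max_halvings: int = 8
    pose_every: int = 10


def _region_energy(I, h):
    w_in = h.sum()
    w_out = h.size - w_in
    c1 = (I * h).sum() / max(w_in, 1e-12)
    c2 = (I * (1.0 - h)).sum() / max(w_out, 1e-12)
    e1 = ((I - c1) ** 2 * h + (I - c2) ** 2 * (1.0 - h)).sum()
    return float(e1), c1, c2


def _total_energy(phi, I, phi_tb, w1, w2, w3, eps):
    h = heaviside(phi, eps)
    e1, c1, c2 = _region_energy(I, h)
    e = w1 * e1
    if w2 > 0 and phi_tb is not None:
        d = h - heaviside(phi_tb, eps)
        e += w2 * float((d * d).sum())
    if w3 > 0:
        hy, hx = np.gradient(h)
        iy, ix = np.gradient(I)
        e += w3 * float(((hy - iy) ** 2 + (hx - ix) ** 2).sum())
    return e, c1, c2


def acm_segment(img: np.ndarray, init_mask: np.ndarray,
                phi_t: np.ndarray | None = None,
                weights: tuple[float, float, float] = (1.0, 0.0, 0.1),
                params: ACMParams = ACMParams()
                ) -> tuple[np.ndarray, np.ndarray]:
    """Gradient-descent minimization of the shape-prior contour energy.

    Returns the binary label map {phi >= 0} and the per-accepted-iteration
    energy trace (non-increasing when ``line_search`` is on).  Deterministic
    for identical inputs.  Raises :class:`DegenerateContourError` if the
    contour collapses to empty or fills the frame.
    """
    w1, w2, w3 = weights
    if min(weights) < 0 or max(weights) == 0:
        raise DomainError("weights must be non-negative and not all zero")
    init_mask = np.asarray(init_mask, dtype=bool)
    if not init_mask.any():
        raise DomainError("init_mask must be non-empty")
    if w2 > 0 and phi_t is None:
        raise DomainError("shape weight w2 > 0 requires a template field")

    I = np.asarray(img, dtype=np.float64) / 255.0
    phi = signed_distance(init_mask)
    pose = [0.0, 0.0, 1.0, 0.0]  # tx, ty, s, theta
    phi_tb = transform_template(phi_t, *pose) if phi_t is not None else None
    eps = params.eps

    e_cur, _, _ = _total_energy(phi, I, phi_tb, w1, w2, w3, eps)
    trace = [e_cur]
    area_prev = int((phi >= 0).sum())
    stable = 0

    for it in range(1, params.max_iters + 1):
        h = heaviside(phi, eps)
        _, c1, c2 = _region_energy(I, h)
        F = w1 * ((I - c1) ** 2 - (I - c2) ** 2)
        if w2 > 0:
            F = F + w2 * 2.0 * (h - heaviside(phi_tb, eps))
        if w3 > 0:
            F = F - w3 * 2.0 * (ndimage.laplace(h) - ndimage.laplace(I))
        G = dirac(phi, eps) * F
        gmax = np.abs(G).max()
        if gmax == 0:
            break
        G = G / gmax

        step = params.step
        accepted = False
        for _ in range(params.max_halvings + 1):
            cand = phi - step * G
            e_new, _, _ = _total_energy(cand, I, phi_tb, w1, w2, w3, eps)
            if e_new <= e_cur or not params.line_search:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        phi, e_cur = cand, e_new
        trace.append(e_cur)

        if params.reinit_every and it % params.reinit_every == 0:
            phi_r = signed_distance(phi >= 0)
            e_r, _, _ = _total_energy(phi_r, I, phi_tb, w1, w2, w3, eps)
            if e_r <= e_cur or not params.line_search:
                phi, e_cur = phi_r, e_r

        if w2 > 0 and params.pose_every and it % params.pose_every == 0:
            phi_tb, pose, e_cur = _pose_step(phi, I, phi_t, phi_tb, pose,
                                             (w1, w2, w3), eps, e_cur)

        area = int((phi >= 0).sum())
        if abs(area - area_prev) <= params.tol_pixels:
            stable += 1
            if stable >= params.stable_iters:
                area_prev = area
                break
        else:
            stable = 0
        area_prev = area

    mask = phi >= 0
    if not mask.any() or mask.all():
        raise DegenerateContourError(
            f"contour degenerate: area = {int(mask.sum())} of {mask.size}")
    return mask.astype(np.uint8), np.asarray(trace)


def _pose_step(phi, I, phi_t, phi_tb, pose, w, eps, e_cur):
    """One coordinate-descent pass on (tx, ty, s, theta), accepting only
    energy-decreasing moves (only the shape term depends on the pose)."""
    w1, w2, w3 = w
    deltas = [(1.0, 0, 0, 0), (-1.0, 0, 0, 0), (0, 1.0, 0, 0), (0, -1.0, 0, 0),
              (0, 0, 0.02, 0), (0, 0, -0.02, 0), (0, 0, 0, 0.02), (0, 0, 0, -0.02)]
    h = heaviside(phi, eps)
    best = e_cur
    best_pose, best_tb = pose, phi_tb
    d0 = h - heaviside(phi_tb, eps)
    shape_cur = w2 * float((d0 * d0).sum())
    for dtx, dty, ds, dth in deltas:
        cand = [pose[0] + dtx, pose[1] + dty, pose[2] * (1.0 + ds), pose[3] + dth]
        tb = transform_template(phi_t, *cand)
        d = h - heaviside(tb, eps)
        e_cand = e_cur - shape_cur + w2 * float((d * d).sum())
        if e_cand < best:
            best, best_pose, best_tb = e_cand, cand, tb
    return best_tb, best_pose, best
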
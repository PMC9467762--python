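"""Synthetic tympanic-membrane phantoms.

Real otoscope images of the eardrum show a bright, roughly elliptical membrane
against a darker ear-canal background, often with a triangular specular
highlight (the "cone of light") and, in otitis media, an effusion region of
shifted intensity behind the membrane.  The generators here emulate that
coarse class structure -- an intensity-graded ellipse on a vignetted
background, an optional wedge highlight, an optional effusion blob, additive
Gaussian texture -- together with ground-truth label maps, sparse seed maps
for seeded segmenters, and measure-exact impulse-noise corruptions, so that
every downstream stage (denoising, segmentation, evaluation) is testable
without clinical data.

All generators are pure functions of (spec, seed): identical inputs give
bit-identical outputs.

Conventions
-----------
* images are ``uint8`` arrays indexed ``[row, col]``;
* label maps use 0 = background, 1 = membrane, 2 = effusion;
* seed maps reserve the sentinel 255 for "unlabeled" so they round-trip
  through 8-bit PNG unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, DomainError, SeedingError

L_DEFAULT = 256
UNLABELED = 255

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "Wedge",
    "Blob",
    "make_phantom",
    "add_impulse_noise",
    "make_seeds",
    "suite",
    "UNLABELED",
]


@dataclass(frozen=True)
class Wedge:
    """Cone-of-light descriptor: a wedge of boosted intensity inside the membrane.

    The wedge opens from an apex (offset from the membrane centre, in pixels)
    along ``direction_deg`` with total angular span ``span_deg``; ``boost`` is
    added to the underlying membrane intensity.  Angles follow the image
    convention (x = columns to the right, y = rows downward, degrees CCW from
    the +x axis).
    """

    direction_deg: float = 55.0
    span_deg: float = 40.0
    boost: int = 25
    apex_offset: tuple[float, float] = (0.0, 0.0)  # (row, col) from membrane centre


@dataclass(frozen=True)
class Blob:
    """Effusion descriptor: an axis-aligned ellipse with an intensity shift."""

    center_offset: tuple[float, float] = (18.0, -14.0)  # (row, col) from membrane centre
    axes: tuple[float, float] = (26.0, 20.0)  # (row semi-axis, col semi-axis)
    shift: int = -30


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic otoscope frame.

    Intensity bands are (edge, centre) pairs: the region's base intensity
    grades linearly from the band's first value at the region boundary to the
    second at the region centre.  A degenerate band (lo == hi) produces a
    constant region.  The default membrane centre sits on the half-integer
    grid centre so the rasterized ellipse is 4-fold symmetric and its tips are
    two-pixel balanced.
    """

    height: int = 256
    width: int = 256
    membrane_center: tuple[float, float] = (127.5, 127.5)  # (row, col)
    membrane_axes: tuple[float, float] = (70.0, 88.0)  # (row semi-axis, col semi-axis)
    membrane_band: tuple[int, int] = (140, 215)  # edge -> centre
    background_band: tuple[int, int] = (30, 80)  # periphery -> centre
    cone_of_light: Optional[Wedge] = field(default_factory=Wedge)
    effusion: Optional[Blob] = None
    texture_sd: float = 6.0
    rng_seed: int = 0

    def validate(self) -> None:
        cy, cx = self.membrane_center
        by, bx = self.membrane_axes
        if self.height < 1 or self.width < 1:
            raise ConfigurationError("image dimensions must be positive")
        if by <= 0 or bx <= 0:
            raise ConfigurationError("membrane axes must be positive")
        if not (0 <= cy - by and cy + by <= self.height - 1
                and 0 <= cx - bx and cx + bx <= self.width - 1):
            raise ConfigurationError("membrane ellipse extends outside the image")
        lo_m = min(self.membrane_band)
        hi_b = max(self.background_band)
        if self.effusion is not None:
            lo_m = min(lo_m, min(self.membrane_band) + min(self.effusion.shift, 0))
        if lo_m - hi_b < 30:
            raise ConfigurationError(
                f"membrane/background bands must be separated by >= 30 gray "
                f"levels (got {lo_m - hi_b})")
        if self.effusion is not None:
            ey = cy + self.effusion.center_offset[0]
            ex = cx + self.effusion.center_offset[1]
            ay, ax = self.effusion.axes
            if not (0 <= ey - ay and ey + ay <= self.height - 1
                    and 0 <= ex - ax and ex + ax <= self.width - 1):
                raise ConfigurationError("effusion blob extends outside the image")
        if self.texture_sd < 0:
            raise ConfigurationError("texture_sd must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """Impulse-noise description.

    ``density`` is the corrupted-pixel fraction p in [0, 1].  ``kind`` is
    ``"fixed"`` (salt/pepper: replacements drawn from {0, L-1}) or
    ``"random"`` (replacement drawn uniformly from [0, L-1] excluding the
    original value, so every masked pixel is actually corrupted).
    """

    density: float
    kind: str = "fixed"
    rng_seed: int = 0
    L: int = L_DEFAULT

    def validate(self) -> None:
        if not (0.0 <= self.density <= 1.0):
            raise DomainError(f"noise density must be in [0, 1], got {self.density}")
        if self.kind not in ("fixed", "random"):
            raise DomainError(f"noise kind must be 'fixed' or 'random', got {self.kind!r}")


def _ellipse_rho2(shape, center, axes):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (((yy - center[0]) / axes[0]) ** 2
            + ((xx - center[1]) / axes[1]) ** 2)


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a phantom and its aligned ground-truth label map.

    Returns
    -------
    image : (H, W) uint8
    truth : (H, W) uint8 with labels {0: background, 1: membrane, 2: effusion}
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    H, W = spec.height, spec.width
    cy, cx = spec.membrane_center

    rho2 = _ellipse_rho2((H, W), spec.membrane_center, spec.membrane_axes)
    inside = rho2 <= 1.0
    rho = np.sqrt(rho2)

    yy, xx = np.mgrid[0:H, 0:W]
    r = np.hypot(yy - cy, xx - cx)
    r_max = max(np.hypot(cy, cx), np.hypot(cy, W - 1 - cx),
                np.hypot(H - 1 - cy, cx), np.hypot(H - 1 - cy, W - 1 - cx))
    b_lo, b_hi = spec.background_band
    base = b_lo + (b_hi - b_lo) * (1.0 - r / r_max)

    m_lo, m_hi = spec.membrane_band
    base[inside] = m_lo + (m_hi - m_lo) * (1.0 - rho[inside])

    truth = np.zeros((H, W), dtype=np.uint8)
    truth[inside] = 1

    if spec.cone_of_light is not None:
        w = spec.cone_of_light
        ay = cy + w.apex_offset[0]
        ax = cx + w.apex_offset[1]
        ang = np.degrees(np.arctan2(-(yy - ay), xx - ax))  # CCW, +x axis = 0
        diff = np.abs((ang - w.direction_deg + 180.0) % 360.0 - 180.0)
        wedge = inside & (diff <= w.span_deg / 2.0) & (rho <= 0.98)
        base[wedge] += w.boost

    if spec.effusion is not None:
        e = spec.effusion
        ecen = (cy + e.center_offset[0], cx + e.center_offset[1])
        eff = (_ellipse_rho2((H, W), ecen, e.axes) <= 1.0) & inside
        base[eff] += e.shift
        truth[eff] = 2

    if spec.texture_sd > 0:
        base = base + rng.normal(0.0, spec.texture_sd, size=(H, W))

    image = np.clip(np.rint(base), 0, 255).astype(np.uint8)
    return image, truth


def add_impulse_noise(img: np.ndarray, noise: NoiseSpec) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt exactly round(p * n) distinct pixels of ``img``.

    Sampling is without replacement, so the returned boolean mask marks
    exactly the corrupted sites and tests can assert exact counts.
    Non-masked pixels are returned unchanged.
    """
    noise.validate()
    n = img.size
    k = int(round(noise.density * n))
    rng = np.random.default_rng(noise.rng_seed)
    out = img.copy()
    mask = np.zeros(img.shape, dtype=bool)
    if k == 0:
        return out, mask
    idx = rng.choice(n, size=k, replace=False)
    flat = out.reshape(-1)
    if noise.kind == "fixed":
        vals = rng.integers(0, 2, size=k).astype(np.uint8) * (noise.L - 1)
    else:
        # uniform over [0, L-1] \ {original}: draw from L-1 values, skip original
        draw = rng.integers(0, noise.L - 1, size=k)
        vals = (draw + (draw >= flat[idx].astype(np.int64))).astype(np.uint8)
    flat[idx] = vals
    mask.reshape(-1)[idx] = True
    return out, mask


def make_seeds(truth: np.ndarray, per_class: int, rng_seed: int = 0,
               unlabeled: int = UNLABELED) -> np.ndarray:
    """Draw ``per_class`` seed pixels per class from class interiors.

    Seeds are placed >= 2 px from the class boundary when the eroded interior
    is large enough, otherwise anywhere in the class.  All other pixels carry
    the ``unlabeled`` sentinel.
    """
    if per_class < 1:
        raise DomainError("per_class must be >= 1")
    rng = np.random.default_rng(rng_seed)
    seeds = np.full(truth.shape, unlabeled, dtype=np.uint8)
    labels = np.unique(truth)
    for lab in labels:
        mask = truth == lab
        interior = ndimage.binary_erosion(mask, iterations=2)
        pool = np.flatnonzero(interior)
        if pool.size < per_class:
            pool = np.flatnonzero(mask)
        if pool.size < per_class:
            raise SeedingError(
                f"class {int(lab)} has only {pool.size} pixels; cannot place "
                f"{per_class} seeds")
        chosen = rng.choice(pool, size=per_class, replace=False)
        seeds.reshape(-1)[chosen] = lab
    return seeds


def suite() -> dict[str, PhantomSpec]:
    """The packaged 10-phantom benchmark suite (IM1..IM10 stand-ins).

    These are named synthetic specs of varying contrast, texture, cone and
    effusion presence -- not reconstructions of any clinical image.  IM1 is
    texture-free with smooth elliptical boundaries and no cone, so that
    zero-noise filter identities can be asserted exactly.
    """
    return {
        "IM1": PhantomSpec(cone_of_light=None, texture_sd=0.0, rng_seed=101),
        "IM2": PhantomSpec(texture_sd=6.0, rng_seed=102),
        "IM3": PhantomSpec(effusion=Blob(), texture_sd=6.0, rng_seed=103),
        "IM4": PhantomSpec(texture_sd=10.0, rng_seed=104),
        "IM5": PhantomSpec(membrane_band=(130, 200), background_band=(40, 90),
                           texture_sd=8.0, rng_seed=105),
        "IM6": PhantomSpec(membrane_axes=(48.0, 60.0), texture_sd=4.0, rng_seed=106),
        "IM7": PhantomSpec(membrane_axes=(80.0, 100.0), effusion=Blob(),
                           texture_sd=8.0, rng_seed=107),
        "IM8": PhantomSpec(membrane_band=(150, 225), background_band=(45, 100),
                           texture_sd=12.0, rng_seed=108),
        "IM9": PhantomSpec(cone_of_light=None,
                           effusion=Blob(shift=25, axes=(24.0, 18.0)),
                           texture_sd=6.0, rng_seed=109),
        "IM10": PhantomSpec(cone_of_light=None, membrane_band=(125, 190),
                            background_band=(30, 75), texture_sd=10.0,
                            rng_seed=110),
    }
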
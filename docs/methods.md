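# Methods

This note documents the models implemented in `otoseg`, the defaults and why
they were chosen, what the synthetic phantoms do and do not emulate, and the
numerical choices that make every run deterministic.

## Noise model and phantoms

Impulse noise of density *p* replaces exactly `round(p·n)` distinct pixels,
sampled without replacement — not i.i.d. Bernoulli — so tests can assert exact
counts and detector recall/FPR are measured against exact ground truth.
Fixed-valued noise draws replacements from {0, L−1}; random-valued noise draws
uniformly from [0, L−1] excluding the original value, so every masked pixel is
genuinely corrupted.

Phantoms emulate the coarse structure of otoscope frames: a bright elliptical
membrane (intensity graded from its rim to its center) over a darker,
vignetted canal background, an optional cone-of-light wedge, an optional
effusion ellipse with an intensity shift, and additive Gaussian texture.
Intensity bands are `(edge, center)` pairs; a degenerate band (`lo == hi`)
yields a constant region, which is how the exact-identity filter tests build
two-constant-region images. The membrane center defaults to the half-integer
grid center (127.5, 127.5): the rasterized ellipse is then 4-fold symmetric,
its tips are two-pixel balanced, and every boundary pixel keeps at least four
same-class neighbors — the geometric condition under which median-type
filters leave a clean two-level phantom exactly unchanged. Default bands
(background 30→80, membrane 140→215) keep a ≥ 30 gray-level class gap
(enforced by validation) so a global threshold separates the classes, while
the shading spreads the histogram enough that histogram equalization is a
sensible contrast operation.

What the phantoms do **not** emulate: specular glints, hair/wax occlusions,
vascularization, color, illumination falloff asymmetry, or the appearance
statistics of diagnostic subtypes. Passing benchmarks therefore demonstrates
algorithmic correctness and the relative ordering of methods under controlled
impulse noise, not clinical performance.

The packaged benchmark suite (IM1..IM10) varies contrast, texture
(sd 0–12 gray levels), membrane size, cone and effusion presence. IM1 is
texture-free and cone-free so that zero-noise identities can be asserted
bit-exactly.

## Histogram equalization

`y = round((L−1) · CDF(v) / n)`, the plain CDF mapping; it is monotone,
idempotent up to ±1 quantization, and maps the occupied range onto the full
scale. A constant image is returned unchanged (the degenerate histogram has
no meaningful CDF spread, and identity is the only choice that keeps the
filter pipeline exact on constant frames). The look-up table is exposed
(`equalize_mapping`) so a clean reference image can be pushed through the
same mapping the filter applied to its input.

## Impulse detection

A pixel is flagged when either test fires, minus a refinement:

1. **ROAD** (rank-ordered absolute differences): sum of the `road_k = 4`
   smallest absolute differences to the 8 Moore neighbors, thresholded at
   `road_threshold = 40` gray levels. Isolated impulses score ≥ 4·(gap to
   surround); pixels on straight or gently curved region boundaries keep ≥ 4
   same-side neighbors and score ~0.
2. **Adaptive-window extreme test**: starting at 3×3 the window grows by 2
   (to `max_window = 9`) while its median is unreliable (not strictly between
   the window min and max — e.g. inside dense noise or two-valued
   neighborhoods); in a reliable window, a pixel that is not strictly
   interior to (min, max) is flagged. Constant windows are decided clean; on
   exhaustion, window extremes are flagged provisionally.
3. **Refinement**: each provisional flag is compared with the median of the
   *non-flagged* pixels in a window grown while the flagged fraction inside
   exceeds `window_growth_fraction = 0.5`; if the pixel value is within
   `refine_threshold = 20` gray levels of the nearer central order statistic,
   the flag is dropped. This rescues clean pixels adjacent to impulses,
   region boundaries, and texture outliers, and is why false-positive rates
   stay below 1 % on texture-free phantoms at 30 % noise.

`refine_threshold` is half the ROAD threshold: large enough to absorb texture
fluctuations (±3 sd at the default texture levels), small enough that a
saturated impulse at least 20 levels from its surround stays flagged.
Impulses closer than that to the local median are indistinguishable from
texture — and cost equally little if left in place.

## ACWM replacement

Flagged pixels are replaced by a weighted median of the **non-flagged**
pixels in a window grown until it holds at least 3 of them (cap 9×9); the odd
`center_weight = 3` attaches to every non-flagged sample at Chebyshev
distance 1 from the center. The corrupted center value itself is never part
of the multiset: the weight emphasizes the nearest non-noise evidence rather
than the damaged sample, and `center_weight = 1` reduces to the plain
non-flagged median. Weighting the whole adjacent ring rather than a single
nearest neighbor measurably lowers replacement variance (~0.5 dB suite-median
PSNR at 30–50 % noise): tripling one sample makes the median follow that
sample's texture fluctuation. Windows with zero non-flagged pixels fall back
to the plain median of the full 9×9 window (logged). Even-size multisets take
the lower median; together with raster-order tie-breaks this makes the filter
fully deterministic.

The filter has two output scales. `output_scale="raw"` (default) detects and
replaces on the input scale, so the restoration is directly comparable to the
clean original and to the baselines, and equalization remains available as a
separate enhancement step. `output_scale="equalized"` equalizes first and
works on the stretched scale; its natural reference is the clean image pushed
through the filter's own HE mapping. The benchmark defaults to raw-scale
scoring: on class-separated phantoms the HE mapping has local slope well
above 1 in the dominant region, so equalized-scale PSNR multiplies every
residual error by that slope and measures the contrast stretch more than the
restoration.

## Baseline filters

*Weighted median*: every pixel replaced by the weighted median of its 3×3
window; default stencil is all ones with center weight 3, which preserves
edges and survives single impulses but degrades quickly as density grows
(the window median itself gets corrupted).

*Adaptive median*: stage A grows the window (3..9) until the window median is
strictly interior to (min, max); stage B keeps the pixel if it is itself
strictly interior, else substitutes the median. When no window produces a
reliable median (two-valued neighborhoods, extreme noise), only saturated
values (0 or L−1) are replaced by the largest window's median; everything
else passes through. This exhaustion policy keeps the filter an exact
identity on clean two-level phantoms while still clearing saturated impulses
— the classical always-substitute variant smooths region boundaries even at
zero noise.

## Active contour with shape prior

The contour is the zero level set of φ (positive inside), evolved to minimize
`E_T = w1·E1 + w2·E2 + w3·E3` with the Chan–Vese two-phase region term E1
(the region energy is not otherwise specified by the formulation this
implements), the shape term E2 = Σ(H(φ) − H(φ_T∘B_T))², and the edge term
E3 = Σ|∇H(φ) − ∇I|² (central differences, image scaled to [0,1]). The
smoothed Heaviside is the arctangent form with `eps = 1.5` px; its derivative
is the matching Lorentzian. The pose B_T composes translation, isotropic
scale and the standard 2-D rotation about the grid center, resampled
bilinearly through the inverse map.

Descent uses gradient steps normalized to `step = 2` px of maximal level-set
motion, with step halving until the energy does not increase (so the trace
over accepted iterations is non-increasing); after 8 failed halvings the
contour is declared converged. φ is reinitialized to a signed distance
function every 20 iterations via the Euclidean distance transform, skipped
whenever it would raise the energy (reinitialization changes the smoothed
indicator slightly; unconditional reinitialization would break the monotone
trace). The pose follows by coordinate descent (±1 px translation, ±2 %
scale, ±0.02 rad) every 10 iterations when w2 > 0. Iteration stops when the
segmented area changes by ≤ 2 px for 5 consecutive iterations, or at
`max_iters = 300`. Empty or full contours raise a diagnostic error.

## Grow Cut

State per cell: (label, strength θ ∈ [0,1], feature C = gray value). Seeds
start at θ = 1 (scaling all seed strengths by a common factor leaves the
labels invariant). Synchronous sweeps: every neighbor q attacks p with force
g(|C_p − C_q|)·θ_q, g(d) = 1 − d/255; the strongest attacker wins, ties
broken by larger force then smaller label, and conquers only if its force
strictly exceeds θ_p. Strengths never decrease; convergence (a sweep that
changes nothing) is a fixed point, checked in the tests. Identical-feature
neighbors transmit full strength, so a uniform region floods from one seed;
across a full-range feature step (d = 255) the force is 0 and labels never
cross without seeds. Moore (8-) and Von Neumann (4-) neighborhoods are both
available; Moore is the default.

## Multiscale histogram threshold

The 256-bin histogram is decomposed by a 1-D orthonormal Haar pyramid
(periodic extension). At the coarsest level with ≥ 8 bins that shows two
separated local maxima, the threshold is the deepest minimum strictly between
the two largest maxima; descending the pyramid the index doubles and is
re-localized inside a ±2-bin corridor on each finer approximation. Ties in
the corridor prefer (smaller value, then proximity to the corridor center,
then smaller index): between well-separated modes the inter-mode gap is often
exactly flat, and pure smallest-index tie-breaking would walk the threshold
off the valley. If no scale shows two separated modes the histogram median is
returned with a warning. The 2-D transform (`dwt2`/`idwt2`) uses the same
orthonormal Haar filters; round-trips are exact to 1e−8 and coefficient
energy equals pixel energy (Parseval), both asserted in tests.

## Evaluation metrics

PSNR uses peak L−1 = 255 and the MSE over all pixels; identical images report
an infinite sentinel (the CSV writer emits `inf`). RI, GCE and VI follow the
standard definitions over the label contingency table; VI uses base-2
logarithms (bits, reported to 4 decimals). The benchmark scores segmenters
against phantom ground truth (three classes where an effusion is present);
GCE's refinement tolerance means a binary prediction can still score 0
against a three-class truth, which is the intended semantics.

## Benchmark harness

The harness is a pure function of (config, seed): per-cell RNG streams derive
from (global seed, image id, density) through a stable FNV-1a hash, so adding
a method or reordering the suite never changes another cell's noise
realization, and two runs emit byte-identical CSVs. Problem sizes are
256×256 phantoms, ten suite images, densities {0.30, 0.40, 0.50}; a full
denoise + segmentation benchmark completes in well under a minute on one
CPU. Any cell failure is logged with a traceback and recorded as NA without
aborting the run.

Default harness choices for the segmenters (the formulation leaves them
open): Grow Cut receives 10 interior seeds per class drawn ≥ 2 px inside
class boundaries; the active contour starts from an ellipse 12 px outside the
membrane axes with a centered disc of the mean membrane radius as a weak
shape template (w = (1, 2·10⁻³, 0.05)); the DWT segmenter needs no
configuration.

## Known limitations

- The impulse detector cannot (by design) distinguish impulses within
  `refine_threshold` of the local median from texture; such pixels are left
  unfiltered.
- Random-valued noise near the local intensity is likewise undetectable by
  any local statistic; recall targets apply to fixed-valued noise.
- The active contour is two-phase only and its shape prior is a single rigid
  template with similarity pose; no multi-template or learned priors.
- Grow Cut's runtime grows with region diameter (one sweep moves labels one
  cell); the 256×256 phantoms converge in a few hundred sweeps.
- All algorithms operate on 8-bit grayscale; color otoscopy is out of scope.
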
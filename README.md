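# otoseg

Impulse-noise filtering, segmentation and evaluation for otoscope-style
grayscale images.

Otitis media is diagnosed by inspecting the tympanic membrane through an
otoscope, and computer-aided analysis of such images starts from two noisy,
error-prone steps: removing acquisition noise and delineating the membrane.
`otoseg` packages a tested implementation of that front end for image-analysis
researchers: a histogram-equalization-based **adaptive center-weighted median
(HE/ACWM)** impulse-noise filter with classical baselines, three segmentation
algorithms, the standard segmentation quality metrics, and a synthetic phantom
generator so everything is reproducible without clinical data.

## What is implemented

**Denoising.** For impulse noise of density *p* (a fraction *p* of pixels
replaced by salt/pepper extremes or random gray levels), the HE/ACWM filter
runs in five phases: histogram equalization through the intensity CDF
(*y = round((L−1)·CDF(v)/n)*); impulse detection combining the rank-ordered
absolute difference statistic ROAD(x) = Σ of the *k* smallest |x − neighbor|
with an adaptive-window extreme-value test; a deviation-based refinement of
the detection mask; and replacement of each flagged pixel by the
center-weighted median of the non-flagged pixels in an adaptively grown
window. Unflagged pixels are never modified. Baselines: a sliding weighted
median filter and the classical two-stage adaptive median filter.

**Segmentation.** (1) A level-set active contour minimizing
*E_T = w₁E₁ + w₂E₂ + w₃E₃* — Chan–Vese region term, shape-prior term
∫(H(φ) − H(φ_T∘B_T))² for a template under translation/scale/rotation, and an
edge term ∫|∇H(φ) − ∇I|² — by accepted-step gradient descent (the energy
trace is non-increasing). (2) Grow Cut: a cellular automaton where seeded
cells attack neighbors with force *g(‖C_p − C_q‖)·θ_q*, *g(d) = 1 − d/255*,
until a fixed point. (3) Haar-DWT multiscale thresholding: a 1-D Haar pyramid
of the 256-bin histogram locates the valley between the two dominant modes at
a coarse scale and refines it scale by scale.

**Evaluation.** PSNR = 10·log₁₀((L−1)²/MSE); Rand Index; Global Consistency
Error; Variation of Information (bits) — contingency-table implementations
cross-checked in the tests against brute-force definitions.

**Phantoms.** Seeded generators for membrane-on-canal phantoms (elliptical
membrane, cone-of-light wedge, optional effusion blob, Gaussian texture),
ground-truth label maps, interior seed maps, and measure-exact impulse noise
(exactly round(p·n) corrupted pixels, so detector recall/FPR are exact).

## Worked example

```bash
python examples/02_denoise.py
```

```
detector: recall 1.0000, false-positive rate 0.0044
PSNR noisy           :  10.15 dB
PSNR weighted median :  19.68 dB
PSNR adaptive median :  33.04 dB
PSNR HE/ACWM         :  33.81 dB
```

On a textured phantom with 30 % fixed-valued impulse noise the detector finds
every corrupted pixel while flagging 0.4 % of clean ones; the restoration
recovers ~24 dB over the noisy input and leads both baselines because only
flagged pixels are touched. `examples/01_make_phantoms.py`,
`03_segment.py` and `04_benchmark.py` walk the phantom generator, the three
segmenters (printing RI/GCE/VI per method against ground truth) and the
benchmark tables.

A thin CLI mirrors the library: `otoseg phantoms | denoise | segment |
evaluate | bench-denoise | bench-seg` (see `otoseg --help`).

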
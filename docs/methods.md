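# Methods

## The processing problem

Hyperpolarized ²⁹Si MRI detects antibody-functionalized silicon particles
bound to colorectal lesions. The silicon channel is acquired on a small
matrix (nominally 32 × 32 over a 64 mm field of view) because the
hyperpolarized signal is transient; the proton anatomical channel is
acquired back to back at 256 × 256 × 22 slices without moving the subject.
Raw silicon images carry strong confounders: Rayleigh-distributed
background (magnitude of complex Gaussian receiver noise), bright signal
from particles left in the injection syringe or spilled outside the body,
day-to-day receiver drift, and occasional RF-overflow (ADC clipping)
artifacts. Naive per-image auto-scaling makes studies incomparable and can
show spurious signal as if it were real. The pipeline makes the images
comparable and the true signal identifiable:

1. **Reconstruction.** k-space is stored DC-at-center; the silicon matrix
   is zero-filled symmetrically to the anatomical grid and reconstructed as
   the modulus of the centered inverse DFT. Zero-filling is periodic-sinc
   interpolation: it refines the pixel grid (2 mm → 0.25 mm here) without
   changing the field of view or adding information.
2. **Per-study noise estimation.** The mean and sample standard deviation
   of the pooled four corner patches (each ⅛ of the image per axis — 32 × 32
   patches on the 256 grid) estimate the study's own background. Corners are
   read on the *unmasked* reconstruction: they define background and must
   not be zeroed by the subject mask.
3. **Masking and thresholding.** An optional quadrangle ROI zeroes
   everything outside the subject (syringe, spills). Pixels below
   5 × mean background are set to zero (strict `<`; a pixel exactly at the
   threshold survives).
4. **Normalization.** Each study is divided by its silicon-oil phantom
   reference (cancels scanner drift: a common gain factor multiplies both
   the signal and the phantom, so it divides out), then the whole study set
   is divided by the single universal peak so the set shares one [0, 1]
   display scale with all between-study ratios intact.
5. **Co-registration.** The chosen anatomical slice is contrast-stretched
   (1% of pixels saturated at each extreme, `k = ⌈p·n⌉` rank rule) and the
   silicon map is blended over it with intensity-proportional opacity
   (`rgb = (1 − a)·gray + a·hot(si)`, `a = 0.7·si`). Zero silicon shows the
   anatomy unchanged; the blend is a convex combination, so channels stay
   in [0, 1]. Registration is the identity by design — both images are
   acquired without repositioning.
6. **Quantification.** `SNR = |μ_t − μ_b|/σ_b` over 7 mm circular ROIs at
   the tumor sites and at matched non-tumor positions;
   `CNR = |μ_t − μ_m|/σ_m` against the torso polygon minus the tumor ROIs.
   Cohorts are compared with one-way ANOVA assembled from explicit sums of
   squares (auditable against hand computation); the p-value comes from the
   F survival function.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `threshold_multiplier` | 5 | denoise cutoff as a multiple of mean corner background |
| `corner_fraction` | 0.125 | corner patch size per axis (32 px on a 256 grid) |
| `tail_percent` | 1 | anatomical display saturation per intensity tail |
| `alpha_max` | 0.7 | peak opacity of the silicon overlay layer |
| ROI diameter | 7 mm | circular ROI for SNR/CNR statistics |

All are recorded in the run-record JSON, which together with the manifest
re-executes a run bit-identically.

## Numerical conventions

* Pixel centers sit at `(col + 0.5, row + 0.5)`; mm = pixel units ×
  spacing; row 0 is the top of the displayed image. ROI vertices and
  centers use these coordinates.
* Zero-fill pads `⌈extra/2⌉` rows/columns before the data block and
  `⌊extra/2⌋` after, keeping the Nyquist row of an even-sized input with
  the leading block; with upsampling factor `r`, fine pixel `r·p`
  coincides with coarse pixel `p` up to the constant `(n·m)/(N·M)`. The
  helper `mm_to_zerofilled_coord` accounts for the resulting fixed
  `(r − 1)/2`-pixel offset when placing mm-defined ROIs on the fine grid.
* Polygon rasterization uses the even–odd crossing rule on pixel centers;
  centers exactly on the boundary count as inside. Circle masks include
  centers at distance exactly the radius.
* Sample standard deviations use `n − 1` throughout.
* Thresholding is idempotent and never alters a surviving pixel.
  A constant image contrast-stretches to all 0.5 (degenerate contract).
* In ANOVA, zero within-group variance with distinct means yields
  `F = ∞, p = 0`; all-identical data raises an undefined-statistic error.

The quantification image is the masked, phantom- and set-normalized chain
*without* the threshold step. A hard threshold zeroes essentially every
background pixel, which would make σ_b and σ_m exactly zero (SNR/CNR
undefined) on any study without supra-threshold signal — including all
negative controls. SNR and CNR are invariant under positive affine
rescaling, so which normalization stage they are computed on is
irrelevant; only the threshold is deliberately omitted. The displayed
(thresholded) image and the quantification image are both written per
study.

## The synthetic study generator

`synthstudy` emulates the *structure* of the real acquisitions, not their
biology: an elliptical torso volume (256 × 256 × 22, 0.25 mm pixels,
0.75 mm slices) with smooth interior texture; a silicon ground truth of
Gaussian blobs — tumors (2.5–3 mm radius, mirroring 5–10 mm lesions)
inside the torso, a 10× syringe beacon and a spill outside it; complex
Gaussian noise added in k-space so the magnitude background is genuinely
Rayleigh; optional symmetric hard clipping of the k-space channels (the
RF-overflow mechanism); a per-study lognormal drift factor multiplying
both the k-space and the phantom reference; and a 4-cohort layout
(targeted at the configured amplitude; biological, chemical and
pre-blocked controls at tumor amplitude zero with all artifacts retained,
n = 3 per cohort, twelve studies per set).

Default amplitudes put the tumor peak at 20 background sigmas in the image
domain (`noise_sigma = 1.6` in k-space units → σ ≈ 0.05 against blob
amplitude 1.0 on the 32-grid), comfortably above the 5 × Rayleigh-mean
threshold (≈ 6.3 σ) while leaving the controls with nothing that survives
it. The beacon is rendered at 3 mm radius: a sub-pixel point source on the
2 mm coarse grid would ring (Gibbs sidelobes of the periodic-sinc
interpolation) far beyond its physical extent, which is a rendering
artifact rather than modeled physics. It sits in the lateral gap between
torso and FOV edge, 9 mm outside the quadrangle, and the spill is kept
clear of the corner patches so neither biases the background estimate.

What the generator does **not** model: RARE sequence physics, T₁ decay
during acquisition, motion/aliasing artifacts, susceptibility, coil
sensitivity profiles, or anatomically realistic torsos. Passing tests
therefore demonstrate the correctness of the processing contracts
(reconstruction, statistics, normalizations, recovery under the stated
noise model) — not clinical performance on in vivo data.

## Problem sizes used in tests

The test suite and the acceptance script run entirely on generated data:
brute-force Fourier oracles on ≤ 8 × 8 matrices, exhaustive ROI loops on
≤ 120 × 120 grids, ten 256² noise replicates for Rayleigh recovery, and
twenty independent 12-study cohort sets (4 cohorts × 3) for the
end-to-end recovery check — sizes chosen to match the nominal acquisition
geometry while keeping a full run in well under a minute.

## Known limitations

* Registration is identity-only; any subject motion between the two
  acquisitions is out of scope.
* The phantom reference is modeled as one positive scalar per study; its
  acquisition is not simulated.
* Corner noise estimation assumes the subject does not reach the image
  corners; a subject filling the FOV would bias the background estimate.
* ANOVA is the omnibus test only; no post-hoc pairwise comparisons.
* With clipping enabled the reconstruction is *not* corrected for the
  overflow artifact; the generator only reproduces it.
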
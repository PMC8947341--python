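# hypersi

Post-acquisition processing for hyperpolarized ²⁹Si MRI of targeted
silicon particles: reconstruction, per-study noise-adaptive denoising,
phantom and cross-study normalization, anatomical co-registration, and
SNR/CNR quantification. Written for preclinical imaging groups who need a
set of silicon studies — acquired on different days, with different noise
and receiver gain — processed onto one comparable scale and fused onto the
proton anatomical image, without per-image manual windowing.

## The method

A silicon acquisition is a small complex k-space matrix (nominally
32 × 32 over a 64 mm FOV). The pipeline, per study *i*:

1. zero-fill the k-space symmetrically to the anatomical matrix
   (256 × 256) and reconstruct `S_i = |IFFT2(k_i)|` (DC-centered
   convention);
2. estimate background `μ_bg, σ_bg` from the pooled four corner patches
   (⅛ of each dimension → the 32 × 32 corner sections);
3. mask everything outside a user-drawn quadrangle (syringe, spills), then
   zero pixels below `5·μ_bg`;
4. divide by the study's silicon-oil phantom reference (cancels day-to-day
   receiver drift), then divide the whole set by the universal peak
   `max_i max(S_i)` so all studies share one [0, 1] scale;
5. contrast-stretch the chosen anatomical slice (1% tail saturation) and
   blend the silicon map over it with intensity-proportional opacity;
6. quantify targeting with 7 mm circular ROIs:

   SNR = |μ_t − μ_b| / σ_b,  CNR = |μ_t − μ_m| / σ_m

   where μ_t is the mean at the tumor positions, μ_b/σ_b the statistics of
   an equal circle shifted to a non-tumor region, and μ_m/σ_m those of the
   torso excluding the tumors; cohorts are compared with one-way ANOVA.

Because no animal data are distributed, the package ships a synthetic
study generator (`hypersi.synthstudy`) producing complete dual-nuclei
studies — torso-shaped anatomical volumes, sparse silicon signal with
tumor foci, a syringe beacon and a spill outside the body, Rayleigh
magnitude background, optional ADC-clipping artifacts, and a 4-cohort
(targeted / biological / chemical / pre-blocked, n = 3) layout.

## Worked example

```
$ hypersi simulate --outdir demo --n-per-cohort 3 --seed 5
demo/manifest.csv
$ hypersi process --manifest demo/manifest.csv --outdir demo/out
{"universal_peak": 0.0002994165475936214, "n_studies": 12, "outdir": ".../demo/out"}
```

`demo/out` now holds, per study, the processed silicon map
(`*_processed.nii`), the fused overlay (`*_overlay.png`) and the ROI
statistics (`*_quant.json`), plus `run_record.json` with every parameter,
per-study peak and the cohort comparison. For this seed:

```
targeted_01            SNR 5.94   CNR 8.23
biological_control_01  SNR 0.40   CNR 0.07
SNR ANOVA across cohorts: F = 697.2, p = 5.2e-10
```

The targeted studies stand far above all three controls — the particles
"bound" at the planted tumors — while the universal peak (2.99e-4 in
phantom-normalized units) anchors every image to one comparable scale.
`hypersi quantify --rundir demo/out` recomputes the statistics from the
stored images without reprocessing.

The same machinery is available as a library:

```python
from hypersi import synthstudy as ss
from hypersi.pipeline import process_study_set, quantify_set

inputs = [s for s, _, _ in ss.make_cohort_studies(3, ss.SynthParams(seed=5))]
result = quantify_set(process_study_set(inputs, (256, 256)), inputs)
print(result.cohort_snr.p_value)
```

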
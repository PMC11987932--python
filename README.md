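# mrcytometry

Estimation of **cell size and cellularity from multi-diffusion-time
diffusion MRI** ("MR cytometry"), with a histology-based simulation test bed
for liver tissue. The package targets the problem of distinguishing
hepatocellular carcinoma (HCC, small cells ≈10–15 µm at roughly twice
normal density) from cirrhotic regenerative nodules and normal liver
parenchyma (hepatocytes ≈15–25 µm) — a distinction that conventional ADC
mapping cannot make specific. It is aimed at researchers in quantitative
diffusion microstructure imaging who want a self-contained forward model,
tissue simulator and fitting pipeline.

## The model

Normalized diffusion-weighted signals are modelled as three pools:

```
S_total(b, t_diff) = (1 − f_IVIM) [ v_in S_in + (1 − v_in) S_ex ] + f_IVIM S_blood

S_in  = exp(−b · ADC_sphere(d, D_in, t_diff))     restricted, impermeable sphere (GPA)
S_ex  = exp(−b · D_ex)                            hindered extracellular water
S_blood = exp(−b · D*)                            perfusion (IVIM) pseudo-diffusion
```

`ADC_sphere` comes from the Gaussian phase approximation: the eigenfunction
expansion of the position autocorrelation in a bounded geometry, evaluated
either by the Murday–Cotts closed form (rectangular PGSE) or by an exact
double-integral recursion for arbitrary gradient waveforms (cosine OGSE,
STEAM). Short diffusion times (cosine OGSE at 50 Hz, t_diff = 1/(4f) =
5 ms) ignore transcytolemmal water exchange; long diffusion times (PGSE/
STEAM, t_diff = Δ − δ/3 up to 70 ms) use the modified Kärger two-compartment
exchange model with the intracellular diffusivity replaced by the
time-dependent restricted ADC. Fitting d, v_in, D_in, D_ex (and τ_in) under
physiological bounds yields cellularity = 6 v_in / ((2π)^(2/3) d²).

The validation loop is fully in silico: synthetic 2-D tissue substrates
(random sequential addition of non-overlapping cells matching each
pathology's morphology) → finite-difference Bloch–Torrey simulation with
permeable membranes (κ = 0–0.05 µm/ms) → Rician noise (SNR 10/20/50) →
model inversion → group statistics (one-way ANOVA, Bonferroni-corrected
pairwise tests) and estimate-vs-truth correlations.

## Worked example

```bash
mrcyto generate --pathology HCC --size-px 500 --seed 4 --outdir demo
mrcyto simulate demo/substrate_HCC_4.tif --snr 50 --seed 1 --out demo/signals.csv
mrcyto fit demo/signals.csv --seed 0
```

The `generate` step reports the ground truth of the synthetic slide:

```
wrote demo/substrate_HCC_4.tif
{
  "n_cells": 246,
  "mean_diameter_um": 12.146,
  "mean_diameter_volume_weighted_um": 12.474,
  "cellularity_per_mm2": 3936.0,
  "area_fraction": 0.4511,
  "saturated": false
}
```

and `fit` inverts the simulated four-protocol signal set (two PGSE
diffusion times, 50 Hz cosine OGSE, STEAM; five b-values each):

```
{
  "d_um": 15.02,
  "vin": 0.646,
  "Din_um2_ms": 1.254,
  "Dex_um2_ms": 1.834,
  "tau_in_ms": 421.0,
  "f_IVIM": 0.0,
  "D_star_um2_ms": 20.0,
  "cellularity_per_mm2": 5047.6,
  "residual_rms": 0.0166,
  "n_starts_used": 20,
  "converged": true,
  "informative": true
}
```

(floats shortened here for readability). The fitted diameter (≈15 µm)
sits above the volume-weighted truth (12.5 µm) with the expected upward
bias from fitting a sphere model to 2-D disk substrates. The MRI-derived cellularity uses the fitted (v_in, d) under
the packed-spheres formula and is not on the same absolute scale as the
histological count — across pathologies it is the contrast that matters
(HCC ≈ 2–3× normal). The same pipeline over the full pathology ×
permeability × SNR grid is `mrcyto study`.

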
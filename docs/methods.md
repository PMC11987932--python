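# Methods

## Signal model

The tissue is modelled as three water pools with no net flow between the
vascular pool and the rest:

* **Restricted pool** (fraction `vin`): water inside impermeable spheres of
  diameter `d` with intrinsic diffusivity `Din`. Its attenuation is
  `exp(-b ADC_sphere)` under the Gaussian phase approximation (GPA): the
  one-axis position autocorrelation in a bounded pore is
  `⟨x(t₁)x(t₂)⟩ = Σ_k B_k exp(−a_k|t₁−t₂|)` with `a_k = α_k² Din/R²`, where
  the `α_k` solve the Neumann eigenvalue condition (`j₁'(α)=0` for the
  sphere, `J₁'(α)=0` for the disk; found by bracketed root-finding, never
  hard-coded) and the weights satisfy `Σ B_k = R²/5` (sphere) or `R²/4`
  (disk). The echo attenuation is
  `−ln S = (γ²/2) Σ_k B_k ∬ g(t₁)g(t₂)e^{−a_k|t₁−t₂|} dt₁dt₂`, evaluated by
  the Murday–Cotts closed form for rectangular pulse pairs and by an exact
  piecewise-constant recursion for arbitrary sampled waveforms. Because the
  log-attenuation is proportional to b for a fixed waveform shape,
  `ADC_sphere` is b-independent.
* **Hindered pool** (fraction `1−vin`): mono-exponential `exp(−b Dex)` with
  a single time-independent apparent diffusivity (no dispersion term).
* **Perfusion pool** (fraction `f_IVIM`): pseudo-diffusion `exp(−b D*)`.

**Water exchange.** For protocols with effective diffusion time above
10 ms the intra/extracellular mixture is replaced by the two-compartment
Kärger solution with rates `k_in = 1/τ_in`, `k_ex = k_in·vin/(1−vin)`
(detailed balance) and wavevector `q² = b/t_diff`; the intracellular
Gaussian diffusivity is substituted by the diffusion-time-dependent
restricted ADC ("modified" Kärger). The solution is the closed-form
matrix exponential of the 2×2 system; it conserves signal at b = 0 for any
τ_in and reduces to the no-exchange mixture (τ→∞) and to the
volume-weighted mono-exponential (τ→0). The 10 ms threshold places the
5 ms OGSE measurement in the no-exchange regime and the 30/70 ms PGSE/STEAM
measurements in the exchange regime; a protocol sitting exactly at the
threshold (PGSE δ/Δ = 3/11, t_diff = 10 ms) ignores exchange.

**Effective diffusion times.** `1/(4f)` for cosine OGSE; `Δ − δ/3` for
PGSE and STEAM. STEAM is treated as PGSE for diffusion weighting (the
mixing interval carries no gradient and relaxation is homogeneous, so it
drops out of normalized signals).

## Acquisitions

Unit system: µm, ms, µm²/ms, mT/m, b in ms/µm² (1 ms/µm² = 1000 s/mm²);
γ = 2.675×10⁸ rad s⁻¹T⁻¹ rescaled accordingly. The packaged ex-vivo
protocol set is PGSE δ/Δ = 3/11 and 3/31 ms, cosine OGSE 50 Hz with
δ/Δ = 20/25 ms (one whole period per lobe) and STEAM δ/Δ = 3/71 ms, all at
g_max = 360 mT/m with five b-values per protocol spaced at equal log
intervals from 0 to 1 ms/µm² or the hardware maximum, whichever is lower
(PGSE 3/11 tops out at ≈0.835 ms/µm²). A log ladder cannot contain 0, so
"log-spaced from 0" is implemented as {0} ∪ {4 points spanning one decade
up to b_max}; the decade span is configurable. Waveforms are sampled at
0.01 ms (analytic work) or at the FD time step (simulation); each sample is
the exact average of the analytic lobe over its interval, so rectangular
waveforms are represented exactly and the numerically integrated b always
matches the request to machine precision after amplitude scaling.

## Synthetic substrates

2-D label images emulate segmented liver histology. Cells are
non-overlapping disks with diameters uniform in the profile range, placed
by random sequential addition (RSA) until a target intracellular area
fraction is met (within 10% relative) or a candidate budget (10⁵) is
exhausted (the substrate is then flagged `saturated`). Defaults: normal
liver U(15, 25) µm at area fraction 0.55; CRN U(15, 25) µm at 0.45 (lower
cellularity than normal); HCC U(10, 15) µm at 0.45, which yields ≈2× the
normal cell count per mm² — the published morphological contrast. An HCC
fraction much above ~0.55 is not reachable by RSA (jamming) and would
imply ≈3× normal density, so the 2× density statement fixes the default.
Ground-truth metrics use pixel-area equivalent diameters of cells not
touching the field border (clipped cross-sections would bias sizes down);
cellularity counts all cell cross-sections per mm². "Volume-weighted"
mean diameter weights each cell by its cross-section area, mirroring the
volume weighting of MR signals.

What the generator does **not** emulate: polygonal cell shapes, nuclei,
sinusoids/vasculature (two compartments only), size-position correlations,
and 3-D connectivity. Passing tests therefore demonstrate correctness of
the estimation machinery under the stated geometric idealization, not
performance on real slides.

## Finite-difference engine

Lattice Bloch–Torrey on the label image: per step, conservative diffusion
exchange between 4-neighbours (conductance = compartment diffusivity for
like labels, `κ·Δx` across membranes — the interface-conductance treatment
of a permeable membrane; κ = 0 is perfectly reflecting), then the gradient
phase rotation `exp(−iγ g(t) x Δt)` about the field centre, single gradient
direction along the image rows. Zero-flux outer boundary; no periodic wrap
(the position-dependent gradient phase is incompatible with naive
periodicity). Time step `0.9·Δx²/(4 max D)` by default; larger requested
steps are refused. T2 and proton density are homogeneous and drop out of
the normalized dynamics. The scheme conserves total magnetization exactly
at g = 0 (symmetric conductances), and the b = 0 reference is therefore
taken analytically unless an explicit conservation run is requested.

Validation: free diffusion in a uniform medium reproduces `exp(−b D)`
(wall effects decay as 1/L, so the check uses an elongated box along the
gradient axis); a single impermeable disk matches the GPA disk model to
≈1%, with the residual at the highest b traceable to the GPA itself — the
GPA omits the positive diffusional kurtosis of restricted water, worth
about 1.3% at b = 1 ms/µm², t_diff = 30 ms, d = 15 µm, as confirmed by
grid-refined FD and an independent Monte-Carlo random walk. This is a
known accuracy boundary of the analytic model, not of the engine.

**Rician noise.** Each normalized magnitude S becomes
`√((S+ε₁)² + ε₂²)`, ε ~ N(0, σ²) with σ = (b=0 magnitude)/SNR, applied
independently per (protocol, b) entry, deterministic per seed.

## Inverse problem

Sequential pipeline: (1) preprocessing pass-through; (2) model selection =
the exchange-regime rule above (no information criterion: only the regime
choice is defined by the method); (3) optional perfusion removal:
log-linear fit over b ≥ 0.2 ms/µm², `f_IVIM = max(0, 1−intercept)`,
correction of the b ≥ 0.2 points by `1/(1−f_IVIM)`; f_IVIM is then fixed;
(4) bounded least squares over `0≤d≤30 µm, 0≤vin≤1, 0≤Din, Dex≤3 µm²/ms,
0≤τ_in≤1000 ms` (τ_in only fitted when a long-t_diff protocol is present)
with 20 random interior starts (seeded), a trust-region-reflective solver
(cost tolerance 1e-8, parameter tolerance 1e-6), best residual wins.
Small positive floors (d ≥ 0.1 µm, τ_in ≥ 0.2 ms) keep the eigen-series
and exchange rates off their singular limits. Forward evaluations inside
the optimizer use per-protocol caches of the GPA double integral,
tabulated on a log grid of decay rates and interpolated log-log (relative
error < 2×10⁻³ against the exact recursion, ~10³× faster).

Perfusion removal is **off by default for simulated tissue**: the FD
substrates contain no vascular pool, and applying the mono-exponential
extrapolation to genuinely multi-exponential tissue manufactures a
spurious f_IVIM ≈ 0.05 that biases vin. The step is validated on
analytic three-pool signals, where a mono-exponential tissue pool gives
f_IVIM back to ±0.002 and the full composite to ±0.02.

Cellularity is `6 vin/((2π)^{2/3} d²)` (spheres densely packed on an FCC
grid), reported per mm² with d in mm; the constant is
`(2π)^{2/3} = 3.40503`. Absolute MRI cellularity is on the formula's own
scale, not the histological nuclei-count scale; across-pathology contrast
is the meaningful readout.

## Simulation study

Factorial grid pathology × substrate × κ × SNR × replicate; noiseless
signals are FD-simulated once per (substrate, κ), noise and fitting are
per replicate, and child seeds derive deterministically from the master
seed, so the whole table is bit-reproducible. The study fits at ROI level
(the field-summed signal per image), matching one diffusion data set per
histological image. Group statistics: one-way ANOVA across the three
pathologies plus Welch pairwise t-tests with Bonferroni scaling (×3,
capped at 1); replicates enter as observations, which overstates the
effective sample size slightly. Desk-scale problem sizes used in the test
suite: 500×500 px substrates (0.25×0.25 mm at 0.5 µm/px), six substrates
per pathology for the discrimination study (matching the six images of
the full design; quick variants use three), κ ∈ {0, 0.02} µm/ms,
SNR ∈ {20, 50}, three noise replicates; the full design (six 1000×1000 px
substrates per pathology, six κ values, three SNR levels) is available
through `StudyConfig()`/`--full`.

At SNR 20 the intrinsic spread of single-ROI fitted diameters is large
(SD ≈ 5 µm; the heavy tails are true global minima of the noisy least
squares — more multi-starts reproduce them exactly), so at desk scale the
diameter metric alone separates HCC from CRN but not from normal liver.
The cellularity metric, `vin/d²`, concentrates the same contrast and
separates HCC from both other groups at SNR 20 (Bonferroni-adjusted
p < 0.05); at SNR 50 all contrasts are clean. Fitted diameters correlate
with the area-weighted ground truth at ρ ≈ 0.77 (SNR 50, impermeable
membranes).

## Known limitations

* The inverse model is a 3-D sphere while the simulated substrates are
  2-D disks — deliberately mirroring the histology-based validation
  design, whose slides are 2-D. Disk-restricted water decorrelates more
  slowly than sphere-restricted water at equal diameter (α₁ = 1.84 vs
  2.08), so fitted diameters carry a systematic upward bias of roughly
  10–20% relative to the 2-D ground truth; HCC substrates with
  volume-weighted truth ≈12.5 µm fit to ≈14–15 µm.
* GPA accuracy degrades with b (kurtosis neglect, ~1.3% at b = 1 in the
  worst protocol/geometry combination tested).
* Exchange enters the inverse model only through τ_in; the FD engine's
  membrane κ maps onto τ_in only approximately (τ ≈ V/(S κ)), and fits on
  leaky substrates show the expected drift of fitted d and vin with κ
  rather than a calibrated correspondence.
* Uniform diameter distributions and circular cells are idealizations;
  registration/denoising of real scanner data are out of scope (a
  pass-through hook marks their place in the pipeline).
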
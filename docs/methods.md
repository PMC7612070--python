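# Methods

This note documents the models implemented in `hypermet`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter.

## Two-pool exchange model

The dynamic ¹³C signal is modelled as unidirectional label exchange from
pyruvate (Mp) to lactate (Ml) with effective longitudinal relaxation and a
vascular input feeding the pyruvate pool:

    dMp/dt = −(kPL + R1p)·Mp + u(t)
    dMl/dt =  kPL·Mp − R1l·Ml

Back-exchange is absorbed into the *apparent* kPL, as usual for this class
of acquisition. Excitation is interleaved and metabolite-specific: a
pyruvate pulse (default 15°) every `frame_interval` = 4 s, a lactate pulse
(default 40°) `tr` = 2 s later, so each metabolite is sampled once per
frame. At each pulse the recorded signal is sin(α)·Mz at the pulse
instant, and the longitudinal pool is multiplied by cos(α) immediately
afterwards. Note the two metabolites are therefore never sampled at the
same instant; invariants that involve both pools (e.g. conservation)
hold at equal times, not across the TR offset.

Integration is exact over inter-pulse gaps: the homogeneous part uses the
closed-form 2×2 matrix exponential of the lower-triangular rate matrix,
and the bolus contribution is integrated with 16-point Gauss–Legendre
quadrature per gap. A 1-ms explicit-Euler integration serves as the
independent reference in tests; agreement is ≲0.01% (the tested bound is
0.1%).

### Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| kPL | 0.0064 | s⁻¹ | cohort-baseline mean exchange rate, used as planted truth |
| R1p | 1/30 | s⁻¹ | field-typical in-vivo pyruvate T₁ ≈ 30 s |
| R1l | 1/25 | s⁻¹ | field-typical in-vivo lactate T₁ ≈ 25 s |
| flips | 15° / 40° | — | small pyruvate angle preserves the pool; larger lactate angle boosts SNR |
| TR / frame | 2 / 4 | s | interleaved excitation, 4-s temporal resolution |
| bolus | gamma-variate, arrival 8 s, shape 3, rate 4 s | — | realistic bolus with analytic form |

The acquisitions this emulates do not publish assumed T₁ values, coil
counts or the bolus shape; the values above are declared defaults chosen
for realism, all configurable, and none is inferred from data.

## Noise model

Magnitude noise is Rician: the modulus of a complex Gaussian perturbation
(`rician()`), i.e. a single effective receive channel. Multi-coil
noncentral-χ statistics are not modelled because a coil count would be an
invented parameter. Background voxels are therefore Rayleigh, which the
noise estimator exploits: the default robust SD is MAD×1.4826; the
Rayleigh-corrected mode recovers the per-channel σ from the background
median via σ = median/√(2 ln 2).

## ¹³C summary metrics

* **Summed SNR** per voxel = Σₜ S(t) / (σ·√n_frames): the denominator is
  the SD of a sum of n independent noise terms. The SNR normalisation
  convention (single-frame vs summed-image noise) is not standardised; this
  definition is declared and used consistently.
* **LAC/PYR** = ROI mean of voxelwise (Σ lac)/(Σ pyr), following the
  ROI-mean convention of per-voxel parameter maps. Ratio-of-ROI-sums is
  available behind `method="ratio_of_sums"`; the two coincide on
  proportional maps. Voxels with summed pyruvate below a floor (default
  5× the summed-image noise) are excluded and counted; the floor is a
  declared rule, not a published one.
* **Spectral path**: when only dynamic spectra exist (the
  low-temporal-resolution fallback), spectra are summed over time and the
  magnitude integrated in user-set chemical-shift windows; no lineshape
  fitting.

## kPL estimation (inputless fit)

The measured pyruvate time course drives a discrete lactate forward model:

    Ml(t+Δ) = Ml(t)·cos(α_lac)·e^(−R1l·Δ) + kPL·∫ Mp(s)·e^(−R1l·(t+Δ−s)) ds

The driving pool Mp(s) is reconstructed from the measured samples by
dividing out the accumulated cos(α_pyr) pulse losses, interpolating the
smooth pulse-free curve with a monotone cubic (PCHIP), and reapplying the
pulse history; the integral uses trapezoidal quadrature on 20 substeps per
frame (refinement-stable to <0.5%). The initial lactate pool is taken from
the first measured lactate frame.

**Why a one-parameter fit.** Given the measured driver, the predicted
lactate is exactly linear in kPL, so a free amplitude multiplying the
prediction is perfectly degenerate with the rate — only their product is
identifiable. Since both metabolites share the receive chain and flip
angles are corrected explicitly, the amplitude is fixed to 1 and kPL
carries the fit. The reported `scale` is the post-hoc least-squares
amplitude of the best prediction: a consistency diagnostic that is ≈1 when
model and data agree, not a fitted parameter.

The 1-D search uses bounded scalar minimisation (xatol 10⁻⁹) from three
overlapping brackets covering [0, 0.2] s⁻¹, keeps the lowest residual
(ties → lower kPL) and checks the k = 0 boundary explicitly so
zero-lactate inputs resolve to 0 rather than a bracket edge. R1l is fixed
(default 1/25 s⁻¹) because a two-rate per-voxel fit is not identifiable at
clinical SNR; the assumed value is recorded in every fit result. Fits with
fewer than 5 frames are rejected (the low-temporal-resolution exclusion),
as are series whose pyruvate peak SNR is below 3 when a noise level is
known. Mis-specified flip angles bias kPL materially; a test demonstrates
the effect.

**Rician noise-floor correction.** At summed lactate SNR ≈ 7 the
per-frame lactate SNR peaks near 3, where the Rician magnitude floor
inflates the whole curve and biases kPL by ~+10% (verified by fitting the
exact expected Rician-mean curve). When σ is known the fit first applies
the standard Gudbjartsson–Patz correction √|M²−σ²| to both series, which
the same deterministic check shows is near-unbiased; Monte-Carlo median
bias is <1% at 200 replicates. The correction is on by default whenever
`noise_sd` is passed.

## Proton-MRI stage

* **IVIM**: S(b) = S₀[f·e^(−b·D*) + (1−f)·e^(−b·D)]. The segmented fit
  (log-linear over b ≥ 200 s/mm² → D, intercept → f, then D* with (f, D)
  fixed) is followed by a joint nonlinear polish of all four parameters
  started from the segmented estimates. The polish matters: with
  D* = 10⁻² mm²/s the pseudo-diffusion term has only decayed to e⁻² at the
  threshold, biasing the pure segmented f by ~18%. `refine=False`
  restores the plain segmented behaviour. Parameters are clipped to their
  physical bounds with a flag; monotone-increasing signals are flagged as
  failed fits.
* **Tofts**: Ct(t) = Ktrans·∫ Cp(τ)·e^(−kep(t−τ))dτ, kep = Ktrans/ve.
  The convolution assumes a piecewise-linear plasma curve and is evaluated
  by an exact per-segment recursion; `aif="impulse"` selects the closed
  form Ktrans·e^(−kep·t). Bounds Ktrans ∈ [0, 5] min⁻¹, ve ∈ (0, 1];
  three deterministic starts; flat curves return Ktrans ≈ 0 with an
  uncertainty flag rather than an error. A population gamma-variate AIF is
  provided for simulation work and recorded when used.
* **iAUC90**: trapezoidal integral of the baseline-subtracted curve over
  exactly 90 s past the (explicit, never inferred) injection time, with
  interpolated window endpoints. Baseline = mean of pre-injection samples.
* **Volume**: voxel count × voxel volume in mL. Signal-to-concentration
  conversion, registration and segmentation are out of scope; curves and
  masks are inputs.

Units: b in s/mm², D and D* in mm²/s, DCE rates in min⁻¹ (curve times in
minutes), iAUC in concentration·seconds, volumes in mL.

## Response classification

Percent change is relative to baseline, 100·(follow-up − baseline)/baseline.
The fixed rules are: responder iff ΔLAC/PYR ≥ +20% (boundary inclusive on
the responder side) and responder iff ΔkPL ≥ −15% (above threshold).
Missing kPL withholds the call rather than defaulting. The thresholds are
treated as fixed constants — a 7-patient cohort cannot support threshold
learning, so sweeps exist only for synthetic power studies. PARP-treated
patients are classified but stratified separately and never enter
standard-of-care validation counts, because PARP inhibition plausibly
raises lactate labeling pharmacodynamically regardless of response.

## Statistics and survival

Pearson correlation (two-sided p via t = r·√((n−2)/(1−r²))) and Student t
tests (paired on differences) are delegated to scipy behind the module
surface; tests verify them against hand-computed formulas to 10⁻¹⁰. No
multiple-testing correction is applied by default (results are
exploratory); Benjamini–Hochberg is available behind `adjust_pvalues`.
Identical paired samples return t = 0, p = 1; a constant nonzero paired
shift is rejected as degenerate (zero-variance differences).

Expression log-intensities are standardised to z-scores (sample SD), and
"overexpression" is strictly above the 85th percentile with numpy's
linear-interpolation percentile definition — both declared choices, since
percentile conventions differ. Kaplan–Meier estimation and the two-group
log-rank test use lifelines, cross-checked in tests against a hand-worked
product-limit example and a naive observed-vs-expected summation loop.
Covariate-adjusted survival modelling is out of scope.

## Synthetic cohorts

`simulate_cohort` draws per-patient tables that emulate the study
structure: 7 patients (4 TNBC / 3 HER2⁺), 3 responders, 2 on PARP
inhibitor (one per outcome group), follow-up 7–11 days after the first
dose, one standard-of-care nonresponder with missing kPL. Baseline
metrics are drawn at the study's printed summary scale (LAC/PYR
0.28 ± 0.17, kPL 0.0064 ± 0.0058 s⁻¹, summed SNR_PYR 19.7 ± 19.9, summed
SNR_LAC 7.0 ± 5.6, volumes 7.4 ± 3.6 mL HER2⁺ / 2.4 ± 0.7 mL TNBC, lower
baseline f in responders). Percent-change windows plant the response
structure: non-PARP responders ≥ +25%, non-PARP nonresponders ≤ +10%, the
PARP nonresponder +25…+60% (the deliberate rule violation); kPL changes
follow the −15% rule analogously. Everything is drawn from a single
seeded generator and is bit-reproducible.

What the generator does **not** emulate: k-space acquisition and
reconstruction (spiral readouts, spectral decomposition, coil
combination), B₀/B₁ inhomogeneity, motion, partial-volume effects,
physiological inter-patient correlation structure, and real biological
variability in response magnitude. Passing tests therefore demonstrate
the correctness of the analysis chain under the declared forward models —
they do not demonstrate clinical performance on real data.

`simulate_expression_survival` plants a prognostic upper tail: samples
above the 85th percentile of the lead gene carry a configurable hazard
ratio (default 2) on an exponential baseline (median 120 months,
administrative censoring at 240 months), with optional equicorrelated
co-expressed genes.

## Problem sizes

Simulation studies in the tests and the acceptance script use 20-frame
dynamics, 100 random propagator draws against a 1-ms Euler reference, 200
noise replicates for kPL recovery, 100–200 replicates for IVIM noise and
the log-rank power study (n = 500 per cohort), and 10 synthetic 7-patient
cohorts for classification. These sizes give stable medians and rates
while keeping a full run in well under a minute per stage.

## Known limitations

* The kPL estimator is the declared inputless discrete model, not a
  reimplementation of any specific published reconstruction/fitting chain;
  apparent rates are comparable only under matching assumptions (R1l,
  flip-angle bookkeeping).
* LAC/PYR mean-of-ratios vs ratio-of-sums differ on heterogeneous ROIs;
  both are available and the default is declared above.
* The Tofts stage consumes concentration/enhancement curves; T₁-based
  signal conversion errors are outside the model.
* Single-channel Rician noise understates the floor of multi-coil
  sum-of-squares data.
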
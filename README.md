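# hypermet

Quantitative response assessment for breast cancer from hyperpolarized
[1-¹³C]pyruvate MRI, rebuilt as a tested, reusable Python pipeline.

Aggressive breast cancers (triple-negative, HER2⁺) upregulate glycolysis, and
the exchange of the hyperpolarized ¹³C label between injected pyruvate and
tumor lactate can be imaged in real time. After only 7–11 days of neoadjuvant
chemotherapy, the *change* in lactate labeling carries response information
that anatomical and perfusion MRI do not yet show. This package implements
the full analysis chain needed to study that signal, driven by a synthetic
data generator that emulates the acquisitions, so every stage is testable
without patient data.

## What it computes

**Two-pool exchange model.** Between excitations the longitudinal
magnetizations obey

    dMp/dt = −(kPL + R1p)·Mp + u(t)
    dMl/dt =  kPL·Mp − R1l·Ml

with a gamma-variate vascular input u(t). Acquisition uses interleaved
metabolite-specific excitation (15° pyruvate / 40° lactate pulses, TR 2 s,
4 s per frame): each pulse records sin(α)·Mz and costs the pool a factor
cos(α). Integration is by exact matrix exponential with Gauss–Legendre
quadrature of the bolus.

**¹³C metrics.** Time-summed SNR of pyruvate and lactate and the summed
lactate-to-pyruvate ratio (LAC/PYR), from sum-of-squares reconstructions,
as ROI means of voxelwise values; a spectral fallback path integrates
time-summed magnitude spectra when only dynamic spectra were acquired.

**kPL estimation.** The "inputless" fit: measured pyruvate drives a
discrete lactate forward model with flip-angle and relaxation correction,
and kPL is obtained by bound-constrained least squares. Because the model
is linear in kPL given the driver, the amplitude is fixed and the rate
carries the fit (see `docs/methods.md`).

**Proton-MRI stage.** IVIM biexponential fit (perfusion fraction f, tissue
diffusivity D, pseudo-diffusion D*) via a segmented fit with joint polish;
standard Tofts DCE fit (Ktrans, kep, ve); iAUC90; tumor volume.

**Response classification.** Percent change between baseline and the
day-7–11 scan, classified against fixed thresholds: responder iff
ΔLAC/PYR ≥ +20% (inclusive) or ΔkPL ≥ −15%. PARP-inhibitor-treated
patients are classified but stratified separately, since PARP inhibition
can raise lactate labeling regardless of response.

**Statistics & survival.** Pearson correlations, two-sided (paired) t
tests with no multiple-testing correction, and the large-cohort validation
stage: expression z-scoring, 85th-percentile dichotomization, Kaplan–Meier
curves and log-rank tests.

## Worked example

```python
import numpy as np
from hypermet import (AcquisitionScheme, ExchangeParams,
                      simulate_exchange, fit_kpl, run_pipeline)

scheme = AcquisitionScheme(n_frames=20)          # 15°/40°, TR 2 s, 4 s frames
series = simulate_exchange(ExchangeParams(k_pl=0.0064), scheme)
fit = fit_kpl(series.pyr_signal, series.lac_signal, scheme)
print(f"kPL = {fit.k_pl_hat:.5f} 1/s  (scale diagnostic {fit.scale:.3f})")

result = run_pipeline({"seed": 11})
print(result["summary"]["lacpyr"]["standard_of_care"])
```

prints

```
kPL = 0.00641 1/s  (scale diagnostic 1.000)
{'tp': 2, 'fp': 0, 'tn': 3, 'fn': 0, 'n_called': 5}
```

The fitted kPL recovers the planted 0.0064 s⁻¹ exchange rate to 0.2%, and
on a default synthetic 7-patient cohort (3 responders, 2 on PARP
inhibitor) the +20% LAC/PYR rule classifies every standard-of-care patient
correctly.

There is also a small CLI:

```bash
hypermet run --seed 17 --out results/      # metrics.csv, calls.csv, report.md
hypermet fit-kpl --pyr pyr.nii --lac lac.nii --roi mask.nii \
    --sidecar meta.json --out fits.csv
```

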
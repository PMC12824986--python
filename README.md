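# wnmr — benchtop water-proton NMR relaxometry analysis

Water-proton NMR relaxometry (wNMR) reads out the transverse relaxation
rate of the *solvent* water, R₂(¹H₂O), as a quality-control signal for
liquid pharmaceutical products — therapeutic proteins, aluminum-adjuvanted
vaccines — measured non-invasively in the sealed vial on compact benchtop
NMR instruments. This package implements the complete data-analysis chain
for a multi-laboratory CPMG relaxometry study, plus a synthetic multi-lab
study generator, so the whole analysis runs end to end with no external
data. It is aimed at analytical scientists evaluating wNMR for QC/QA and
at anyone building interlab comparison pipelines for echo-train
relaxometry.

## What it computes

A CPMG echo train decays as an offset mono-exponential,

    S(t) = A·exp(−α·t) + b,        α ≡ R₂(¹H₂O) = 1/T₂,

fitted by nonlinear least squares after correcting three instrument
artifacts: a zero-order quadrature phase rotation, a fast exponentially
damped sinusoid from eddy currents (induced e.g. in aluminum vial caps),
and constant-amplitude AC power-line oscillations visible as spikes in the
Fourier spectrum of the fit residual. On top of the per-vial rates:

* **Relaxivity calibration** per lab and sample class:
  R₂(C) = R₂,₀ + r₂·C, where the slope r₂ (relaxivity, (mg/mL)⁻¹·s⁻¹)
  measures how efficiently the solute relaxes water protons.
* **Interlab dispersion**: span (max−min) and CV = (σ/μ)·100% of the
  seven labs' relaxivities.
* **Freeze/thaw outlier detection**: %change = [1 − R₂(frozen)/R₂(unfrozen)]·100,
  flagged against the larger of a 10% line and an error band propagated
  from the calibration RMSD (freezing agglomerates adjuvant particles
  irreversibly and lowers R₂).
* **Negative controls**: ETFE particle series (susceptibility-matched to
  water) must show a relaxivity slope consistent with zero.

The synthetic generator emulates seven labs spanning realistic operating
ranges (interpulse delay τ = 250–6000 μs, 4–32 scans, 25–33 °C, dense
time-domain echo grids or a sparse 17-point frequency-domain-style grid),
with per-lab artifact profiles and complex Gaussian thermal noise.

## Worked example

```python
from wnmr import (default_models, default_manifest, default_profiles,
                  simulate_decay, correct_trace, fit_monoexponential, true_r2)

models, kit, labs = default_models(), default_manifest(), default_profiles()
vial = kit.by_code("S09")            # blinded 1.25 mg/mL Alhydrogel vial
trace = simulate_decay(models[vial.sample_class], vial, labs[0], seed=7)
corrected, report = correct_trace(trace)
fit = fit_monoexponential(corrected)
```

This prints (via the fields of `report` and `fit`):

```
phase angle      : +0.0201 rad
eddy transient   : amp 0.98, rate 86 /s
AC spikes        : [(60.0, 1187.1)]
noise sd         : 0.288
R2(1H2O)         : 1.5122 +/- 0.0006 s^-1   (T2 = 0.661 s)
amplitude, offset: 99.96, 0.997
```

The corrected fit recovers the vial's true rate (0.35 + 0.93·1.25 =
1.5125 s⁻¹) to 0.02%, identifies the small phase rotation this lab
profile applies (0.02 rad), and reports the 60 Hz line pickup in the
residual spectrum. The same machinery runs at study scale from the shell:

```sh
wnmr simulate --seed 1 --out study_dir      # 7 labs x 24 vials of CSV decays
wnmr run --seed 1 --out out_dir             # simulate + correct + fit + report
```

The numbered scripts under `analysis/` walk through the study narrative:
`01_simulate_study.py` (generate the blinded kit for all labs),
`02_artifact_corrections.py` (how much each correction moves R₂),
`03_interlab_relaxivity.py` (calibrations, span, CV, the settled-vial
outlier lab), `04_freeze_thaw_controls.py` (stress detection and control
rates). Each writes its tables under `results/`.

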
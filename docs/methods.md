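# Methods

## Signal model

A CPMG echo train samples the transverse magnetization envelope at the
echo times t_k = 2τk (τ the interpulse delay, k = 1..n). For
predominantly aqueous, single-environment samples the envelope is an
offset mono-exponential

    S(t) = A·exp(−α t) + b,

with A the echo intensity extrapolated to t = 0, α ≡ R₂(¹H₂O) = 1/T₂ the
water-proton transverse relaxation rate (s⁻¹), and b a constant offset
absorbing signals that decay to nonzero values. The offset is always
estimated, never pinned to zero. Fits use the real channel after phase
correction, not the magnitude: under noise the magnitude has a Rician
floor that biases b (and through it α), while the phased real channel
keeps Gaussian, zero-mean errors.

The fit is unweighted nonlinear least squares (Levenberg–Marquardt via
`scipy.optimize.least_squares` with an analytic Jacobian); optional
inverse-variance weights are accepted. Convergence tolerances (relative
parameter/cost/gradient 1e-12, 200 function evaluations) live in one
`FitConfig` object. Starting values: b₀ = mean of the last 5% of points,
A₀ = first point − b₀, α₀ from a log-linear regression of (S − b₀)
restricted to points at least 3 robust-sd above the tail noise floor. A
signal with no resolvable decay raises a flat-signal error; a fit ending
at α ≤ 0 or hitting the iteration budget is returned flagged, not raised.
Parameter standard errors come from the Jacobian at the optimum scaled by
the residual variance (n − 3 dof).

Departure from mono-exponential behaviour is scored as
residual RMS / noise sd; ratios above 2 suggest multi-exponential
relaxation. Multi-exponential decomposition itself (inverse-Laplace,
stretched exponentials) is out of scope.

## Artifact model and corrections

Three artifact classes are modelled, matching what benchtop instruments
show in practice:

1. **Zero-order phase.** Imperfect 180° pulses rotate signal between the
   quadrature channels by a small global angle φ. The estimator is the
   closed form φ = atan2(Σ w·Im s, Σ w·Re s) with magnitude weights
   w = |s| over the first half of the points (the high-SNR window);
   correction multiplies by exp(−iφ). Only a global (zero-order) phase is
   sensible — echo-train data has no frequency axis for a first-order
   term. Real-only submissions skip the step with a flag. Rotations this
   small scale the real channel by cos φ ≈ 1, so the correction moves α
   only through the noise realization: the measured RMS shift for
   |φ| ≤ 0.05 rad is ~0.001%, consistent with a "well below 0.1%" bound.

2. **Eddy-current transient.** Conductive parts (notably aluminum vial
   caps) ring down as an exponentially damped sinusoid
   a·exp(−r t)·sin(2πf t + θ) much faster than the water decay. The
   pipeline fits this model to the residual of the mono-exponential fit
   on an early-time window (the larger of the first 10% of points and
   t < 5 ms; configurable), then subtracts and refits once. The
   four-parameter form and its initialization are this package's own
   convention. Nonlinear fitting is multi-started over frequency
   candidates from the dominant FFT bin (±1) of both the full window and
   a short early sub-window — the sub-window matters because a transient
   spanning a handful of echoes is spectrally buried under persistent
   tones — and over two damping-rate starts. Solutions that do not decay
   within the window (r·span < 2) are disfavoured: a persistent tone is
   not an eddy transient. The pipeline subtracts only when the fitted
   amplitude exceeds twice the robust residual noise; this guard keeps
   the sequence idempotent (a second pass moves α by < 0.01%) and stops
   the corrector from chasing noise on clean traces. With amplitudes up
   to 2% of A the measured RMS α shift is ≪ 5%.

   Identifiability caveat: on a coarse echo grid (dt = 2τ comparable to
   the ringdown time) only a few samples carry the transient, so the
   fitted (a, r, f, θ) are individually poorly determined — aliasing maps
   f onto the grid's Nyquist band and amplitude/rate trade off — but the
   *sampled* model values, which are what get subtracted, are well
   determined.

3. **AC power-line pickup.** Constant-amplitude mains oscillations are
   invisible in the decay but appear as narrow spikes in the magnitude
   spectrum of the fit residual. Bins exceeding median + k·(1.4826·MAD)
   of the spectrum (k = 5, DC excluded) are reported sorted by magnitude.
   Spikes are reported, not filtered, by default — centered at zero they
   perturb the fit like thermal noise of equal power (a property the test
   suite checks) — with an optional notch that zeroes flagged bins and
   inverse-transforms. Detection requires a uniform grid; non-uniform
   (sparse frequency-domain) traces are skipped with a flag, never
   silently resampled. The false-positive calibration (< 5% of clean
   traces flagging anything) is stated for ~1024-point residuals
   (~512 bins); much longer traces test more bins and the familywise rate
   rises accordingly.

Thermal noise is estimated as 1.4826·MAD of the final fit residual,
pooling both quadrature channels when present (each centered on its
median), which tolerates gross outliers and residual artifact energy.

## Study statistics

Relaxivity calibrations are unweighted OLS lines of R₂ against
concentration per lab and sample class (statsmodels); buffer vials enter
the NISTmAb series as 0 mg/mL points; freeze/thaw-stressed vials are
excluded from calibration. The reported rmsd is the RMS of measured minus
fitted R₂ — the study's practical error estimate, encapsulating
instrument, handling and operational error. For the slope's standard
error, two routes exist: when every point carries an R₂ standard error
from its decay fit, those known variances are propagated through the OLS
slope (Var(b) = Σ(x−x̄)²se²/Sxx²); otherwise the residual-based OLS
formula is used (absent for 2-point fits). The propagated route keeps the
zero-slope control criterion |slope| ≤ 2·slope_se calibrated near the
nominal ~95% for short series — with only 5 concentrations the
residual-based se turns it into a heavy-tailed t(3) criterion that false-
alarms ~14% of the time.

Across labs, dispersion per class is the span (max − min) and
CV = (σ/μ)·100 with the sample (n−1) standard deviation by default
(population sd via a flag). Freeze/thaw assessment computes
%change = (1 − R₂,frozen/R₂,unfrozen)·100 (positive = decrease, the
expected direction for agglomerated adjuvant); the flag fires when
|%change| exceeds the larger of the fixed 10% threshold and the
calibration rmsd projected onto the ratio scale (100·rmsd/R₂,unfrozen).
Duplicate submissions for the same (lab, vial) resolve to the later
record and are logged as anomalies; a stressed vial without an unstressed
mate is reported unassessable rather than fatal.

## Synthetic study generator

The generator is the package's data source and defines its reference
conditions. Per trace:

    s(t_k) = [A·exp(−R₂ t) + b + eddy(t) + ac(t) + ε(t)]·exp(iφ),

with ε complex Gaussian, per-component sd = noise_sd/√n_scans, fully
reproducible from a seed (study-level runs derive per-trace streams from
SeedSequence(study seed, profile index, entry index)). SNR is defined as
A/noise_sd; the defaults A = 100, b = 1, noise_sd = 1 give the reference
SNR 100.

Ground truth per class follows R₂(C) = R₂,₀ + r₂C with the interlab mean
relaxivities as the class defaults — NISTmAb 8.77×10⁻³, Alhydrogel (AH)
0.93, Adju-Phos (AP) 1.98 (mg/mL)⁻¹s⁻¹ — and zero for ETFE particles and
buffer. The intercept defaults to R₂,₀ = 0.35 s⁻¹, a convention for
dilute aqueous buffer near room temperature (intercepts are
configuration, not an anchored quantity). Freeze/thaw stress multiplies
R₂ by (1 − δ) with δ = 0.15, placing the expected change at 15% so the
10% detection line is exercised with margin but not trivially. A
profile's `settled_factor < 1` scales adjuvant relaxivity down before
simulation, emulating an operator who did not invert the vial and
measured a partially settled suspension.

The seven default lab profiles span the operating ranges benchtop
instruments actually used: τ from 250 to 6000 μs, 4–32 scans, 25–33 °C,
echo counts from 1000 to 12000, two labs submitting real-only (2-column)
data, and one frequency-domain lab contributing only 17 hand-picked
points (emulated as log-spaced sparse sampling of the same
mono-exponential; no spectral integration is modelled). Three labs carry
eddy transients (amplitudes ≤ 2% of A, ringdown ~1 ms), four carry phase
offsets up to 0.05 rad, three carry 50/60 Hz pickup below the thermal
noise floor. The defaults describe a fully compliant study; the
settled-vial outlier labs are introduced explicitly where the analysis
examines them.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: genuine between-lab differences in true
R₂ (field-strength and temperature dependence, sample equilibration), so
the simulated interlab CV reflects measurement error only (< 1%) rather
than the tens-of-percent operational spread seen across real instruments;
sedimentation kinetics during acquisition; B₀/B₁ inhomogeneity and pulse
miscalibration (artifacts enter phenomenologically, not via Bloch
dynamics); multi-exponential relaxation; shipping effects.

## Problem sizes and numerical choices

Replicated experiments use 100 traces per condition (recovery, control
rates), 40-trace sweeps for correction impact, and the full 7×24 study
for end-to-end analysis — sizes at which every reported rate is stable to
a few percent while a complete run stays in the minutes range on one
core. Oracle cross-checks compare the NLS optimum against a profiled grid
search over α (A, b solved linearly per grid point, step 1e-4 s⁻¹) and
the closed-form phase estimator against a 1-D grid (step 1e-5 rad) on 20
seeded instances each.

Ties and degenerate inputs: out-of-order time rows are sorted and
flagged, not rejected; duplicate AC spike magnitudes keep spectral order;
a flat residual yields an amplitude-0 eddy model; zero noise with nonzero
residual yields an infinite departure ratio, flagged. Display rounding is
3 significant figures; all comparisons in tests use unrounded values.

## Known limitations

* The eddy model is a single damped sinusoid; overlapping multi-component
  ringdowns would be absorbed only approximately.
* The eddy/AC separation is heuristic (transient-preference rule); a very
  strong mains tone inside the fit window can still bias the transient
  fit on dense grids.
* The zero-slope verdict needs per-point standard errors to be well
  calibrated on 5-point series; without them it is anti-conservative.
* Sparse non-uniform grids forgo AC detection and eddy correction
  entirely (flagged); with 17 points there is no residual bandwidth to
  support them.
* R₂ is temperature-dependent but temperatures are metadata only; no
  normalization across labs is attempted.
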
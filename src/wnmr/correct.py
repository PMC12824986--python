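"""Artifact detection and removal ahead of exponential fitting.

Three artifact classes affect benchtop CPMG decays:

* a small zero-order quadrature phase rotation (many imperfect 180-degree
  pulses leak real-channel signal into the imaginary channel),
* a fast exponentially damped sinusoid from eddy currents induced in
  conductive parts such as aluminum vial caps (sub-millisecond transient),
* constant-amplitude AC power-line oscillations, invisible in the decay
  but appearing as spikes in the Fourier spectrum of the fit residual.

The standard correction sequence is: estimate/apply the global phase, fit
the mono-exponential, fit the damped sinusoid on the early-time residual,
subtract it, refit.  AC spikes are reported (optionally notch-filtered)
and thermal noise is estimated robustly from the final residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, InsufficientDataError
from .io import DecayTrace
from .relaxfit import FitConfig, FitResult, correction_impact, fit_monoexponential
from .synth import EddyCurrentModel

__all__ = [
    "CorrectionReport",
    "estimate_phase",
    "apply_phase",
    "fit_eddy_current",
    "subtract_eddy",
    "detect_ac_artifacts",
    "estimate_noise",
    "correct_trace",
]


@dataclass(frozen=True)
class CorrectionReport:
    """What was found and removed from one trace, and what it changed."""

    phase_angle: float  # radians, in (-pi, pi]
    eddy: EddyCurrentModel | None
    ac_spikes: tuple[tuple[float, float], ...] | None  # (frequency Hz, magnitude)
    noise_sd: float
    r2_shift_phase: float  # % change of fitted R2 from phase correction
    r2_shift_eddy: float  # % change of fitted R2 from eddy correction
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if not (-math.pi < self.phase_angle <= math.pi):
            raise ValueError(f"phase_angle {self.phase_angle} outside (-pi, pi]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _wrap_phase(phi: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    phi = (phi + math.pi) % (2.0 * math.pi) - math.pi
    if phi == -math.pi:
        phi = math.pi
    return phi


def estimate_phase(trace: DecayTrace, window_frac: float = 0.5) -> float:
    """Zero-order phase of a quadrature trace, radians.

    Closed form phi = atan2(sum(imag*w), sum(real*w)) with magnitude
    weights w = |signal|, evaluated over the high-SNR early window (first
    half of the points by default).  Real-only traces return 0.0 (phase
    correction is not applicable to them).
    """
    if not trace.is_quadrature:
        return 0.0
    n = max(3, int(round(window_frac * trace.n_points)))
    s = trace.signal[:n]
    w = np.abs(s)
    return _wrap_phase(math.atan2(float(np.sum(s.imag * w)), float(np.sum(s.real * w))))


def apply_phase(trace: DecayTrace, phi: float) -> DecayTrace:
    """Rotate the signal by exp(-i*phi); applying phi then -phi is identity."""
    if phi == 0.0:
        return trace
    signal = trace.signal * np.exp(-1j * phi)
    is_quad = trace.is_quadrature or bool(np.any(signal.imag != 0.0))
    return replace(trace, signal=signal, is_quadrature=is_quad)


# ---------------------------------------------------------------------------
# eddy currents


def _eddy_window(residual: DecayTrace, window: float | None) -> int:
    """Number of leading points in the eddy-fit window.

    Default: the larger of the first 10% of points and t < 5 ms — eddy
    transients live on the sub-millisecond scale, far faster than water.
    """
    t = residual.time
    if window is not None:
        n_win = int(np.sum(t <= window))
    else:
        n_win = max(int(np.sum(t < 5e-3)), int(np.ceil(0.1 * t.size)))
    return n_win


def fit_eddy_current(residual: DecayTrace, window: float | None = None) -> EddyCurrentModel:
    """Fit amp*exp(-rate*t)*sin(2*pi*f*t + phase) to the early residual.

    ``residual`` is the trace minus the current best mono-exponential
    model.  The frequency is multi-started from the dominant FFT bin of
    the windowed residual plus its +/- 2 neighbours; the best nonlinear
    least-squares solution is returned, with phase wrapped to (-pi, pi]
    and amplitude nonnegative.  A flat residual yields an amplitude ~0
    model.
    """
    n_win = _eddy_window(residual, window)
    if n_win < 6:
        raise InsufficientDataError(
            f"eddy-fit window has {n_win} points; need at least 6"
        )
    t = residual.time[:n_win]
    y = residual.real[:n_win]
    span = float(t[-1] - t[0])

    rms = float(np.sqrt(np.mean(y**2)))
    if rms < 1e-300:
        return EddyCurrentModel(0.0, decay_rate=1.0 / span, frequency=0.0, phase=0.0)

    # Frequency candidates: dominant FFT bin (+/- 1 bin) of the full window
    # and of a short early sub-window.  The sub-window matters when the
    # transient only spans the first few echoes: its energy is then buried
    # below persistent tones (AC pickup) in the full-window spectrum.
    dt = float(np.median(np.diff(t)))

    def _fft_candidates(seg: np.ndarray) -> list[float]:
        if seg.size < 4:
            return []
        m = np.abs(np.fft.rfft(seg - np.mean(seg)))
        fr = np.fft.rfftfreq(seg.size, dt)
        if m.size <= 1:
            return []
        k0 = int(np.argmax(m[1:])) + 1
        df_ = fr[1]
        return [max(fr[k0] + k * df_, 0.5 * df_) for k in (-1, 0, 1)]

    candidates = _fft_candidates(y)
    n_sub = min(t.size, max(8, int(np.sum(t < 5e-3))))
    candidates += _fft_candidates(y[:n_sub])
    if not candidates:
        candidates = [1.0 / span]

    amp0 = max(math.sqrt(2.0) * rms, float(np.max(np.abs(y))))
    sub_span = float(t[min(n_sub, t.size) - 1] - t[0]) or span
    rate_starts = sorted({3.0 / span, 2.0 / sub_span})

    def resid(p):
        a, r, f, ph = p
        return a * np.exp(-r * t) * np.sin(2.0 * np.pi * f * t + ph) - y

    solutions = []
    seen = set()
    for f0 in candidates:
        for r0 in rate_starts:
            for ph0 in (0.0, math.pi / 2.0):
                key = (round(f0, 9), round(r0, 9), ph0)
                if key in seen:
                    continue
                seen.add(key)
                try:
                    sol = least_squares(
                        resid, [amp0, r0, f0, ph0],
                        bounds=([0.0, 1e-12, 0.0, -2.0 * math.pi],
                                [np.inf, np.inf, np.inf, 2.0 * math.pi]),
                        xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=400,
                    )
                except ValueError:
                    continue
                solutions.append(sol)

    # an eddy signature must decay within the fit window; prefer such
    # transient solutions over persistent-tone fits of equal/lower cost
    transient = [s for s in solutions if s.x[1] * span >= 2.0]
    pool = transient or solutions
    best = min(pool, key=lambda s: s.cost)
    a, r, f, ph = best.x
    return EddyCurrentModel(
        amplitude=float(a), decay_rate=float(r), frequency=float(f),
        phase=_wrap_phase(float(ph)),
    )


def subtract_eddy(trace: DecayTrace, model: EddyCurrentModel) -> DecayTrace:
    """Subtract the damped-sinusoid model from the real channel."""
    if model.amplitude == 0.0:
        return trace
    signal = (trace.real - model(trace.time)) + 1j * trace.imag
    return trace.with_signal(signal, is_quadrature=trace.is_quadrature)


# ---------------------------------------------------------------------------
# AC power-line artifacts and noise


def _check_uniform(time: np.ndarray) -> float:
    dt = np.diff(time)
    dt0 = float(np.median(dt))
    bad = np.flatnonzero(~np.isclose(dt, dt0, rtol=1e-6, atol=0.0))
    if bad.size:
        head = ", ".join(
            f"[{i}->{i + 1}]: {dt[i]:.6g}s" for i in bad[:5]
        )
        raise DomainError(
            f"non-uniform time grid (median step {dt0:.6g}s); offending "
            f"intervals {head}" + (" ..." if bad.size > 5 else "")
        )
    return dt0


def detect_ac_artifacts(
    residual: DecayTrace, threshold_k: float = 5.0
) -> list[tuple[float, float]]:
    """Spectral spikes of the residual, as (frequency Hz, magnitude) pairs.

    AC power-line pickup is invisible in the decay but shows up as narrow
    spikes in the residual's magnitude spectrum.  Bins exceeding
    median + threshold_k * (scaled MAD) are reported, DC excluded, sorted
    by magnitude descending.  Requires a uniform grid; callers must
    resample non-uniform data explicitly first.
    """
    dt = _check_uniform(residual.time)
    y = residual.real
    mags = np.abs(np.fft.rfft(y))
    freqs = np.fft.rfftfreq(y.size, dt)
    mags, freqs = mags[1:], freqs[1:]  # drop DC
    med = float(np.median(mags))
    mad = 1.4826 * float(np.median(np.abs(mags - med)))
    cut = med + threshold_k * mad
    idx = np.flatnonzero(mags > cut)
    order = idx[np.argsort(mags[idx])[::-1]]
    return [(float(freqs[i]), float(mags[i])) for i in order]


def estimate_noise(residual: DecayTrace) -> float:
    """Robust per-point noise sd: 1.4826 * MAD of the fit residual.

    Quadrature residuals pool both channels (each centered on its median).
    """
    chans = [residual.real]
    if residual.is_quadrature:
        chans.append(residual.imag)
    pooled = np.concatenate([c - np.median(c) for c in chans])
    return 1.4826 * float(np.median(np.abs(pooled)))


# ---------------------------------------------------------------------------
# full correction pipeline


def _residual_trace(trace: DecayTrace, fit: FitResult) -> DecayTrace:
    resid = trace.real - (fit.amplitude * np.exp(-fit.alpha * trace.time) + fit.offset)
    return replace(trace, signal=resid.astype(complex), is_quadrature=False)


def correct_trace(
    trace: DecayTrace,
    *,
    phase: bool = True,
    eddy: bool = True,
    detect_ac: bool = True,
    notch: bool = False,
    threshold_k: float = 5.0,
    eddy_window: float | None = None,
    fit_config: FitConfig | None = None,
) -> tuple[DecayTrace, CorrectionReport]:
    """Run the full correction sequence on one trace.

    Order: phase -> mono-exponential fit -> eddy fit on the early residual
    -> subtract (one iteration) -> refit -> AC-spike report and noise
    estimate from the final residual.  The fitted damped sinusoid is only
    subtracted when its amplitude exceeds twice the robust residual noise,
    which keeps the pipeline idempotent on clean traces.
    """
    flags: list[str] = []

    phi = 0.0
    corrected = trace
    r2_shift_phase = 0.0
    if phase and trace.is_quadrature:
        phi = estimate_phase(trace)
        corrected = apply_phase(trace, phi)
        fit_raw = fit_monoexponential(trace, config=fit_config)
        fit0 = fit_monoexponential(corrected, config=fit_config)
        if fit_raw.converged and fit0.converged:
            r2_shift_phase = correction_impact(fit_raw, fit0)
    else:
        if phase and not trace.is_quadrature:
            flags.append("phase_not_applicable")
        fit0 = fit_monoexponential(corrected, config=fit_config)

    eddy_model: EddyCurrentModel | None = None
    r2_shift_eddy = 0.0
    fit_final = fit0
    if eddy:
        residual = _residual_trace(corrected, fit0)
        try:
            candidate = fit_eddy_current(residual, window=eddy_window)
        except (InsufficientDataError, DomainError):
            candidate = None
            flags.append("eddy_fit_skipped")
        if candidate is not None:
            noise_now = estimate_noise(residual)
            if candidate.amplitude > 2.0 * noise_now and candidate.amplitude > 0:
                eddy_model = candidate
                corrected = subtract_eddy(corrected, eddy_model)
                fit_final = fit_monoexponential(
                    corrected, guess=(fit0.amplitude, fit0.alpha, fit0.offset),
                    config=fit_config,
                )
                r2_shift_eddy = correction_impact(fit0, fit_final)
            else:
                flags.append("eddy_negligible")

    final_residual = _residual_trace(corrected, fit_final)
    noise_input = replace(
        final_residual,
        signal=final_residual.real + 1j * corrected.imag,
        is_quadrature=corrected.is_quadrature,
    )
    noise_sd = estimate_noise(noise_input)

    spikes: tuple[tuple[float, float], ...] | None = None
    if detect_ac:
        try:
            spikes = tuple(detect_ac_artifacts(final_residual, threshold_k=threshold_k))
        except DomainError:
            spikes = None
            flags.append("ac_detection_skipped_nonuniform")
        if notch and spikes:
            corrected = _notch_filter(corrected, fit_final, spikes)

    report = CorrectionReport(
        phase_angle=_wrap_phase(phi),
        eddy=eddy_model,
        ac_spikes=spikes,
        noise_sd=noise_sd,
        r2_shift_phase=r2_shift_phase,
        r2_shift_eddy=r2_shift_eddy,
        flags=tuple(flags),
    )
    return corrected, report


def _notch_filter(
    trace: DecayTrace, fit: FitResult, spikes: tuple[tuple[float, float], ...]
) -> DecayTrace:
    """Zero flagged residual bins and rebuild the real channel."""
    dt = _check_uniform(trace.time)
    model = fit.amplitude * np.exp(-fit.alpha * trace.time) + fit.offset
    resid = trace.real - model
    spec = np.fft.rfft(resid)
    freqs = np.fft.rfftfreq(resid.size, dt)
    for f, _ in spikes:
        spec[int(np.argmin(np.abs(freqs - f)))] = 0.0
    filtered = np.fft.irfft(spec, n=resid.size)
    signal = (model + filtered) + 1j * trace.imag
    return trace.with_signal(signal, is_quadrature=trace.is_quadrature)
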
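import math

import numpy as np
import pytest

from wnmr.correct import (
    apply_phase,
    correct_trace,
    detect_ac_artifacts,
    estimate_noise,
    estimate_phase,
    fit_eddy_current,
    subtract_eddy,
)
from wnmr.errors import DomainError, InsufficientDataError
from wnmr.io import ManifestEntry
from wnmr.relaxfit import fit_monoexponential
from wnmr.synth import EddyCurrentModel, LabProfile, TrueRelaxationModel, simulate_decay

from conftest import decay_trace, make_trace
from oracles import dft_magnitudes, grid_search_phase


class TestPhase:
    def test_real_only_trace_returns_zero(self):
        tr = decay_trace(alpha=2.0, quadrature=False)
        assert estimate_phase(tr) == 0.0

    def test_purely_real_positive_decay_has_zero_phase(self):
        tr = decay_trace(alpha=2.0, quadrature=True)
        assert estimate_phase(tr) == pytest.approx(0.0, abs=1e-12)

    def test_clean_rotation_recovered(self):
        tr = apply_phase(decay_trace(alpha=2.0, quadrature=True), -np.pi / 6)
        assert estimate_phase(tr) == pytest.approx(np.pi / 6, abs=1e-9)

    def test_noisy_rotation_matches_grid_search(self):
        tr = decay_trace(alpha=2.0, noise_sd=1.0, seed=7)  # SNR 100
        rotated = apply_phase(tr, -0.3)
        phi_grid = grid_search_phase(rotated.signal, step=1e-5)
        assert estimate_phase(rotated) == pytest.approx(phi_grid, abs=1e-4)

    def test_apply_zero_is_identity(self):
        tr = decay_trace(alpha=2.0, quadrature=True)
        assert apply_phase(tr, 0.0) is tr

    def test_apply_then_invert_round_trips(self):
        tr = decay_trace(alpha=2.0, noise_sd=0.5, seed=1)
        back = apply_phase(apply_phase(tr, 0.4), -0.4)
        assert back.signal == pytest.approx(tr.signal, rel=1e-12)

    def test_correction_suppresses_imaginary_channel(self):
        tr = decay_trace(alpha=2.0, noise_sd=0.1, seed=3)
        rotated = apply_phase(tr, -np.pi / 12)
        corrected = apply_phase(rotated, estimate_phase(rotated))
        imag_rms = np.sqrt(np.mean(corrected.imag**2))
        real_rms = np.sqrt(np.mean(corrected.real**2))
        assert imag_rms < 0.01 * real_rms


class TestEddyFit:
    def test_exact_damped_sinusoid_recovered(self):
        t = np.linspace(1e-5, 4e-3, 400)
        truth = EddyCurrentModel(0.05, 1000.0, 5000.0, 0.0)
        resid = make_trace(t, truth(t))
        m = fit_eddy_current(resid, window=4e-3)
        assert m.amplitude == pytest.approx(truth.amplitude, rel=1e-6)
        assert m.decay_rate == pytest.approx(truth.decay_rate, rel=1e-6)
        assert m.frequency == pytest.approx(truth.frequency, rel=1e-6)
        assert m(t) == pytest.approx(truth(t), abs=1e-9 * truth.amplitude)

    def test_zero_residual_gives_zero_amplitude(self):
        t = np.linspace(1e-5, 4e-3, 100)
        m = fit_eddy_current(make_trace(t, np.zeros_like(t)), window=4e-3)
        assert m.amplitude < 1e-12

    def test_noisy_residual_frequency_within_one_bin(self):
        rng = np.random.default_rng(3)
        t = np.linspace(1e-5, 4e-3, 400)
        truth = EddyCurrentModel(0.05, 1000.0, 5000.0, 0.3)
        y = truth(t) + rng.normal(0, 0.05 / 20.0, t.size)  # SNR 20
        m = fit_eddy_current(make_trace(t, y), window=4e-3)
        bin_width = 1.0 / (t[-1] - t[0])
        assert abs(m.frequency - truth.frequency) < bin_width

    def test_tiny_window_rejected(self):
        t = np.linspace(1e-3, 1.0, 20)
        with pytest.raises(InsufficientDataError):
            fit_eddy_current(make_trace(t, np.zeros(20)), window=5e-3)

    def test_subtract_zero_model_is_identity(self):
        tr = decay_trace(alpha=2.0)
        m = EddyCurrentModel(0.0, 1000.0, 100.0)
        assert subtract_eddy(tr, m) is tr

    def test_subtract_then_readd_round_trips(self):
        tr = decay_trace(alpha=2.0, noise_sd=0.2, seed=5)
        m = EddyCurrentModel(1.0, 800.0, 300.0, 0.1)
        sub = subtract_eddy(tr, m)
        readd = sub.with_signal(sub.real + m(sub.time) + 1j * sub.imag)
        assert readd.signal == pytest.approx(tr.signal, rel=1e-12)


class TestACDetection:
    def _residual(self, n=1024, dt=1e-3, noise_sd=0.01, seed=0, tones=()):
        rng = np.random.default_rng(seed)
        t = dt * np.arange(1, n + 1)
        y = rng.normal(0, noise_sd, n)
        for freq, amp in tones:
            y = y + amp * np.sin(2 * np.pi * freq * t)
        return make_trace(t, y)

    def test_white_noise_rarely_flags(self):
        hits = sum(
            bool(detect_ac_artifacts(self._residual(seed=s)))
            for s in range(100)
        )
        assert hits < 5  # < 5% false-positive rate per trace

    def test_single_60hz_tone_detected(self):
        spikes = detect_ac_artifacts(
            self._residual(seed=11, tones=[(60.0, 0.1)]))  # 10x noise sd
        assert len(spikes) >= 1
        bin_width = 1.0 / (1024 * 1e-3)
        assert abs(spikes[0][0] - 60.0) <= bin_width

    def test_two_tones_sorted_by_magnitude(self):
        # tones centered on DFT bins so each occupies a single bin
        bin_w = 1.0 / (1024 * 1e-3)
        f_lo, f_hi = 51 * bin_w, 154 * bin_w  # ~50 Hz and ~150 Hz
        spikes = detect_ac_artifacts(
            self._residual(seed=2, tones=[(f_lo, 0.08), (f_hi, 0.2)]))
        assert len(spikes) == 2
        assert abs(spikes[0][0] - f_hi) <= bin_w
        assert abs(spikes[1][0] - f_lo) <= bin_w
        assert spikes[0][1] > spikes[1][1]

    def test_magnitudes_match_direct_dft(self):
        resid = self._residual(seed=4, tones=[(60.0, 0.2)])
        spikes = detect_ac_artifacts(resid)
        freqs, mags = dft_magnitudes(resid.real, 1e-3)
        for f, m in spikes:
            k = int(np.argmin(np.abs(freqs - f)))
            assert m == pytest.approx(mags[k], rel=1e-9)

    def test_non_uniform_grid_refused_with_interval(self):
        t = np.array([1e-3, 2e-3, 3e-3, 5e-3, 6e-3, 7e-3, 8e-3, 9e-3])
        with pytest.raises(DomainError, match="interval"):
            detect_ac_artifacts(make_trace(t, np.zeros(t.size)))


class TestNoiseEstimate:
    def test_zero_residual(self):
        t = np.linspace(1e-3, 1.0, 100)
        assert estimate_noise(make_trace(t, np.zeros(100))) == 0.0

    def test_gaussian_residual_recovered(self):
        rng = np.random.default_rng(5)
        t = np.linspace(1e-3, 1.0, 1000)
        est = estimate_noise(make_trace(t, rng.normal(0, 0.01, 1000)))
        assert est == pytest.approx(0.01, rel=0.1)

    def test_robust_to_gross_outlier(self):
        rng = np.random.default_rng(6)
        t = np.linspace(1e-3, 1.0, 1000)
        y = rng.normal(0, 0.01, 1000)
        clean = estimate_noise(make_trace(t, y))
        y2 = y.copy()
        y2[500] = 100.0
        dirty = estimate_noise(make_trace(t, y2))
        assert abs(dirty - clean) / clean < 0.05

    def test_quadrature_pools_both_channels(self):
        rng = np.random.default_rng(8)
        t = np.linspace(1e-3, 1.0, 2000)
        tr = make_trace(t, rng.normal(0, 0.02, 2000), rng.normal(0, 0.02, 2000))
        assert estimate_noise(tr) == pytest.approx(0.02, rel=0.1)


class TestCorrectionPipeline:
    model = TrueRelaxationModel(r2_0=0.35, relaxivity=0.93)
    sample = ManifestEntry("S1", "AH", 1.25)
    profile = LabProfile(
        "L", tau=500e-6, n_echoes=4000, n_scans=16, noise_sd=1.0,
        eddy=EddyCurrentModel(1.8, 900.0, 240.0, 0.0),
        phase_offset=0.03, ac_amplitude=0.2, ac_freq=60.0,
    )

    def test_eddy_correction_does_not_increase_residual_rms(self):
        tr = simulate_decay(self.model, self.sample, self.profile, seed=9)
        phased = apply_phase(tr, estimate_phase(tr))
        fit_before = fit_monoexponential(phased)
        corrected, report = correct_trace(tr)
        fit_after = fit_monoexponential(corrected)
        assert report.eddy is not None
        assert fit_after.residual_rms <= fit_before.residual_rms

    def test_pipeline_is_idempotent(self):
        tr = simulate_decay(self.model, self.sample, self.profile, seed=10)
        once, _ = correct_trace(tr)
        fit_once = fit_monoexponential(once)
        twice, _ = correct_trace(once)
        fit_twice = fit_monoexponential(twice)
        change = 100.0 * abs(fit_twice.alpha - fit_once.alpha) / fit_once.alpha
        assert change < 0.01

    def test_report_fields_populated(self):
        tr = simulate_decay(self.model, self.sample, self.profile, seed=11)
        _, report = correct_trace(tr)
        assert report.phase_angle == pytest.approx(0.03, abs=2e-3)
        assert report.noise_sd == pytest.approx(1.0 / math.sqrt(16), rel=0.15)
        assert report.ac_spikes is not None and len(report.ac_spikes) >= 1
        assert abs(report.ac_spikes[0][0] - 60.0) < 1.0

    def test_sparse_trace_skips_eddy_and_ac_with_flags(self):
        sparse = LabProfile("FD", tau=3000e-6, n_echoes=1200, n_scans=4,
                            mode="frequency_domain", quadrature=False)
        tr = simulate_decay(self.model, self.sample, sparse, seed=12)
        _, report = correct_trace(tr)
        assert "eddy_fit_skipped" in report.flags
        assert "ac_detection_skipped_nonuniform" in report.flags
        assert "phase_not_applicable" in report.flags
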
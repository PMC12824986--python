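import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wnmr.errors import DomainError, IntegrityError
from wnmr.io import ManifestEntry
from wnmr.relaxfit import FitResult, fit_monoexponential
from wnmr.study import (
    RelaxivityFit,
    assess_outlier,
    build_report,
    cv_from_stats,
    fit_relaxivity,
    freeze_thaw_change,
    relaxivity_cv,
    slope_span,
    zero_slope_test,
)
from wnmr.synth import (
    LabProfile,
    TrueRelaxationModel,
    default_manifest,
    default_models,
    simulate_decay,
    simulate_study,
)


def _fit(alpha, converged=True):
    return FitResult(amplitude=100.0, alpha=alpha, offset=1.0, param_se=None,
                     residual_rms=0.0, n_points=100, converged=converged)


class TestFitRelaxivity:
    def test_exact_line(self):
        pts = [(c, 0.3 + 2.0 * c) for c in (0.5, 1.0, 2.0, 4.0)]
        f = fit_relaxivity(pts)
        assert f.slope == pytest.approx(2.0, rel=1e-12)
        assert f.intercept == pytest.approx(0.3, rel=1e-12)
        assert f.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_two_points_exact_interpolation(self):
        f = fit_relaxivity([(1.0, 2.3), (2.0, 4.3)])
        assert f.slope == pytest.approx(2.0)
        assert f.rmsd == 0.0
        assert f.slope_se is None

    def test_equal_concentrations_rejected(self):
        with pytest.raises(DomainError):
            fit_relaxivity([(1.0, 2.0), (1.0, 2.1), (1.0, 1.9)])

    def test_simulated_series_recovers_slope(self):
        """AH series over 100 seeds: mean fitted slope within 1% of truth."""
        model = TrueRelaxationModel(r2_0=0.35, relaxivity=0.93)
        profile = LabProfile("L", tau=2000e-6, n_echoes=1500, n_scans=1,
                             noise_sd=1.0)  # SNR 100
        concs = (0.31, 0.63, 1.25, 2.5, 5.0, 10.0)
        slopes = []
        for seed in range(100):
            pts = []
            for i, c in enumerate(concs):
                tr = simulate_decay(model, ManifestEntry(f"S{i}", "AH", c),
                                    profile, seed=1000 * seed + i)
                pts.append((c, fit_monoexponential(tr).alpha))
            slopes.append(fit_relaxivity(pts).slope)
        assert np.mean(slopes) == pytest.approx(0.93, rel=0.01)


class TestDispersionStats:
    def test_span_of_printed_extreme_pairs(self):
        assert slope_span([6.61e-3, 12.82e-3]) == pytest.approx(6.21e-3, abs=1e-9)
        assert slope_span([0.71, 1.08]) == pytest.approx(0.37, abs=1e-9)

    def test_span_degenerate_cases(self):
        assert slope_span([1.5]) == 0.0
        with pytest.raises(DomainError):
            slope_span([])

    def test_cv_of_identical_slopes_is_zero(self):
        assert relaxivity_cv([1.0, 1.0, 1.0]) == 0.0

    def test_cv_from_printed_summary_stats(self):
        assert round(cv_from_stats(8.77e-3, 2.09e-3), 1) == 23.8

    def test_cv_closed_form_two_values(self):
        # sample sd of {1,3} is sqrt(2); mean 2 -> 70.71%
        assert relaxivity_cv([1.0, 3.0]) == pytest.approx(70.71, abs=0.01)

    def test_cv_zero_mean_rejected(self):
        with pytest.raises(DomainError):
            relaxivity_cv([-1.0, 1.0])

    @settings(max_examples=30, derandomize=True)
    @given(c=st.floats(min_value=1e-6, max_value=1e6),
           seed=st.integers(min_value=0, max_value=2**16))
    def test_cv_scale_invariant_and_span_scales(self, c, seed):
        rng = np.random.default_rng(seed)
        slopes = rng.uniform(0.5, 2.0, 5)
        assert relaxivity_cv(slopes * c) == pytest.approx(relaxivity_cv(slopes), rel=1e-9)
        assert slope_span(slopes * c) == pytest.approx(c * slope_span(slopes), rel=1e-9)


class TestFreezeThaw:
    def test_equal_rates_no_change(self):
        assert freeze_thaw_change(2.0, 2.0) == 0.0

    def test_ten_percent_detection_line(self):
        assert freeze_thaw_change(0.9, 1.0) == pytest.approx(10.0)

    def test_halved_rate(self):
        assert freeze_thaw_change(1.0, 2.0) == pytest.approx(50.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(DomainError):
            freeze_thaw_change(1.0, 0.0)

    @settings(max_examples=30, derandomize=True)
    @given(r=st.floats(min_value=0.1, max_value=0.99))
    def test_ratio_inversion_flips_sign(self, r):
        fwd = freeze_thaw_change(r, 1.0)
        rev = freeze_thaw_change(1.0, r)
        assert fwd > 0 > rev
        assert fwd == pytest.approx((1 - r) * 100.0)
        assert rev == pytest.approx((1 - 1 / r) * 100.0)


class TestAssessOutlier:
    calib = RelaxivityFit("Lab1", "AH", slope=0.93, intercept=0.35,
                          slope_se=0.01, rmsd=0.02, n_points=6)

    def test_identical_pair_not_flagged(self):
        out = assess_outlier((_fit(1.5), _fit(1.5)), self.calib)
        assert out.percent_change == 0.0
        assert not out.flagged
        assert out.direction == "none"

    def test_stressed_decrease_flagged(self):
        out = assess_outlier((_fit(1.5 * 0.85), _fit(1.5)), self.calib)
        assert out.flagged and out.direction == "decrease"
        assert out.percent_change == pytest.approx(15.0)

    def test_increase_direction_recorded(self):
        out = assess_outlier((_fit(1.8), _fit(1.5)), self.calib)
        assert out.flagged and out.direction == "increase"

    def test_band_can_exceed_fixed_threshold(self):
        wide = RelaxivityFit("Lab1", "AH", 0.93, 0.35, 0.01, rmsd=0.3, n_points=6)
        out = assess_outlier((_fit(1.5 * 0.88), _fit(1.5)), wide, threshold=10.0)
        assert out.band_halfwidth == pytest.approx(100 * 0.3 / 1.5)
        assert not out.flagged  # 12% change, but the band is 20%

    def test_mismatched_lab_rejected(self):
        with pytest.raises(IntegrityError):
            assess_outlier((_fit(1.0), _fit(1.0)), self.calib, lab_id="Lab9")


class TestZeroSlopeTest:
    def test_exact_zero_slope_consistent(self):
        pts = [(c, 0.35) for c in (1.0, 2.0, 4.0, 8.0)]
        assert zero_slope_test(fit_relaxivity(pts)) == "consistent_with_zero"

    def test_clear_slope_nonzero(self):
        pts = [(c, 0.35 + 0.9 * c + 0.001 * (-1) ** i) for i, c in
               enumerate((1.0, 2.0, 4.0, 8.0))]
        assert zero_slope_test(fit_relaxivity(pts)) == "nonzero"

    def test_two_point_fit_indeterminate(self):
        assert zero_slope_test(fit_relaxivity([(1.0, 1.0), (2.0, 1.0)])) == "indeterminate"


class TestBuildReport:
    def _study_fits(self, profiles, seed=3):
        models = default_models()
        manifest = default_manifest()
        traces = simulate_study(models, manifest, profiles, seed=seed)
        return {k: fit_monoexponential(tr) for k, tr in traces.items()}, manifest

    def test_counting_contract(self):
        profiles = (LabProfile("A", tau=2000e-6, n_echoes=800, n_scans=8),
                    LabProfile("B", tau=1000e-6, n_echoes=1500, n_scans=16))
        fits, manifest = self._study_fits(profiles)
        report = build_report(fits, manifest)
        # one calibration per lab per class (mAb incl. buffer, AH, AP, ETFE)
        assert len(report.relaxivity_table) == 2 * 4
        assert set(report.cv) == {"mAb", "AH", "AP", "ETFE"}
        # one freeze/thaw assessment per stressed vial per lab
        assert len(report.outliers) == 2 * 2
        assert all(o.flagged for o in report.outliers)

    def test_empty_input_gives_empty_report(self):
        report = build_report({}, default_manifest(), provenance={"seed": 0})
        assert report.relaxivity_table == ()
        assert report.outliers == ()
        assert report.provenance == {"seed": 0}

    def test_duplicate_submission_uses_later_and_logs(self):
        profiles = (LabProfile("A", tau=2000e-6, n_echoes=800, n_scans=8),)
        fits, manifest = self._study_fits(profiles)
        items = [(lab, code, fr) for (lab, code), fr in fits.items()]
        dup_key = items[0][:2]
        items.insert(0, (dup_key[0], dup_key[1], _fit(99.0)))  # earlier, bogus
        report = build_report(items, manifest)
        assert any("duplicate" in a for a in report.anomalies)
        clean = build_report(fits, manifest)
        assert report.relaxivity_frame().equals(clean.relaxivity_frame())

    def test_class_ranking_of_relaxivities(self):
        profiles = (LabProfile("A", tau=2000e-6, n_echoes=800, n_scans=8),
                    LabProfile("B", tau=1000e-6, n_echoes=1500, n_scans=16))
        fits, manifest = self._study_fits(profiles)
        report = build_report(fits, manifest)
        frame = report.relaxivity_frame().set_index(["lab_id", "sample_class"])
        for lab in ("A", "B"):
            ap = frame.loc[(lab, "AP"), "slope"]
            ah = frame.loc[(lab, "AH"), "slope"]
            mab = frame.loc[(lab, "mAb"), "slope"]
            assert ap > ah > mab
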
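"""SNAP/CMAP processing: filtering, background statistics, peak readout,
recruitment curves, target-intensity rule, maintenance controller, charge."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from septrial import synth
from septrial.emg import (CMAP_WINDOW_MS, SNAP_WINDOW_MS, EmgEpochs,
                          RecruitmentCurve, background_level,
                          build_recruitment_curve, compute_charge,
                          detect_target_intensity, filter_emg,
                          monitor_assessment, peak_response)

FS = 3200.0


def _epochs(data, intensities=None):
    return EmgEpochs(data=data, fs=FS, intensities=intensities)


class TestFilterEmg:
    def test_dc_rejected(self):
        y = filter_emg(np.ones(3200), FS)
        assert np.abs(y).max() < 1e-6

    def test_inband_tone_preserved(self):
        t = np.arange(0, 1, 1 / FS)
        y = filter_emg(np.sin(2 * np.pi * 200 * t), FS)
        assert np.abs(y[800:-800]).max() == pytest.approx(1.0, abs=0.05)

    def test_line_frequency_attenuated(self):
        t = np.arange(0, 1, 1 / FS)
        y = filter_emg(np.sin(2 * np.pi * 60 * t), FS)
        assert 20 * np.log10(np.abs(y[800:-800]).max()) < -20

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            filter_emg(np.zeros(100), 600.0)


class TestBackgroundLevel:
    def test_rectified_median_of_simple_values(self):
        data = np.zeros((1, 320))
        ep = _epochs(data)
        m = ep.window_mask((-50.0, -15.0))
        pattern = np.resize([-1.0, 2.0, -3.0], m.sum())
        data[0, m] = pattern
        med, _sd = background_level(_epochs(data))
        assert med == 2.0

    def test_all_zero_epochs(self):
        med, sd = background_level(_epochs(np.zeros((3, 320))))
        assert med == 0.0 and sd == 0.0

    def test_gaussian_noise_matches_half_normal_median(self, rng):
        sigma = 1.7
        med, _ = background_level(_epochs(rng.normal(0, sigma, (500, 320))))
        assert med == pytest.approx(0.674 * sigma, rel=0.05)

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            background_level(_epochs(np.zeros((2, 320))), window_ms=(-200, -150))


class TestPeakResponse:
    def test_flat_trial_returns_zero_at_window_start(self):
        amps, lats = peak_response(_epochs(np.zeros((1, 320))), SNAP_WINDOW_MS)
        assert amps[0] == 0.0
        t = _epochs(np.zeros((1, 320))).times_ms
        assert lats[0] == t[(t >= SNAP_WINDOW_MS[0])][0]

    def test_tied_peaks_resolve_to_earliest(self):
        data = np.zeros((1, 320))
        ep = _epochs(data)
        idx = np.nonzero(ep.window_mask(SNAP_WINDOW_MS))[0]
        data[0, idx[3]] = 5.0
        data[0, idx[9]] = 5.0
        amps, lats = peak_response(_epochs(data), SNAP_WINDOW_MS)
        assert amps[0] == 5.0
        assert lats[0] == ep.times_ms[idx[3]]

    def test_noiseless_trial_recovers_generator_truth(self, default_subject):
        snap, cmap, truth = synth.synth_emg_trial(12.0, 1.0, default_subject,
                                                  noiseless=True)
        ep = _epochs(np.vstack([snap]))
        amps, lats = peak_response(ep, SNAP_WINDOW_MS)
        assert amps[0] == pytest.approx(truth["snap_amp_realized"], rel=1e-12)
        assert lats[0] == pytest.approx(truth["snap_lat_realized"], rel=1e-12)
        amps_c, _ = peak_response(_epochs(np.vstack([cmap])), CMAP_WINDOW_MS)
        assert amps_c[0] == pytest.approx(truth["cmap_amp_realized"], rel=1e-12)

    def test_polarity_options(self):
        data = np.zeros((1, 320))
        ep = _epochs(data)
        idx = np.nonzero(ep.window_mask(SNAP_WINDOW_MS))[0]
        data[0, idx[2]] = -7.0
        data[0, idx[5]] = 4.0
        assert peak_response(_epochs(data), SNAP_WINDOW_MS, "max")[0][0] == 4.0
        assert peak_response(_epochs(data), SNAP_WINDOW_MS, "min")[0][0] == -7.0
        assert peak_response(_epochs(data), SNAP_WINDOW_MS, "absmax")[0][0] == -7.0


class TestRecruitmentCurve:
    def test_group_mean_of_four_trials(self):
        data = np.zeros((8, 320))
        ep0 = _epochs(data)
        idx = np.nonzero(ep0.window_mask(SNAP_WINDOW_MS))[0][0]
        data[:, idx] = [1, 2, 3, 4, 5, 6, 7, 8]
        intensities = np.array([1.0] * 4 + [1.5] * 4)
        curve = build_recruitment_curve(_epochs(data, intensities))
        assert curve.means[0] == pytest.approx(2.5)
        assert curve.means[1] == pytest.approx(6.5)

    def test_trial_order_invariance(self, rng, default_subject):
        rows, intens = [], []
        for lv in (8.0, 8.5, 9.0):
            for k in range(4):
                s, _, _ = synth.synth_emg_trial(lv, 1.0, default_subject,
                                                seed=int(lv * 10 + k))
                rows.append(s)
                intens.append(lv)
        rows, intens = np.asarray(rows), np.asarray(intens)
        perm = rng.permutation(len(rows))
        c1 = build_recruitment_curve(_epochs(rows, intens))
        c2 = build_recruitment_curve(_epochs(rows[perm], intens[perm]))
        assert np.allclose(c1.means, c2.means)

    def test_noiseless_sigmoid_recovered_pointwise(self, default_subject):
        rows, intens = [], []
        levels = np.arange(6.0, 12.0, 0.5)
        for lv in levels:
            s, _, truth = synth.synth_emg_trial(lv, 1.0, default_subject,
                                                noiseless=True)
            rows.extend([s] * 4)
            intens.extend([lv] * 4)
        curve = build_recruitment_curve(_epochs(np.asarray(rows), np.asarray(intens)))
        expected = [synth.recruitment_amplitude(lv, 1.0, "snap", default_subject)
                    for lv in levels]
        # Realized sampled peaks track the recruitment sigmoid to within the
        # (constant) wavelet sampling factor.
        factor = curve.means / np.asarray(expected)
        assert np.allclose(factor, factor[0], rtol=1e-9)
        assert factor[0] == pytest.approx(1.0, abs=0.05)

    def test_underfilled_level_flagged(self):
        data = np.zeros((7, 320))
        intens = np.array([1.0] * 4 + [1.5] * 3)
        curve = build_recruitment_curve(_epochs(data, intens))
        assert curve.underfilled == [1.5]

    def test_missing_intensities_rejected(self):
        with pytest.raises(ValueError):
            build_recruitment_curve(_epochs(np.zeros((4, 320))))


def _curve(levels, peaks_per_level, bg_median=0.0, bg_sd=1.0):
    return RecruitmentCurve(
        intensities=np.asarray(levels, dtype=float),
        trial_peaks=[np.asarray(p, dtype=float) for p in peaks_per_level],
        means=np.asarray([np.mean(p) for p in peaks_per_level]),
        background_median=bg_median, background_sd=bg_sd)


class TestDetectTarget:
    def test_pure_noise_yields_absence(self, rng):
        curve = _curve([1, 1.5, 2], [rng.normal(0, 1, 4) for _ in range(3)])
        assert detect_target_intensity(curve) is None

    def test_rule_boundary_three_of_four(self):
        # criterion is median + 3 SD = 3.0; level 1.5 has 2/4 supra, level
        # 2.0 has exactly 3/4 -> the rule returns 2.0.
        curve = _curve([1.5, 2.0], [[4, 4, 1, 1], [4, 4, 4, 1]])
        assert detect_target_intensity(curve) == 2.0

    def test_cmap_criterion_must_also_hold(self):
        snap = _curve([1.5, 2.0], [[4, 4, 4, 4], [4, 4, 4, 4]])
        cmap = _curve([1.5, 2.0], [[0, 0, 0, 0], [4, 4, 4, 0]])
        assert detect_target_intensity(snap, cmap) == 2.0

    def test_monotone_in_snap_amplitude(self, rng):
        peaks = [rng.normal(lv, 0.3, 4) for lv in (1.0, 2.5, 4.0, 6.0)]
        lo = _curve([1, 1.5, 2, 2.5], peaks)
        hi = _curve([1, 1.5, 2, 2.5], [p * 1.5 for p in peaks])
        t_lo = detect_target_intensity(lo)
        t_hi = detect_target_intensity(hi)
        assert t_hi is not None and (t_lo is None or t_hi <= t_lo)

    def test_cohort_detection_within_one_step_of_calibration(self):
        # End-to-end: synthetic recruitment at each pulse width recovers the
        # calibrated threshold to within one 0.5 mA acquisition step.
        from septrial.report import StudyConfig, _recruitment
        cfg = StudyConfig()
        for seed in (0, 1):
            for s in synth.sample_cohort(2, seed=seed):
                for pw in (0.1, 0.5, 1.0):
                    r = np.random.default_rng(seed + int(pw * 10))
                    _, _, target = _recruitment(s, pw, cfg, r)
                    assert target is not None
                    assert abs(target - s.threshold("snap", pw)) <= 0.5 + 1e-9


class TestMonitorAssessment:
    def test_all_in_band_no_adjustments(self):
        trials = [(10.0, 100.0)] * 20
        log = monitor_assessment(trials, 10.0, 100.0, start_intensity=9.0)
        assert log.n_adjustments == 0
        assert log.table["in_band"].all()

    def test_alternating_within_band_no_adjustments(self):
        trials = [(10.0, 115.0), (10.0, 85.0)] * 10
        log = monitor_assessment(trials, 10.0, 100.0, start_intensity=9.0)
        assert log.n_adjustments == 0

    def test_sustained_sag_recovers_into_band(self, default_subject):
        target = default_subject.threshold("snap", 1.0)
        gain = {"value": 0.70}   # 30 % CMAP sag

        def respond(intensity, k):
            snap = synth.recruitment_amplitude(intensity, 1.0, "snap", default_subject)
            cmap = synth.recruitment_amplitude(intensity, 1.0, "cmap", default_subject)
            return snap * gain["value"], cmap * gain["value"]

        t_snap = synth.recruitment_amplitude(target, 1.0, "snap", default_subject)
        t_cmap = synth.recruitment_amplitude(target, 1.0, "cmap", default_subject)
        log = monitor_assessment(respond, t_snap, t_cmap, start_intensity=target,
                                 n_trials=60)
        adjustments = log.table["adjustment_mA"].to_numpy()
        assert (adjustments >= 0).all()
        assert set(np.round(np.abs(adjustments[adjustments != 0]), 10)) == {0.1}
        assert log.table["in_band"].tail(10).all()

    def test_intensity_changes_are_single_steps(self, default_subject):
        def respond(intensity, k):
            return (5.0, 60.0) if k < 10 else (5.0, 100.0)
        log = monitor_assessment(respond, 10.0, 100.0, start_intensity=9.0,
                                 n_trials=30)
        deltas = np.round(np.abs(np.diff(log.table["intensity_mA"])), 10)
        assert set(deltas) <= {0.0, 0.1}

    def test_discomfort_limit_never_exceeded(self):
        def respond(intensity, k):
            return 5.0, 10.0   # persistently low CMAP: controller pushes up
        log = monitor_assessment(respond, 10.0, 100.0, start_intensity=9.8,
                                 n_trials=50, discomfort_limit=10.0)
        assert (log.table["intensity_mA"] <= 10.0 + 1e-12).all()

    def test_non_positive_targets_rejected(self):
        with pytest.raises(ValueError):
            monitor_assessment([(1.0, 1.0)], 0.0, 100.0, start_intensity=1.0)


class TestCharge:
    def test_printed_values_reproduced_exactly(self):
        assert compute_charge(8.3, 1.0) == pytest.approx(8.30e-6, rel=1e-12)
        assert compute_charge(9.5, 0.5) == pytest.approx(4.75e-6, rel=1e-12)

    def test_zero_current_gives_zero_charge(self):
        assert compute_charge(0.0, 1.0) == 0.0

    @given(i=hst.floats(0, 100), pw=hst.floats(0, 5))
    def test_bilinear(self, i, pw):
        assert compute_charge(2 * i, pw) == pytest.approx(2 * compute_charge(i, pw))
        assert compute_charge(i, 2 * pw) == pytest.approx(2 * compute_charge(i, pw))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_charge(-1.0, 1.0)
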
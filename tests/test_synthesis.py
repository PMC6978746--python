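"""Signal generator and sensor transduction model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fsrgesture as fg
from fsrgesture.acquisition import saturation_voltage, volts_per_kg
from fsrgesture.labels import ACTIVE_GESTURES

REST = fg.GestureLabel.REST


class TestActivationProfile:
    def test_rest_column_is_zero(self, profile):
        assert np.all(profile.plateau_force[:, REST] == 0.0)

    def test_preload_matches_armband_grip_force(self, profile):
        assert profile.preload == pytest.approx(0.1)

    def test_extensor_dominates_wrist_extension(self, profile):
        col = profile.plateau_force[:, fg.GestureLabel.WRIST_EXTENSION]
        assert np.argmax(col) + 1 == fg.SensorChannel.FSR3

    def test_anatomical_involvement(self, profile):
        p = profile.plateau_force
        fcu, fcr, ed = 0, 1, 2
        assert p[fcu, fg.GestureLabel.WRIST_ADDUCTION] == p[:, fg.GestureLabel.WRIST_ADDUCTION].max()
        assert p[fcr, fg.GestureLabel.WRIST_ABDUCTION] == p[:, fg.GestureLabel.WRIST_ABDUCTION].max()
        assert p[ed, fg.GestureLabel.FINGERS_ABDUCTION] == p[:, fg.GestureLabel.FINGERS_ABDUCTION].max()

    def test_gesture_plateaus_separated_beyond_noise(self, profile):
        """Pairwise plateau distances exceed 6x the noise SD, so class
        clusters occupy disjoint regions of force space."""
        cols = profile.plateau_force.T
        dists = [
            np.linalg.norm(cols[a] - cols[b])
            for a in range(len(cols))
            for b in range(a + 1, len(cols))
        ]
        assert min(dists) > 6 * profile.noise_sd

    def test_rejects_nonzero_rest_activation(self, profile):
        bad = profile.plateau_force.copy()
        bad[:, REST] = 0.2
        with pytest.raises(ValueError):
            fg.ActivationProfile(plateau_force=bad)


class TestGenerateTrial:
    def test_seed_determinism(self, profile):
        a = fg.generate_trial(profile, 3, [fg.GestureLabel.CLENCHED_FIST], seed=7)
        b = fg.generate_trial(profile, 3, [fg.GestureLabel.CLENCHED_FIST], seed=7)
        assert np.array_equal(a.forces, b.forces)
        assert a.timeline == b.timeline

    def test_rest_only_trial_sits_at_preload(self, profile):
        rec = fg.generate_trial(profile, 4, [REST], seed=2)
        lo = profile.preload - 4 * profile.noise_sd
        hi = profile.preload + 4 * profile.noise_sd
        frac_inside = np.mean((rec.forces >= lo) & (rec.forces <= hi))
        assert frac_inside > 0.9995
        assert all(t.label is REST for t in rec.timeline)

    @pytest.mark.parametrize("reps,gestures", [(3, 2), (5, 1), (1, 8)])
    def test_timeline_has_reps_times_gestures_plateaus(self, profile, reps, gestures):
        labels = list(fg.GestureLabel)[:gestures]
        rec = fg.generate_trial(profile, reps, labels, seed=0)
        assert len(rec.timeline) == reps * gestures
        # plateaus are sorted, disjoint, and hold_time long
        hold = round(profile.hold_time * rec.sampling_rate)
        assert all(t.n_samples == hold for t in rec.timeline)

    def test_plateau_level_matches_profile(self, profile):
        rec = fg.generate_trial(profile, 1, [fg.GestureLabel.CLENCHED_FIST], seed=3)
        t = rec.timeline[0]
        plateau = rec.forces[:, t.start_sample : t.end_sample].mean(axis=1)
        expected = profile.preload + profile.plateau_force[:, fg.GestureLabel.CLENCHED_FIST]
        assert plateau == pytest.approx(expected, abs=5e-3)

    def test_forces_never_negative(self, profile):
        rec = fg.generate_trial(profile, 2, list(fg.GestureLabel), seed=11)
        assert rec.forces.min() >= 0.0

    def test_invalid_repetitions_rejected(self, profile):
        with pytest.raises(ValueError):
            fg.generate_trial(profile, 0, [REST], seed=0)
        with pytest.raises(ValueError):
            fg.generate_trial(profile, -3, [REST], seed=0)
        with pytest.raises(ValueError):
            fg.generate_trial(profile, 2, [], seed=0)

    def test_subject_scale_and_offset_applied(self, profile):
        import dataclasses

        prof = dataclasses.replace(
            profile, subject_scale=(2.0, 1.0, 1.0), subject_offset=(0.0, 0.3, 0.0), noise_sd=0.0
        )
        rec = fg.generate_trial(prof, 1, [fg.GestureLabel.CLENCHED_FIST], seed=0)
        t = rec.timeline[0]
        plateau = rec.forces[:, t.start_sample : t.end_sample].mean(axis=1)
        base = profile.plateau_force[:, fg.GestureLabel.CLENCHED_FIST]
        expected = prof.preload + np.array([0.0, 0.3, 0.0]) + np.array([2.0, 1.0, 1.0]) * base
        assert plateau == pytest.approx(expected, abs=1e-12)


class TestSession:
    def test_protocol_session_structure(self, session0):
        assert [r for r in session0.gestures] == list(fg.GestureLabel)
        assert all(len(r.timeline) == 10 for r in session0.recordings)


class TestTransduction:
    def test_zero_force_gives_constant_baseline(self, acq):
        calib = fg.default_calibration(acq)
        forces = np.zeros((3, 100))
        v = fg.transduce(forces, calib, acq)
        rg = np.asarray(acq.gain_resistances)
        expected = rg * acq.v_cc * np.asarray(calib.conductance_offset)
        step = acq.adc_step
        assert np.all(np.abs(v - expected[:, None]) <= step / 2 + 1e-12)
        assert np.all(v == v[:, :1])  # constant per channel

    def test_linearity_below_saturation(self, acq):
        """Doubling the force doubles the above-baseline voltage."""
        calib = fg.default_calibration(acq)
        f1 = np.full((3, 1), 0.4)
        base = fg.transduce(np.zeros((3, 1)), calib, acq)
        v1 = fg.transduce(f1, calib, acq) - base
        v2 = fg.transduce(2 * f1, calib, acq) - base
        assert v2 == pytest.approx(2 * v1, abs=2 * acq.adc_step)

    def test_channel_gains_equalized(self, acq):
        """Sensitivities inversely proportional to the 850/790/960 ohm gain
        resistors give identical volts-per-kg slopes on all channels."""
        calib = fg.default_calibration(acq)
        slopes = volts_per_kg(calib, acq)
        assert np.ptp(slopes) < 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_force(self, seed):
        acq = fg.AcquisitionConfig()
        calib = fg.default_calibration(acq)
        rng = np.random.default_rng(seed)
        f = np.sort(rng.uniform(0, 3.0, size=(3, 50)), axis=1)
        v = fg.transduce(f, calib, acq)
        assert np.all(np.diff(v, axis=1) >= 0)

    def test_channel_count_mismatch_rejected(self, acq):
        calib = fg.FsrCalibration((1e-4,), (1e-4,), (2.0,))
        with pytest.raises(fg.ConfigurationError):
            fg.transduce(np.zeros((3, 5)), calib, acq)


class TestInverseCalibration:
    def test_round_trip_error_within_one_adc_step(self, profile, acq):
        calib = fg.default_calibration(acq)
        rec = fg.generate_trial(profile, 2, list(ACTIVE_GESTURES), seed=9)
        v = fg.transduce(rec, calib, acq)
        recovered, saturated = fg.inverse_calibrate(v, calib, acq)
        assert not saturated.any()
        bound = acq.adc_step / volts_per_kg(calib, acq).min()
        assert np.nanmax(np.abs(recovered - rec.forces)) <= bound

    def test_saturated_samples_flagged_not_inverted(self, acq):
        calib = fg.default_calibration(acq)
        f = np.array([[0.5], [1.0], [5.0]])  # channel 3 far beyond saturation
        v = fg.transduce(f, calib, acq)
        recovered, saturated = fg.inverse_calibrate(v, calib, acq)
        assert saturated[2, 0] and not saturated[:2, 0].any()
        assert np.isnan(recovered[2, 0])

    def test_baseline_voltage_maps_to_zero_force(self, acq):
        calib = fg.default_calibration(acq)
        v = fg.transduce(np.zeros((3, 10)), calib, acq)
        recovered, _ = fg.inverse_calibrate(v, calib, acq)
        bound = acq.adc_step / volts_per_kg(calib, acq).min()
        assert np.nanmax(np.abs(recovered)) <= bound

    def test_out_of_range_voltages_rejected(self, acq):
        calib = fg.default_calibration(acq)
        with pytest.raises(ValueError):
            fg.inverse_calibrate(np.full((3, 2), acq.v_cc + 1.0), calib, acq)

    def test_saturation_voltage_clamped_to_supply(self, acq):
        calib = fg.default_calibration(acq)
        assert np.all(saturation_voltage(calib, acq) <= acq.v_cc)
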
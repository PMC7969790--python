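"""Extraction pipeline: calibration, integration, segmentation, window
selection, representative stride, phasing, events, ROM and symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitrel import (
    SensorStream,
    SessionProtocol,
    calibrate_orientation,
    classify_gait,
    expected_variables,
    extract_record,
    integrate_orientation,
    limb_phasing,
    recode_protraction,
    representative_stride,
    segment_strides,
    select_window,
    simulate_horse_profile,
    simulate_session,
    spatial_variables,
    symmetry_index,
    temporal_variables,
    VARIABLE_COLUMNS,
)
from gaitrel.errors import (
    CalibrationError,
    EventDetectionError,
    ParameterError,
    PhaseError,
    SegmentationError,
    SelectionError,
)

FS = 102.4


def _stream(gyro, accel=None, placement="LH_mt", fs=FS):
    gyro = np.asarray(gyro, dtype=float)
    if accel is None:
        accel = np.tile([0.0, 0.0, -1.0], (len(gyro), 1))
    return SensorStream(placement, fs, gyro, accel)


class TestCalibration:
    def test_gravity_aligned_gives_zero_tilt(self):
        n = 256
        s = _stream(np.zeros((n, 3)))
        (sag, cor), bias = calibrate_orientation(s, (0, n))
        assert sag == pytest.approx(0.0) and cor == pytest.approx(0.0)
        np.testing.assert_allclose(bias, 0.0)

    def test_sagittal_tilt_recovered_from_gravity(self):
        # tilt about the lateromedial x axis moves gravity into -y
        n = 256
        th = np.radians(10.0)
        accel = np.tile([0.0, -np.sin(th), -np.cos(th)], (n, 1))
        (sag, cor), _ = calibrate_orientation(_stream(np.zeros((n, 3)), accel), (0, n))
        assert sag == pytest.approx(10.0, abs=1e-9)
        assert cor == pytest.approx(0.0, abs=1e-9)

    def test_noisy_standstill_within_half_degree(self):
        rng = np.random.default_rng(0)
        n = 1024
        th = np.radians(7.0)
        accel = np.tile([0.0, -np.sin(th), -np.cos(th)], (n, 1)) + rng.normal(0, 0.01, (n, 3))
        (sag, _), _ = calibrate_orientation(_stream(np.zeros((n, 3)), accel), (0, n))
        assert abs(sag - 7.0) < 0.5

    def test_short_window_and_degenerate_gravity_rejected(self):
        n = 256
        with pytest.raises(CalibrationError):
            calibrate_orientation(_stream(np.zeros((n, 3))), (0, 10))
        zero_g = np.zeros((n, 3))
        with pytest.raises(CalibrationError):
            calibrate_orientation(_stream(np.zeros((n, 3)), zero_g), (0, n))


class TestIntegration:
    def test_constant_rate_integrates_linearly(self):
        fs = 100.0  # integer samples over exactly 2 s
        n = int(2 * fs) + 1
        gyro = np.zeros((n, 3))
        gyro[:, 0] = 10.0  # deg/s for 2 s -> +20 deg
        ori = integrate_orientation(_stream(gyro, fs=fs))
        assert ori.sagittal_angle[-1] == pytest.approx(20.0, rel=1e-6)

    def test_sinusoid_amplitude_closed_form(self):
        # A*sin(2*pi*f*t) integrates to amplitude A/(2*pi*f)
        a_amp, f = 36 * np.pi, 1.368
        t = np.arange(int(10 * FS)) / FS
        gyro = np.zeros((len(t), 3))
        gyro[:, 0] = a_amp * np.sin(2 * np.pi * f * t)
        ori = integrate_orientation(_stream(gyro))
        assert np.ptp(ori.sagittal_angle) / 2 == pytest.approx(a_amp / (2 * np.pi * f), rel=0.01)

    def test_bias_with_detrending_leaves_rom_unchanged(self, default_profile):
        roms = {}
        for bias in (0.0, 0.5):
            proto = SessionProtocol(noise_sd_gyro=0.0, noise_sd_accel=0.0,
                                    gyro_bias=bias, seed=3)
            rec = extract_record(simulate_session(default_profile, proto))
            roms[bias] = rec.values["rom_sag_hock_L"]
        assert roms[0.5] == pytest.approx(roms[0.0], rel=0.01)


class TestSegmentation:
    def test_twenty_trot_cycles_give_nineteen_strides(self, pure_trot_session, default_profile):
        series = segment_strides(pure_trot_session.streams["LH_mt"])
        assert series.n_strides == 19
        np.testing.assert_allclose(
            series.durations, default_profile.stride_duration, atol=1.0 / FS
        )

    def test_flat_gyro_raises(self):
        with pytest.raises(SegmentationError):
            segment_strides(_stream(np.zeros((2048, 3))))

    def test_boundaries_strictly_increasing(self, clean_session):
        series = segment_strides(clean_session.streams["LH_mt"])
        assert np.all(np.diff(series.boundaries) > 0)


class TestGaitClassification:
    @pytest.mark.parametrize(
        "phases, expected",
        [
            ({"LF": 63.0, "RF": 14.0, "RH": 50.0}, "trot"),
            ({"LF": 75.0, "RF": 25.0, "RH": 50.0}, "walk"),
            ({"LF": 40.0, "RF": 40.0, "RH": 40.0}, "unknown"),
        ],
    )
    def test_phase_templates(self, phases, expected):
        assert classify_gait(phases) == expected

    def test_missing_limb_rejected(self):
        with pytest.raises(ParameterError):
            classify_gait({"LF": 63.0, "RF": 14.0})


class TestWindowSelection:
    def test_steady_strides_select_full_range(self):
        assert select_window(np.full(20, 0.731)) == (0, 20)

    def test_minimum_five_stride_rule(self):
        with pytest.raises(SelectionError):
            select_window(np.full(4, 0.731))

    def test_ramps_are_excluded(self):
        d = np.concatenate([[1.05, 0.95, 0.85], np.full(12, 0.731), [0.85, 0.95, 1.05]])
        lo, hi = select_window(d)
        assert (lo, hi) == (3, 15)

    def test_manual_window_validated(self):
        d = np.full(20, 0.731)
        assert select_window(d, manual=(2, 10)) == (2, 10)
        with pytest.raises(SelectionError):
            select_window(d, manual=(0, 3))
        with pytest.raises(SelectionError):
            select_window(d, manual=(15, 25))


class TestRepresentativeStride:
    def test_identical_cycles_tie_break_to_first(self):
        cycles = np.tile(np.sin(np.linspace(0, 2 * np.pi, 100)), (6, 1))
        assert representative_stride(cycles) == 0

    def test_outlier_is_never_representative(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 100))
        cycles = np.tile(base, (5, 1))
        cycles[2] += 5.0
        assert representative_stride(cycles) == 0

    def test_matches_brute_force_ssd_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            cycles = rng.normal(size=(8, 100))
            ssd = np.zeros(8)
            for i in range(8):
                for j in range(8):
                    ssd[i] += ((cycles[i] - cycles[j]) ** 2).sum()
            assert representative_stride(cycles) == int(np.argmin(ssd))

    def test_window_too_small_rejected(self):
        with pytest.raises(ParameterError):
            representative_stride(np.zeros((5, 100)), (2, 3))


class TestLimbPhasing:
    def test_identical_cycle_zero_lag(self):
        ref = np.sin(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        phases = limb_phasing({"LH": ref, "LF": ref.copy()})
        assert phases["LF"] == pytest.approx(0.0, abs=1e-9)

    def test_quarter_cycle_shift_is_25_percent(self):
        ref = np.sin(np.linspace(0, 2 * np.pi, 100, endpoint=False)) + \
            0.3 * np.sin(np.linspace(0, 4 * np.pi, 100, endpoint=False))
        phases = limb_phasing({"LH": ref, "RF": np.roll(ref, 25)})
        assert phases["RF"] == pytest.approx(25.0, abs=1e-6)

    def test_zero_variance_cycle_rejected(self):
        ref = np.sin(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        with pytest.raises(PhaseError):
            limb_phasing({"LH": ref, "LF": np.full(100, 3.0)})

    @settings(deadline=None, max_examples=25)
    @given(lag=st.integers(min_value=0, max_value=99), seed=st.integers(0, 1000))
    def test_common_rotation_leaves_phase_differences_unchanged(self, lag, seed, circ):
        rng = np.random.default_rng(seed)
        grid = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        cycles = {
            limb: np.sin(grid + rng.uniform(0, 2 * np.pi)) + 0.4 * np.sin(2 * grid + rng.uniform(0, 2 * np.pi))
            for limb in ("LH", "RH", "LF", "RF")
        }
        base = limb_phasing(cycles)
        rolled = {limb: np.roll(c, lag) for limb, c in cycles.items()}
        shifted = limb_phasing(rolled)
        for a in ("RH", "LF", "RF"):
            for b in ("RH", "LF", "RF"):
                d1 = (base[a] - base[b]) % 100
                d2 = (shifted[a] - shifted[b]) % 100
                assert circ(d1, d2) < 1e-6


class TestTemporalVariables:
    def test_cos_cycle_retraction_at_zero(self):
        cyc = np.cos(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        ev = temporal_variables(cyc)
        assert ev["retraction"] == 0.0
        assert ev["protraction"] == 50.0

    def test_shifted_cos_peak_at_18_percent(self):
        cyc = np.cos(np.linspace(0, 2 * np.pi, 100, endpoint=False) - 2 * np.pi * 0.18)
        assert temporal_variables(cyc)["retraction"] == 18.0

    def test_flat_cycle_rejected(self):
        with pytest.raises(EventDetectionError):
            temporal_variables(np.zeros(100))

    def test_stride_duration_is_window_mean(self):
        cyc = np.cos(np.linspace(0, 2 * np.pi, 100, endpoint=False))
        ev = temporal_variables(cyc, durations=[0.72, 0.74])
        assert ev["stride_duration"] == pytest.approx(0.73)


class TestRecodeProtraction:
    @pytest.mark.parametrize("raw, recoded", [(98.0, 2.0), (96.0, 4.0), (94.0, 6.0), (18.0, 18.0)])
    def test_published_worked_examples(self, raw, recoded):
        assert recode_protraction(raw) == recoded

    @given(st.floats(min_value=0.0, max_value=99.999))
    def test_recoding_is_idempotent(self, p):
        # a late-cycle value and its early-cycle image are the same event, so
        # recoding an already-recoded value changes nothing
        assert recode_protraction(recode_protraction(p)) == pytest.approx(recode_protraction(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            recode_protraction(100.0)
        with pytest.raises(ParameterError):
            recode_protraction(-1.0)


class TestSpatialAndSymmetry:
    def test_sinusoid_rom_is_twice_amplitude(self):
        n = 1000
        angle = 10.0 * np.sin(np.linspace(0, 8 * np.pi, n))
        boundaries = np.arange(0, n + 1, 250)[:5]
        rom = spatial_variables(angle, boundaries, (0, 4), detrend=False)
        assert rom == pytest.approx(20.0, rel=1e-3)

    def test_constant_angle_rom_zero(self):
        assert spatial_variables(np.full(1000, 5.0), np.arange(0, 1001, 250)[:5], (0, 4)) == 0.0

    @given(offset=st.floats(min_value=-500, max_value=500))
    @settings(max_examples=25)
    def test_rom_invariant_to_constant_offset(self, offset):
        n = 1000
        angle = 10.0 * np.sin(np.linspace(0, 8 * np.pi, n))
        boundaries = np.arange(0, n + 1, 250)[:5]
        a = spatial_variables(angle, boundaries, (0, 4), detrend=False)
        b = spatial_variables(angle + offset, boundaries, (0, 4), detrend=False)
        assert b == pytest.approx(a, abs=1e-9)

    @pytest.mark.parametrize("left, right, expected", [(40.0, 40.0, 0.0), (30.0, 20.0, 40.0)])
    def test_symmetry_examples(self, left, right, expected):
        assert symmetry_index(left, right) == pytest.approx(expected)

    def test_symmetry_of_published_hock_roms(self):
        # |42.093 - 37.160| / mean * 100
        assert symmetry_index(42.093, 37.160) == pytest.approx(12.449, abs=1e-3)

    def test_non_positive_mean_rejected(self):
        with pytest.raises(ParameterError):
            symmetry_index(1.0, -1.0)


class TestEndToEnd:
    def test_noise_free_recovery_of_all_19_variables(self, circ):
        # 20 seeded horses: phases/events within 1% of stride, continuous
        # variables within 2% relative (hock symmetry: 2 points absolute,
        # since its truth can be arbitrarily close to zero)
        for s in range(20):
            profile = simulate_horse_profile(seed=s)
            session = simulate_session(
                profile, SessionProtocol(noise_sd_gyro=0.0, noise_sd_accel=0.0, seed=100 + s)
            )
            record = extract_record(session)
            truth = expected_variables(profile)
            for name in VARIABLE_COLUMNS:
                est, t = record.values[name], truth[name]
                if any(k in name for k in ("phasing", "protraction", "retraction")):
                    assert circ(est, t) < 1.0, name
                elif name == "symmetry_hock":
                    assert abs(est - t) < 2.0, name
                else:
                    assert est == pytest.approx(t, rel=0.02), name

    def test_walk_only_session_has_no_trot_window(self, default_profile):
        proto = SessionProtocol(n_trot_strides=1, walk_segments=(12.0,), ramp_strides=0,
                                noise_sd_gyro=0.0, noise_sd_accel=0.0, seed=9)
        session = simulate_session(default_profile, proto)
        with pytest.raises(SelectionError):
            extract_record(session)

    def test_periodic_session_windows_agree(self):
        # integer samples per stride makes the signal exactly periodic, so two
        # different valid windows must give identical records
        profile = simulate_horse_profile(seed=1)
        profile.stride_duration = 80.0 / FS  # exactly 80 samples per stride
        session = simulate_session(
            profile, SessionProtocol(noise_sd_gyro=0.0, noise_sd_accel=0.0,
                                     walk_segments=(), ramp_strides=0, seed=4)
        )
        a = extract_record(session, window=(2, 12))
        b = extract_record(session, window=(8, 18))
        for name in VARIABLE_COLUMNS:
            assert a.values[name] == pytest.approx(b.values[name], abs=1e-6), name

    def test_noise_degradation_does_not_improve_phase_recovery(self, circ):
        # mean (over 20 seeds) worst-case phase error under heavy gyro noise
        # is no better than in the noise-free case
        errors = {}
        for sd in (0.0, 60.0):
            errs = []
            for s in range(20):
                profile = simulate_horse_profile(seed=s)
                session = simulate_session(
                    profile, SessionProtocol(noise_sd_gyro=sd, noise_sd_accel=0.02, seed=300 + s)
                )
                rec = extract_record(session)
                truth = expected_variables(profile)
                errs.append(max(
                    circ(rec.values[f"limb_phasing_{limb}"], truth[f"limb_phasing_{limb}"])
                    for limb in ("LF", "RF", "RH")
                ))
            errors[sd] = float(np.mean(errs))
        assert errors[60.0] >= errors[0.0]
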
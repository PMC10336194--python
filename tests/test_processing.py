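"""Measurement-chain units: wall filter, spectra, envelope, beats, angle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import carodop as cd
from carodop import processing as proc
from carodop.errors import ConfigError, DataError

PRF = 12000.0
F0 = 4.0e6


def tone(f_hz, duration=2.0, prf=PRF, amp=1.0):
    n = int(duration * prf)
    t = np.arange(n) / prf
    return amp * np.exp(2j * np.pi * f_hz * t)


def synthetic_envelope(values_per_beat, n_beats, frame_rate=400.0):
    v = np.tile(np.asarray(values_per_beat, dtype=float), n_beats)
    t = np.arange(len(v)) / frame_rate
    return proc.Envelope(t=t, v_max=v, quality=np.ones(len(v), bool),
                         snr=np.full(len(v), 50.0),
                         noise_floor=np.full(len(v), 1e-6))


class TestWallFilter:
    def test_dc_attenuated_40db(self):
        x = np.full(24000, 1.0 + 0.5j)
        y = proc.wall_filter(x, PRF)
        assert np.mean(np.abs(y) ** 2) <= 1e-4 * np.mean(np.abs(x) ** 2)

    def test_passband_tone_preserved(self):
        x = tone(2000.0)
        y = proc.wall_filter(x, PRF, cutoff_hz=100.0)
        gain_db = 10 * np.log10(np.mean(np.abs(y) ** 2) / np.mean(np.abs(x) ** 2))
        assert abs(gain_db) < 1.0

    def test_zero_in_zero_out(self):
        assert np.allclose(proc.wall_filter(np.zeros(4096, complex), PRF), 0.0)

    def test_cutoff_bound(self):
        with pytest.raises(ConfigError):
            proc.wall_filter(tone(100.0), PRF, cutoff_hz=PRF / 2)


class TestSpectrogram:
    def test_tone_maps_to_velocity(self):
        spec = proc.compute_spectrogram(tone(1732.0), PRF, F0)
        v_expected = 1540.0 * 1732.0 / (2 * F0) * 100.0  # 33.3 cm/s axial
        peak = spec.velocity_axis[np.argmax(spec.power.mean(axis=0))]
        assert peak == pytest.approx(v_expected, abs=spec.bin_width_cm_s)

    def test_negative_tone_in_negative_half_axis(self):
        spec = proc.compute_spectrogram(tone(-1500.0), PRF, F0)
        peak = spec.velocity_axis[np.argmax(spec.power.mean(axis=0))]
        assert peak < 0

    def test_white_noise_flat_within_3db(self):
        rng = np.random.default_rng(0)
        x = (rng.standard_normal(240000) + 1j * rng.standard_normal(240000))
        spec = proc.compute_spectrogram(x, PRF, F0)
        mean_bins = spec.power.mean(axis=0)
        db_spread = 10 * np.log10(mean_bins.max() / mean_bins.min())
        assert db_spread < 3.0

    def test_record_too_short(self):
        with pytest.raises(DataError):
            proc.compute_spectrogram(tone(500.0, duration=0.015), PRF, F0)


class TestColorMMode:
    def test_autocorrelation_velocity_identity(self):
        f_d = 1732.0
        mm = proc.compute_color_mmode(tone(f_d), PRF, F0)
        v_expected = 1540.0 * f_d / (2 * F0) * 100.0
        assert np.allclose(mm.mean_velocity, v_expected, atol=1e-6)

    def test_aliasing_wraps_negative(self):
        mm = proc.compute_color_mmode(tone(PRF / 2 + 500.0), PRF, F0)
        assert (mm.mean_velocity < 0).all()

    def test_zero_signal_convention(self):
        mm = proc.compute_color_mmode(np.zeros(2400, complex), PRF, F0)
        assert np.all(mm.mean_velocity == 0.0)
        assert np.all(mm.power == 0.0)


class TestSelectGate:
    def _mmode(self, active=(4,), amp=30.0, n_gates=8, frame_rate=50.0,
               duration=10.0, power_boost=1.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(duration * frame_rate)
        t = np.arange(n) / frame_rate
        # identical noise per gate so equally active gates tie exactly
        v = np.tile(rng.normal(0.0, 0.2, size=n), (n_gates, 1))
        p = np.full((n_gates, n), 0.01)
        for g in active:
            v[g] += amp * np.sin(2 * np.pi * 1.5 * t)
            p[g] = power_boost
        return proc.ColorMMode(t=t, mean_velocity=v, power=p,
                               frame_rate=frame_rate)

    def test_pulsatile_gate_wins(self):
        assert proc.select_gate(self._mmode(active=(4,))) == 4

    def test_tie_breaks_shallower(self):
        assert proc.select_gate(self._mmode(active=(3, 5))) == 3

    def test_clutter_only_returns_sentinel(self):
        assert proc.select_gate(self._mmode(active=(), amp=0.0)) is None


class TestEnvelope:
    def test_tone_envelope_near_true_velocity(self):
        spec = proc.compute_spectrogram(tone(1732.0, amp=10.0)
                                        + 1e-3 * tone(0.0), PRF, F0)
        env = proc.trace_envelope(spec)
        v_expected = 33.3
        assert np.median(env.v_max) == pytest.approx(
            v_expected, abs=2 * spec.bin_width_cm_s)
        assert env.quality.all()

    def test_pure_noise_flagged_zero(self):
        rng = np.random.default_rng(1)
        x = 1e-3 * (rng.standard_normal(48000) + 1j * rng.standard_normal(48000))
        env = proc.trace_envelope(proc.compute_spectrogram(x, PRF, F0))
        assert not env.quality.any()
        assert np.allclose(env.v_max, 0.0)

    def test_reverse_flow_gives_negative_envelope(self, vco_pipeline):
        traces, _, result = vco_pipeline
        env = result.envelopes[0]
        # the end of the occlusion carries reverse (negative) envelope values
        late = env.t > traces.duration * 0.9
        assert env.v_max[late].min() < -10.0


class TestBeats:
    def test_simulated_beats_recovered(self):
        bt = cd.BeatTemplate(systolic_amplitude=90.0, systolic_duration=0.25,
                             diastolic_level=25.0, period=0.8, end_level=10.0)
        frame_rate = 400.0
        one = cd.gen_beat_waveform(bt, np.arange(0, 0.8, 1 / frame_rate))
        env = synthetic_envelope(one, 10, frame_rate)
        beats = proc.detect_beats(env)
        assert len(beats) == 10
        metrics = proc.compute_beat_metrics(env, beats)
        assert metrics.hr.median() == pytest.approx(75.0, abs=2.0)

    def test_flat_envelope_no_beats(self):
        env = synthetic_envelope([30.0] * 400, 3)
        assert len(proc.detect_beats(env)) == 0

    def test_noise_envelope_no_beats(self):
        rng = np.random.default_rng(2)
        v = rng.normal(0.0, 2.0, 2000)
        env = proc.Envelope(t=np.arange(2000) / 400.0, v_max=v,
                            quality=np.zeros(2000, bool),
                            snr=np.ones(2000), noise_floor=np.ones(2000))
        assert len(proc.detect_beats(env)) == 0


class TestBeatMetrics:
    def test_rectangular_beat_closed_form(self):
        frame_rate = 400.0
        beat = [100.0] * 80 + [20.0] * 240  # 0.2 s systole, 0.6 s diastole
        env = synthetic_envelope(beat, 6, frame_rate)
        onsets = np.arange(0, 6) * 320
        beats = proc.Beats(onset_idx=onsets, peak_idx=onsets + 40, t=env.t)
        m = proc.compute_beat_metrics(env, beats)
        row = m.iloc[0]
        assert row.psv == pytest.approx(100.0)
        assert row.edv == pytest.approx(20.0)
        assert row.tav == pytest.approx(40.0, rel=1e-6)
        assert row.ri == pytest.approx(0.8)
        assert row.pi == pytest.approx(2.0)
        assert row.hr == pytest.approx(75.0)

    def test_constant_envelope_zero_indices(self):
        env = synthetic_envelope([30.0] * 400, 2)
        beats = proc.Beats(onset_idx=np.array([0, 400]),
                           peak_idx=np.array([10, 410]), t=env.t)
        m = proc.compute_beat_metrics(env, beats)
        assert m.iloc[0].ri == 0.0 and m.iloc[0].pi == 0.0
        assert m.iloc[0].psv == m.iloc[0].edv == m.iloc[0].tav == 30.0

    def test_low_bp_reference_values(self):
        # PSV 73, EDV -29, TAV 16 -> RI 1.397, PI 6.375
        frame_rate = 50.0
        seg = np.array([73.0, 4.0, -29.0])
        env = proc.Envelope(t=np.arange(6, dtype=float) / frame_rate,
                            v_max=np.tile(seg, 2),
                            quality=np.ones(6, bool), snr=np.full(6, 50.0),
                            noise_floor=np.full(6, 1e-6))
        beats = proc.Beats(onset_idx=np.array([0, 3]),
                           peak_idx=np.array([0, 3]), t=env.t)
        m = proc.compute_beat_metrics(env, beats)
        assert m.iloc[0].ri == pytest.approx((73 + 29) / 73, abs=1e-3)
        assert m.iloc[0].pi == pytest.approx(102 / 16, abs=1e-3)

    def test_zero_tav_pi_sentinel(self):
        env = synthetic_envelope([50.0, 0.0, -50.0, 0.0] * 100, 2)
        beats = proc.Beats(onset_idx=np.array([0, 400]),
                           peak_idx=np.array([0, 400]), t=env.t)
        m = proc.compute_beat_metrics(env, beats)
        assert np.isnan(m.iloc[0].pi)


class TestAngleEstimate:
    def test_symmetric_case(self):
        est = cd.estimate_angle(34.641, 34.641, 30.0)
        assert est.alpha_deg == pytest.approx(0.0, abs=1e-9)
        assert est.speed_cm_s == pytest.approx(40.0, abs=1e-3)

    def test_ten_degree_case(self):
        est = cd.estimate_angle(46.985, 38.302, 30.0)
        assert est.alpha_deg == pytest.approx(10.0, abs=1e-2)
        assert est.speed_cm_s == pytest.approx(50.0, abs=1e-2)

    def test_thirty_degree_case(self):
        est = cd.estimate_angle(40.0, 20.0, 30.0)
        assert est.alpha_deg == pytest.approx(30.0, abs=1e-9)
        assert est.speed_cm_s == pytest.approx(40.0, abs=1e-9)

    @given(v=st.floats(5.0, 150.0), alpha=st.floats(-40.0, 40.0))
    def test_round_trip_exact(self, v, alpha):
        theta = np.deg2rad(30.0)
        a = np.deg2rad(alpha)
        tav1 = v * np.cos(a - theta)
        tav2 = v * np.cos(a + theta)
        est = cd.estimate_angle(tav1, tav2, 30.0)
        assert est.alpha_deg == pytest.approx(alpha, abs=1e-9)
        assert est.speed_cm_s == pytest.approx(v, rel=1e-9)

    def test_indeterminate(self):
        with pytest.raises(DataError):
            cd.estimate_angle(10.0, -10.0, 30.0)


class TestClassify:
    def test_pulsatile_window(self):
        bt = cd.BeatTemplate(systolic_amplitude=80.0, systolic_duration=0.25,
                             diastolic_level=20.0, period=0.75, end_level=8.0)
        one = cd.gen_beat_waveform(bt, np.arange(0, 0.75, 1 / 400.0))
        env = synthetic_envelope(one, 12)
        states = proc.classify_flow_state(None, env)
        assert set(states.table.state) == {"pulsatile"}

    def test_no_flow_without_ecg(self):
        rng = np.random.default_rng(3)
        n = 4000
        env = proc.Envelope(t=np.arange(n) / 400.0,
                            v_max=np.zeros(n),
                            quality=np.zeros(n, bool), snr=np.zeros(n),
                            noise_floor=np.ones(n))
        states = proc.classify_flow_state(None, env)
        assert set(states.table.state) == {"no_flow"}

    def test_pea_with_ecg_events(self):
        rng = np.random.default_rng(4)
        n = 4000
        v = 9.0 + rng.normal(0, 0.8, n)  # low, near-pulseless flow
        env = proc.Envelope(t=np.arange(n) / 400.0, v_max=v,
                            quality=np.ones(n, bool), snr=np.full(n, 10.0),
                            noise_floor=np.full(n, 1e-3))
        ecg = np.arange(0.0, 10.0, 0.66)
        states = proc.classify_flow_state(None, env, ecg_events=ecg)
        assert set(states.table.state) == {"low_flow_pea"}
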
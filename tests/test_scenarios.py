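"""Scenario generator: beat waveforms, VCO/VF/PEA sequences, studies, sync."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import carodop as cd
from carodop.errors import ConfigError


def _grid(period, fs=1000.0):
    return np.arange(0.0, period, 1.0 / fs)


class TestBeatWaveform:
    def test_bounds_flat_tail(self):
        bt = cd.BeatTemplate(systolic_amplitude=100, systolic_duration=0.2,
                             diastolic_level=10, period=0.8)
        v = cd.gen_beat_waveform(bt, _grid(0.8))
        assert v.min() == pytest.approx(10.0, abs=1e-9)
        assert v.max() == pytest.approx(100.0, abs=1e-3)

    def test_rectangular_time_average(self):
        # degenerate rectangle: (100*0.2 + 20*0.6) / 0.8 = 40 cm/s
        bt = cd.BeatTemplate(systolic_amplitude=100, systolic_duration=0.2,
                             diastolic_level=20, period=0.8)
        v = cd.gen_beat_waveform(bt, _grid(0.8, 10000.0), shape="rect")
        assert v.mean() == pytest.approx(40.0, rel=1e-3)

    def test_reverse_lobe_minimum(self):
        bt = cd.BeatTemplate(systolic_amplitude=100, systolic_duration=0.2,
                             diastolic_level=10, period=0.8,
                             reverse_amplitude=29.0)
        v = cd.gen_beat_waveform(bt, _grid(0.8))
        assert v.min() == pytest.approx(-29.0, abs=1e-2)

    @given(s=st.floats(40, 150), d=st.floats(-20, 35), ts=st.floats(0.1, 0.4),
           period=st.floats(0.5, 1.2), e=st.floats(-35, 35))
    def test_closed_form_time_average(self, s, d, ts, period, e):
        if ts >= period or s <= d:
            return
        bt = cd.BeatTemplate(systolic_amplitude=s, systolic_duration=ts,
                             diastolic_level=d, period=period, end_level=e)
        v = cd.gen_beat_waveform(bt, _grid(period, 20000.0))
        assert v.mean() == pytest.approx(bt.time_average(), abs=0.05)

    def test_invalid_period_rejected(self):
        with pytest.raises(ConfigError):
            cd.BeatTemplate(systolic_amplitude=100, systolic_duration=0.2,
                            diastolic_level=10, period=-1.0)


class TestVCO:
    def test_nadir_sbp_below_60(self):
        traces = cd.gen_vco_sequence(cd.ScenarioConfig(kind="vco"),
                                     np.random.default_rng(0))
        assert traces.truth["sbp"].min() < 60.0

    def test_no_reverse_flow_above_sbp_80(self):
        traces = cd.gen_vco_sequence(cd.ScenarioConfig(kind="vco"),
                                     np.random.default_rng(1))
        high = traces.truth[traces.truth["sbp"] > 80.0]
        assert (high["edv"] > 0).all()
        # waveform itself never reverses during those beats
        for _, b in high.iterrows():
            mask = (traces.time >= b.t_start) & (traces.time < b.t_end)
            assert traces.velocity[mask].min() > 0

    def test_tav_coupling_noise_free(self):
        cfg = cd.ScenarioConfig(kind="baseline", duration=10.0, noise_sd=0.0,
                                map_noise_frac=0.0, baseline_map=86.0)
        traces = cd.gen_vco_sequence(cfg, np.random.default_rng(2))
        # TAV = 8.3 + 0.333 * 86 = 36.938 cm/s for every beat
        assert np.allclose(traces.truth["tav"], 8.3 + 0.333 * 86.0, atol=1e-9)

    def test_map_declines_monotonically_without_noise(self):
        cfg = cd.ScenarioConfig(kind="vco", map_noise_frac=0.0, noise_sd=0.0)
        traces = cd.gen_vco_sequence(cfg, np.random.default_rng(3))
        assert (np.diff(traces.truth["map"]) < 0).all()

    def test_waveform_beat_mean_matches_truth_tav(self):
        traces = cd.gen_vco_sequence(cd.ScenarioConfig(kind="vco"),
                                     np.random.default_rng(4))
        for _, b in traces.truth.iloc[::10].iterrows():
            mask = (traces.time >= b.t_start) & (traces.time < b.t_end)
            # 100 Hz sampling rounds the beat boundaries: a fraction of one
            # ~100 cm/s systolic sample can move the 0.67 s beat mean by
            # a few tenths of a cm/s
            assert traces.velocity[mask].mean() == pytest.approx(b.tav, abs=0.8)

    def test_invalid_nadir_rejected(self):
        with pytest.raises(ConfigError):
            cd.ScenarioConfig(kind="vco", nadir_map=90.0, baseline_map=86.0,
                              nadir_sbp=33.0)

    def test_uniform_strictly_increasing_grid(self):
        traces = cd.gen_vco_sequence(cd.ScenarioConfig(kind="vco"),
                                     np.random.default_rng(5))
        dt = np.diff(traces.time)
        assert dt.min() > 0 and np.allclose(dt, dt[0])


class TestVF:
    def test_defib_delay_bounded(self):
        for seed in range(5):
            traces = cd.gen_vf_episode(cd.ScenarioConfig(kind="vf"),
                                       np.random.default_rng(seed))
            assert traces.meta["defib_delay"] <= 60.0

    def test_flow_cessation_no_beat_locked_oscillation(self):
        cfg = cd.ScenarioConfig(kind="vf", vf_onset=10.0, defib_delay=15.0)
        traces = cd.gen_vf_episode(cfg, np.random.default_rng(6))
        t0 = traces.meta["vf_onset"] + 2.0
        t1 = traces.meta["rosc"]
        mask = (traces.time > t0) & (traces.time < t1)
        v = traces.velocity[mask]
        # zero-mean noise at the configured SD, no cardiac-band power excess
        assert abs(v.mean()) < 1.0
        assert v.std() == pytest.approx(cfg.vf_noise_sd, rel=0.3)
        ecg = traces.ecg_events
        assert not np.any((ecg > traces.meta["vf_onset"]) & (ecg < t1))

    def test_ecg_resumes_at_rosc(self):
        traces = cd.gen_vf_episode(cd.ScenarioConfig(kind="vf", vf_onset=8.0),
                                   np.random.default_rng(7))
        rosc = traces.meta["rosc"]
        assert np.any(traces.ecg_events >= rosc)

    def test_onset_after_duration_rejected(self):
        with pytest.raises(ConfigError):
            cd.ScenarioConfig(kind="vf", duration=20.0, vf_onset=25.0)


class TestPEA:
    def test_pressure_and_velocity_levels(self):
        cfg = cd.ScenarioConfig(kind="pea", duration=20.0)
        traces = cd.gen_pea_segment(cfg, np.random.default_rng(8))
        assert traces.pressure.max() == pytest.approx(20.0, abs=1.0)
        assert np.abs(traces.velocity).mean() == pytest.approx(10.0, abs=1.5)
        assert len(traces.ecg_events) >= 20

    def test_zero_velocity_gives_pure_noise(self):
        cfg = cd.ScenarioConfig(kind="pea", duration=10.0, pea_velocity=0.0)
        traces = cd.gen_pea_segment(cfg, np.random.default_rng(9))
        assert abs(traces.velocity.mean()) < 0.5
        assert traces.velocity.std() == pytest.approx(cfg.pea_noise_sd, rel=0.2)


class TestSyncChannel:
    def test_exact_intervals_without_jitter(self):
        pulses = cd.gen_sync_channel(60.0, 6.0, 0.0)
        assert len(pulses) == 10
        assert np.allclose(np.diff(pulses), 6.0)

    def test_short_record_single_pulse(self):
        assert np.array_equal(cd.gen_sync_channel(3.0, 6.0, 0.0), [0.0])

    def test_jitter_interval_sd(self):
        # SD of the difference of two independent jitters = sqrt(2) * 0.01
        pulses = cd.gen_sync_channel(6006.0, 6.0, 0.01,
                                     np.random.default_rng(10))
        sd = np.diff(pulses).std()
        assert sd == pytest.approx(np.sqrt(2) * 0.01, rel=0.1)


class TestStudy:
    def test_default_study_has_41_sequences(self):
        ds = cd.gen_study(cd.StudyConfig(seed=3))
        assert len(ds.sequences) == 41
        assert ds.table["sequence"].nunique() == 41

    def test_nesting_conservation(self):
        ds = cd.gen_study(cd.StudyConfig(seed=4))
        per_animal = ds.table.groupby("animal")["sequence"].nunique()
        assert per_animal.sum() == sum(ds.config.sequences_per_animal)
        # each sequence belongs to exactly one animal
        assert (ds.table.groupby("sequence")["animal"].nunique() == 1).all()

    def test_zero_sds_identical_coupling(self):
        sc = cd.StudyConfig(seed=5, animal_sd=0.0, sequence_sd=0.0,
                            residual_sd=0.0, n_animals=3,
                            sequences_per_animal=(2, 2, 2))
        scen = cd.ScenarioConfig(kind="vco", noise_sd=0.0)
        ds = cd.gen_study(sc, scen)
        m = ds.table["map_mmHg"].to_numpy()
        expected = 8.3 + 0.333 * m
        assert np.allclose(ds.table["tav_cm_s"], expected, atol=1e-9)

    def test_variance_decomposition_large_n(self):
        sc = cd.StudyConfig(seed=6, n_animals=60,
                            sequences_per_animal=(4,) * 60,
                            sequence_duration=40.0)
        ds = cd.gen_study(sc)
        a = np.asarray(ds.effects["animal_intercepts"])
        b = np.asarray(list(ds.effects["sequence_intercepts"].values()))
        assert a.var() == pytest.approx(9.381 ** 2, rel=0.35)
        assert b.var() == pytest.approx(2.449 ** 2, rel=0.35)

    def test_determinism_same_seed(self):
        ds1 = cd.gen_study(cd.StudyConfig(seed=7))
        ds2 = cd.gen_study(cd.StudyConfig(seed=7))
        pd.testing.assert_frame_equal(ds1.table, ds2.table)
        for (a1, s1, t1), (a2, s2, t2) in zip(ds1.sequences, ds2.sequences):
            assert (a1, s1) == (a2, s2)
            assert np.array_equal(t1.velocity, t2.velocity)
            assert np.array_equal(t1.pressure, t2.pressure)

    def test_mismatched_sequence_counts_rejected(self):
        with pytest.raises(ConfigError):
            cd.StudyConfig(n_animals=3, sequences_per_animal=(2, 2))

    def test_durations_average_near_50s(self):
        ds = cd.gen_study(cd.StudyConfig(seed=8))
        durations = [tr.duration for _, _, tr in ds.sequences]
        assert np.mean(durations) == pytest.approx(50.0, abs=1.0)
        assert min(durations) >= 29.0 and max(durations) <= 70.0
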
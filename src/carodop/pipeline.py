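"""End-to-end orchestration of the virtual device.

``process_record`` runs the full measurement chain on a dual-transducer IQ
record: wall filter -> colour M-mode -> gate selection -> spectrogram ->
envelope -> beats -> per-beat indices on both transducers -> per-beat angle
correction -> flow states.  ``run_sequence`` couples it to the scenario
simulator and IQ synthesizer for closed-loop recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import processing as proc
from .errors import DataError
from .probes import ProbeGeometry, VesselModel
from .scenarios import ScenarioConfig, ScenarioTraces, gen_vco_sequence
from .synthesize import DualIQRecord, synthesize_iq

__all__ = ["ProcessingSettings", "ProcessResult", "process_record", "run_sequence"]


@dataclass(frozen=True)
class ProcessingSettings:
    """Tunable parameters of the measurement chain (device configuration)."""

    wall_cutoff_hz: float = 100.0
    wall_order: int = 4
    spec_window_s: float = 0.010
    spec_overlap: float = 0.75
    mmode_frame_s: float = 0.02
    envelope_percentile: float = 0.95
    noise_margin_db: float = 6.0
    smooth_frames: int = 5
    min_beat_interval_s: float = 0.25
    beat_prominence: float = 20.0
    pulsatile_psv: float = 20.0
    pea_tav: float = 12.0
    state_window_s: float = 2.0
    signed_tav: bool = True


@dataclass
class ProcessResult:
    """Outputs of one processed record."""

    gate_idx: tuple[int, int]
    envelopes: tuple[proc.Envelope, proc.Envelope]
    metrics: pd.DataFrame
    flow_states: proc.FlowStateSeries
    mmode: tuple[proc.ColorMMode, proc.ColorMMode]
    spectrograms: tuple[proc.Spectrogram, proc.Spectrogram]
    settings: ProcessingSettings
    meta: dict = field(default_factory=dict)


def _metrics_over_windows(env: proc.Envelope, windows: list[tuple[int, int]],
                          signed_tav: bool) -> pd.DataFrame:
    """Beat metrics of a second transducer evaluated on the reference
    transducer's beat windows (both envelopes share the frame clock)."""
    rows = []
    v = env.v_max
    n_end = max(int(round(0.012 * env.frame_rate)), 1)
    for b, (i0, i1) in enumerate(windows):
        seg = v[i0:i1]
        tav_seg = seg if signed_tav else np.clip(seg, 0.0, None)
        rows.append((b, float(seg.max()), float(np.median(seg[-n_end:])),
                     float(tav_seg.mean())))
    return pd.DataFrame(rows, columns=["beat", "psv", "edv", "tav"])


def process_record(record: DualIQRecord,
                   settings: ProcessingSettings | None = None,
                   ecg_events: np.ndarray | None = None) -> ProcessResult:
    """Run the full measurement chain on a dual IQ record.

    Beats are segmented on transducer 1 (self-contained, no ECG needed); the
    same beat windows are evaluated on transducer 2 so each beat yields the
    TAV pair for the geometric angle inversion.  Corrected columns
    (alpha_deg, speed_corrected, psv_corrected, edv_corrected) are appended
    to the per-beat table; when no beats are found the table is empty and the
    flow-state series still covers the record.
    """
    st = settings or ProcessingSettings()
    geom = record.geometry
    filtered = proc.wall_filter(record.iq, record.prf, st.wall_cutoff_hz,
                                st.wall_order)
    mmodes, gates, specs, envs = [], [], [], []
    for k in (0, 1):
        mm = proc.compute_color_mmode(filtered[k], record.prf, geom.f0,
                                      geom.c_sound, st.mmode_frame_s)
        mmodes.append(mm)
        g = proc.select_gate(mm)
        if g is None:
            g = int(np.argmax(mm.power.mean(axis=-1)))  # no-flow fallback gate
        gates.append(g)
        sp = proc.compute_spectrogram(filtered[k, g], record.prf, geom.f0,
                                      geom.c_sound, st.spec_window_s,
                                      st.spec_overlap)
        specs.append(sp)
        envs.append(proc.trace_envelope(sp, st.envelope_percentile,
                                        st.noise_margin_db, st.smooth_frames))

    env1, env2 = envs
    beats = proc.detect_beats(env1, st.min_beat_interval_s, st.beat_prominence)
    theta0 = geom.half_angle_deg
    if len(beats):
        metrics = proc.compute_beat_metrics(env1, beats, st.signed_tav)
        windows = proc._beat_windows(beats, len(env1.v_max))
        m2 = _metrics_over_windows(env2, windows, st.signed_tav)
        alphas, speeds, psv_c, edv_c = [], [], [], []
        for (_, r1), (_, r2) in zip(metrics.iterrows(), m2.iterrows()):
            try:
                est = proc.estimate_angle(r1.tav, r2.tav, theta0)
            except DataError:
                alphas.append(np.nan); speeds.append(np.nan)
                psv_c.append(np.nan); edv_c.append(np.nan)
                continue
            c1 = np.cos(np.deg2rad(est.alpha_deg - theta0))
            c2 = np.cos(np.deg2rad(est.alpha_deg + theta0))
            alphas.append(est.alpha_deg)
            speeds.append(est.speed_cm_s)
            psv_c.append(0.5 * (r1.psv / c1 + r2.psv / c2))
            edv_c.append(0.5 * (r1.edv / c1 + r2.edv / c2))
        metrics = metrics.assign(alpha_deg=alphas, speed_corrected=speeds,
                                 psv_corrected=psv_c, edv_corrected=edv_c,
                                 tav2=m2["tav"].to_numpy())
    else:
        metrics = pd.DataFrame(columns=proc.METRIC_COLUMNS
                               + ["alpha_deg", "speed_corrected",
                                  "psv_corrected", "edv_corrected", "tav2"])

    states = proc.classify_flow_state(metrics if len(metrics) else None, env1,
                                      ecg_events=ecg_events, beats=beats,
                                      window_s=st.state_window_s,
                                      pulsatile_psv=st.pulsatile_psv,
                                      pea_tav=st.pea_tav)
    return ProcessResult(gate_idx=(gates[0], gates[1]),
                         envelopes=(env1, env2), metrics=metrics,
                         flow_states=states, mmode=tuple(mmodes),
                         spectrograms=tuple(specs), settings=st,
                         meta={"settings": asdict(st)})


def run_sequence(scenario: ScenarioConfig | None = None,
                 geometry: ProbeGeometry | None = None,
                 vessel: VesselModel | None = None,
                 settings: ProcessingSettings | None = None,
                 snr_db: float = 20.0, clutter_db: float = 40.0,
                 rng: np.random.Generator | int | None = None,
                 traces: ScenarioTraces | None = None,
                 ) -> tuple[ScenarioTraces, DualIQRecord, ProcessResult]:
    """Simulate (or accept) one scenario, synthesize IQ, and process it."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if rng is None:
        rng = np.random.default_rng()
    if traces is None:
        scenario = scenario or ScenarioConfig(kind="vco")
        traces = gen_vco_sequence(scenario, rng)
    record = synthesize_iq(traces, geometry, vessel, snr_db=snr_db,
                           clutter_db=clutter_db, rng=rng)
    result = process_record(record, settings, ecg_events=traces.ecg_events)
    return traces, record, result
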
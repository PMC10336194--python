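"""Ground-truth hemodynamic scenario generation.

This module produces paired carotid pressure/velocity traces for the study
conditions the virtual Doppler device is evaluated on:

* controlled hypotension by vena cava occlusion (VCO): mean arterial pressure
  (MAP) falls roughly 86 -> 23 mmHg over ~50 s, pulse pressure shrinks, and a
  high-resistance reverse-flow component grows once systolic pressure drops
  below ~80 mmHg, reaching about -29 cm/s end-diastolic velocity at the nadir;
* ventricular fibrillation (VF): pulsatile flow ceases after a short broadband
  "white noise" marker, pressure collapses, and organized flow returns at ROSC
  after a defibrillation delay of at most 60 s;
* true pulseless electrical activity (PEA): organized ECG events continue while
  systolic pressure sits near 20 mmHg and flow is near-pulseless around
  10 cm/s.

Beat-wise time-averaged velocity (TAV) is coupled to instantaneous MAP through
a configurable polynomial, and full multi-animal studies add hierarchical
animal/sequence random effects so the downstream mixed-model analysis sees the
variance structure it assumes.

All traces are returned as :class:`ScenarioTraces` on a uniform 100 Hz grid,
with per-beat ground truth (PSV/EDV/TAV plus pressures) carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "BeatTemplate",
    "ScenarioConfig",
    "ScenarioTraces",
    "StudyConfig",
    "StudyDataset",
    "gen_beat_waveform",
    "gen_vco_sequence",
    "gen_vf_episode",
    "gen_pea_segment",
    "gen_sync_channel",
    "gen_study",
]

TRUTH_COLUMNS = [
    "beat",
    "t_start",
    "t_end",
    "psv",
    "edv",
    "tav",
    "sbp",
    "dbp",
    "map",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeatTemplate:
    """Parametric single-beat velocity waveform.

    The beat is a raised-cosine systolic lobe rising from ``diastolic_level``
    to ``systolic_amplitude`` and back, followed by a half-cosine diastolic
    decay from ``diastolic_level`` to the end-diastolic level.  The end level
    defaults to ``-reverse_amplitude`` when a reverse component is configured
    (high-resistance flow reversing in diastole) and to ``diastolic_level``
    otherwise; it can also be set explicitly, e.g. baseline carotid beats that
    decay from ~35 cm/s after systole to ~10 cm/s at end-diastole.

    All velocities are cm/s, durations seconds.
    """

    systolic_amplitude: float
    systolic_duration: float
    diastolic_level: float
    period: float
    reverse_amplitude: float = 0.0
    end_level: float | None = None

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ConfigError(f"period must be positive, got {self.period}")
        if not 0 < self.systolic_duration < self.period:
            raise ConfigError(
                "systolic_duration must lie in (0, period), got "
                f"{self.systolic_duration} for period {self.period}"
            )
        if self.reverse_amplitude < 0:
            raise ConfigError("reverse_amplitude is a magnitude and must be >= 0")
        if not self.systolic_amplitude > self.diastolic_level:
            raise ConfigError("systolic_amplitude must exceed diastolic_level")

    @property
    def resolved_end_level(self) -> float:
        if self.end_level is not None:
            return float(self.end_level)
        if self.reverse_amplitude > 0:
            return -float(self.reverse_amplitude)
        return float(self.diastolic_level)

    def time_average(self) -> float:
        """Closed-form mean of the beat over one period.

        mean = D0/2 + fs*S/2 + (1-fs)*E/2 with fs = systolic fraction,
        D0 the diastolic (post-systolic) level and E the end level; both the
        raised-cosine lobe and the half-cosine decay average to the midpoint
        of their endpoints.
        """
        fs = self.systolic_duration / self.period
        d0 = self.diastolic_level
        return 0.5 * (d0 + fs * self.systolic_amplitude + (1.0 - fs) * self.resolved_end_level)


@dataclass
class ScenarioConfig:
    """Scenario parameters; defaults are the study's calibration anchors.

    Pressure and velocity anchors tie the generator to the observed VCO
    means: baseline (MAP 86, SBP 111, DBP 66, PSV 102, TAV ~37, EDV 10) and
    nadir (MAP 23, SBP 33, DBP 18, PSV 73, TAV ~16, EDV -29).  Reverse flow
    ramps in below a systolic pressure of 80 mmHg.
    """

    kind: str = "vco"  # baseline | vco | vf | pea
    duration: float = 50.0
    sample_rate: float = 100.0
    heart_rate: float = 90.0
    systolic_duration: float = 0.25

    baseline_map: float = 86.0
    nadir_map: float = 23.0
    baseline_sbp: float = 111.0
    nadir_sbp: float = 33.0
    baseline_dbp: float = 66.0
    nadir_dbp: float = 18.0
    reverse_onset_sbp: float = 80.0

    psv_baseline: float = 102.0
    psv_nadir: float = 73.0
    edv_baseline: float = 10.0
    edv_nadir: float = -29.0

    tav_map_intercept: float = 8.3
    tav_map_slope: float = 0.333
    tav_map_quad: float = 0.0

    noise_sd: float = 1.0  # per-beat TAV noise, cm/s
    map_noise_frac: float = 0.015  # per-beat multiplicative MAP noise

    vf_onset: float = 10.0
    vf_max_duration: float = 60.0
    vf_marker_duration: float = 1.5
    vf_marker_sd: float = 30.0  # cm/s, broadband fibrillation marker
    vf_noise_sd: float = 2.0  # cm/s, no-flow velocity noise
    vf_pressure: float = 15.0  # mmHg, non-pulsatile collapsed pressure
    defib_delay: float | None = None  # None -> drawn uniform on [15, vf_max]
    vf_episode_gap: float = 300.0  # s between consecutive episodes

    pea_sbp: float = 20.0
    pea_velocity: float = 10.0
    pea_noise_sd: float = 1.0

    sync_interval: float = 6.0
    sync_jitter_sd: float = 0.005

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.kind not in ("baseline", "vco", "vf", "pea"):
            raise ConfigError(f"unknown scenario kind {self.kind!r}")
        if self.duration <= 0 or self.sample_rate <= 0 or self.heart_rate <= 0:
            raise ConfigError("duration, sample_rate and heart_rate must be positive")
        period = 60.0 / self.heart_rate
        if not 0 < self.systolic_duration < period:
            raise ConfigError("systolic_duration must fit within one cardiac cycle")
        for name in ("baseline_sbp", "baseline_dbp", "nadir_sbp", "nadir_dbp",
                     "baseline_map", "nadir_map", "pea_sbp"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.kind == "vco":
            if self.nadir_map >= self.baseline_map:
                raise ConfigError("VCO nadir MAP must be below baseline MAP")
            if self.nadir_sbp >= 60.0:
                # occlusion is maintained until systolic pressure drops below 60
                raise ConfigError("VCO terminates below SBP 60 mmHg; nadir_sbp must be < 60")
        if self.kind == "vf":
            if self.vf_max_duration > 60.0:
                raise ConfigError("untreated VF is limited to 60 s before defibrillation")
            if self.vf_onset >= self.duration:
                raise ConfigError("vf_onset must precede the end of the record")
            if self.defib_delay is not None and not 0 < self.defib_delay <= self.vf_max_duration:
                raise ConfigError("defib_delay must lie in (0, vf_max_duration]")


@dataclass
class ScenarioTraces:
    """Uniformly sampled ground-truth traces plus per-beat truth records.

    ``velocity`` is signed centerline velocity (negative = reverse flow).
    ``ecg_events`` and ``sync_pulses`` are event times snapped to the sample
    grid.  ``truth`` holds one row per complete beat with PSV/EDV/TAV and the
    beat's systolic/diastolic/mean pressures.  ``segments`` tags intervals
    such as VF flow cessation and ROSC for downstream validation.
    """

    time: np.ndarray
    pressure: np.ndarray
    velocity: np.ndarray
    ecg_events: np.ndarray
    sync_pulses: np.ndarray
    truth: pd.DataFrame
    segments: list[tuple[str, float, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def fs(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) + 1.0 / self.fs

    def validate(self) -> None:
        dt = np.diff(self.time)
        if len(dt) and (dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-9)):
            raise ConfigError("time grid must be strictly increasing and uniform")


@dataclass
class StudyConfig:
    """Hierarchical multi-animal study layout and variance structure.

    Defaults reproduce the reference study: 7 animals contributing 41 VCO
    sequences, intercept SDs chosen so the animal : sequence : residual
    variance decomposition of TAV is 88 : 6 : 6 (ICCs 0.88 and 0.94).
    """

    n_animals: int = 7
    sequences_per_animal: Sequence[int] = (6, 6, 6, 6, 6, 6, 5)
    animal_sd: float = 9.381
    sequence_sd: float = 2.449
    residual_sd: float = 2.449
    slope_sd: tuple[float, float] = (0.0, 0.0)  # per-animal SDs for MAP, MAP^2 slopes
    fixed_beta: tuple[float, float, float] = (8.3, 0.333, 0.0)
    seed: int = 0
    obs_rate: float = 1.0  # Hz of the long-format observation table
    sequence_duration: float | None = None  # None -> uniform(30, 69) rescaled to mean 50
    baseline_map_sd: float = 6.0  # between-sequence biological variation
    nadir_map_sd: float = 2.5

    def __post_init__(self) -> None:
        if len(self.sequences_per_animal) != self.n_animals:
            raise ConfigError("sequences_per_animal must have n_animals entries")
        if any(n <= 0 for n in self.sequences_per_animal):
            raise ConfigError("each animal needs at least one sequence")
        for name in ("animal_sd", "sequence_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if any(s < 0 for s in self.slope_sd):
            raise ConfigError("slope SDs must be >= 0")

    @property
    def n_sequences(self) -> int:
        return int(sum(self.sequences_per_animal))


@dataclass
class StudyDataset:
    """Generated study: tagged per-sequence traces plus the 1 Hz long table.

    ``table`` columns: animal, sequence, t_s, map_mmHg, tav_cm_s.
    """

    sequences: list[tuple[str, str, ScenarioTraces]]
    table: pd.DataFrame
    config: StudyConfig
    scenario: ScenarioConfig
    effects: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------


def _piecewise_beat(t_local: np.ndarray, peak: float, level: float, end: float,
                    t_sys: float, period: float) -> np.ndarray:
    """Raised-cosine systolic lobe (level->peak->level over ``t_sys``) followed
    by a half-cosine decay from ``level`` to ``end`` over the diastole."""
    v = np.empty_like(t_local, dtype=float)
    sys_mask = t_local < t_sys
    tau = t_local[sys_mask]
    v[sys_mask] = level + (peak - level) * 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / t_sys))
    s = (t_local[~sys_mask] - t_sys) / (period - t_sys)
    v[~sys_mask] = end + (level - end) * 0.5 * (1.0 + np.cos(np.pi * s))
    return v


def gen_beat_waveform(template: BeatTemplate, t_grid: np.ndarray,
                      shape: str = "cosine") -> np.ndarray:
    """Sample one beat of the template on ``t_grid`` (seconds within [0, period)).

    ``shape="rect"`` gives the degenerate piecewise-constant beat (systolic
    amplitude during systole, diastolic level otherwise), useful as an
    analytic oracle: its time average is exactly
    ``(S*Ts + D*(T-Ts))/T``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size and (t.min() < 0 or t.max() >= template.period):
        raise ConfigError("t_grid must lie within one period [0, period)")
    if shape == "rect":
        return np.where(t < template.systolic_duration,
                        template.systolic_amplitude, template.diastolic_level)
    if shape != "cosine":
        raise ConfigError(f"unknown beat shape {shape!r}")
    return _piecewise_beat(t, template.systolic_amplitude, template.diastolic_level,
                           template.resolved_end_level, template.systolic_duration,
                           template.period)


def gen_sync_channel(duration: float, interval: float = 6.0, jitter_sd: float = 0.0,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Synchronization pulse times: one pulse every ``interval`` seconds plus
    independent Gaussian jitter, starting at t=0."""
    if interval <= 0:
        raise ConfigError("sync interval must be positive")
    base = np.arange(0.0, duration, interval)
    if base.size == 0:
        base = np.array([0.0])
    if jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        jitter = rng.normal(0.0, jitter_sd, size=base.size)
        jitter[0] = max(jitter[0], -0.0)  # first pulse stays at/after t=0
        return np.sort(base + jitter)
    return base


def _snap(times: np.ndarray, fs: float) -> np.ndarray:
    return np.round(np.asarray(times, dtype=float) * fs) / fs


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------


def _affine(x: float, x0: float, x1: float, y0: float, y1: float) -> float:
    return y0 + (y1 - y0) * (x - x0) / (x1 - x0)


def _beat_schedule_vco(cfg: ScenarioConfig, n_beats: int, rng: np.random.Generator,
                       tav_offset: float, slope_offset: float, quad_offset: float,
                       baseline_map: float, nadir_map: float) -> pd.DataFrame:
    """Per-beat targets for a VCO run: MAP ramps linearly from baseline to
    nadir; SBP/DBP/PSV follow global affine maps anchored at the nominal
    baseline/nadir pairs; EDV ramps negative once SBP crosses the reverse-flow
    onset; TAV follows the (possibly offset) MAP coupling."""
    frac = np.linspace(0.0, 1.0, n_beats) if n_beats > 1 else np.zeros(1)
    m = baseline_map + (nadir_map - baseline_map) * frac
    if cfg.map_noise_frac > 0:
        m = m * (1.0 + rng.normal(0.0, cfg.map_noise_frac, size=n_beats))
    bm, nm = cfg.baseline_map, cfg.nadir_map
    sbp = _affine(m, nm, bm, cfg.nadir_sbp, cfg.baseline_sbp)
    dbp = _affine(m, nm, bm, cfg.nadir_dbp, cfg.baseline_dbp)
    psv = _affine(m, nm, bm, cfg.psv_nadir, cfg.psv_baseline)
    rev = np.clip((cfg.reverse_onset_sbp - sbp)
                  / (cfg.reverse_onset_sbp - cfg.nadir_sbp), 0.0, None)
    edv = cfg.edv_baseline + (cfg.edv_nadir - cfg.edv_baseline) * rev
    tav = ((cfg.tav_map_intercept + tav_offset)
           + (cfg.tav_map_slope + slope_offset) * m
           + (cfg.tav_map_quad + quad_offset) * m ** 2)
    if cfg.noise_sd > 0:
        tav = tav + rng.normal(0.0, cfg.noise_sd, size=n_beats)
    return pd.DataFrame({"map": m, "sbp": sbp, "dbp": dbp,
                         "psv": psv, "edv": edv, "tav": tav})


def _render_beats(cfg: ScenarioConfig, sched: pd.DataFrame, t0: float = 0.0):
    """Sample the velocity and pressure waveforms for a run of beats.

    Returns (time, velocity, pressure, ecg_events, truth) covering exactly
    ``n_beats`` complete cardiac cycles starting at ``t0``.
    """
    period = 60.0 / cfg.heart_rate
    fs_frac = cfg.systolic_duration / period
    n_beats = len(sched)
    dt = 1.0 / cfg.sample_rate
    n_samples = int(round(n_beats * period * cfg.sample_rate))
    t = t0 + np.arange(n_samples) * dt
    velocity = np.empty(n_samples)
    pressure = np.empty(n_samples)
    onsets = t0 + np.arange(n_beats) * period
    rows = []
    for k in range(n_beats):
        lo = int(round(k * period * cfg.sample_rate))
        hi = int(round((k + 1) * period * cfg.sample_rate))
        t_local = (t[lo:hi] - t0) - k * period
        row = sched.iloc[k]
        # post-systolic level solved so the beat mean equals the TAV coupling
        d0 = 2.0 * row["tav"] - fs_frac * row["psv"] - (1.0 - fs_frac) * row["edv"]
        velocity[lo:hi] = _piecewise_beat(t_local, row["psv"], d0, row["edv"],
                                          cfg.systolic_duration, period)
        p0 = 2.0 * row["map"] - fs_frac * row["sbp"] - (1.0 - fs_frac) * row["dbp"]
        pressure[lo:hi] = _piecewise_beat(t_local, row["sbp"], p0, row["dbp"],
                                          cfg.systolic_duration, period)
        rows.append((k, onsets[k], onsets[k] + period, row["psv"], row["edv"],
                     row["tav"], row["sbp"], row["dbp"], row["map"]))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return t, velocity, pressure, onsets, truth


def _finalize(cfg: ScenarioConfig, t, velocity, pressure, ecg_events, truth,
              segments, rng, meta) -> ScenarioTraces:
    fs = cfg.sample_rate
    sync = gen_sync_channel(t[-1] - t[0] + 1.0 / fs, cfg.sync_interval,
                            cfg.sync_jitter_sd, rng)
    traces = ScenarioTraces(
        time=t,
        pressure=pressure,
        velocity=velocity,
        ecg_events=_snap(ecg_events, fs),
        sync_pulses=_snap(sync, fs),
        truth=truth,
        segments=segments,
        meta=meta,
    )
    traces.validate()
    return traces


def gen_vco_sequence(cfg: ScenarioConfig, rng: np.random.Generator | None = None,
                     tav_offset: float = 0.0, slope_offset: float = 0.0,
                     quad_offset: float = 0.0,
                     baseline_map: float | None = None,
                     nadir_map: float | None = None) -> ScenarioTraces:
    """One vena-cava-occlusion sequence (or, for kind="baseline", a flat run
    of beats at the baseline operating point).

    ``tav_offset``/``slope_offset``/``quad_offset`` shift the TAV~MAP coupling
    and carry the hierarchical animal/sequence random effects when called from
    :func:`gen_study`.  The duration is trimmed to an integer number of beats
    so every truth record describes a complete cardiac cycle.
    """
    if cfg.kind not in ("vco", "baseline"):
        raise ConfigError(f"gen_vco_sequence requires kind 'vco' or 'baseline', got {cfg.kind!r}")
    if rng is None:
        rng = np.random.default_rng()
    bm = cfg.baseline_map if baseline_map is None else baseline_map
    nm = cfg.nadir_map if nadir_map is None else nadir_map
    if cfg.kind == "vco" and nm >= bm:
        raise ConfigError("nadir MAP must be below baseline MAP")
    period = 60.0 / cfg.heart_rate
    n_beats = max(int(np.floor(cfg.duration / period)), 1)
    if cfg.kind == "baseline":
        nm = bm  # hold every beat at the baseline operating point
    sched = _beat_schedule_vco(cfg, n_beats, rng, tav_offset, slope_offset,
                               quad_offset, bm, nm)
    t, velocity, pressure, onsets, truth = _render_beats(cfg, sched)
    segments = [("pulsatile", float(t[0]), float(t[-1]))]
    meta = {"kind": cfg.kind, "n_beats": n_beats,
            "baseline_map": bm, "nadir_map": nm,
            "tav_offset": tav_offset, "slope_offset": slope_offset,
            "quad_offset": quad_offset}
    return _finalize(cfg, t, velocity, pressure, onsets, truth, segments, rng, meta)


def gen_vf_episode(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> ScenarioTraces:
    """One VF episode: pulsatile baseline flow, a short broadband marker at
    fibrillation onset, flow cessation with collapsed non-pulsatile pressure,
    then ROSC after the defibrillation delay (at most ``vf_max_duration``)."""
    if cfg.kind != "vf":
        raise ConfigError("gen_vf_episode requires kind='vf'")
    if rng is None:
        rng = np.random.default_rng()
    period = 60.0 / cfg.heart_rate
    dt = 1.0 / cfg.sample_rate
    delay = cfg.defib_delay if cfg.defib_delay is not None else float(
        rng.uniform(15.0, cfg.vf_max_duration))
    if delay > cfg.vf_max_duration:
        raise ConfigError("defibrillation delay exceeds the maximum untreated VF time")

    # pre-arrest beats up to vf_onset
    n_pre = max(int(np.floor(cfg.vf_onset / period)), 1)
    sched_pre = _beat_schedule_vco(cfg, n_pre, rng, 0.0, 0.0, 0.0,
                                   cfg.baseline_map, cfg.baseline_map)
    t_pre, v_pre, p_pre, on_pre, truth_pre = _render_beats(cfg, sched_pre)
    t_onset = float(t_pre[-1]) + dt
    t_marker_end = t_onset + cfg.vf_marker_duration
    t_rosc = t_onset + delay

    # marker + no-flow segment
    n_arrest = int(round((t_rosc - t_onset) * cfg.sample_rate))
    t_arr = t_onset + np.arange(n_arrest) * dt
    v_arr = rng.normal(0.0, cfg.vf_noise_sd, size=n_arrest)
    marker = t_arr < t_marker_end
    v_arr[marker] = rng.normal(0.0, cfg.vf_marker_sd, size=int(marker.sum()))
    # pressure collapses from DBP to the non-pulsatile level over the marker
    p_arr = np.full(n_arrest, cfg.vf_pressure) + rng.normal(0.0, 0.5, size=n_arrest)
    ramp = np.clip((t_arr - t_onset) / max(cfg.vf_marker_duration, dt), 0.0, 1.0)
    p_arr = p_arr + (cfg.baseline_dbp - cfg.vf_pressure) * (1.0 - ramp)

    # ROSC: pulsatile beats resume until the end of the record; keep at least
    # ~6 s after ROSC so the restored circulation is actually observable
    post_dur = max(cfg.duration - (t_rosc - 0.0), 6.0)
    n_post = max(int(np.floor(post_dur / period)), 1)
    sched_post = _beat_schedule_vco(cfg, n_post, rng, 0.0, 0.0, 0.0,
                                    cfg.baseline_map, cfg.baseline_map)
    t_post, v_post, p_post, on_post, truth_post = _render_beats(cfg, sched_post, t0=t_rosc)

    t = np.concatenate([t_pre, t_arr, t_post])
    # rebuild a perfectly uniform grid (concatenation keeps step dt by construction)
    t = t[0] + np.arange(t.size) * dt
    velocity = np.concatenate([v_pre, v_arr, v_post])
    pressure = np.concatenate([p_pre, p_arr, p_post])
    ecg = np.concatenate([on_pre, on_post])  # ECG silent during VF
    truth_post = truth_post.assign(beat=truth_post["beat"] + n_pre)
    truth = pd.concat([truth_pre, truth_post], ignore_index=True)
    segments = [
        ("pulsatile", float(t[0]), t_onset),
        ("vf_marker", t_onset, t_marker_end),
        ("no_flow", t_marker_end, t_rosc),
        ("rosc_pulsatile", t_rosc, float(t[-1])),
    ]
    meta = {"kind": "vf", "vf_onset": t_onset, "flow_cessation": t_marker_end,
            "defib_delay": delay, "rosc": t_rosc,
            "episode_gap": cfg.vf_episode_gap}
    return _finalize(cfg, t, velocity, pressure, ecg, truth, segments, rng, meta)


def gen_pea_segment(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> ScenarioTraces:
    """True PEA: organized ECG events at the configured rate, systolic pressure
    near ``pea_sbp`` and near-pulseless flow around ``pea_velocity`` with at
    most ~20% ECG-locked amplitude modulation."""
    if cfg.kind != "pea":
        raise ConfigError("gen_pea_segment requires kind='pea'")
    if rng is None:
        rng = np.random.default_rng()
    period = 60.0 / cfg.heart_rate
    n_beats = max(int(np.floor(cfg.duration / period)), 1)
    dt = 1.0 / cfg.sample_rate
    n_samples = int(round(n_beats * period * cfg.sample_rate))
    t = np.arange(n_samples) * dt
    phase = (t % period) / period
    # weak ECG-locked modulation, zero-mean-ish: velocity stays ~pea_velocity
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(phase / 0.4, 0.0, 1.0)))
    velocity = cfg.pea_velocity * (1.0 + 0.2 * (bump - 0.5))
    velocity = velocity + rng.normal(0.0, cfg.pea_noise_sd, size=n_samples)
    sbp, dbp = cfg.pea_sbp, cfg.pea_sbp - 4.0
    map_ = dbp + (sbp - dbp) / 3.0
    p0 = 2.0 * map_ - (cfg.systolic_duration / period) * sbp \
        - (1.0 - cfg.systolic_duration / period) * dbp
    pressure = np.empty(n_samples)
    for k in range(n_beats):
        lo = int(round(k * period * cfg.sample_rate))
        hi = int(round((k + 1) * period * cfg.sample_rate))
        pressure[lo:hi] = _piecewise_beat(t[lo:hi] - k * period, sbp, p0, dbp,
                                          cfg.systolic_duration, period)
    ecg = np.arange(n_beats) * period
    truth = pd.DataFrame(columns=TRUTH_COLUMNS)  # no effective beats
    segments = [("pea", float(t[0]), float(t[-1]))]
    meta = {"kind": "pea", "pea_sbp": sbp, "pea_velocity": cfg.pea_velocity}
    return _finalize(cfg, t, velocity, pressure, ecg, truth, segments, rng, meta)


# ---------------------------------------------------------------------------
# full studies
# ---------------------------------------------------------------------------


def gen_study(cfg: StudyConfig, scenario: ScenarioConfig | None = None,
              rng: np.random.Generator | None = None) -> StudyDataset:
    """Generate a hierarchical multi-animal VCO study.

    Per-animal intercepts (SD ``animal_sd``) and optional MAP/MAP^2 slope
    effects, plus per-sequence intercepts (SD ``sequence_sd``), shift the
    TAV~MAP coupling of each generated sequence.  The long-format table is
    sampled at ``obs_rate`` (default 1 Hz) with i.i.d. residual noise
    (SD ``residual_sd``), which is the structure the nested mixed model
    assumes.
    """
    if scenario is None:
        scenario = ScenarioConfig(kind="vco")
    if scenario.kind != "vco":
        raise ConfigError("studies are built from VCO sequences")
    root = np.random.SeedSequence(cfg.seed) if rng is None else rng.bit_generator.seed_seq.spawn(1)[0]
    n_seq = cfg.n_sequences
    streams = root.spawn(n_seq + 1)
    master = np.random.default_rng(streams[0])

    # sequence durations: uniform(30, 69) rescaled to mean 50 s
    if cfg.sequence_duration is None:
        durations = master.uniform(30.0, 69.0, size=n_seq)
        durations = durations * (50.0 / durations.mean())
    else:
        durations = np.full(n_seq, float(cfg.sequence_duration))

    beta0, beta1, beta2 = cfg.fixed_beta
    a = master.normal(0.0, cfg.animal_sd, size=cfg.n_animals)
    u1 = master.normal(0.0, cfg.slope_sd[0], size=cfg.n_animals) if cfg.slope_sd[0] > 0 else np.zeros(cfg.n_animals)
    u2 = master.normal(0.0, cfg.slope_sd[1], size=cfg.n_animals) if cfg.slope_sd[1] > 0 else np.zeros(cfg.n_animals)

    sequences: list[tuple[str, str, ScenarioTraces]] = []
    rows = []
    effects = {"animal_intercepts": a, "animal_slopes_map": u1,
               "animal_slopes_map2": u2, "sequence_intercepts": {}}
    seq_idx = 0
    for i, n_i in enumerate(cfg.sequences_per_animal):
        animal_id = f"a{i + 1:02d}"
        for s in range(n_i):
            seq_id = f"{animal_id}s{s + 1:02d}"
            seq_rng = np.random.default_rng(streams[seq_idx + 1])
            b = float(seq_rng.normal(0.0, cfg.sequence_sd)) if cfg.sequence_sd > 0 else 0.0
            effects["sequence_intercepts"][seq_id] = b
            seq_cfg = replace(scenario, duration=float(durations[seq_idx]))
            bmap = float(seq_rng.normal(scenario.baseline_map, cfg.baseline_map_sd))
            nmap = float(seq_rng.normal(scenario.nadir_map, cfg.nadir_map_sd))
            nmap = min(nmap, bmap - 20.0)  # keep the occlusion a genuine pressure fall
            # fix the coupling to the study's fixed effects, then add random effects
            seq_cfg = replace(seq_cfg, tav_map_intercept=beta0,
                              tav_map_slope=beta1, tav_map_quad=beta2,
                              noise_sd=scenario.noise_sd)
            traces = gen_vco_sequence(seq_cfg, seq_rng,
                                      tav_offset=float(a[i]) + b,
                                      slope_offset=float(u1[i]),
                                      quad_offset=float(u2[i]),
                                      baseline_map=bmap, nadir_map=nmap)
            traces.meta.update({"animal": animal_id, "sequence": seq_id})
            sequences.append((animal_id, seq_id, traces))

            # 1 Hz long table: MAP from the per-beat schedule, TAV from the
            # effective coupling plus iid residual noise
            t_obs = np.arange(0.0, traces.duration, 1.0 / cfg.obs_rate)
            tr = traces.truth
            beat_of = np.clip(np.searchsorted(tr["t_start"].to_numpy(), t_obs, side="right") - 1,
                              0, len(tr) - 1)
            m_obs = tr["map"].to_numpy()[beat_of]
            tav_obs = ((beta0 + a[i] + b) + (beta1 + u1[i]) * m_obs
                       + (beta2 + u2[i]) * m_obs ** 2)
            tav_obs = tav_obs + seq_rng.normal(0.0, cfg.residual_sd, size=t_obs.size)
            rows.append(pd.DataFrame({"animal": animal_id, "sequence": seq_id,
                                      "t_s": t_obs, "map_mmHg": m_obs,
                                      "tav_cm_s": tav_obs}))
            seq_idx += 1

    table = pd.concat(rows, ignore_index=True)
    if table[["map_mmHg", "tav_cm_s"]].isna().any().any():
        raise ConfigError("study table contains missing MAP/TAV pairs")
    return StudyDataset(sequences=sequences, table=table, config=cfg,
                        scenario=scenario, effects=effects)
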
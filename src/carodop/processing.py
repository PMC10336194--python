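"""The pulsed-wave Doppler measurement chain.

Stages, in processing order: slow-time wall filter (clutter rejection),
per-gate spectrogram, colour M-mode via the lag-one autocorrelation (Kasai)
velocity estimator, automatic sample-gate selection by pulsatile-flow score,
maximum-velocity envelope tracing from the spectrogram, beat segmentation,
per-beat hemodynamic indices (PSV, EDV, TAV, RI, PI, HR), dual-transducer
angle correction, and flow-state classification (pulsatile / no_flow /
low_flow_pea).

Velocity axes through the chain are *uncorrected* (axial, i.e. scaled by the
cosine of the beam-flow angle); the geometric angle correction is applied only
at the TAV stage via :func:`estimate_angle`, which is why the ratio indices
RI and PI and the heart rate are insensitive to the inclination angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

from .errors import ConfigError, DataError

__all__ = [
    "Spectrogram",
    "ColorMMode",
    "Envelope",
    "Beats",
    "AngleEstimate",
    "FlowStateSeries",
    "wall_filter",
    "compute_spectrogram",
    "compute_color_mmode",
    "select_gate",
    "trace_envelope",
    "detect_beats",
    "compute_beat_metrics",
    "estimate_angle",
    "classify_flow_state",
]

METRIC_COLUMNS = ["beat", "t_start", "t_end", "psv", "edv", "tav",
                  "ri", "pi", "hr"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Spectrogram:
    """Short-time power spectrum of one gate, frequency mapped to velocity.

    ``velocity_axis`` is signed cm/s assuming cos(phi)=1 (uncorrected axial
    velocity); ``power`` has shape (n_frames, n_bins), linear units.
    """

    t: np.ndarray
    velocity_axis: np.ndarray
    power: np.ndarray
    prf: float
    f0: float
    c_sound: float

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    @property
    def bin_width_cm_s(self) -> float:
        return float(self.velocity_axis[1] - self.velocity_axis[0])


@dataclass
class ColorMMode:
    """Mean velocity and power per gate and frame (depth x time display)."""

    t: np.ndarray
    mean_velocity: np.ndarray  # (n_gates, n_frames), cm/s, uncorrected
    power: np.ndarray          # (n_gates, n_frames)
    frame_rate: float


@dataclass
class Envelope:
    """Composite maximum-velocity trace, defined on every spectrogram frame.

    ``v_max`` is signed (negative = reverse flow dominates the frame);
    frames without above-noise flow power carry v_max = 0 and a low-quality
    flag rather than gaps.
    """

    t: np.ndarray
    v_max: np.ndarray
    quality: np.ndarray  # bool, True = acceptable SNR
    snr: np.ndarray      # above-noise flow power over noise power
    noise_floor: np.ndarray

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass
class Beats:
    """Beat segmentation: systolic upstroke onset indices into the envelope."""

    onset_idx: np.ndarray
    peak_idx: np.ndarray
    t: np.ndarray  # envelope frame times

    @property
    def onset_times(self) -> np.ndarray:
        return self.t[self.onset_idx] if len(self.onset_idx) else np.array([])

    @property
    def peak_times(self) -> np.ndarray:
        return self.t[self.peak_idx] if len(self.peak_idx) else np.array([])

    def __len__(self) -> int:
        return len(self.onset_idx)


@dataclass(frozen=True)
class AngleEstimate:
    """Inclination angle and angle-corrected speed from the two TAVs."""

    alpha_deg: float
    speed_cm_s: float


@dataclass
class FlowStateSeries:
    """Windowed flow-state labels covering the whole record."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)  # t0, t1, state, confidence

    def state_at(self, t: float) -> str:
        row = self.table[(self.table.t0 <= t) & (t < self.table.t1)]
        if row.empty:
            raise DataError(f"time {t} outside classified record")
        return str(row.iloc[0]["state"])

    def __iter__(self):
        return self.table.itertuples(index=False)


# ---------------------------------------------------------------------------
# filtering and spectral estimation
# ---------------------------------------------------------------------------


def wall_filter(iq: np.ndarray, prf: float, cutoff_hz: float = 100.0,
                order: int = 4) -> np.ndarray:
    """Slow-time high-pass clutter filter (zero-phase Butterworth).

    Attenuates DC by well over 40 dB while passing tones above twice the
    cutoff essentially unchanged.  Applies along the last axis.
    """
    if not 0 < cutoff_hz < prf / 4.0:
        raise ConfigError("wall filter cutoff must lie in (0, prf/4)")
    sos = scipy.signal.butter(order, cutoff_hz, btype="highpass", fs=prf,
                              output="sos")
    out = scipy.signal.sosfiltfilt(sos, np.real(iq), axis=-1) \
        + 1j * scipy.signal.sosfiltfilt(sos, np.imag(iq), axis=-1)
    return out.astype(np.complex64) if iq.dtype == np.complex64 else out


def compute_spectrogram(iq_gate: np.ndarray, prf: float, f0: float,
                        c_sound: float = 1540.0, window_s: float = 0.010,
                        overlap_frac: float = 0.75) -> Spectrogram:
    """Short-time Fourier power of one gate's slow-time signal.

    Hann taper of ``window_s`` with fractional ``overlap_frac``; the two-sided
    (signed) frequency axis is mapped to uncorrected axial velocity through
    v = c * f / (2 * f0).  Frames whose window extends beyond the record are
    dropped so edge zero-padding never biases the envelope.
    """
    x = np.asarray(iq_gate)
    nperseg = max(int(round(window_s * prf)), 8)
    if x.size < 2 * nperseg:
        raise DataError("record shorter than two analysis windows")
    hop = max(int(round(nperseg * (1.0 - overlap_frac))), 1)
    win = scipy.signal.windows.hann(nperseg, sym=False)
    sft = scipy.signal.ShortTimeFFT(win, hop=hop, fs=prf, fft_mode="centered")
    S = sft.stft(x)
    times = sft.t(x.size)
    power = (np.abs(S) ** 2).T
    half = window_s / 2.0
    keep = (times >= half) & (times <= x.size / prf - half)
    velocity_axis = c_sound * sft.f / (2.0 * f0) * 100.0  # cm/s
    return Spectrogram(t=times[keep], velocity_axis=velocity_axis,
                       power=power[keep], prf=prf, f0=f0, c_sound=c_sound)


def compute_color_mmode(iq: np.ndarray, prf: float, f0: float,
                        c_sound: float = 1540.0,
                        frame_s: float = 0.02) -> ColorMMode:
    """Colour M-mode: per gate and frame, mean velocity from the phase of the
    lag-one autocorrelation, v = c * prf * arg(R1) / (4 pi f0), and mean power.

    Zero signal maps to zero velocity by convention.
    """
    x = np.atleast_2d(np.asarray(iq))
    frame_len = int(round(frame_s * prf))
    if frame_len < 2 or x.shape[-1] < frame_len:
        raise DataError("record too short for a single M-mode frame")
    n_frames = x.shape[-1] // frame_len
    xf = x[..., : n_frames * frame_len].reshape(x.shape[0], n_frames, frame_len)
    r1 = np.sum(xf[..., 1:] * np.conj(xf[..., :-1]), axis=-1)
    v = c_sound * prf * np.angle(r1) / (4.0 * np.pi * f0) * 100.0  # cm/s
    v[r1 == 0] = 0.0
    power = np.mean(np.abs(xf) ** 2, axis=-1)
    t = (np.arange(n_frames) + 0.5) * frame_len / prf
    return ColorMMode(t=t, mean_velocity=v, power=power, frame_rate=prf / frame_len)


def select_gate(mmode: ColorMMode, band_hz: tuple[float, float] = (0.5, 4.0),
                min_band_rms_cm_s: float = 2.0) -> int | None:
    """Pick the gate with the strongest pulsatile flow.

    Score = variance of the mean-velocity trace within the cardiac band
    (0.5-4 Hz) times the mean power.  Ties break toward the shallower gate;
    returns None (no-flow sentinel) when even the best gate's in-band
    velocity RMS is below ``min_band_rms_cm_s``.
    """
    if mmode.mean_velocity.shape[1] / mmode.frame_rate < 1.0:
        raise DataError("need at least 1 s of M-mode frames for gate selection")
    nyq = mmode.frame_rate / 2.0
    hi = min(band_hz[1], 0.95 * nyq)
    sos = scipy.signal.butter(2, [band_hz[0], hi], btype="bandpass",
                              fs=mmode.frame_rate, output="sos")
    banded = scipy.signal.sosfiltfilt(sos, mmode.mean_velocity, axis=-1)
    band_var = banded.var(axis=-1)
    score = band_var * mmode.power.mean(axis=-1)
    best = int(np.argmax(score))  # argmax takes the first (shallower) on ties
    if np.sqrt(band_var[best]) < min_band_rms_cm_s:
        return None
    return best


# ---------------------------------------------------------------------------
# envelope and beats
# ---------------------------------------------------------------------------


def _directional_candidate(above: np.ndarray, velocities: np.ndarray,
                           percentile: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame envelope candidate for one flow direction.

    ``above`` is above-noise power for this direction's bins ordered by
    increasing |v|; returns (candidate |v| per frame, total above-noise power
    per frame).  The candidate is the smallest |v| at which the cumulative
    power reaches ``percentile`` of the direction total.
    """
    cum = np.cumsum(above, axis=1)
    total = cum[:, -1]
    target = percentile * total
    idx = np.argmax(cum >= target[:, None], axis=1)
    cand = np.abs(velocities)[idx]
    cand[total <= 0] = 0.0
    return cand, total


def trace_envelope(spec: Spectrogram, percentile: float = 0.95,
                   noise_margin_db: float = 6.0, smooth_frames: int = 5,
                   quality_snr: float = 2.0) -> Envelope:
    """Trace the composite maximum-velocity curve from a spectrogram.

    Per frame the noise floor is the median bin power; bins below
    floor * 10^(margin/10) are discarded and the floor subtracted from the
    rest.  For each direction the envelope candidate is the velocity below
    which ``percentile`` of the above-noise power lies; the composite trace
    takes the direction carrying more above-noise power, signed.  A running
    median over ``smooth_frames`` removes single-frame outliers.  All-noise
    frames get v_max = 0 and a low-quality flag (no gaps).
    """
    if spec.power.size == 0:
        raise DataError("empty spectrogram")
    power = spec.power
    v = spec.velocity_axis
    floor = np.median(power, axis=1, keepdims=True)
    thresh = floor * 10.0 ** (noise_margin_db / 10.0)
    above = np.where(power > thresh, power - floor, 0.0)

    pos = v > 0
    neg = v < 0
    cand_pos, tot_pos = _directional_candidate(above[:, pos], v[pos], percentile)
    # negative bins reordered by increasing |v|
    cand_neg, tot_neg = _directional_candidate(above[:, neg][:, ::-1],
                                               v[neg][::-1], percentile)
    v_max = np.where(tot_pos >= tot_neg, cand_pos, -cand_neg)
    v_max[(tot_pos <= 0) & (tot_neg <= 0)] = 0.0
    noise_power = np.squeeze(floor, axis=1) * power.shape[1]
    snr = (tot_pos + tot_neg) / np.maximum(noise_power, 1e-30)
    quality = snr >= quality_snr
    # all-noise frames carry no velocity information: envelope 0, flagged low
    v_max[~quality] = 0.0
    if smooth_frames > 1:
        k = smooth_frames + 1 - smooth_frames % 2  # odd
        v_max = scipy.signal.medfilt(v_max, kernel_size=k)
    return Envelope(t=spec.t, v_max=v_max, quality=quality, snr=snr,
                    noise_floor=np.squeeze(floor, axis=1))


def detect_beats(env: Envelope, min_interval_s: float = 0.25,
                 prominence: float = 20.0, smooth_s: float = 0.06) -> Beats:
    """Segment the envelope into beats.

    Systolic peaks are found by prominence-based peak detection with a
    refractory ``min_interval_s``; each beat onset is placed at the last
    minimum of the envelope before its peak (end-diastole).  Peak finding
    runs on a short centered moving average (``smooth_s``) of the envelope so
    that sign-flickering frames around zero crossings (flow buried in the
    wall-filter stop band) cannot masquerade as systoles; metrics downstream
    still use the raw envelope.  An empty result means no pulsatile flow.
    """
    if env.t[-1] - env.t[0] < 2.0:
        raise DataError("need at least 2 s of envelope for beat detection")
    distance = max(int(round(min_interval_s * env.frame_rate)), 1)
    width = max(int(round(smooth_s * env.frame_rate)), 1)
    smoothed = scipy.ndimage.uniform_filter1d(env.v_max, width)
    peaks, _ = scipy.signal.find_peaks(smoothed, prominence=prominence,
                                       distance=distance)
    onsets = []
    prev = 0
    for p in peaks:
        seg = smoothed[prev:p + 1]
        # last occurrence of the minimum = latest end-diastolic point
        onset = prev + (len(seg) - 1 - int(np.argmin(seg[::-1])))
        onsets.append(onset)
        prev = p
    return Beats(onset_idx=np.asarray(onsets, dtype=int),
                 peak_idx=np.asarray(peaks, dtype=int), t=env.t)


def _beat_windows(beats: Beats, n_frames: int,
                  max_period_s: float = 3.0) -> list[tuple[int, int]]:
    """Frame-index windows [i0, i1) per beat.

    Inter-onset gaps longer than ``max_period_s`` (slower than ~20 bpm) are
    not beats — they arise when isolated spurious peaks bracket a no-flow
    span — and are dropped.  A trailing partial beat is kept when the record
    extends at least 70% of the median period past the last onset (its EDV is
    then the record's final envelope value)."""
    idx = beats.onset_idx
    if len(idx) == 0:
        return []
    dt = float(beats.t[1] - beats.t[0]) if len(beats.t) > 1 else 1.0
    max_len = max_period_s / dt
    windows = [(int(idx[k]), int(idx[k + 1])) for k in range(len(idx) - 1)
               if idx[k + 1] - idx[k] <= max_len]
    if windows:
        med = np.median([i1 - i0 for i0, i1 in windows])
        if 0.7 * med <= n_frames - idx[-1] <= max_len:
            windows.append((int(idx[-1]), n_frames))
    elif len(idx) == 1 and n_frames - idx[-1] <= max_len:
        windows.append((int(idx[-1]), n_frames))
    return windows


def compute_beat_metrics(env: Envelope, beats: Beats,
                         signed_tav: bool = True) -> pd.DataFrame:
    """Per-beat indices from the envelope.

    PSV is the maximum envelope value in the beat, EDV the (signed) envelope
    value at beat end, TAV the time average over the beat; RI=(PSV-EDV)/PSV,
    PI=(PSV-EDV)/TAV (NaN sentinel when TAV is 0), HR=60/period.  With
    ``signed_tav=False`` reverse-flow samples are clipped to zero for the TAV
    only.
    """
    if len(beats) < 1:
        raise DataError("no beats to compute metrics for")
    rows = []
    v = env.v_max
    windows = _beat_windows(beats, len(v))
    if not windows:
        return pd.DataFrame(columns=METRIC_COLUMNS)
    n_end = max(int(round(0.012 * env.frame_rate)), 1)  # ~12 ms end-diastolic read
    for b, (i0, i1) in enumerate(windows):
        seg = v[i0:i1]
        psv = float(seg.max())
        edv = float(np.median(seg[-n_end:]))
        tav_seg = np.clip(seg, 0.0, None) if not signed_tav else seg
        tav = float(tav_seg.mean())
        period = float(env.t[min(i1, len(v) - 1)] - env.t[i0])
        ri = (psv - edv) / psv if psv != 0 else np.nan
        pi = (psv - edv) / tav if abs(tav) > 1e-9 else np.nan
        rows.append((b, float(env.t[i0]), float(env.t[min(i1, len(v) - 1)]),
                     psv, edv, tav, ri, pi, 60.0 / period))
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


# ---------------------------------------------------------------------------
# angle correction and flow-state classification
# ---------------------------------------------------------------------------


def estimate_angle(tav1: float, tav2: float,
                   half_angle_deg: float = 30.0) -> AngleEstimate:
    """Invert the dual-transducer cosine projections.

    With the beams at +/-theta0 about the casing normal, the per-transducer
    time-averaged velocities of flow at speed v and inclination alpha are
    tav_k = v * cos(alpha -/+ theta0).  The unique inversion is

        alpha = atan[(tav1 - tav2) / ((tav1 + tav2) * tan(theta0))]
        v     = (tav1 + tav2) / (2 * cos(theta0) * cos(alpha))

    and forward-projecting (alpha, v) reproduces the inputs exactly.
    """
    s = tav1 + tav2
    if abs(s) < 1e-12:
        raise DataError("tav1 + tav2 = 0: inclination angle indeterminate")
    theta = np.deg2rad(half_angle_deg)
    alpha = np.arctan((tav1 - tav2) / (s * np.tan(theta)))
    speed = s / (2.0 * np.cos(theta) * np.cos(alpha))
    return AngleEstimate(alpha_deg=float(np.rad2deg(alpha)),
                         speed_cm_s=float(speed))


def classify_flow_state(metrics: pd.DataFrame | None, env: Envelope,
                        ecg_events: np.ndarray | None = None,
                        beats: Beats | None = None, window_s: float = 2.0,
                        pulsatile_psv: float = 20.0, pea_tav: float = 12.0,
                        quality_frac: float = 0.5) -> FlowStateSeries:
    """Label consecutive ``window_s`` windows as pulsatile / no_flow /
    low_flow_pea.

    A window is *pulsatile* when it contains a detected systolic peak whose
    beat PSV reaches ``pulsatile_psv``; otherwise *low_flow_pea* when ECG
    events are present (organized electrical activity without pulsatile
    flow); otherwise *no_flow*.  Thresholds are device configuration, not
    physiologic constants.
    """
    if env.t[-1] - env.t[0] < window_s:
        raise DataError("record shorter than one classification window")
    if beats is None:
        beats = detect_beats(env)
    peak_times = beats.peak_times
    peak_ok = np.array([], dtype=bool)
    if metrics is not None and len(metrics) and len(peak_times):
        # a peak counts only when it falls inside a valid beat whose PSV is
        # above threshold (isolated spurious peaks belong to no beat)
        psv_ok = []
        for pt in peak_times:
            in_beat = metrics[(metrics.t_start <= pt) & (pt <= metrics.t_end)]
            psv_ok.append(bool(len(in_beat)) and float(in_beat.iloc[0].psv) >= pulsatile_psv)
        peak_ok = np.asarray(psv_ok)
    elif len(peak_times):
        windows = _beat_windows(beats, len(env.v_max))
        ok = []
        for p in beats.peak_idx:
            inside = [(i0, i1) for i0, i1 in windows if i0 <= p < i1]
            ok.append(bool(inside)
                      and float(env.v_max[inside[0][0]:inside[0][1]].max())
                      >= pulsatile_psv)
        peak_ok = np.asarray(ok, dtype=bool)
    ecg = np.asarray(ecg_events) if ecg_events is not None else np.array([])

    t_start, t_end = float(env.t[0]), float(env.t[-1])
    edges = np.arange(t_start, t_end, window_s)
    rows = []
    for w0 in edges:
        w1 = min(w0 + window_s, t_end)
        has_pulse = bool(len(peak_times)) and np.any(
            (peak_times >= w0) & (peak_times < w1) & peak_ok)
        frames = (env.t >= w0) & (env.t < w1)
        lowq = 1.0 - float(env.quality[frames].mean()) if frames.any() else 1.0
        mean_abs = float(np.abs(env.v_max[frames]).mean()) if frames.any() else 0.0
        # an organized rhythm needs >= 2 ECG events in a full window; a lone
        # boundary event (e.g. the first post-ROSC beat) does not qualify
        n_ecg = int(np.count_nonzero((ecg >= w0) & (ecg < w1))) if len(ecg) else 0
        need = 2 if (w1 - w0) >= window_s else 1
        if has_pulse:
            state, conf = "pulsatile", min(1.0, 0.5 + 0.5 * (1.0 - lowq))
        elif n_ecg >= need and mean_abs < pea_tav:
            state, conf = "low_flow_pea", min(1.0, 0.5 + 0.5 * (1.0 - lowq))
        elif n_ecg >= need:
            # organized ECG with non-pulsatile but non-trivial flow
            state, conf = "low_flow_pea", 0.4
        else:
            state, conf = "no_flow", min(1.0, 0.3 + 0.7 * lowq)
        rows.append((w0, w1, state, conf))
    return FlowStateSeries(pd.DataFrame(rows, columns=["t0", "t1", "state",
                                                       "confidence"]))
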
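"""Forward model: ground-truth velocity traces to dual-transducer multigate IQ.

Each range gate that intersects the vessel lumen receives a sum of scatterer
phasors.  Scatterer ``i`` sits at radius ``r_i`` from the vessel axis and
moves at ``v_i(t) = v_center(t) * (1 - (r_i/R)^n)`` (blunted profile); its
complex baseband contribution has instantaneous Doppler frequency
``f_i(t) = 2 f0 v_i(t) cos(phi_k) / c`` with the phase integrated over slow
time, which yields physical spectral broadening from the in-gate velocity
spread rather than a single synthetic tone.  Near-DC clutter (wall motion)
and white thermal noise are added everywhere; gates outside the lumen carry
clutter and noise only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AliasingError, ConfigError
from .probes import ProbeGeometry, VesselModel, beam_flow_angle, gate_layout
from .scenarios import ScenarioTraces

__all__ = ["DualIQRecord", "synthesize_iq", "lumen_gates"]


@dataclass
class DualIQRecord:
    """Per-transducer, per-gate complex baseband samples at the PRF.

    ``iq`` has shape (2, n_gates, n_samples), complex64, unit-normalized so a
    fully insonated lumen gate has mean flow-signal power ~1.  Both
    transducers share the sample clock.
    """

    iq: np.ndarray
    prf: float
    gate_depths_mm: np.ndarray
    t0: float
    geometry: ProbeGeometry
    vessel: VesselModel
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.iq.shape[-1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.prf

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.prf


def lumen_gates(geometry: ProbeGeometry, vessel: VesselModel) -> np.ndarray:
    """Indices of gates whose center depth falls inside the vessel lumen."""
    depths = gate_layout(geometry)
    return np.flatnonzero(np.abs(depths - vessel.center_depth_mm) < vessel.radius_mm)


def synthesize_iq(traces: ScenarioTraces, geometry: ProbeGeometry | None = None,
                  vessel: VesselModel | None = None, snr_db: float = 20.0,
                  clutter_db: float = 40.0, rng: np.random.Generator | None = None,
                  n_scatterers: int = 50, alias_mode: str = "warn") -> DualIQRecord:
    """Synthesize a dual-transducer multigate IQ record from a velocity trace.

    Parameters
    ----------
    snr_db : flow-signal-to-noise ratio; white complex noise power is
        ``10**(-snr_db/10)`` relative to the unit flow signal.
    clutter_db : near-DC clutter power relative to the flow signal (default
        +40 dB, a strong wall echo that the wall filter must reject).
    alias_mode : "warn" (default), "refuse" (raise AliasingError naming the
        offending velocity) or "ignore" when the peak Doppler shift exceeds
        the Nyquist frequency.
    """
    geometry = geometry or ProbeGeometry()
    vessel = vessel or VesselModel()
    if rng is None:
        rng = np.random.default_rng()
    if traces.duration < 1.0:
        raise ConfigError("trace must be at least 1 s long")

    depths = gate_layout(geometry)
    n_gates = geometry.n_gates
    n_samples = int(round(traces.duration * geometry.prf))
    dt = 1.0 / geometry.prf
    t = traces.time[0] + np.arange(n_samples) * dt
    v_cm_s = np.interp(t, traces.time, traces.velocity)
    v_m_s = v_cm_s * 1e-2

    phis = [beam_flow_angle(vessel.inclination_deg, k, geometry.half_angle_deg)
            for k in (1, 2)]
    for phi in phis:
        f_peak = np.abs(v_m_s).max() * abs(geometry.doppler_coeff(phi))
        if f_peak >= geometry.nyquist_frequency:
            v_off = np.abs(v_cm_s).max()
            msg = (f"peak velocity {v_off:.1f} cm/s aliases at beam angle "
                   f"{phi:.1f} deg (f_d {f_peak:.0f} Hz >= Nyquist "
                   f"{geometry.nyquist_frequency:.0f} Hz)")
            if alias_mode == "refuse":
                raise AliasingError(msg)
            if alias_mode == "warn":
                warnings.warn(msg, stacklevel=2)

    iq = np.empty((2, n_gates, n_samples), dtype=np.complex64)
    noise_sd = np.sqrt(10.0 ** (-snr_db / 10.0) / 2.0)
    clutter_amp = 10.0 ** (clutter_db / 20.0)
    in_lumen = lumen_gates(geometry, vessel)
    radius = vessel.radius_mm

    # cumulative phase per unit Doppler coefficient, shared by all scatterers
    v_int = np.cumsum(v_m_s) * dt  # integral of v(t), m

    for k in (0, 1):
        coeff = geometry.doppler_coeff(phis[k])
        phase_base = 2.0 * np.pi * coeff * v_int  # centerline phase, rad
        for g in range(n_gates):
            gate = np.zeros(n_samples, dtype=np.complex64)
            if g in in_lumen:
                dz = depths[g] - vessel.center_depth_mm
                half_chord = np.sqrt(radius ** 2 - dz ** 2)
                x = rng.uniform(-half_chord, half_chord, size=n_scatterers)
                r = np.hypot(dz, x)
                profile = 1.0 - (r / radius) ** vessel.profile_bluntness
                theta = rng.uniform(0.0, 2.0 * np.pi, size=n_scatterers)
                amp = 1.0 / np.sqrt(n_scatterers)
                for p_i, th_i in zip(profile, theta):
                    gate += (amp * np.exp(1j * (p_i * phase_base + th_i))).astype(np.complex64)
            # clutter: strong near-DC tone with slow band-limited phase wander
            # (wall motion); smooth interpolation keeps the clutter spectrum
            # confined near DC so the wall filter, not luck, must reject it
            f_cl = rng.uniform(2.0, 8.0)
            knot_dt = 0.05  # 20 Hz wander bandwidth
            n_knots = int(np.ceil(n_samples * dt / knot_dt)) + 2
            knots = np.cumsum(rng.normal(0.0, 0.2, size=n_knots))
            walk = np.interp(t - t[0], np.arange(n_knots) * knot_dt, knots)
            gate += (clutter_amp
                     * np.exp(1j * (2.0 * np.pi * f_cl * (t - t[0]) + walk))
                     ).astype(np.complex64)
            gate += (noise_sd * (rng.standard_normal(n_samples)
                                 + 1j * rng.standard_normal(n_samples))
                     ).astype(np.complex64)
            iq[k, g] = gate

    return DualIQRecord(iq=iq, prf=geometry.prf, gate_depths_mm=depths,
                        t0=float(traces.time[0]), geometry=geometry, vessel=vessel,
                        meta={"snr_db": snr_db, "clutter_db": clutter_db,
                              "n_scatterers": n_scatterers,
                              "inclination_deg": vessel.inclination_deg,
                              "beam_angles_deg": phis})
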
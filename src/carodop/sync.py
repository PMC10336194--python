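"""Two-clock synchronization from shared electrical sync pulses.

The acquisition chain timestamps a common pulse train (one impulse every
6 seconds) on two independent clocks; aligning the two event lists recovers
the offset and relative drift needed to merge the recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError

__all__ = ["ClockAlignment", "align_clocks", "apply_alignment"]


@dataclass(frozen=True)
class ClockAlignment:
    """b ~= offset + (1 + drift) * a for matched pulse times (a, b)."""

    offset_s: float
    drift_ppm: float
    residual_rms_s: float
    n_matched: int

    def a_to_b(self, t: np.ndarray) -> np.ndarray:
        return self.offset_s + (1.0 + self.drift_ppm * 1e-6) * np.asarray(t)


def align_clocks(pulses_a: np.ndarray, pulses_b: np.ndarray,
                 max_residual_s: float | None = None) -> ClockAlignment:
    """Estimate offset and drift between two pulse-time lists.

    A coarse offset (median of span-adjusted midpoints) seeds
    nearest-neighbour matching with a gate of half the nominal pulse
    interval; the matched pairs are fit by least squares.  Requires at least
    3 matches.  Periodicity of the train makes the offset identifiable only
    modulo one interval; overlapping recordings of the same physical pulses
    (the intended use) satisfy this.
    """
    a = np.sort(np.asarray(pulses_a, dtype=float))
    b = np.sort(np.asarray(pulses_b, dtype=float))
    if len(a) < 3 or len(b) < 3:
        raise AlignmentError("need at least 3 pulses per channel")
    interval = np.median(np.diff(a))
    gate = interval / 2.0 if max_residual_s is None else max_residual_s

    offset0 = np.median(b) - np.median(a)
    idx = np.searchsorted(b, a + offset0)
    matched_a, matched_b = [], []
    for i, j in enumerate(idx):
        candidates = [c for c in (j - 1, j) if 0 <= c < len(b)]
        if not candidates:
            continue
        best = min(candidates, key=lambda c: abs(b[c] - a[i] - offset0))
        if abs(b[best] - a[i] - offset0) < gate:
            matched_a.append(a[i])
            matched_b.append(b[best])
    if len(matched_a) < 3:
        raise AlignmentError(f"only {len(matched_a)} pulses matched; need >= 3")
    ma = np.asarray(matched_a)
    mb = np.asarray(matched_b)
    slope, intercept = np.polyfit(ma, mb, 1)
    resid = mb - (intercept + slope * ma)
    return ClockAlignment(offset_s=float(intercept),
                          drift_ppm=float((slope - 1.0) * 1e6),
                          residual_rms_s=float(np.sqrt(np.mean(resid ** 2))),
                          n_matched=len(ma))


def apply_alignment(alignment: ClockAlignment, times_a: np.ndarray) -> np.ndarray:
    """Map a timebase recorded on clock A onto clock B."""
    return alignment.a_to_b(times_a)
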
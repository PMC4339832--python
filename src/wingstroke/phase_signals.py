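"""Per-cycle phase-point signals and cycle features.

Each valid wingbeat cycle (anchored at the left wing's dorsal reversal) is
sampled at ``points_per_wing`` temporally equidistant phases; the stroke
angles of both wings at those phases form the multivariate signal X
(rows 1..P left wing, P+1..2P right wing, default P=8 giving 16 rows),
with one column per cycle.  Cycle duration is deliberately not part of X:
the wingbeat-period and downstroke-to-upstroke ratio series are extracted
separately so that correlations between component activations and stroke
timing can be assessed afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import ChordTrace, CycleTable
from .synthetic import WINGS

__all__ = [
    "PhaseSignalMatrix",
    "CycleFeatureSeries",
    "Segment",
    "SegmentTooShortError",
    "extract_phase_points",
    "cycle_features",
    "make_segments",
]


class SegmentTooShortError(ValueError):
    """Recording has fewer valid cycles than one analysis segment."""


@dataclass
class PhaseSignalMatrix:
    """Phase-point signals over the valid cycles of a recording.

    ``X`` has shape ``(2 * points_per_wing, n_valid_cycles)``; columns are
    valid cycles in temporal order.  ``source_index`` maps each column back
    to its row in the originating cycle table.
    """

    X: np.ndarray
    points_per_wing: int
    cycle_start: np.ndarray
    cycle_duration: np.ndarray
    source_index: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.X.shape[1]

    def __post_init__(self):
        if self.X.shape[0] != 2 * self.points_per_wing:
            raise ValueError("X must have 2 * points_per_wing rows")


@dataclass
class CycleFeatureSeries:
    """Per-cycle stroke timing, aligned with the columns of X.

    ``downstroke``/``upstroke``/``ratio`` are per-wing dicts; the ventral
    reversal is located as the chord minimum within each cycle.
    """

    period: np.ndarray
    downstroke: dict[str, np.ndarray]
    upstroke: dict[str, np.ndarray]
    ratio: dict[str, np.ndarray]

    def mean_ratio(self) -> np.ndarray:
        """Wing-averaged downstroke-to-upstroke ratio series."""
        return 0.5 * (self.ratio["left"] + self.ratio["right"])


@dataclass
class Segment:
    """A contiguous fixed-length window of phase-point signals."""

    signals: PhaseSignalMatrix
    offset: int
    recording_id: str = ""

    @property
    def X(self) -> np.ndarray:
        return self.signals.X


def extract_phase_points(trace: ChordTrace, cycles: CycleTable,
                         points_per_wing: int = 8) -> PhaseSignalMatrix:
    """Sample both wings' chords at equidistant phases of each valid cycle.

    Phase point j (j = 0..P-1) of a cycle starting at t0 with duration T is
    the chord angle at t0 + (j/P) T, interpolated linearly on the dense
    (50 kHz) grid.  Only valid cycles contribute columns.
    """
    if points_per_wing < 1:
        raise ValueError("points_per_wing must be positive")
    sel = np.flatnonzero(cycles.valid)
    t0 = cycles.start_time[sel]
    T = cycles.end_time[sel] - cycles.start_time[sel]
    if len(sel) == 0:
        raise ValueError("no valid cycles")
    if t0[0] < trace.times[0] or (t0 + T).max() > trace.times[-1] + 1e-12:
        raise ValueError("cycle outside the support of the chord trace")
    frac = np.arange(points_per_wing) / points_per_wing
    phase_times = (t0[:, None] + frac[None, :] * T[:, None]).ravel()
    rows = []
    for w in WINGS:
        vals = np.interp(phase_times, trace.times, trace.chord[w])
        rows.append(vals.reshape(len(sel), points_per_wing).T)
    X = np.vstack(rows)
    return PhaseSignalMatrix(
        X=X,
        points_per_wing=points_per_wing,
        cycle_start=t0,
        cycle_duration=T,
        source_index=sel,
    )


def _refined_min_time(times: np.ndarray, values: np.ndarray) -> float:
    """Time of the interior minimum, parabola-refined around the argmin."""
    i = int(np.argmin(values))
    if i == 0 or i == len(values) - 1:
        raise ValueError("no interior chord minimum found in cycle")
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.5 * (y0 - y2) / denom if denom > 0 else 0.0
    shift = float(np.clip(shift, -1.0, 1.0))
    dt = times[1] - times[0]
    return float(times[i] + shift * dt)


def cycle_features(trace: ChordTrace, cycles: CycleTable) -> CycleFeatureSeries:
    """Wingbeat period and per-wing downstroke/upstroke durations and ratio."""
    sel = np.flatnonzero(cycles.valid)
    t0 = cycles.start_time[sel]
    t1 = cycles.end_time[sel]
    period = t1 - t0
    downstroke = {}
    upstroke = {}
    ratio = {}
    i0 = np.searchsorted(trace.times, t0)
    i1 = np.searchsorted(trace.times, t1)
    for w in WINGS:
        chord = trace.chord[w]
        down = np.empty(len(sel))
        for k in range(len(sel)):
            a, b = i0[k], i1[k] + 1
            tmin = _refined_min_time(trace.times[a:b], chord[a:b])
            down[k] = tmin - t0[k]
        up = period - down
        if np.any(up <= 0) or np.any(down <= 0):
            raise ValueError("degenerate downstroke/upstroke split")
        downstroke[w] = down
        upstroke[w] = up
        ratio[w] = down / up
    return CycleFeatureSeries(period=period, downstroke=downstroke,
                              upstroke=upstroke, ratio=ratio)


def make_segments(signals: PhaseSignalMatrix, segment_length: int = 2500,
                  recording_id: str = "") -> list[Segment]:
    """Cut consecutive non-overlapping windows; the remainder is dropped."""
    n = signals.n_cycles
    if n < segment_length:
        raise SegmentTooShortError(
            f"recording has {n} valid cycles; one segment needs {segment_length}")
    segments = []
    for off in range(0, n - segment_length + 1, segment_length):
        sl = slice(off, off + segment_length)
        sub = PhaseSignalMatrix(
            X=signals.X[:, sl],
            points_per_wing=signals.points_per_wing,
            cycle_start=signals.cycle_start[sl],
            cycle_duration=signals.cycle_duration[sl],
            source_index=signals.source_index[sl],
        )
        segments.append(Segment(signals=sub, offset=off, recording_id=recording_id))
    return segments
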
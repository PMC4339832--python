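"""Shared fixtures: synthetic recordings, pipeline runs, decompositions.

Expensive objects (full 2500-cycle decompositions) are session-scoped and
shared across test modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from wingstroke.milca import MilcaConfig, Decomposition, milca_decompose
from wingstroke.phase_signals import (CycleFeatureSeries, PhaseSignalMatrix,
                                      Segment, cycle_features,
                                      extract_phase_points, make_segments)
from wingstroke.preprocessing import (ChordTrace, CycleTable, detect_cycles,
                                      discard_mistracked, make_chord_trace)
from wingstroke.synthetic import (EdgeRecording, PatternSpec,
                                  StrokeModelConfig, align_activations,
                                  generate_baseline, inject_pattern)

#: reduced-cost decomposition settings for many-segment tests
FAST_MILCA = dict(angle_grid_size=16, screen_angles=6, search_subsample=750,
                  max_sweeps=3)


@dataclass
class SegmentRun:
    """A recording pushed through preprocessing and signal extraction."""

    recording: EdgeRecording
    trace: ChordTrace
    cycles: CycleTable
    signals: PhaseSignalMatrix
    segment: Segment
    features: CycleFeatureSeries
    activations: list[np.ndarray]  # aligned to the segment's columns


def run_segment(recording: EdgeRecording, segment_length: int) -> SegmentRun:
    trace = make_chord_trace(recording)
    cycles = discard_mistracked(detect_cycles(trace), trace)
    signals = extract_phase_points(trace, cycles)
    feats = cycle_features(trace, cycles)
    seg = make_segments(signals, segment_length)[0]
    sl = slice(seg.offset, seg.offset + segment_length)
    seg_feats = CycleFeatureSeries(
        period=feats.period[sl],
        downstroke={w: feats.downstroke[w][sl] for w in ("left", "right")},
        upstroke={w: feats.upstroke[w][sl] for w in ("left", "right")},
        ratio={w: feats.ratio[w][sl] for w in ("left", "right")},
    )
    acts = align_activations(recording, seg.signals.cycle_start,
                             seg.signals.cycle_duration)
    return SegmentRun(recording=recording, trace=trace, cycles=cycles,
                      signals=signals, segment=seg, features=seg_feats,
                      activations=acts)


def build_recording(specs, n_cycles=2600, seed=0, **config_kwargs) -> EdgeRecording:
    rec = generate_baseline(StrokeModelConfig(n_cycles=n_cycles, seed=seed,
                                              **config_kwargs))
    for s in specs:
        rec = inject_pattern(rec, s)
    return rec


def summed_activation(run: SegmentRun, pattern_type: str) -> np.ndarray:
    return sum(run.activations[i]
               for i, s in enumerate(run.recording.specs)
               if s.pattern_type == pattern_type)


@pytest.fixture(scope="session")
def two_pattern_run() -> SegmentRun:
    """2500-cycle segment with antisymmetric (I) and symmetric (II) events."""
    specs = ([PatternSpec("I", o, 60, 6.0, "antisymmetric")
              for o in (300, 900, 1500, 2100)]
             + [PatternSpec("II", o, 100, 8.0, "symmetric", period_coupling=0.006)
                for o in (500, 1200, 2000)])
    return run_segment(build_recording(specs, seed=11), 2500)


@pytest.fixture(scope="session")
def two_pattern_decomposition(two_pattern_run) -> Decomposition:
    return milca_decompose(two_pattern_run.segment.signals, MilcaConfig(seed=5))


@pytest.fixture(scope="session")
def small_baseline_run() -> SegmentRun:
    """600-cycle clean baseline recording for preprocessing-level tests."""
    return run_segment(build_recording([], n_cycles=600, seed=7), 550)
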
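"""Spline up-sampling, chord filtering, cycle detection, discard rules."""

import numpy as np
import pytest
from scipy.signal import correlate, correlation_lags

from wingstroke.preprocessing import (ChordTrace, CycleTable, chord_trace,
                                      detect_cycles, discard_mistracked,
                                      make_chord_trace, smooth_upsample)
from wingstroke.synthetic import PatternSpec, StrokeModelConfig, generate_baseline, inject_pattern

from conftest import build_recording


class TestSmoothUpsample:
    def test_noise_free_sinusoid_reconstructed_below_tenth_degree(self):
        t = np.arange(0, 0.2, 1 / 3125.0)
        y = 70 * np.cos(2 * np.pi * 200 * t)
        grid, fit = smooth_upsample(t, y)
        truth = 70 * np.cos(2 * np.pi * 200 * grid)
        # exclude spline end effects
        inner = slice(200, -200)
        rms = np.sqrt(np.mean((fit[inner] - truth[inner]) ** 2))
        assert rms < 0.1

    def test_constant_input_gives_constant_output(self):
        t = np.linspace(0, 0.01, 40)
        grid, fit = smooth_upsample(t, np.full(40, 3.5))
        assert np.allclose(fit, 3.5, atol=1e-8)

    def test_smoothing_brings_noisy_samples_closer_to_truth(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 0.3, 1 / 3125.0)
        truth = 70 * np.cos(2 * np.pi * 200 * t)
        noisy = truth + rng.standard_normal(t.size)
        grid, fit = smooth_upsample(t, noisy, grid=t)
        assert np.sqrt(np.mean((fit - truth) ** 2)) < np.sqrt(np.mean((noisy - truth) ** 2))

    @pytest.mark.parametrize("args", [
        (np.array([0.0, 1.0, 2.0]), np.zeros(3)),          # too few
        (np.array([0.0, 2.0, 1.0, 3.0]), np.zeros(4)),     # non-monotone
        (np.arange(5.0), np.array([0, 1, np.nan, 3, 4.0])),  # non-finite
    ])
    def test_invalid_input_rejected(self, args):
        with pytest.raises(ValueError):
            smooth_upsample(*args)


class TestChordTrace:
    def test_passband_sinusoid_passes_unchanged(self):
        t = np.arange(0, 0.1, 1 / 50_000.0)
        y = np.sin(2 * np.pi * 200 * t)
        out = chord_trace(y, y, 50_000.0)
        inner = slice(500, -500)
        assert np.abs(out[inner] - y[inner]).max() < 0.01

    def test_5khz_tone_attenuated_by_20db(self):
        t = np.arange(0, 0.1, 1 / 50_000.0)
        tone = np.sin(2 * np.pi * 5000 * t)
        out = chord_trace(tone, tone, 50_000.0)
        inner = slice(500, -500)
        gain = out[inner].std() / tone[inner].std()
        assert gain < 0.1  # > 20 dB down

    def test_constant_offset_edges_average_to_midline(self):
        t = np.arange(0, 0.02, 1 / 50_000.0)
        trailing = np.sin(2 * np.pi * 200 * t)
        leading = trailing + 20.0
        out = chord_trace(leading, trailing, 50_000.0)
        assert np.abs(out[200:-200] - (trailing[200:-200] + 10.0)).max() < 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chord_trace(np.zeros(10), np.zeros(11), 50_000.0)

    def test_zero_phase_no_lag(self, small_baseline_run):
        """Filtering introduces no lag: cross-correlation peaks at 0."""
        trace = small_baseline_run.trace
        rec = small_baseline_run.recording
        grid, le = smooth_upsample(rec.times["left"], rec.leading["left"],
                                   grid=trace.times)
        _, tr = smooth_upsample(rec.times["left"], rec.trailing["left"],
                                grid=trace.times)
        mean = 0.5 * (le + tr) - np.mean(0.5 * (le + tr))
        filt = trace.chord["left"] - trace.chord["left"].mean()
        xc = correlate(filt, mean, mode="full")
        lags = correlation_lags(len(filt), len(mean), mode="full")
        assert lags[np.argmax(xc)] == 0


class TestDetectCycles:
    def test_pure_sinusoid_durations(self):
        t = np.arange(0, 0.25, 1 / 50_000.0)
        chord = 70 * np.cos(2 * np.pi * 200 * t)
        trace = ChordTrace(times=t, chord={"left": chord, "right": chord},
                           rate=50_000.0)
        cycles = detect_cycles(trace)
        assert np.allclose(cycles.duration, 5e-3, atol=2 / 50_000.0)

    def test_chirp_durations_match_instantaneous_period(self):
        t = np.arange(0, 0.5, 1 / 50_000.0)
        f0, k = 180.0, 80.0  # 180 Hz sweeping up at 80 Hz/s
        phase = 2 * np.pi * (f0 * t + 0.5 * k * t ** 2)
        chord = 70 * np.cos(phase)
        trace = ChordTrace(times=t, chord={"left": chord, "right": chord},
                           rate=50_000.0)
        cycles = detect_cycles(trace)
        mid = 0.5 * (cycles.start_time + cycles.end_time)
        expected = 1.0 / (f0 + k * mid)
        assert np.all(np.abs(cycles.duration - expected) / expected < 0.02)

    def test_type_ii_period_coupling_changes_detected_durations(self):
        rec = build_recording(
            [PatternSpec("II", 100, 200, 8.0, "symmetric", period_coupling=0.02)],
            n_cycles=450, seed=8)
        trace = make_chord_trace(rec)
        cycles = detect_cycles(trace)
        base = np.median(cycles.duration[:80])
        event = np.median(cycles.duration[180:220])
        # plateau period change = 0.02 ms/deg * 8 deg = 0.16 ms
        assert abs((event - base) * 1e3 - 0.16) < 0.03

    def test_flat_trace_rejected(self):
        t = np.arange(0, 0.1, 1 / 50_000.0)
        trace = ChordTrace(times=t, chord={"left": np.zeros_like(t),
                                           "right": np.zeros_like(t)},
                           rate=50_000.0)
        with pytest.raises(ValueError):
            detect_cycles(trace)


def _trace_with_double_peak(n_cycles=10, double_cycle=None, sep_ms=2.0):
    """Clean 200 Hz stroke-like trace, optionally with a spurious second
    dorsal peak ``sep_ms`` after the boundary peak of ``double_cycle``."""
    t = np.arange(0, n_cycles / 200.0 + 0.002, 1 / 50_000.0)
    chord = 70 * np.cos(2 * np.pi * 200 * t)
    if double_cycle is not None:
        t0 = double_cycle / 200.0 + sep_ms * 1e-3
        bump = 60 * np.exp(-0.5 * ((t - t0) / 3e-4) ** 2)
        chord = np.maximum(chord, bump)
    return ChordTrace(times=t, chord={"left": chord, "right": chord.copy()},
                      rate=50_000.0)


class TestDiscardMistracked:
    def test_clean_recording_has_zero_discards(self, small_baseline_run):
        assert small_baseline_run.cycles.valid.all()

    def test_double_peak_invalidates_cycle_and_neighbours(self):
        # 1.5 ms after the reversal: inside the 3 ms window for that peak,
        # comfortably clear (3.5 ms) of the following reversal
        trace = _trace_with_double_peak(double_cycle=4, sep_ms=1.5)
        cycles = detect_cycles(trace)
        out = discard_mistracked(cycles, trace)
        bad = np.flatnonzero(~out.valid)
        # the double peak lands 1.5 ms into the cycle starting at t = 4 cycles
        hit = int(np.flatnonzero(np.isclose(cycles.start_time, 4 / 200.0,
                                            atol=1e-4))[0])
        assert set(bad) == {hit - 1, hit, hit + 1}
        assert out.reason[hit] == "double_dorsal_max"
        assert set(out.reason[[hit - 1, hit + 1]]) == {"neighbor_of_discard"}
        assert out.valid.sum() == cycles.n_cycles - 3

    def test_peaks_4ms_apart_not_discarded(self):
        """The 3 ms window is a strict bound: maxima 4 ms apart survive.

        Uses a 100 Hz stroke so that a 4 ms separation is also clear of the
        following reversal.
        """
        t = np.arange(0, 0.1, 1 / 50_000.0)
        chord = 70 * np.cos(2 * np.pi * 100 * t)
        t0 = 4 / 100.0 + 4e-3
        bump = 60 * np.exp(-0.5 * ((t - t0) / 3e-4) ** 2)
        chord = np.maximum(chord, bump)
        trace = ChordTrace(times=t, chord={"left": chord, "right": chord.copy()},
                           rate=50_000.0)
        cycles = detect_cycles(trace)
        out = discard_mistracked(cycles, trace)
        assert out.valid.all()

    def test_right_wing_artifact_flags_partner(self):
        trace = _trace_with_double_peak(double_cycle=4, sep_ms=2.0)
        trace.chord["left"] = 70 * np.cos(2 * np.pi * 200 * trace.times)
        cycles = detect_cycles(trace)
        out = discard_mistracked(cycles, trace)
        assert not out.valid[4]
        assert out.reason[4] == "partner_wing"

    def test_adding_artifact_never_unflags(self):
        trace1 = _trace_with_double_peak(double_cycle=4, sep_ms=2.0)
        trace2 = _trace_with_double_peak(double_cycle=4, sep_ms=2.0)
        t0 = 7 / 200.0 + 2e-3
        bump = 60 * np.exp(-0.5 * ((trace2.times - t0) / 3e-4) ** 2)
        trace2.chord["left"] = np.maximum(trace2.chord["left"], bump)
        c1 = discard_mistracked(detect_cycles(trace1), trace1)
        c2 = discard_mistracked(detect_cycles(trace1), trace2)
        flagged_before = set(np.flatnonzero(~c1.valid))
        flagged_after = set(np.flatnonzero(~c2.valid))
        assert flagged_before <= flagged_after


def test_preprocessing_idempotent_on_its_own_output(small_baseline_run):
    """Re-smoothing and re-filtering an already-processed chord changes
    little: the pipeline is (approximately) a projection."""
    trace = small_baseline_run.trace
    again = chord_trace(trace.chord["left"], trace.chord["left"], trace.rate)
    inner = slice(1000, -1000)
    assert np.abs(again[inner] - trace.chord["left"][inner]).max() < 0.1
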
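"""Extract the 16 phase-point signals and the cycle-feature series.

Each valid cycle is sampled at 8 equidistant phases per wing; the
wingbeat-period and downstroke-to-upstroke ratio series are computed
separately (cycle duration is deliberately absent from the signal matrix).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from wingstroke.phase_signals import cycle_features, extract_phase_points, make_segments
from wingstroke.preprocessing import ChordTrace, CycleTable

ROOT = Path(__file__).resolve().parents[1]


def load_preprocessed():
    scratch = ROOT / "scratch"
    trace = ChordTrace(
        times=np.load(scratch / "chord_times.npy"),
        chord={"left": np.load(scratch / "chord_left.npy"),
               "right": np.load(scratch / "chord_right.npy")},
        rate=50_000.0)
    df = pd.read_csv(scratch / "cycles.csv")
    cycles = CycleTable(start_time=df["start_time_s"].to_numpy(),
                        end_time=df["end_time_s"].to_numpy(),
                        valid=df["valid"].to_numpy(),
                        reason=df["reason"].to_numpy(dtype=object))
    return trace, cycles


def main():
    trace, cycles = load_preprocessed()
    signals = extract_phase_points(trace, cycles)
    feats = cycle_features(trace, cycles)
    segments = make_segments(signals, 2500)

    np.save(ROOT / "scratch" / "X.npy", signals.X)
    np.save(ROOT / "scratch" / "cycle_start.npy", signals.cycle_start)
    np.save(ROOT / "scratch" / "cycle_duration.npy", signals.cycle_duration)
    pd.DataFrame({
        "period_s": feats.period,
        "ratio_left": feats.ratio["left"],
        "ratio_right": feats.ratio["right"],
    }).to_csv(ROOT / "scratch" / "features.csv", index=False)

    ratio = 0.5 * (feats.ratio["left"] + feats.ratio["right"])
    print(f"X: {signals.X.shape[0]} signals x {signals.n_cycles} cycles; "
          f"{len(segments)} segment(s) of 2500 cycles")
    print(f"baseline downstroke-to-upstroke ratio: median {np.median(ratio):.3f} "
          f"(min {ratio.min():.3f} during the injected ratio event)")


if __name__ == "__main__":
    main()
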
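"""Cohort-level summaries: occurrence, batch subsampling, repeatability.

Simulates a cohort of 10 flies (2 flight segments each, with per-fly
repertoires of kinematic patterns), classifies every segment, and tabulates
which pattern types occur frequently (>= 25% of flies), how the count of
frequent types behaves in subsampled batches of 5-10 flies, and how many
types co-occur in segment pairs from the same fly.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from wingstroke.classification import (classify_decomposition, repeatability,
                                       subsample_batches, tally_occurrence)
from wingstroke.milca import MilcaConfig
from wingstroke.scenarios import FAST_MILCA, analyze_recording
from wingstroke.synthetic import PatternSpec, StrokeModelConfig, generate_baseline, inject_pattern

ROOT = Path(__file__).resolve().parents[1]
SEED = 1
N_FLIES, SEGMENTS_PER_FLY, N_CYCLES, SEG_LEN = 10, 2, 1560, 1500


def fly_segment(rng, repertoire, seed):
    rec = generate_baseline(StrokeModelConfig(n_cycles=N_CYCLES, seed=seed))
    for t in repertoire:
        if t == "I":
            for o in rng.choice(np.arange(100, N_CYCLES - 200, 400), 2, replace=False):
                rec = inject_pattern(rec, PatternSpec("I", int(o), int(rng.integers(45, 90)),
                                                      float(rng.uniform(5, 7)), "antisymmetric"))
        elif t == "II":
            rec = inject_pattern(rec, PatternSpec("II", int(rng.integers(200, 800)),
                                                  int(rng.integers(80, 120)),
                                                  float(rng.uniform(6, 9)), "symmetric",
                                                  period_coupling=float(rng.uniform(0.004, 0.008))))
        elif t == "III":
            rec = inject_pattern(rec, PatternSpec("III", int(rng.integers(200, 600)),
                                                  int(rng.integers(150, 250)),
                                                  float(rng.uniform(-0.09, -0.05)), "symmetric"))
        elif t in ("IV", "V"):
            rec = inject_pattern(rec, PatternSpec(t, 50, N_CYCLES - 100,
                                                  float(rng.uniform(4.5, 6)), "antisymmetric"))
        elif t == "VI":
            rec = inject_pattern(rec, PatternSpec("VI", int(rng.integers(200, 900)),
                                                  int(rng.integers(80, 150)),
                                                  float(rng.uniform(2.5, 3.5)), "symmetric"))
        elif t == "VII":
            rec = inject_pattern(rec, PatternSpec("VII", 50, N_CYCLES - 100,
                                                  float(rng.uniform(4, 6)), "right_only",
                                                  modulation_period_cycles=int(rng.integers(40, 51))))
    return rec


def main():
    rng = np.random.default_rng(SEED)
    all_types = np.array(["I", "II", "III", "IV", "V", "VI", "VII"])
    cfg = MilcaConfig(seed=SEED, **FAST_MILCA)

    labels_by_fly = {}
    for f in range(N_FLIES):
        # each fly exercises a random repertoire of 2-4 pattern types
        repertoire = rng.choice(all_types, size=int(rng.integers(2, 5)),
                                replace=False)
        seg_labels = []
        for s in range(SEGMENTS_PER_FLY):
            rec = fly_segment(rng, repertoire, seed=int(rng.integers(2 ** 31)))
            analysis = analyze_recording(rec, segment_length=SEG_LEN,
                                         milca_config=cfg)
            labs = classify_decomposition(analysis.decomposition,
                                          analysis.segment.signals,
                                          analysis.features)
            found = {l.primary for l in labs} - {"noise", "unclassified"}
            seg_labels.append(found)
        labels_by_fly[f"fly{f:02d}"] = seg_labels
        print(f"fly{f:02d}: repertoire {sorted(repertoire.tolist())} -> "
              f"found {[sorted(s) for s in seg_labels]}")

    table = tally_occurrence(labels_by_fly)
    pd.DataFrame(table.presence, index=table.flies, columns=table.types) \
        .to_csv(ROOT / "results" / "occurrence.csv")
    frequent = [t for t, f in zip(table.types, table.frequent) if f]
    print(f"frequent types (>= 25% of {N_FLIES} flies): {frequent}")

    boots = subsample_batches(table, batch_sizes=range(5, 11), n_draws=2000,
                              seed=SEED)
    modal = {size: int(np.bincount(c).argmax()) for size, c in boots.items()}
    print(f"modal frequent-type count by batch size: {modal}")

    rep = repeatability(labels_by_fly)
    (ROOT / "results" / "cohort_summary.json").write_text(json.dumps({
        "frequent_types": frequent,
        "modal_frequent_count_by_batch_size": modal,
        "repeatability_mean_min_max": rep}, indent=2))
    means = [v[0] for v in rep.values()]
    print(f"repeatability: mean co-occurring types per segment pair "
          f"{np.mean(means):.2f} (range {min(v[1] for v in rep.values())}"
          f"-{max(v[2] for v in rep.values())})")


if __name__ == "__main__":
    main()
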
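"""Partial reconstruction and selective artifact removal.

Two demonstrations on the demo segment's decomposition: (i) the stroke
deformation carried by the most prominent component alone, against the
baseline stroke; (ii) selective denoising on a dedicated recording pair
(same seed with and without mistracking artifacts): suppressing the
component that captured the artifact lowers the reconstruction error
against the artifact-free ground truth, without touching genuine
single-cycle kinematics the way a frequency-domain filter would.
"""

import json
from pathlib import Path

import numpy as np

from wingstroke.milca import MilcaConfig
from wingstroke.pipeline import child_seed
from wingstroke.reconstruction import baseline_stroke, denoise, partial_reconstruct
from wingstroke.scenarios import (analyze_recording, best_matching_component,
                                  type_i_recording)
from wingstroke.synthetic import PatternSpec, inject_pattern, read_recording

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main():
    demo = read_recording(ROOT / "scratch" / "demo_recording.csv")
    a_demo = analyze_recording(demo, milca_config=MilcaConfig(seed=2))
    base = baseline_stroke(a_demo.segment.signals)
    top = partial_reconstruct(a_demo.decomposition, [0])
    dev = top.deviation(base)
    print(f"demo segment, component 1 alone: stroke deviation spans "
          f"{dev.min():.1f} to {dev.max():.1f} deg around the baseline stroke")

    # denoising demonstration: known-clean twin of an artifact-laden recording
    clean = type_i_recording(child_seed(SEED, "denoise"))
    noisy = clean
    for onset in (700, 1500, 2200):
        noisy = inject_pattern(noisy, PatternSpec("mistracking", onset, 10,
                                                  15.0, "left_only"))
    a_clean = analyze_recording(clean, decompose=False)
    a_noisy = analyze_recording(noisy, milca_config=MilcaConfig(seed=3))
    dec = a_noisy.decomposition
    gt = a_noisy.summed_activation("mistracking")
    bm, r = best_matching_component(dec, gt)
    recon = denoise(dec, [bm])
    n = min(a_clean.segment.X.shape[1], a_noisy.segment.X.shape[1])
    err_raw = float(np.sqrt(np.mean((a_noisy.segment.X[:, :n]
                                     - a_clean.segment.X[:, :n]) ** 2)))
    err_den = float(np.sqrt(np.mean((recon.X_hat[:, :n]
                                     - a_clean.segment.X[:, :n]) ** 2)))
    (ROOT / "results" / "reconstruction_summary.json").write_text(json.dumps({
        "mistracking_component": bm + 1,
        "gt_match_abs_r": r,
        "rms_error_raw_deg": err_raw,
        "rms_error_denoised_deg": err_den}, indent=2))
    print(f"mistracking isolated in component {bm + 1} (|r|={r:.2f}); "
          f"RMS error vs clean ground truth {err_raw:.3f} -> {err_den:.3f} deg")


if __name__ == "__main__":
    main()
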
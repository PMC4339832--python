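"""End-to-end orchestration: simulate -> preprocess -> signals -> decompose
-> dependence -> reconstruction -> classification, with deterministic
seeding and bit-stable serialization of every stage.

A single global seed fans out to per-stage child seeds by stable derivation
(``numpy.random.SeedSequence``), so any stage can be re-run individually and
reproduce the full pipeline's output.  Every stage writes its artifacts
under an output directory together with a manifest entry (stage name, file
hashes, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (ClassificationThresholds, ComponentLabel,
                             classify_decomposition)
from .dependence import NullModel, pairwise_mi_matrix, shuffle_null
from .milca import Decomposition, MilcaConfig, milca_decompose, scale_separating_vectors
from .phase_signals import (CycleFeatureSeries, PhaseSignalMatrix, Segment,
                            cycle_features, extract_phase_points, make_segments)
from .preprocessing import ChordTrace, CycleTable, detect_cycles, discard_mistracked, make_chord_trace
from .synthetic import (EdgeRecording, PatternSpec, StrokeModelConfig,
                        generate_baseline, inject_pattern, write_recording)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "child_seed",
           "load_config", "save_config"]


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed derived from the global seed."""
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "little")
    return int(np.random.SeedSequence([int(seed), h]).generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Nested settings for all stages; round-trips through YAML/JSON."""

    stroke: StrokeModelConfig = field(default_factory=StrokeModelConfig)
    patterns: list[PatternSpec] = field(default_factory=list)
    target_rate: float = 50_000.0
    noise_variance: float = 3.0
    cutoff_hz: float = 1500.0
    points_per_wing: int = 8
    segment_length: int = 2500
    milca: MilcaConfig = field(default_factory=MilcaConfig)
    alpha: float = 0.01
    null_draws: int = 2000
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["patterns"] = [asdict(p) for p in self.patterns]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stroke" in d:
            d["stroke"] = StrokeModelConfig(**d["stroke"])
        if "patterns" in d:
            d["patterns"] = [PatternSpec(**p) for p in d["patterns"]]
        if "milca" in d:
            d["milca"] = MilcaConfig(**d["milca"])
        if "thresholds" in d:
            th = d["thresholds"]
            if "type_i_event_range" in th:
                th["type_i_event_range"] = tuple(th["type_i_event_range"])
            if "type_iii_event_range" in th:
                th["type_iii_event_range"] = tuple(th["type_iii_event_range"])
            d["thresholds"] = ClassificationThresholds(**th)
        return cls(**d)


def save_config(config: PipelineConfig, path) -> None:
    path = Path(path)
    text = (json.dumps(config.to_dict(), indent=2) if path.suffix == ".json"
            else yaml.safe_dump(config.to_dict(), sort_keys=False))
    path.write_text(text)


def load_config(path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.from_dict(d)


@dataclass
class SegmentResult:
    segment: Segment
    features: CycleFeatureSeries
    decomposition: Decomposition
    mi_matrix: np.ndarray
    null: NullModel
    labels: list[ComponentLabel]


@dataclass
class PipelineResult:
    config: PipelineConfig
    recording: EdgeRecording
    trace: ChordTrace
    cycles: CycleTable
    signals: PhaseSignalMatrix
    segments: list[SegmentResult]


class _Manifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.entries: list[dict] = []

    def add(self, stage: str, files: list[Path], seed: int | None = None) -> None:
        hashes = {}
        for f in files:
            hashes[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        self.entries.append({"stage": stage, "files": hashes, "seed": seed,
                             "version": __version__})

    def write(self) -> None:
        (self.out_dir / "manifest.json").write_text(
            json.dumps(self.entries, indent=2))


def _write_matrix(path: Path, M: np.ndarray, prefix: str) -> None:
    cols = [f"{prefix}{i + 1}" for i in range(M.shape[1])]
    pd.DataFrame(M, columns=cols).to_csv(path, index=False, float_format="%.12g")


def simulate(config: PipelineConfig) -> EdgeRecording:
    """Generate the configured recording with a derived stroke seed."""
    stroke = replace(config.stroke, seed=child_seed(config.seed, "simulate"))
    rec = generate_baseline(stroke)
    for spec in config.patterns:
        rec = inject_pattern(rec, spec)
    return rec


def run_pipeline(config: PipelineConfig,
                 recording: EdgeRecording | None = None,
                 out_dir=None) -> PipelineResult:
    """Execute every stage; optionally serialize all artifacts to ``out_dir``.

    If no recording is supplied, one is simulated from ``config.stroke`` and
    ``config.patterns``.  Stage failures propagate with the stage name
    prepended to the error message.
    """
    out = Path(out_dir) if out_dir is not None else None
    manifest = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        manifest = _Manifest(out)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # annotate failures with stage context
            raise type(exc)(f"[stage {name}] {exc}") from exc

    if recording is None:
        recording = _stage("simulate", lambda: simulate(config))
        if out is not None:
            write_recording(recording, out / "recording.csv")
            manifest.add("simulate",
                         [out / "recording.csv", out / "recording.csv.json"],
                         recording.config.seed)

    trace = _stage("preprocess", lambda: make_chord_trace(
        recording, config.target_rate, config.noise_variance, config.cutoff_hz))
    cycles = _stage("preprocess", lambda: discard_mistracked(
        detect_cycles(trace), trace))
    if out is not None:
        cycles.to_frame().to_csv(out / "cycles.csv", index=False,
                                 float_format="%.12g")
        manifest.add("preprocess", [out / "cycles.csv"])

    signals = _stage("phase_signals", lambda: extract_phase_points(
        trace, cycles, config.points_per_wing))
    features_all = _stage("phase_signals", lambda: cycle_features(trace, cycles))
    segments = _stage("phase_signals", lambda: make_segments(
        signals, config.segment_length))
    if out is not None:
        _write_matrix(out / "signals.csv", signals.X.T, "X")
        pd.DataFrame({
            "period_s": features_all.period,
            "ratio_left": features_all.ratio["left"],
            "ratio_right": features_all.ratio["right"],
        }).to_csv(out / "features.csv", index=False, float_format="%.12g")
        manifest.add("phase_signals", [out / "signals.csv", out / "features.csv"])

    milca_cfg = replace(config.milca, seed=child_seed(config.seed, "milca"))
    results = []
    for si, seg in enumerate(segments):
        sl = slice(seg.offset, seg.offset + config.segment_length)
        feats = CycleFeatureSeries(
            period=features_all.period[sl],
            downstroke={w: features_all.downstroke[w][sl] for w in ("left", "right")},
            upstroke={w: features_all.upstroke[w][sl] for w in ("left", "right")},
            ratio={w: features_all.ratio[w][sl] for w in ("left", "right")},
        )
        dec = _stage("milca", lambda: milca_decompose(seg.signals, milca_cfg))
        mi = _stage("dependence", lambda: pairwise_mi_matrix(dec, milca_cfg))
        null = _stage("dependence", lambda: shuffle_null(
            dec, config.null_draws, config.alpha, milca_cfg,
            seed=child_seed(config.seed, f"null{si}")))
        labels = _stage("classification", lambda: classify_decomposition(
            dec, seg.signals, feats, config.thresholds))
        results.append(SegmentResult(seg, feats, dec, mi.values, null, labels))
        if out is not None:
            tag = f"seg{si:02d}"
            _write_matrix(out / f"{tag}_W.csv", dec.W, "w")
            _write_matrix(out / f"{tag}_W_inv.csv", dec.W_inv, "w")
            _write_matrix(out / f"{tag}_Z.csv", dec.Z.T, "Z")
            _write_matrix(out / f"{tag}_scaled_vectors.csv",
                          scale_separating_vectors(dec, seg.signals), "w")
            _write_matrix(out / f"{tag}_mi_matrix.csv", mi.values, "Z")
            (out / f"{tag}_null.json").write_text(json.dumps({
                "sd": null.sd, "alpha": null.alpha, "threshold": null.threshold,
                "n_draws": null.n_draws, "seed": null.seed}, indent=2))
            (out / f"{tag}_labels.json").write_text(json.dumps([
                {"component": ci + 1, "primary": lab.primary,
                 "labels": list(lab.labels), "wiener_entropy": lab.wiener_entropy,
                 "r_period": lab.r_period, "r_ratio": lab.r_ratio,
                 "events": lab.events,
                 "evidence": {k: (v if np.isfinite(v) else None)
                              for k, v in lab.evidence.items()}}
                for ci, lab in enumerate(labels)], indent=2))
            manifest.add(f"analyze_{tag}",
                         sorted(out.glob(f"{tag}_*")),
                         milca_cfg.seed)

    if out is not None:
        manifest.write()
    return PipelineResult(config=config, recording=recording, trace=trace,
                          cycles=cycles, signals=signals, segments=results)
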
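"""Synthetic two-wing stroke recordings with injected kinematic patterns.

Emulates the output of a wingbeat tracker on a tethered fly: per-wing
leading/trailing edge angular positions sampled at a fixed rate while the
wing executes an asymmetric-duty periodic stroke (downstroke from the dorsal
to the ventral reversal over a fraction ``downstroke_fraction`` of the cycle,
upstroke over the remainder; a duty-cycled cosine through a smooth monotone
phase warp, with continuous first derivative).  Seven recurring kinematic pattern types plus a tracking
artifact can be injected on top of the baseline with smooth on/off
envelopes; each injection records its per-cycle ground-truth activation
course so downstream stages can be validated against a known answer.

All deformations act additively on per-cycle waveform parameters, so
injections commute and superpose exactly, and the per-sample measurement
noise is frozen by the recording seed independently of the injected
patterns.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StrokeModelConfig",
    "PatternSpec",
    "EdgeRecording",
    "generate_baseline",
    "inject_pattern",
    "write_recording",
    "read_recording",
    "PATTERN_TYPES",
    "LATERALITIES",
]

PATTERN_TYPES = ("I", "II", "III", "IV", "V", "VI", "VII", "mistracking")
LATERALITIES = ("symmetric", "antisymmetric", "left_only", "right_only")
WINGS = ("left", "right")

#: the localized position pulse for the dorsal-reversal (type IV) and
#: mid-upstroke (type V) jitters is a Gaussian-windowed sinc whose zeros sit
#: at +-1/8 cycle: band-limited to ~800 Hz (resolvable at the per-wing
#: sample rate) while vanishing at the neighbouring phase points
_BUMP_ZERO_SPACING = 0.125
_BUMP_WINDOW_SIGMA = 0.08
#: phase of the mid-upstroke bump: phase point 7 of 8 (0-based index 6)
_MID_UPSTROKE_PHASE = 0.75
#: raised-cosine on/off ramp length of event envelopes, in cycles
_RAMP_CYCLES = 5


@dataclass(frozen=True)
class StrokeModelConfig:
    """Baseline stroke model: ~200 Hz wingbeat sampled at 3125 Hz per wing.

    Angles are in degrees, rates in Hz.  ``downstroke_fraction`` is the
    fraction of the cycle spent moving from the dorsal to the ventral
    reversal (0.60 gives the resting downstroke-to-upstroke ratio of 1.5).
    ``chord_halfwidth`` is the angular offset of the leading/trailing edge
    from the wing chord.
    """

    wingbeat_frequency: float = 200.0
    dorsal_amplitude: float = 70.0
    ventral_amplitude: float = -70.0
    downstroke_fraction: float = 0.60
    per_wing_sample_rate: float = 3125.0
    angular_noise_sd: float = 1.0
    chord_halfwidth: float = 10.0
    n_cycles: int = 2500
    seed: int = 0

    def validate(self) -> None:
        scalars = (
            self.wingbeat_frequency,
            self.dorsal_amplitude,
            self.ventral_amplitude,
            self.downstroke_fraction,
            self.per_wing_sample_rate,
            self.angular_noise_sd,
            self.chord_halfwidth,
        )
        if not all(np.isfinite(v) for v in scalars):
            raise ValueError("non-finite value in stroke model config")
        if not 0.0 < self.downstroke_fraction < 1.0:
            raise ValueError("downstroke_fraction must lie in (0, 1)")
        if self.dorsal_amplitude <= self.ventral_amplitude:
            raise ValueError("dorsal_amplitude must exceed ventral_amplitude")
        if self.wingbeat_frequency <= 0 or self.per_wing_sample_rate <= 0:
            raise ValueError("rates must be positive")
        if self.per_wing_sample_rate / self.wingbeat_frequency < 8:
            raise ValueError("need at least 8 samples per wing per cycle")
        if self.angular_noise_sd < 0:
            raise ValueError("angular_noise_sd must be non-negative")
        if self.chord_halfwidth <= 0:
            raise ValueError("chord_halfwidth must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be positive")


@dataclass(frozen=True)
class PatternSpec:
    """One injected kinematic event.

    ``magnitude`` is in degrees for amplitude-type patterns (I, II, IV-VII,
    mistracking displacement) and is the dimensionless shift of the
    ventral-reversal phase (change of the downstroke fraction) for type III.
    ``period_coupling`` (type II only) is the change of wingbeat period in
    milliseconds per degree of amplitude change.  ``modulation_period_cycles``
    (type VII only) is the period of the slow sinusoidal modulation.
    """

    pattern_type: str
    onset_cycle: int
    duration_cycles: int
    magnitude: float
    laterality: str = "symmetric"
    period_coupling: float = 0.0
    modulation_period_cycles: int = 45

    def validate(self, config: StrokeModelConfig) -> None:
        if self.pattern_type not in PATTERN_TYPES:
            raise ValueError(f"unknown pattern_type {self.pattern_type!r}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if self.onset_cycle < 0 or self.duration_cycles < 1:
            raise ValueError("event must have non-negative onset and positive duration")
        if self.onset_cycle + self.duration_cycles > config.n_cycles:
            raise ValueError("event extends past the end of the recording")
        if self.pattern_type == "VII" and self.modulation_period_cycles < 4:
            raise ValueError("modulation period too short")


@dataclass
class EdgeRecording:
    """Raw per-wing edge-angle samples plus generator ground truth.

    ``ground_truth[k]`` is the per-cycle activation course of ``specs[k]``
    (signed magnitude of the injected deformation in each cycle, or a 0/1
    indicator for mistracking).  ``cycle_starts`` holds the true cycle
    boundary times (length ``n_cycles + 1``).
    """

    config: StrokeModelConfig
    specs: list[PatternSpec]
    times: dict[str, np.ndarray]
    leading: dict[str, np.ndarray]
    trailing: dict[str, np.ndarray]
    ground_truth: list[np.ndarray]
    cycle_starts: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.config.n_cycles


def _envelope(n_cycles: int, onset: int, duration: int) -> np.ndarray:
    """Smooth 0->1->0 activation envelope with raised-cosine ramps."""
    env = np.zeros(n_cycles)
    r = min(_RAMP_CYCLES, duration // 2)
    core = np.ones(duration)
    if r > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(1, r + 1)) / (r + 1)))
        core[:r] = ramp
        core[duration - r:] = ramp[::-1]
    env[onset:onset + duration] = core
    return env


def _spec_rng(config: StrokeModelConfig, spec: PatternSpec) -> np.random.Generator:
    # seed depends only on (recording seed, spec content): injections commute
    key = json.dumps(asdict(spec), sort_keys=True).encode()
    s = ((config.seed & 0x7FFFFFFF) * 2654435761 + zlib.crc32(key)) % (2 ** 31)
    return np.random.default_rng(s)


def _lateral_signs(laterality: str) -> tuple[float, float]:
    table = {
        "symmetric": (1.0, 1.0),
        "antisymmetric": (1.0, -1.0),
        "left_only": (1.0, 0.0),
        "right_only": (0.0, 1.0),
    }
    return table[laterality]


class _Deformation:
    """Accumulated per-cycle waveform-parameter deltas."""

    def __init__(self, n: int):
        self.dD = {w: np.zeros(n) for w in WINGS}
        self.dV = {w: np.zeros(n) for w in WINGS}
        self.dduty = {w: np.zeros(n) for w in WINGS}
        self.dT = np.zeros(n)  # seconds
        self.bumps: list[tuple[str, float, np.ndarray]] = []  # (wing, phi0, amps)
        self.mistracks: list[tuple[str, int, float, float, float]] = []
        # (wing, cycle, phase_start, span_cycles, offset_deg)


def _apply_spec(spec: PatternSpec, config: StrokeModelConfig,
                d: _Deformation) -> np.ndarray:
    """Add one pattern's deltas to ``d``; return its activation course."""
    n = config.n_cycles
    e = _envelope(n, spec.onset_cycle, spec.duration_cycles)
    m = spec.magnitude
    t = spec.pattern_type

    if t == "I":
        # antisymmetric ventral-amplitude change; period untouched.
        lat = "antisymmetric" if spec.laterality == "symmetric" else spec.laterality
        sl, sr = _lateral_signs(lat)
        d.dV["left"] += -sl * m * e   # more negative = larger ventral amplitude
        d.dV["right"] += -sr * m * e
        return m * e
    if t == "II":
        sl, sr = _lateral_signs(spec.laterality)
        for w, s in (("left", sl), ("right", sr)):
            d.dD[w] += 0.5 * s * m * e
            d.dV[w] += -0.5 * s * m * e
        d.dT += spec.period_coupling * 1e-3 * m * e
        return m * e
    if t == "III":
        sl, sr = _lateral_signs(spec.laterality)
        d.dduty["left"] += sl * m * e
        d.dduty["right"] += sr * m * e
        return m * e
    if t in ("IV", "V"):
        rng = _spec_rng(config, spec)
        # temporally correlated, heavy-tailed jitter: physiological position
        # noise persists over a few cycles and arrives in bursts rather than
        # being cycle-to-cycle white Gaussian.  AR(2) resonance near
        # 0.15 / cycle with Laplace innovations.
        from scipy.signal import lfilter
        r_pole, w0 = 0.7, 2 * np.pi * 0.15
        a = [1.0, -2 * r_pole * np.cos(w0), r_pole ** 2]
        innov = rng.laplace(0.0, 1.0, size=n) * (rng.random(n) < 0.3)
        raw = lfilter([1.0], a, innov)
        sd = raw.std()
        jitter = (raw / sd if sd > 0 else raw) * abs(m) * e
        lat = "antisymmetric" if spec.laterality == "symmetric" else spec.laterality
        sl, sr = _lateral_signs(lat)
        phi0 = 0.0 if t == "IV" else _MID_UPSTROKE_PHASE
        if sl:
            d.bumps.append(("left", phi0, sl * jitter))
        if sr:
            d.bumps.append(("right", phi0, sr * jitter))
        return jitter
    if t == "VI":
        c = np.arange(n) - spec.onset_cycle
        alt = np.where(c % 2 == 0, 1.0, -1.0)
        course = m * e * alt
        d.dV["left"] += -course
        d.dV["right"] += -course
        return course
    if t == "VII":
        c = np.arange(n) - spec.onset_cycle
        course = m * np.sin(2 * np.pi * c / spec.modulation_period_cycles) * e
        lat = "right_only" if spec.laterality == "symmetric" else spec.laterality
        sl, sr = _lateral_signs(lat)
        d.dD["left"] += sl * course
        d.dD["right"] += sr * course
        return course
    if t == "mistracking":
        rng = _spec_rng(config, spec)
        span = float(rng.uniform(0.5, 2.0))
        last = spec.onset_cycle + spec.duration_cycles - max(1, int(np.ceil(span)))
        cyc = int(rng.integers(spec.onset_cycle, max(spec.onset_cycle, last) + 1))
        phase = float(rng.uniform(0.2, 0.4))  # mid-downstroke
        wing = "right" if spec.laterality == "right_only" else "left"
        offset = m if m != 0 else 0.0
        d.mistracks.append((wing, cyc, phase, span, offset))
        act = np.zeros(n)
        act[cyc:min(n, cyc + int(np.ceil(span)) + 1)] = 1.0
        return act
    raise ValueError(f"unknown pattern_type {t!r}")


def _waveform(phi: np.ndarray, D: np.ndarray, V: np.ndarray,
              duty: np.ndarray) -> np.ndarray:
    """Duty-cycled cosine stroke via a smooth monotone phase warp.

    The chord is cos(2 pi psi(phi)) scaled to [V, D], where psi is a
    piecewise-quintic monotone warp with psi(0) = 0, psi(duty) = 0.5,
    psi(1) = 1, unit slope and zero warp curvature at every reversal.
    This keeps the waveform locally symmetric around each reversal, so
    low-pass filtering in the preprocessing stage does not displace the
    detected reversal times (a plain piecewise cosine has unequal curvature
    on the two flanks of each reversal, which would bias the measured
    downstroke-to-upstroke ratio).  The warp is monotone for any duty in
    (0, 1).
    """
    mid = 0.5 * (D + V)
    amp = 0.5 * (D - V)
    psi = np.empty_like(phi)
    down = phi < duty
    u = phi[down] / duty[down]
    h = duty[down]
    smoothstep = 10 * u**3 - 15 * u**4 + 6 * u**5
    psi[down] = h * u + (0.5 - h) * smoothstep
    up = ~down
    u = (phi[up] - duty[up]) / (1.0 - duty[up])
    h = 1.0 - duty[up]
    smoothstep = 10 * u**3 - 15 * u**4 + 6 * u**5
    psi[up] = 0.5 + h * u + (0.5 - h) * smoothstep
    return mid + amp * np.cos(2 * np.pi * psi)


def _synthesize(config: StrokeModelConfig,
                specs: list[PatternSpec]) -> EdgeRecording:
    config.validate()
    for s in specs:
        s.validate(config)
    n = config.n_cycles
    d = _Deformation(n)
    activations = [_apply_spec(s, config, d) for s in specs]

    base_T = 1.0 / config.wingbeat_frequency
    T = base_T + d.dT
    if np.any(T <= 0):
        raise ValueError("injected period changes produce non-positive cycle duration")
    starts = np.concatenate([[0.0], np.cumsum(T)])
    total = starts[-1]

    fs = config.per_wing_sample_rate
    n_samp = int(np.floor(total * fs))
    t = np.arange(n_samp) / fs
    ci = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n - 1)
    phi = np.clip((t - starts[ci]) / T[ci], 0.0, np.nextafter(1.0, 0.0))

    # frozen noise pool: independent of injected patterns
    rng = np.random.default_rng(config.seed)
    pool = int(np.ceil(2.0 * n * base_T * fs)) + 64
    if n_samp > pool:
        raise ValueError("injected period changes exceed the noise pool headroom")
    noise = {(w, edge): config.angular_noise_sd * rng.standard_normal(pool)
             for w in WINGS for edge in ("leading", "trailing")}

    duty_base = config.downstroke_fraction
    times, leading, trailing = {}, {}, {}
    for w in WINGS:
        D = config.dorsal_amplitude + d.dD[w][ci]
        V = config.ventral_amplitude + d.dV[w][ci]
        duty = np.clip(duty_base + d.dduty[w][ci], 0.05, 0.95)
        chord = _waveform(phi, D, V, duty)
        for wing_b, phi0, amps in d.bumps:
            if wing_b != w:
                continue
            # the pulse of cycle c can spill across cycle boundaries; each
            # spilled image keeps its own cycle's amplitude so the chord
            # stays continuous at the boundaries
            a_prev = np.concatenate([[0.0], amps[:-1]])
            a_next = np.concatenate([amps[1:], [0.0]])
            bump = np.zeros_like(phi)
            for shift, amp_c in ((0.0, amps), (1.0, a_next), (-1.0, a_prev)):
                x = phi - phi0 - shift
                bump += amp_c[ci] * (np.sinc(x / _BUMP_ZERO_SPACING)
                                     * np.exp(-0.5 * (x / _BUMP_WINDOW_SIGMA) ** 2))
            chord = chord + bump
        le = chord + config.chord_halfwidth + noise[(w, "leading")][:n_samp]
        tr = chord - config.chord_halfwidth + noise[(w, "trailing")][:n_samp]
        for wing_m, cyc, ph, span, off in d.mistracks:
            if wing_m != w or off == 0:
                continue
            t0 = starts[cyc] + ph * T[cyc]
            t1 = t0 + span * T[cyc]
            mask = (t >= t0) & (t < t1)
            le = le + off * mask
            tr = tr + off * mask
        times[w] = t.copy()
        leading[w] = le
        trailing[w] = tr

    return EdgeRecording(
        config=config,
        specs=list(specs),
        times=times,
        leading=leading,
        trailing=trailing,
        ground_truth=activations,
        cycle_starts=starts,
    )


def generate_baseline(config: StrokeModelConfig) -> EdgeRecording:
    """Generate a pattern-free recording from the baseline stroke model."""
    return _synthesize(config, [])


def inject_pattern(recording: EdgeRecording, spec: PatternSpec) -> EdgeRecording:
    """Return a new recording with ``spec`` injected on top of existing specs.

    Deformations add on the angle (or parameter) scale, so the result does
    not depend on the order of successive injections.
    """
    spec.validate(recording.config)
    return _synthesize(recording.config, recording.specs + [spec])


def align_activations(recording: EdgeRecording,
                      cycle_start_times: np.ndarray,
                      cycle_durations: np.ndarray | None = None
                      ) -> list[np.ndarray]:
    """Ground-truth activation courses aligned to detected cycles.

    Detected cycle boundaries need not coincide index-wise with generator
    cycles (the recording's first boundary is not a detectable reversal),
    so each detected cycle is mapped to the generator cycle containing its
    midpoint.  Returns one aligned activation series per injected spec.
    """
    t = np.asarray(cycle_start_times, dtype=float)
    if cycle_durations is None:
        mid = t + 0.5 * float(np.median(np.diff(t))) if len(t) > 1 else t
    else:
        mid = t + 0.5 * np.asarray(cycle_durations, dtype=float)
    idx = np.clip(np.searchsorted(recording.cycle_starts, mid) - 1,
                  0, recording.n_cycles - 1)
    return [a[idx] for a in recording.ground_truth]


def write_recording(recording: EdgeRecording, csv_path) -> None:
    """Write edge samples as CSV plus a JSON sidecar with full provenance."""
    frames = []
    for w in WINGS:
        frames.append(pd.DataFrame({
            "time_s": recording.times[w],
            "wing": "L" if w == "left" else "R",
            "leading_deg": recording.leading[w],
            "trailing_deg": recording.trailing[w],
        }))
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    sidecar = {
        "config": asdict(recording.config),
        "specs": [asdict(s) for s in recording.specs],
        "seed": recording.config.seed,
        "cycle_starts": recording.cycle_starts.tolist(),
        "ground_truth": [a.tolist() for a in recording.ground_truth],
    }
    with open(str(csv_path) + ".json", "w") as fh:
        json.dump(sidecar, fh)


def read_recording(csv_path) -> EdgeRecording:
    """Read a recording written by :func:`write_recording`."""
    df = pd.read_csv(csv_path)
    with open(str(csv_path) + ".json") as fh:
        sidecar = json.load(fh)
    config = StrokeModelConfig(**sidecar["config"])
    specs = [PatternSpec(**s) for s in sidecar["specs"]]
    times, leading, trailing = {}, {}, {}
    for w, code in (("left", "L"), ("right", "R")):
        sub = df[df["wing"] == code]
        times[w] = sub["time_s"].to_numpy()
        leading[w] = sub["leading_deg"].to_numpy()
        trailing[w] = sub["trailing_deg"].to_numpy()
    return EdgeRecording(
        config=config,
        specs=specs,
        times=times,
        leading=leading,
        trailing=trailing,
        ground_truth=[np.asarray(a, dtype=float) for a in sidecar["ground_truth"]],
        cycle_starts=np.asarray(sidecar["cycle_starts"], dtype=float),
    )
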
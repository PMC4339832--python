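"""Screening and classification of least-dependent kinematic components.

Components are first screened for broadband noise by spectral flatness
(Wiener entropy of the Welch spectrum > 0.9), then tested against the seven
recurring pattern types:

I    antisymmetric ventral-amplitude events (40-100 cycles), uncorrelated
     with the wingbeat period -- the yaw-torque / saccade signature;
II   symmetric stroke-amplitude changes correlated with the period
     (flight-force control);
III  events altering the downstroke-to-upstroke duration ratio
     (pitch-torque control);
IV   separating vector dominated by the left-right difference at the
     dorsal reversal (phase points 1 and 9);
V    the same dominance at mid-upstroke (phase points 7 and 15);
VI   period-2 alternation of ventral amplitude, spectral power concentrated
     near the Nyquist frequency (0.5 / cycle);
VII  slow periodic modulation with a dominant spectral peak near
     0.02 / cycle (period 40-50 cycles).

Types are evaluated in the order noise, VI, VII, IV, V, I, II, III; a
component keeps every label it matches (the supersets are not mutually
exclusive) with the first match as its primary label.  Classification is
deterministic given a decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import medfilt, welch

from .milca import Decomposition, MilcaConfig, kraskov_mi, scale_separating_vectors
from .phase_signals import CycleFeatureSeries, PhaseSignalMatrix
from .dependence import MIMatrix

__all__ = [
    "SpectralSummary",
    "ComponentLabel",
    "ClassificationThresholds",
    "OccurrenceTable",
    "wiener_entropy",
    "welch_spectrum",
    "detect_events",
    "classify_component",
    "classify_decomposition",
    "tally_occurrence",
    "subsample_batches",
    "repeatability",
    "compare_pca",
]

TYPE_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Numeric criteria for the pattern types (all per-cycle units).

    Defaults implement the printed bounds (noise flatness 0.9, period
    correlation 0.45 / 0.2, type VII peak at 0.02 +- 0.005 per cycle, type
    VI band power ratio of 10 between 0.35 and 0.5 per cycle, events of
    40-100 cycles) plus documented conventions for what the printed bounds
    leave open (60% L1 dominance for IV/V, +-0.5 symmetry, event detector
    z > 3 over >= 8 cycles).
    """

    we_noise: float = 0.9
    event_z: float = 3.0
    event_min_cycles: int = 8
    event_merge_gap: int = 5
    vi_band_ratio: float = 10.0
    vi_run_cycles: int = 20
    vii_peak_freq: float = 0.02
    vii_peak_tol: float = 0.005
    vii_peak_factor: float = 5.0
    dominance_l1: float = 0.6
    r_period_type_ii: float = 0.45
    r_period_type_i: float = 0.2
    symmetry: float = 0.5
    type_i_event_range: tuple[int, int] = (40, 100)
    type_iii_event_range: tuple[int, int] = (40, 600)
    r_ratio_type_iii: float = 0.45
    ratio_excursion: float = 0.1
    welch_nperseg: int = 256


@dataclass
class SpectralSummary:
    """Welch spectrum (cycle^-1), flatness, and dominant-peak data."""

    frequencies: np.ndarray
    density: np.ndarray
    wiener_entropy: float
    peak_frequency: float
    peak_power: float

    def band_power(self, lo: float, hi: float) -> float:
        mask = (self.frequencies >= lo) & (self.frequencies <= hi)
        return float(self.density[mask].mean()) if mask.any() else 0.0


@dataclass
class ComponentLabel:
    """Primary label, full multi-label set, and the evidence behind them."""

    primary: str
    labels: tuple[str, ...]
    wiener_entropy: float
    r_period: float
    r_ratio: float
    events: list[tuple[int, int, int]]  # (onset, duration, polarity)
    evidence: dict = field(default_factory=dict)


@dataclass
class OccurrenceTable:
    """Presence of pattern types per fly, with the frequent-pattern rule.

    A type is "frequent" if present in at least 25% of the flies (e.g. 3 of
    10, or 2 of 8).
    """

    flies: list[str]
    types: tuple[str, ...]
    presence: np.ndarray  # flies x types, bool
    counts: np.ndarray
    frequent: np.ndarray

    @staticmethod
    def required(n_flies: int) -> int:
        return int(np.ceil(0.25 * n_flies))


def welch_spectrum(z: np.ndarray, nperseg: int = 256) -> SpectralSummary:
    """Welch power spectrum on the per-cycle scale (Nyquist = 0.5 cycle^-1).

    Hann window, 50% overlap, DC bin excluded.  Wiener entropy is the ratio
    of the geometric to the arithmetic mean of the density: 0 for a pure
    sinusoid, 1 for white noise.  A constant series has no spectrum and is
    returned flagged with entropy 0.
    """
    z = np.asarray(z, dtype=float).ravel()
    if z.size < 2 * nperseg:
        nperseg = max(16, 2 ** int(np.log2(max(z.size // 2, 16))))
    if z.std() == 0:
        f = np.array([0.5])
        return SpectralSummary(f, np.zeros(1), 0.0, 0.0, 0.0)
    f, p = welch(z, fs=1.0, window="hann", nperseg=nperseg,
                 noverlap=nperseg // 2, detrend="constant")
    keep = f > 0
    f, p = f[keep], p[keep]
    p_safe = np.maximum(p, np.finfo(float).tiny)
    we = float(np.exp(np.mean(np.log(p_safe))) / np.mean(p_safe))
    ipk = int(np.argmax(p))
    return SpectralSummary(f, p, we, float(f[ipk]), float(p[ipk]))


def wiener_entropy(z: np.ndarray, nperseg: int = 256) -> float:
    """Spectral flatness of a component series; see :func:`welch_spectrum`."""
    z = np.asarray(z, dtype=float).ravel()
    if z.size < 256:
        raise ValueError("need at least 256 cycles for a stable flatness estimate")
    return welch_spectrum(z, nperseg).wiener_entropy


def detect_events(z: np.ndarray, z_thresh: float = 3.0, min_cycles: int = 8,
                  merge_gap: int = 5) -> list[tuple[int, int, int]]:
    """Activation events: sustained robust-z excursions of the time course.

    Maximal runs with |z - median| / (1.4826 MAD) > ``z_thresh`` lasting at
    least ``min_cycles``; runs separated by fewer than ``merge_gap`` cycles
    are merged.  Returns (onset, duration, polarity) triples.
    """
    z = np.asarray(z, dtype=float).ravel()
    med = np.median(z)
    mad = np.median(np.abs(z - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = z.std() or 1.0
    rz = (z - med) / scale
    active = np.abs(rz) > z_thresh
    if not active.any():
        return []
    # maximal runs
    edges = np.flatnonzero(np.diff(np.concatenate([[0], active.view(np.int8), [0]])))
    runs = list(zip(edges[::2], edges[1::2]))  # [start, stop)
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] < merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    out = []
    for a, b in merged:
        if b - a >= min_cycles:
            polarity = 1 if np.mean(rz[a:b]) >= 0 else -1
            out.append((int(a), int(b - a), polarity))
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _dominance(vector: np.ndarray, i: int, j: int) -> tuple[float, bool]:
    l1 = np.abs(vector).sum()
    mass = (abs(vector[i]) + abs(vector[j])) / l1 if l1 > 0 else 0.0
    opposite = vector[i] * vector[j] < 0
    return float(mass), bool(opposite)


def _ventral_symmetry(mixing_column: np.ndarray, baseline: np.ndarray,
                      P: int) -> float:
    """Sign of the left-vs-right deviation at the ventral reversal.

    For a single component the per-cycle ventral deviations of the two
    wings are exactly proportional, so their correlation is +-1 (the sign
    of the product of the mixing coefficients); 0 when either wing's
    ventral coefficient is negligible.
    """
    vl = int(np.argmin(baseline[:P]))
    vr = P + int(np.argmin(baseline[P:]))
    u = mixing_column
    guard = 0.1 * np.abs(u).max()
    if abs(u[vl]) < guard or abs(u[vr]) < guard:
        return 0.0
    return float(np.sign(u[vl] * u[vr]))


def _alternating_run(z: np.ndarray) -> int:
    """Longest run (in cycles) of sign-alternating successive differences."""
    s = np.sign(np.diff(z))
    if s.size < 2:
        return 0
    alt = s[1:] * s[:-1] < 0
    best = cur = 0
    for a in alt:
        cur = cur + 1 if a else 0
        best = max(best, cur)
    # a run of m consecutive alternating difference pairs spans m + 2 cycles
    return best + 2 if best > 0 else 0


def classify_component(z: np.ndarray, *, period: np.ndarray, ratio: np.ndarray,
                       scaled_vector: np.ndarray, mixing_column: np.ndarray,
                       baseline: np.ndarray, points_per_wing: int = 8,
                       thresholds: ClassificationThresholds = ClassificationThresholds()
                       ) -> ComponentLabel:
    """Assign pattern-type labels to one component given its segment context.

    See the module docstring for the criteria; evaluation order fixes the
    primary label, the full label set is retained.
    """
    th = thresholds
    z = np.asarray(z, dtype=float).ravel()
    P = points_per_wing
    for name, arr in (("period", period), ("ratio", ratio),
                      ("scaled_vector", scaled_vector),
                      ("mixing_column", mixing_column), ("baseline", baseline)):
        if arr is None:
            raise ValueError(f"missing context element: {name}")

    spec = welch_spectrum(z, th.welch_nperseg)
    we = spec.wiener_entropy
    r_period = _pearson(z, period)
    r_ratio = _pearson(z, ratio)
    events = detect_events(z, th.event_z, th.event_min_cycles, th.event_merge_gap)
    evidence: dict = {"wiener_entropy": we, "r_period": r_period,
                      "r_ratio": r_ratio, "peak_frequency": spec.peak_frequency}

    if we > th.we_noise:
        return ComponentLabel("noise", ("noise",), we, r_period, r_ratio,
                              events, evidence)

    labels: list[str] = []

    hi = spec.band_power(0.45, 0.5)
    lo = spec.band_power(0.30, 0.35)
    band_ratio = hi / lo if lo > 0 else np.inf
    run = _alternating_run(z)
    evidence["vi_band_ratio"] = band_ratio
    evidence["vi_alternating_run"] = run
    if band_ratio >= th.vi_band_ratio and run >= th.vi_run_cycles:
        labels.append("VI")

    median_density = float(np.median(spec.density))
    if (0 < spec.peak_frequency <= 0.05
            and abs(spec.peak_frequency - th.vii_peak_freq) <= th.vii_peak_tol
            and spec.peak_power >= th.vii_peak_factor * median_density):
        labels.append("VII")

    for lab, (i, j) in (("IV", (0, P)), ("V", (P - 2, 2 * P - 2))):
        mass, opposite = _dominance(scaled_vector, i, j)
        evidence[f"dominance_{lab}"] = mass
        if mass >= th.dominance_l1 and opposite:
            labels.append(lab)

    lo_i, hi_i = th.type_i_event_range
    has_type_i_events = any(lo_i <= dur <= hi_i for _, dur, _ in events)
    ventral_sym = _ventral_symmetry(mixing_column, baseline, P)
    evidence["ventral_symmetry"] = ventral_sym
    if (has_type_i_events and abs(r_period) < th.r_period_type_i
            and ventral_sym < -th.symmetry):
        labels.append("I")

    profile_sym = _pearson(mixing_column[:P], mixing_column[P:])
    evidence["profile_symmetry"] = profile_sym
    if abs(r_period) > th.r_period_type_ii and profile_sym > th.symmetry:
        labels.append("II")

    lo_iii, hi_iii = th.type_iii_event_range
    iii_events = [(a, dur) for a, dur, _ in events if lo_iii <= dur <= hi_iii]
    if iii_events:
        mask = np.zeros(z.size, dtype=bool)
        for a, dur in iii_events:
            mask[a:a + dur] = True
        r_ratio_ev = _pearson(z[mask], ratio[mask]) if mask.sum() >= 30 else 0.0
        smooth_ratio = medfilt(ratio, 21)
        excursion = float(np.abs(smooth_ratio[mask] - np.median(ratio)).max())
        evidence["r_ratio_events"] = r_ratio_ev
        evidence["ratio_excursion"] = excursion
        if abs(r_ratio_ev) > th.r_ratio_type_iii or excursion >= th.ratio_excursion:
            labels.append("III")

    primary = labels[0] if labels else "unclassified"
    return ComponentLabel(primary, tuple(labels) or ("unclassified",),
                          we, r_period, r_ratio, events, evidence)


def classify_decomposition(decomposition: Decomposition,
                           signals: PhaseSignalMatrix,
                           features: CycleFeatureSeries,
                           thresholds: ClassificationThresholds = ClassificationThresholds()
                           ) -> list[ComponentLabel]:
    """Classify every component of a segment's decomposition."""
    scaled = scale_separating_vectors(decomposition, signals)
    baseline = signals.X.mean(axis=1)
    ratio = features.mean_ratio()
    out = []
    for i in range(decomposition.n_components):
        out.append(classify_component(
            decomposition.Z[i],
            period=features.period,
            ratio=ratio,
            scaled_vector=scaled[i],
            mixing_column=decomposition.W_inv[:, i],
            baseline=baseline,
            points_per_wing=signals.points_per_wing,
            thresholds=thresholds,
        ))
    return out


def tally_occurrence(labels_by_fly: dict[str, list[set[str]]]) -> OccurrenceTable:
    """Presence grid of pattern types per fly and the frequent-type flags.

    ``labels_by_fly`` maps a fly id to the per-segment sets of type labels.
    """
    flies = list(labels_by_fly)
    presence = np.zeros((len(flies), len(TYPE_LABELS)), dtype=bool)
    for fi, fly in enumerate(flies):
        seen: set[str] = set().union(*labels_by_fly[fly]) if labels_by_fly[fly] else set()
        for ti, t in enumerate(TYPE_LABELS):
            presence[fi, ti] = t in seen
    counts = presence.sum(axis=0)
    need = OccurrenceTable.required(len(flies))
    return OccurrenceTable(flies=flies, types=TYPE_LABELS, presence=presence,
                           counts=counts, frequent=counts >= need)


def subsample_batches(table: OccurrenceTable, batch_sizes,
                      n_draws: int = 1000, seed: int = 0) -> dict[int, np.ndarray]:
    """Bootstrap the frequent-pattern count for smaller batches of flies.

    Batches are drawn with replacement from the measured flies; in each
    draw a type counts as frequent if it is present in at least 25% of the
    drawn flies (duplicates counted).  Returns, per batch size, the array
    of frequent-type counts over draws.
    """
    rng = np.random.default_rng(seed)
    n_flies = len(table.flies)
    out = {}
    for size in batch_sizes:
        need = OccurrenceTable.required(size)
        counts = np.empty(n_draws, dtype=int)
        for t in range(n_draws):
            drawn = rng.integers(0, n_flies, size=size)
            counts[t] = int((table.presence[drawn].sum(axis=0) >= need).sum())
        out[int(size)] = counts
    return out


def repeatability(labels_by_fly: dict[str, list[set[str]]]
                  ) -> dict[str, tuple[float, int, int]]:
    """Per-fly (mean, min, max) number of types shared by segment pairs."""
    out = {}
    for fly, segs in labels_by_fly.items():
        type_sets = [set(s) & set(TYPE_LABELS) for s in segs]
        counts = [len(a & b) for ai, a in enumerate(type_sets)
                  for b in type_sets[ai + 1:]]
        if counts:
            out[fly] = (float(np.mean(counts)), int(min(counts)), int(max(counts)))
    return out


def compare_pca(X: np.ndarray | PhaseSignalMatrix,
                config: MilcaConfig = MilcaConfig()):
    """Principal components of the same segment and their pairwise MI.

    The Karhunen-Loeve transform decorrelates the signals but does not make
    them statistically independent; returning the PC series together with
    their MI matrix enables a direct contrast with the least-dependent
    components.
    """
    if isinstance(X, PhaseSignalMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    Xc = X - mu
    C = Xc @ Xc.T / X.shape[1]
    evals, U = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    U = U[:, order]
    pcs = U.T @ Xc
    d = pcs.shape[0]
    mi = np.full((d, d), np.nan)
    rng = np.random.default_rng(config.seed)
    for i in range(d - 1):
        for j in range(i + 1, d):
            mi[i, j] = mi[j, i] = kraskov_mi(
                pcs[i], pcs[j], k=config.k_neighbors,
                neighborhood=config.neighborhood, rng=rng)
    return pcs, MIMatrix(values=mi)
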
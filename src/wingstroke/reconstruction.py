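"""Baseline stroke, partial reconstruction, and component-selective denoising.

The wing stroke in each cycle is represented as the baseline (mean) stroke
<X> plus the deformation W^-1 (Z - <Z>).  Keeping only a subset of
components in the second term gives the partial reconstruction of the
corresponding stroke deformation modes; suppressing the component(s) that
encode a tracking artifact denoises the trajectory without touching true
single-cycle kinematics.  Reconstructions are linear in the included set:
deviations from baseline superpose additively over disjoint component sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .milca import Decomposition
from .phase_signals import PhaseSignalMatrix

__all__ = [
    "BaselineStroke",
    "ReconstructedStroke",
    "baseline_stroke",
    "partial_reconstruct",
    "denoise",
    "attach_times",
]


@dataclass
class BaselineStroke:
    """Mean stroke angles, one per phase point (the baseline wing stroke)."""

    mean_angles: np.ndarray


@dataclass
class ReconstructedStroke:
    """Reconstructed phase points for a subset of components.

    ``X_hat`` has the same (phase point x cycle) layout as the input signal
    matrix.  ``times`` (optional) maps phase points back to seconds using
    the recorded per-cycle durations, for plotting against the raw trace.
    """

    X_hat: np.ndarray
    included: tuple[int, ...]
    times: np.ndarray | None = None

    def deviation(self, baseline: BaselineStroke) -> np.ndarray:
        return self.X_hat - baseline.mean_angles[:, None]


def baseline_stroke(X: np.ndarray | PhaseSignalMatrix) -> BaselineStroke:
    """Row means of the phase-point signals over the segment."""
    if isinstance(X, PhaseSignalMatrix):
        X = X.X
    return BaselineStroke(mean_angles=np.asarray(X, dtype=float).mean(axis=1))


def _check_indices(include, n: int) -> tuple[int, ...]:
    include = tuple(sorted(set(int(i) for i in include)))
    if any(i < 0 or i >= n for i in include):
        raise IndexError(f"component index out of range 0..{n - 1}")
    return include


def partial_reconstruct(decomposition: Decomposition,
                        include) -> ReconstructedStroke:
    """Reconstruct phase points from a subset of components.

    X_hat = <X> + W^-1_restricted (Z - <Z>), where the restriction zeroes
    every column of the mixing matrix outside ``include``.  Including all
    components reproduces X exactly; including none returns the baseline
    stroke in every cycle.
    """
    d = decomposition.n_components
    include = _check_indices(include, d)
    Zc = decomposition.Z - decomposition.Z_mean[:, None]
    mean_X = decomposition.W_inv @ decomposition.Z_mean
    cols = np.zeros(d)
    cols[list(include)] = 1.0
    X_hat = mean_X[:, None] + (decomposition.W_inv * cols[None, :]) @ Zc
    return ReconstructedStroke(X_hat=X_hat, included=include)


def denoise(decomposition: Decomposition, exclude) -> ReconstructedStroke:
    """Reconstruct from all components except ``exclude``.

    Used to selectively remove mistracking artifacts: the excluded
    component(s) carry the statistically independent artifact, so the
    remaining reconstruction keeps genuine kinematics intact.
    """
    d = decomposition.n_components
    exclude = _check_indices(exclude, d)
    if not exclude:
        raise ValueError("exclude must be nonempty")
    include = tuple(i for i in range(d) if i not in exclude)
    return partial_reconstruct(decomposition, include)


def attach_times(recon: ReconstructedStroke, signals: PhaseSignalMatrix) -> ReconstructedStroke:
    """Attach per-cycle time points from the recorded cycle durations."""
    P = signals.points_per_wing
    frac = np.arange(P) / P
    per_wing = signals.cycle_start[None, :] + frac[:, None] * signals.cycle_duration[None, :]
    recon.times = np.vstack([per_wing, per_wing])
    return recon


def interpolated_curves(recon: ReconstructedStroke, signals: PhaseSignalMatrix,
                        samples_per_cycle: int = 64):
    """Cubic-interpolated reconstruction for plotting (presentation only).

    Returns ``(times, curves)`` with one smooth curve per wing; statistics
    should always use the per-cycle phase points, not these curves.
    """
    P = signals.points_per_wing
    frac = np.arange(P) / P
    dense_frac = np.arange(samples_per_cycle) / samples_per_cycle
    out_t, out_l, out_r = [], [], []
    for c in range(signals.n_cycles):
        t0, T = signals.cycle_start[c], signals.cycle_duration[c]
        for rows, acc in ((slice(0, P), out_l), (slice(P, 2 * P), out_r)):
            y = recon.X_hat[rows, c]
            spl = CubicSpline(np.append(frac, 1.0), np.append(y, y[0]),
                              bc_type="periodic")
            acc.append(spl(dense_frac))
        out_t.append(t0 + dense_frac * T)
    return (np.concatenate(out_t),
            {"left": np.concatenate(out_l), "right": np.concatenate(out_r)})
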
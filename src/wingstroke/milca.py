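"""Mutual-information-based least-dependent component analysis.

The decomposition Z = W X seeks the linear combinations of the phase-point
signals that are as close as possible to mutual statistical independence.
Dependence is measured with the binless Kraskov k-nearest-neighbour mutual
information estimator (default: k = 12, "rectangular" marginal neighbourhood
counts).  After prewhitening, the residual freedom is the orthogonal group;
we minimize the sum of pairwise MIs by Jacobi-style sweeps over all signal
pairs, fitting the pi/2-periodic MI-versus-rotation-angle curve of each pair
with its first two Fourier harmonics and rotating to the fitted minimum.

The 16-dimensional joint MI itself is not estimated (unreliable at a few
thousand samples); under orthogonal remixing of whitened data, the sum of
pairwise MIs is the operative contrast, and decreasing it can only decrease
the joint dependence that pairwise structure can express.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .phase_signals import PhaseSignalMatrix

__all__ = [
    "MilcaConfig",
    "Decomposition",
    "RotationResult",
    "kraskov_mi",
    "whiten",
    "optimal_rotation",
    "milca_decompose",
    "scale_separating_vectors",
    "amari_index",
]


@dataclass(frozen=True)
class MilcaConfig:
    """Settings for the decomposition.

    ``k_neighbors`` and ``neighborhood`` parameterize the Kraskov MI
    estimator; ``angle_grid_size`` angles over [0, pi/2) are evaluated per
    signal pair, of which ``screen_angles`` are probed first to skip pairs
    whose MI-vs-angle contrast is flat at the level expected from estimator
    noise alone (``contrast_floor_scale`` times the null spread).  Sweeps
    stop when the summed fitted MI decrease falls below ``sweep_tolerance``
    (nats) or after ``max_sweeps``.
    """

    k_neighbors: int = 12
    neighborhood: str = "rectangular"  # or "cubic"
    angle_grid_size: int = 32
    fourier_terms: int = 2
    sweep_tolerance: float = 1e-3
    max_sweeps: int = 50
    seed: int = 0
    contrast_floor_scale: float = 4.0
    screen_angles: int = 8
    search_subsample: int | None = 1250
    min_drop_scale: float = 1.0

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.neighborhood not in ("rectangular", "cubic"):
            raise ValueError("neighborhood must be 'rectangular' or 'cubic'")
        if self.angle_grid_size < 4 * self.fourier_terms + 1:
            raise ValueError("angle grid too coarse for the Fourier fit")


@dataclass
class RotationResult:
    theta: float
    mi_drop: float
    low_contrast: bool
    mi_zero: float


@dataclass
class Decomposition:
    """Separating matrix W, components Z = W X, and mixing matrix W^-1.

    Rows of ``W`` are separating vectors; components are ordered by
    descending activation-event prominence and signed so that each
    component's largest-magnitude excursion from its mean is positive.
    """

    W: np.ndarray
    W_inv: np.ndarray
    Z: np.ndarray
    Z_mean: np.ndarray
    whitening_matrix: np.ndarray
    whitening_mean: np.ndarray
    input_std: np.ndarray
    converged: bool
    n_sweeps: int
    sweep_drops: list[float]
    prominence: np.ndarray
    config: MilcaConfig = field(default_factory=MilcaConfig)

    @property
    def n_components(self) -> int:
        return self.W.shape[0]


@lru_cache(maxsize=8)
def _psi_table(n: int) -> np.ndarray:
    return digamma(np.arange(1, n + 1, dtype=float))


def _null_sd(n: int) -> float:
    # empirical spread of the k~12 estimator on independent pairs; only used
    # to scale the low-contrast screening floor, not any reported statistic
    return 0.56 / np.sqrt(n)


def _mi_core(x: np.ndarray, y: np.ndarray, k: int, rectangular: bool) -> float:
    """Kraskov kNN MI in nats; inputs assumed tie-free and roughly unit scale."""
    n = x.size
    pts = np.column_stack((x, y))
    tree = cKDTree(pts)
    dist, idx = tree.query(pts, k=k + 1, p=np.inf)
    psi = _psi_table(n)
    xs = np.sort(x)
    ys = np.sort(y)
    if rectangular:
        nb = idx[:, 1:]
        ex = np.abs(x[nb] - x[:, None]).max(axis=1) * (1.0 + 1e-12)
        ey = np.abs(y[nb] - y[:, None]).max(axis=1) * (1.0 + 1e-12)
        nx = (np.searchsorted(xs, x + ex, side="right")
              - np.searchsorted(xs, x - ex, side="left") - 1)
        ny = (np.searchsorted(ys, y + ey, side="right")
              - np.searchsorted(ys, y - ey, side="left") - 1)
        return float(digamma(k) - 1.0 / k + psi[n - 1]
                     - np.mean(psi[nx - 1] + psi[ny - 1]))
    eps = dist[:, -1]
    # counts include the point itself, so psi[nx - 1] == digamma(n_strict + 1)
    nx = (np.searchsorted(xs, x + eps, side="left")
          - np.searchsorted(xs, x - eps, side="right"))
    ny = (np.searchsorted(ys, y + eps, side="left")
          - np.searchsorted(ys, y - eps, side="right"))
    return float(digamma(k) + psi[n - 1] - np.mean(psi[nx - 1] + psi[ny - 1]))


def kraskov_mi(x: np.ndarray, y: np.ndarray, k: int = 12,
               neighborhood: str = "rectangular",
               rng: np.random.Generator | None = None) -> float:
    """Kraskov k-nearest-neighbour mutual information estimate, in nats.

    The default "rectangular" variant counts marginal neighbours inside the
    per-point kNN hyper-rectangle; "cubic" uses the max-norm ball.  Small
    negative values are an expected property of the estimator on independent
    data.  Exact ties are broken by a seeded rank-preserving jitter of
    relative scale 1e-9; a warning is issued if more than 10% of samples are
    tied.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("series length mismatch")
    if x.size < 50:
        raise ValueError("need at least 50 samples for a stable MI estimate")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant series has undefined mutual information")
    x = (x - x.mean()) / sx
    y = (y - y.mean()) / sy
    n = x.size
    n_tied = 2 * n - np.unique(x).size - np.unique(y).size
    if n_tied > 0:
        if n_tied > 0.1 * n:
            warnings.warn(
                f"{n_tied}/{n} tied samples; applying seeded rank jitter",
                stacklevel=2)
        if rng is None:
            rng = np.random.default_rng(0)
        x = x + 1e-9 * rng.standard_normal(n)
        y = y + 1e-9 * rng.standard_normal(n)
    return _mi_core(x, y, k, neighborhood == "rectangular")


def whiten(X: np.ndarray | PhaseSignalMatrix):
    """Zero-mean, identity-covariance transform of the signal matrix.

    Returns ``(Y, Wwh, mu)`` with ``Y = Wwh @ (X - mu)``.
    """
    if isinstance(X, PhaseSignalMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] <= X.shape[0]:
        raise ValueError("X must be (signals x cycles) with more cycles than signals")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    mu = X.mean(axis=1)
    Xc = X - mu[:, None]
    C = Xc @ Xc.T / X.shape[1]
    variances = np.diag(C)
    evals, U = np.linalg.eigh(C)
    if evals[0] < 1e-10 * evals[-1]:
        flat = np.flatnonzero(variances < 1e-10 * variances.max())
        what = (f"rows {flat.tolist()} are (near-)constant" if flat.size
                else "linearly dependent rows")
        raise ValueError(f"rank-deficient signal covariance: {what}")
    Wwh = (U / np.sqrt(evals)).T[::-1]  # descending-variance order
    Y = Wwh @ Xc
    return Y, Wwh, mu


def _search_view(x: np.ndarray, m: int | None) -> np.ndarray:
    if m is None or x.size <= m:
        return x
    idx = np.unique(np.linspace(0, x.size - 1, m).astype(int))
    return x[idx]


def optimal_rotation(x: np.ndarray, y: np.ndarray,
                     config: MilcaConfig = MilcaConfig()) -> RotationResult:
    """Rotation angle minimizing the pair's MI, via a Fourier-smoothed grid.

    MI of the rotated pair is pi/2-periodic for whitened signals, so the
    curve is fitted with a0 + sum_m [am cos(4 m theta) + bm sin(4 m theta)]
    (m = 1..fourier_terms) over ``angle_grid_size`` angles in [0, pi/2);
    the fitted minimum is then evaluated directly.  Pairs whose sampled MI
    range does not exceed the estimator's noise floor are flagged
    ``low_contrast`` and left unrotated.
    """
    config.validate()
    k = config.k_neighbors
    rect = config.neighborhood == "rectangular"
    xs = _search_view(np.asarray(x, dtype=float), config.search_subsample)
    ys = _search_view(np.asarray(y, dtype=float), config.search_subsample)
    n = xs.size
    G = config.angle_grid_size
    thetas = np.arange(G) * (np.pi / 2) / G

    def mi_at(t: float) -> float:
        c, s = np.cos(t), np.sin(t)
        return _mi_core(c * xs + s * ys, -s * xs + c * ys, k, rect)

    vals = np.full(G, np.nan)
    screen_idx = np.unique(np.linspace(0, G - 1, min(config.screen_angles, G)).astype(int))
    for i in screen_idx:
        vals[i] = mi_at(thetas[i])
    sampled = vals[screen_idx]
    floor = config.contrast_floor_scale * _null_sd(n)
    mi0 = float(vals[0])
    if sampled.max() - sampled.min() < floor:
        return RotationResult(theta=0.0, mi_drop=0.0, low_contrast=True, mi_zero=mi0)
    for i in range(G):
        if np.isnan(vals[i]):
            vals[i] = mi_at(thetas[i])

    m = np.arange(1, config.fourier_terms + 1)
    design = np.column_stack(
        [np.ones(G)]
        + [np.cos(4 * mm * thetas) for mm in m]
        + [np.sin(4 * mm * thetas) for mm in m])
    coef, *_ = np.linalg.lstsq(design, vals, rcond=None)
    fine = np.linspace(0, np.pi / 2, 721, endpoint=False)
    fine_design = np.column_stack(
        [np.ones(fine.size)]
        + [np.cos(4 * mm * fine) for mm in m]
        + [np.sin(4 * mm * fine) for mm in m])
    fitted = fine_design @ coef
    theta_hat = float(fine[np.argmin(fitted)])
    # the fitted curve averages the grid's estimator noise, so the fitted
    # drop (not the noisier pointwise difference) drives the decision and
    # the sweep-convergence accounting
    drop = float(fitted[0] - fitted.min())
    if drop < config.min_drop_scale * _null_sd(n) or theta_hat == 0.0:
        return RotationResult(theta=0.0, mi_drop=0.0, low_contrast=False, mi_zero=mi0)
    return RotationResult(theta=theta_hat, mi_drop=drop,
                          low_contrast=False, mi_zero=mi0)


def _prominence_scores(Zc: np.ndarray, window: int = 9) -> np.ndarray:
    """Max |z-score| of the moving-average-smoothed activation course."""
    kernel = np.ones(window) / window
    scores = np.empty(Zc.shape[0])
    for i, row in enumerate(Zc):
        sd = row.std()
        if sd == 0:
            scores[i] = 0.0
            continue
        smooth = np.convolve(row, kernel, mode="same")
        scores[i] = np.abs(smooth).max() / sd
    return scores


def milca_decompose(X: np.ndarray | PhaseSignalMatrix,
                    config: MilcaConfig = MilcaConfig()) -> Decomposition:
    """Whiten, then minimize summed pairwise MI by Jacobi rotation sweeps.

    Returns a :class:`Decomposition` with ``Z = W @ X`` exactly.  If the
    sweep budget is exhausted before the summed MI decrease falls below
    tolerance, the best separating matrix found is returned with
    ``converged=False``.
    """
    config.validate()
    if isinstance(X, PhaseSignalMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    d, n = X.shape
    Y, Wwh, mu = whiten(X)
    R = np.eye(d)
    drops: list[float] = []
    converged = False
    changed = np.ones(d, dtype=bool)
    flat = np.zeros((d, d), dtype=bool)  # cached low-contrast pairs
    for _ in range(config.max_sweeps):
        total = 0.0
        now_changed = np.zeros(d, dtype=bool)
        for i in range(d - 1):
            for j in range(i + 1, d):
                if flat[i, j] and not (changed[i] or changed[j]):
                    continue
                res = optimal_rotation(Y[i], Y[j], config)
                flat[i, j] = res.low_contrast
                if res.low_contrast or res.theta == 0.0:
                    continue
                c, s = np.cos(res.theta), np.sin(res.theta)
                yi = c * Y[i] + s * Y[j]
                yj = -s * Y[i] + c * Y[j]
                Y[i], Y[j] = yi, yj
                ri = c * R[i] + s * R[j]
                rj = -s * R[i] + c * R[j]
                R[i], R[j] = ri, rj
                now_changed[i] = now_changed[j] = True
                total += res.mi_drop
        changed = now_changed
        drops.append(total)
        if total < config.sweep_tolerance:
            converged = True
            break

    W = R @ Wwh
    Z = W @ X
    Zc = Z - Z.mean(axis=1, keepdims=True)
    scores = _prominence_scores(Zc)
    order = np.argsort(-scores, kind="stable")
    W, Z, Zc, scores = W[order], Z[order], Zc[order], scores[order]
    peak = Zc[np.arange(d), np.argmax(np.abs(Zc), axis=1)]
    flip = peak < 0
    W[flip] *= -1.0
    Z[flip] *= -1.0
    W_inv = np.linalg.inv(W)
    return Decomposition(
        W=W,
        W_inv=W_inv,
        Z=Z,
        Z_mean=Z.mean(axis=1),
        whitening_matrix=Wwh,
        whitening_mean=mu,
        input_std=X.std(axis=1),
        converged=converged,
        n_sweeps=len(drops),
        sweep_drops=drops,
        prominence=scores,
        config=config,
    )


def scale_separating_vectors(decomposition: Decomposition,
                             X: np.ndarray | PhaseSignalMatrix) -> np.ndarray:
    """Separating vectors rescaled to act on unit-variance signals.

    Each coefficient w_ij is multiplied by the standard deviation of signal
    j and the rows are renormalized to unit Euclidean norm, so the entries
    show the relative contribution of each phase point's variability.
    """
    if isinstance(X, PhaseSignalMatrix):
        X = X.X
    sd = np.asarray(X, dtype=float).std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance signal cannot be rescaled")
    S = decomposition.W * sd[None, :]
    norms = np.linalg.norm(S, axis=1, keepdims=True)
    return S / norms


def amari_index(P: np.ndarray) -> float:
    """Amari separation index of a (separating x mixing) matrix product.

    0 for a perfect signed, scaled permutation; larger values indicate
    residual mixing.  Normalized to [0, 1].
    """
    P = np.abs(np.asarray(P, dtype=float))
    d = P.shape[0]
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * d * (d - 1)))
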
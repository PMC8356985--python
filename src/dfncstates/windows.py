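"""Tapered sliding-window, sparsity-regularized functional connectivity.

Per subject, a rectangular window of ``window_len_tr`` TRs convolved with a
Gaussian of SD ``gauss_sigma_tr`` slides in steps of ``step_tr``; each window
yields a weighted covariance, a graphical-lasso sparse precision estimate, the
implied regularized correlation matrix, and its Fisher-z upper triangle.

The graphical lasso maximizes

    log det(Theta) - trace(C Theta) - lambda * sum_{j != k} |Theta_jk|

by block coordinate descent over columns (each column subproblem an L1
regression solved by coordinate descent).  The solver is numba-compiled and
warm-started from the previous window of the same subject: consecutive
windows overlap in all but one sample, so one or two sweeps usually suffice,
making whole-cohort estimation cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit


# ---------------------------------------------------------------------------
# taper and window geometry


@dataclass(frozen=True)
class TaperSpec:
    window_len_tr: int = 22
    gauss_sigma_tr: float = 3.0
    step_tr: int = 1

    def __post_init__(self):
        if self.window_len_tr < 3:
            raise ValueError("window length must be >= 3 TRs")
        if self.gauss_sigma_tr <= 0:
            raise ValueError("Gaussian sigma must be positive")
        if self.step_tr < 1:
            raise ValueError("step must be >= 1 TR")

    @property
    def pad(self) -> int:
        """Half-width of the Gaussian skirt (3 sigma, rounded up)."""
        return int(math.ceil(3.0 * self.gauss_sigma_tr))


def make_taper(spec: TaperSpec) -> np.ndarray:
    """Rectangle of width w convolved with a Gaussian of SD sigma.

    Support is ``w + 2*ceil(3*sigma)`` samples (the Gaussian truncated at
    3 sigma); weights are nonnegative, symmetric, and normalized to sum 1.
    """
    pad = spec.pad
    offsets = np.arange(-pad, pad + 1, dtype=float)
    kernel = np.exp(-0.5 * (offsets / spec.gauss_sigma_tr) ** 2)
    taper = np.convolve(np.ones(spec.window_len_tr), kernel)
    return taper / taper.sum()


def window_positions(T: int, spec: TaperSpec) -> np.ndarray:
    """0-based start indices of the half-open windows [start, start + w)."""
    w = spec.window_len_tr
    if T < w:
        raise ValueError(f"series length {T} shorter than window {w}")
    return np.arange(0, T - w + 1, spec.step_tr)


def windowed_covariance(X: np.ndarray, weights: np.ndarray, start: int) -> np.ndarray:
    """Weighted covariance over the support [start, start + len(weights)).

    Weights are renormalized to sum 1 over the support; centering uses the
    weighted mean, so uniform weights reduce to the population-normalized
    sample covariance of the window.
    """
    X = np.asarray(X, dtype=float)
    weights = np.asarray(weights, dtype=float)
    L = weights.size
    if start < 0 or start + L > X.shape[0]:
        raise ValueError("window support outside the series")
    a = weights / weights.sum()
    Xw = X[start:start + L]
    m = a @ Xw
    Xc = Xw - m
    C = (a[:, None] * Xc).T @ Xc
    if np.any(np.diag(C) <= 1e-12):
        raise ValueError("component with zero weighted variance in window")
    return C


# ---------------------------------------------------------------------------
# graphical lasso


@dataclass(frozen=True)
class SparsityConfig:
    lam: float = 0.1
    lambda_policy: str = "fixed"  # "fixed" | "grid-cv"
    grid: tuple[float, ...] = (0.01, 0.023403, 0.054772, 0.128184, 0.3)
    cv_folds: int = 3
    max_sweeps: int = 200
    tol: float = 1e-5

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.lambda_policy not in ("fixed", "grid-cv"):
            raise ValueError("lambda_policy must be 'fixed' or 'grid-cv'")
        if self.lambda_policy == "grid-cv" and not self.grid:
            raise ValueError("grid must be nonempty under grid-cv")


class GlassoConvergenceError(RuntimeError):
    """Raised when coordinate descent exhausts its sweep budget.

    Carries the last iterate (``precision``) and the sweep count.
    """

    def __init__(self, precision: np.ndarray, sweeps: int):
        super().__init__(f"graphical lasso did not converge in {sweeps} sweeps")
        self.precision = precision
        self.sweeps = sweeps


@njit(cache=True)
def _glasso_cd(S, lam, W, B, max_sweeps, tol, inner_max, inner_tol):  # pragma: no cover
    """Block coordinate descent; W and B are updated in place.

    W approximates the regularized covariance (inverse of the precision
    estimate), B holds the per-column lasso coefficients.  Returns the number
    of sweeps used, negated when the change criterion was not met.
    """
    p = S.shape[0]
    # off-diagonal-only penalty: stationarity fixes the diagonal at S_jj
    for j in range(p):
        W[j, j] = S[j, j]
    q = np.empty(p)
    for sweep in range(max_sweeps):
        max_d = 0.0
        for j in range(p):
            # lasso: min 0.5 b' V b - s12' b + lam |b|_1 over b = B[:, j],
            # with q[a] = sum_{b != j} W[a, b] * B[b, j] kept current
            for a in range(p):
                s = 0.0
                for b in range(p):
                    if b != j:
                        s += W[a, b] * B[b, j]
                q[a] = s
            for _ in range(inner_max):
                d_in = 0.0
                for a in range(p):
                    if a == j:
                        continue
                    r = S[a, j] - (q[a] - W[a, a] * B[a, j])
                    old = B[a, j]
                    if r > lam:
                        new = (r - lam) / W[a, a]
                    elif r < -lam:
                        new = (r + lam) / W[a, a]
                    else:
                        new = 0.0
                    if new != old:
                        delta = new - old
                        B[a, j] = new
                        for c in range(p):
                            q[c] += W[c, a] * delta
                        if abs(delta) > d_in:
                            d_in = abs(delta)
                if d_in < inner_tol:
                    break
            # w12 = V beta is exactly q (rows a != j)
            for a in range(p):
                if a == j:
                    continue
                d = abs(q[a] - W[a, j])
                if d > max_d:
                    max_d = d
                W[a, j] = q[a]
                W[j, a] = q[a]
        if max_d < tol:
            return sweep + 1
    return -max_sweeps


def _precision_from_wb(W: np.ndarray, B: np.ndarray) -> np.ndarray:
    p = W.shape[0]
    theta = np.zeros((p, p))
    for j in range(p):
        b = B[:, j].copy()
        b[j] = 0.0
        denom = W[j, j] - float(W[:, j] @ b)
        tjj = 1.0 / denom
        theta[:, j] = -b * tjj
        theta[j, j] = tjj
    return (theta + theta.T) / 2.0


def _cov2corr(C: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(C))
    R = C / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def glasso_objective(theta: np.ndarray, C: np.ndarray, lam: float) -> float:
    """The penalized log-likelihood being maximized (off-diagonal penalty)."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    pen = lam * (np.abs(theta).sum() - np.abs(np.diag(theta)).sum())
    return float(logdet - np.trace(C @ theta) - pen)


def _fit_window(
    C: np.ndarray,
    cfg: SparsityConfig,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """One graphical-lasso fit; returns (theta, R, sweeps), sweeps < 0 when
    the change criterion was not met within the sweep budget."""
    C = np.asarray(C, dtype=float)
    C = (C + C.T) / 2.0
    if cfg.lam == 0.0:
        theta = np.linalg.inv(C)
        return (theta + theta.T) / 2.0, _cov2corr(C), 0
    if warm is None:
        # damp off-diagonals so the initial working covariance is PD even
        # when the window estimate is nearly rank-deficient
        W = C * 0.95
        np.fill_diagonal(W, np.diag(C))
        B = np.zeros_like(C)
    else:
        W, B = warm
    sweeps = _glasso_cd(C, cfg.lam, W, B, cfg.max_sweeps, cfg.tol, 100, 1e-8)
    theta = _precision_from_wb(W, B)
    return theta, _cov2corr(W), sweeps


def sparse_precision(
    C: np.ndarray,
    cfg: SparsityConfig | float = 0.1,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
    strict: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Graphical-lasso precision and regularized correlation for one window.

    Returns ``(theta, R)`` where ``R`` is the correlation matrix of the
    regularized covariance ``theta^{-1}``.  ``lam = 0`` reduces to the plain
    inverse of ``C``.  ``warm`` carries (W, B) state between overlapping
    windows; with ``strict=False`` a non-converged iterate is returned instead
    of raising :class:`GlassoConvergenceError`.
    """
    if isinstance(cfg, (int, float)):
        cfg = SparsityConfig(lam=float(cfg))
    theta, R, sweeps = _fit_window(C, cfg, warm)
    if sweeps < 0 and strict:
        raise GlassoConvergenceError(theta, -sweeps)
    return theta, R


def select_lambda_cv(
    window_covs: np.ndarray,
    grid: Sequence[float],
    cv_folds: int = 3,
) -> float:
    """Pick lambda by contiguous-fold CV over a subject's window covariances.

    For each fold, a precision matrix is fit to the mean training covariance
    at each candidate lambda and scored by the held-out Gaussian
    log-likelihood ``log det(Theta) - trace(S_test Theta)``; the lambda with
    the highest mean held-out score wins.
    """
    window_covs = np.asarray(window_covs)
    W = window_covs.shape[0]
    if W < cv_folds:
        raise ValueError("fewer windows than folds")
    folds = np.array_split(np.arange(W), cv_folds)
    scores = np.zeros(len(grid))
    for f in folds:
        train = np.ones(W, dtype=bool)
        train[f] = False
        S_train = window_covs[train].mean(axis=0)
        S_test = window_covs[f].mean(axis=0)
        for i, lam in enumerate(grid):
            theta, _ = sparse_precision(S_train, SparsityConfig(lam=lam), strict=False)
            sign, logdet = np.linalg.slogdet(theta)
            scores[i] += logdet - float(np.trace(S_test @ theta))
    return float(grid[int(np.argmax(scores))])


# ---------------------------------------------------------------------------
# Fisher z and the cohort-level driver


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """atanh of a correlation, clipped to +-(1 - 1e-6) so |r| = 1 is finite."""
    return np.arctanh(np.clip(r, -1.0 + 1e-6, 1.0 - 1e-6))


def pair_index(partition) -> list[tuple[str, str]]:
    """Upper-triangle component pairs in partition (network-block) order."""
    ids = partition.component_ids
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def between_network_mask(partition) -> np.ndarray:
    """Boolean mask over pairs: True where the two components' networks differ."""
    lab = partition.labels
    n = len(lab)
    return np.asarray(
        [lab[i] != lab[j] for i in range(n) for j in range(i + 1, n)], dtype=bool
    )


@dataclass
class WindowedFNC:
    """Subjects x windows x pairs array of Fisher-z connectivity."""

    values: np.ndarray  # (S, W, P)
    subject_ids: list[str]
    pair_ids: list[tuple[str, str]]
    partition: object
    taper: TaperSpec
    lam: np.ndarray  # per-subject lambda actually used
    meta: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[2]


def compute_dfnc(
    cohort,
    taper: TaperSpec | None = None,
    cfg: SparsityConfig | None = None,
    discard_initial: int = 0,
    standardize: bool = True,
    strict: bool = False,
) -> WindowedFNC:
    """Windowed sparse connectivity for every subject of a cohort.

    Per window: tapered covariance -> graphical-lasso precision ->
    regularized correlation -> Fisher-z upper triangle.  The taper's Gaussian
    skirt extends ``3*sigma`` samples beyond the rectangular window on each
    side; at the series edges the skirt is clipped and the weights
    renormalized.  Components are standardized per subject (over the full
    scan) so the penalty scale is comparable across subjects.

    ``discard_initial`` drops leading volumes before windowing (some
    acquisition protocols discard unsaturated initial volumes, which also
    changes the window count).
    """
    taper = taper or TaperSpec()
    cfg = cfg or SparsityConfig()
    S = cohort.n_subjects
    iu = np.triu_indices(cohort.n_components, k=1)
    weights_full = make_taper(taper)
    pad = taper.pad

    values = None
    lams = np.empty(S)
    n_nonconverged = 0
    for s in range(S):
        X = np.asarray(cohort.data[s], dtype=float)[discard_initial:]
        if standardize:
            X = (X - X.mean(axis=0)) / X.std(axis=0)
        T = X.shape[0]
        starts = window_positions(T, taper)
        if values is None:
            values = np.empty((S, starts.size, iu[0].size))
        covs = []
        for p0 in starts:
            lo = max(p0 - pad, 0)
            hi = min(p0 + taper.window_len_tr + pad, T)
            w = weights_full[lo - (p0 - pad): weights_full.size - (p0 + taper.window_len_tr + pad - hi)]
            covs.append(windowed_covariance(X, w, lo))
        covs = np.asarray(covs)
        if cfg.lambda_policy == "grid-cv":
            lam = select_lambda_cv(covs, cfg.grid, cfg.cv_folds)
        else:
            lam = cfg.lam
        lams[s] = lam
        sub_cfg = SparsityConfig(lam=lam, max_sweeps=cfg.max_sweeps, tol=cfg.tol)
        warm = None
        for wi in range(starts.size):
            if lam > 0 and warm is None:
                W0 = covs[wi] * 0.95
                np.fill_diagonal(W0, np.diag(covs[wi]))
                warm = (W0, np.zeros_like(covs[wi]))
            theta, R, sweeps = _fit_window(covs[wi], sub_cfg, warm)
            if sweeps < 0:
                n_nonconverged += 1
                if strict:
                    raise GlassoConvergenceError(theta, -sweeps)
            values[s, wi] = fisher_z(R[iu])

    return WindowedFNC(
        values=values,
        subject_ids=list(cohort.subject_ids),
        pair_ids=pair_index(cohort.partition),
        partition=cohort.partition,
        taper=taper,
        lam=lams,
        meta={
            "discard_initial": discard_initial,
            "standardize": standardize,
            "n_nonconverged": n_nonconverged,
        },
    )
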
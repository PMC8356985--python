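"""Recurring connectivity states via L1 (city-block) k-means.

Clustering follows the two-phase convention of sliding-window connectivity
analysis: first, high-variance *exemplar* windows are pooled across subjects
and clustered with multiple random restarts; then a single k-means pass over
every window of every subject is initialized at the exemplar centroids.
City-block distance with element-wise median centroids is used throughout.

The number of states is chosen by an elbow criterion on the cluster validity
index (mean within-cluster distance over mean between-centroid distance).
State labels are reported 1-based, with state 1 fixed to the centroid having
the larger mean between-network connectivity (the *integrated* state) so
state identity is reproducible across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .windows import WindowedFNC, between_network_mask


@dataclass
class StateModel:
    k: int
    centroids: np.ndarray  # (K, P)
    labels: np.ndarray  # (S, W), values in 1..K
    validity_curve: dict[int, float] | None
    objective: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)


def select_exemplars(fnc_subject: np.ndarray) -> np.ndarray:
    """Window indices at local maxima of the across-pair variance series.

    Boundary windows are compared against their single neighbor.  When the
    variance series has no strict local maximum (e.g. constant), every
    ceil(W/10)-th window is taken instead.
    """
    fnc_subject = np.asarray(fnc_subject)
    W = fnc_subject.shape[0]
    if W < 3:
        raise ValueError("need at least 3 windows")
    v = fnc_subject.var(axis=1)
    picks = [i for i in range(W) if (i == 0 or v[i] > v[i - 1]) and (i == W - 1 or v[i] > v[i + 1])]
    if not picks:
        step = math.ceil(W / 10)
        picks = list(range(0, W, step))
    return np.asarray(picks, dtype=np.int64)


def _assign(data: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    D = cdist(data, centroids, metric="cityblock")
    labels = D.argmin(axis=1)
    return labels, D[np.arange(len(labels)), labels]


def kmeans_l1(
    data: np.ndarray,
    k: int,
    n_restarts: int = 10,
    max_iter: int = 100,
    seed: int | np.random.Generator | None = None,
    init: np.ndarray | None = None,
    return_history: bool = False,
):
    """Lloyd iterations under city-block distance with median centroids.

    The objective (sum of L1 distances to assigned centroids) is
    non-increasing across iterations; an empty cluster is re-seeded with the
    point farthest from its assigned centroid.  With ``init`` given, a single
    run starts from those centroids; otherwise the best of ``n_restarts``
    random initializations (distinct data rows) by final objective wins.

    Returns ``(labels, centroids, objective)``, plus the per-iteration
    objective history of the winning run when ``return_history``.
    """
    data = np.asarray(data, dtype=float)
    M = data.shape[0]
    if k > M:
        raise ValueError(f"k={k} exceeds number of points {M}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def one_run(centroids):
        centroids = centroids.copy()
        labels = np.full(M, -1)
        history = []
        for _ in range(max_iter):
            new_labels, dists = _assign(data, centroids)
            # re-seed empty clusters with the farthest point
            for c in range(k):
                if not np.any(new_labels == c):
                    far = int(np.argmax(dists))
                    centroids[c] = data[far]
                    new_labels, dists = _assign(data, centroids)
            history.append(float(dists.sum()))
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                members = labels == c
                if members.any():
                    centroids[c] = np.median(data[members], axis=0)
        labels, dists = _assign(data, centroids)
        history.append(float(dists.sum()))
        return labels, centroids, float(dists.sum()), history

    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.shape[0] != k:
            raise ValueError("init must provide k centroids")
        best = one_run(init)
    else:
        best = None
        for _ in range(n_restarts):
            idx = rng.choice(M, size=k, replace=False)
            run = one_run(data[idx])
            if best is None or run[2] < best[2]:
                best = run
    labels, centroids, objective, history = best
    if return_history:
        return labels + 1, centroids, objective, history
    return labels + 1, centroids, objective


def compute_validity_curve(
    data: np.ndarray,
    k_range=range(2, 11),
    n_restarts: int = 5,
    max_iter: int = 100,
    seed: int | None = None,
) -> dict[int, float]:
    """validity(k) = mean within-cluster L1 distance / mean between-centroid
    L1 distance, for each k in ``k_range``."""
    data = np.asarray(data, dtype=float)
    if np.allclose(data, data[0]):
        raise ValueError("degenerate data: all points identical")
    rng = np.random.default_rng(seed)
    curve: dict[int, float] = {}
    for k in k_range:
        labels, centroids, objective = kmeans_l1(
            data, k, n_restarts=n_restarts, max_iter=max_iter, seed=rng
        )
        within = objective / data.shape[0]
        pair_d = cdist(centroids, centroids, metric="cityblock")
        iu = np.triu_indices(k, 1)
        between = pair_d[iu].mean()
        curve[k] = within / between
    return curve


def elbow_from_curve(curve: dict[int, float]) -> int:
    """Elbow of the validity curve.

    Axes are normalized to [0, 1] and the signed perpendicular distance from
    each point to the chord joining the curve's endpoints is computed
    (below-chord positive).  The k with the largest positive distance is the
    elbow; when no interior point falls below the chord (the curve has no
    bend beyond its first point), the k minimizing the validity index is
    returned.
    """
    ks = np.asarray(sorted(curve))
    vs = np.asarray([curve[k] for k in ks], dtype=float)
    if len(ks) == 1:
        return int(ks[0])
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    span = vs.max() - vs.min()
    y = (vs - vs.min()) / (span if span > 0 else 1.0)
    # signed distance below the chord from (x0,y0) to (x1,y1)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = math.hypot(dx, dy)
    signed = (dy * (x - x[0]) - dx * (y - y[0])) / norm
    # a genuine bend must also improve on the smallest k; otherwise the
    # curve rises from its first point and that point is the elbow
    candidate = (signed > 1e-9) & (vs < vs[0])
    if candidate.any():
        signed = np.where(candidate, signed, -np.inf)
        return int(ks[int(np.argmax(signed))])
    return int(ks[int(np.argmin(vs))])


def elbow_select_k(
    data: np.ndarray,
    k_range=range(2, 11),
    seed: int | None = None,
    n_restarts: int = 5,
    max_iter: int = 100,
) -> int:
    """Select the number of clusters by the elbow of the validity index."""
    curve = compute_validity_curve(data, k_range, n_restarts, max_iter, seed)
    return elbow_from_curve(curve)


def pooled_exemplars(fnc: WindowedFNC, sort: bool = True) -> np.ndarray:
    """Stack each subject's exemplar windows; rows lexicographically sorted so
    the pooled set is invariant to subject ordering."""
    rows = [fnc.values[s][select_exemplars(fnc.values[s])] for s in range(len(fnc.subject_ids))]
    pooled = np.vstack(rows)
    if sort:
        order = np.lexsort(pooled.T[::-1])
        pooled = pooled[order]
    return pooled


def fit_states(
    fnc: WindowedFNC,
    k: int | None = 2,
    seed: int = 0,
    k_range=None,
    n_restarts: int = 10,
    max_iter: int = 150,
) -> StateModel:
    """Two-phase state identification over a cohort's windowed connectivity.

    Phase 1 clusters pooled exemplar windows (``n_restarts`` random
    initializations); phase 2 runs a single pass over all windows of all
    subjects initialized at the phase-1 centroids, capped at ``max_iter``
    iterations.  When ``k_range`` is given, k is first chosen by the elbow
    criterion on the exemplar set.  States are then relabeled so state 1 is
    the centroid with the larger mean between-network Fisher-z value.
    """
    if k is None and k_range is None:
        raise ValueError("either k or k_range is required")
    exemplars = pooled_exemplars(fnc)
    curve = None
    if k_range is not None:
        curve = compute_validity_curve(exemplars, k_range, n_restarts=5, seed=seed)
        k = elbow_from_curve(curve)
    if k < 2:
        raise ValueError("k must be >= 2")

    _, centroids0, _ = kmeans_l1(
        exemplars, k, n_restarts=n_restarts, max_iter=100, seed=seed
    )
    S, W, P = fnc.values.shape
    allw = fnc.values.reshape(S * W, P)
    labels_flat, centroids, objective = kmeans_l1(allw, k, init=centroids0, max_iter=max_iter)

    # fix state identity: descending mean between-network connectivity
    bmask = between_network_mask(fnc.partition)
    order = np.argsort(-centroids[:, bmask].mean(axis=1), kind="stable")
    centroids = centroids[order]
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    labels = remap[labels_flat - 1].reshape(S, W) + 1

    return StateModel(
        k=k,
        centroids=centroids,
        labels=labels,
        validity_curve=curve,
        objective=objective,
        seed=seed,
    )
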
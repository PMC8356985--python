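"""Temporal-dynamics indices of state label sequences.

Three per-subject indices summarize how a subject moves among connectivity
states over the scan: fractional windows (occupancy), mean dwell time, and
number of transitions.  Labels are 1-based integers in ``1..k``; dwell time is
reported in windows, with an optional seconds conversion (windows x TR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _validate_labels(labels: np.ndarray, k: int | None = None) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels must be a nonempty 1-D sequence")
    if k is not None and (labels.min() < 1 or labels.max() > k):
        raise ValueError(f"labels must lie in 1..{k}")
    return labels.astype(np.int64)


def run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal constant runs of a sequence: (state of each run, run length)."""
    labels = _validate_labels(labels)
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [labels.size]))
    return labels[starts], ends - starts


def fractional_windows(labels: np.ndarray, k: int) -> np.ndarray:
    """Proportion of windows spent in each state; sums to 1."""
    labels = _validate_labels(labels, k)
    counts = np.bincount(labels, minlength=k + 1)[1:]
    return counts / labels.size


def mean_dwell_time(labels: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean consecutive-run length per state, in windows.

    Returns ``(dt, visited)``; an unvisited state has ``dt = 0`` and
    ``visited = False`` so downstream statistics can exclude rather than
    zero-fill.
    """
    states, lengths = run_lengths(labels)
    _validate_labels(labels, k)
    dt = np.zeros(k)
    visited = np.zeros(k, dtype=bool)
    for s in range(1, k + 1):
        mask = states == s
        if mask.any():
            dt[s - 1] = lengths[mask].mean()
            visited[s - 1] = True
    return dt, visited


def num_transitions(labels: np.ndarray) -> int:
    """Number of adjacent positions whose labels differ."""
    labels = _validate_labels(labels)
    return int(np.count_nonzero(np.diff(labels) != 0))


def compute_temporal_metrics(
    labels: np.ndarray,
    k: int,
    subject_ids: list[str] | None = None,
    tr_seconds: float | None = None,
) -> pd.DataFrame:
    """Per-subject metrics table from an (S, W) label array.

    Columns: ``fw_state<j>``, ``dt_state<j>`` (windows; appended
    ``dt_state<j>_seconds`` when ``tr_seconds`` given), ``n_transitions``,
    ``visited_state<j>``.
    """
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[None, :]
    S = labels.shape[0]
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(S)]
    rows = []
    for i in range(S):
        fw = fractional_windows(labels[i], k)
        dt, visited = mean_dwell_time(labels[i], k)
        row: dict[str, object] = {"subject_id": subject_ids[i]}
        for j in range(k):
            row[f"fw_state{j + 1}"] = fw[j]
        for j in range(k):
            row[f"dt_state{j + 1}"] = dt[j]
        if tr_seconds is not None:
            for j in range(k):
                row[f"dt_state{j + 1}_seconds"] = dt[j] * tr_seconds
        row["n_transitions"] = num_transitions(labels[i])
        for j in range(k):
            row[f"visited_state{j + 1}"] = bool(visited[j])
        rows.append(row)
    return pd.DataFrame(rows)
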
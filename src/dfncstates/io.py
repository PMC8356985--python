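"""On-disk formats: TSV time courses, manifests, model artifacts, JSON sidecars.

A cohort directory holds ``manifest.tsv``, ``partition.tsv`` and
``timecourses/<subject_id>.tsv`` (T rows x N columns, header = component ids);
ground truth, when present, is ``ground_truth.json``.  Windowed connectivity
is one TSV per subject (rows = windows, columns = pairs, header ``A|B``) plus
a JSON sidecar; the state model is centroid/label TSVs plus JSON metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CohortTimecourses, GroundTruth, NetworkPartition
from .windows import TaperSpec, WindowedFNC
from .clustering import StateModel

MANIFEST_COLUMNS = [
    "subject_id", "group", "ybocs_total", "ocir",
    "bdi", "stai_state", "stai_trait", "education_years",
]


class CohortFormatError(ValueError):
    """A cohort directory violates the on-disk contract."""


def write_partition(partition: NetworkPartition, path: Path) -> None:
    pd.DataFrame(
        {"component_id": partition.component_ids,
         "network": [partition.network_of[c] for c in partition.component_ids]}
    ).to_csv(path, sep="\t", index=False)


def read_partition(path: Path) -> NetworkPartition:
    df = pd.read_csv(path, sep="\t")
    return NetworkPartition(
        tuple(df["component_id"]), dict(zip(df["component_id"], df["network"]))
    )


def write_cohort(cohort: CohortTimecourses, out_dir: Path, truth: GroundTruth | None = None) -> Path:
    out_dir = Path(out_dir)
    (out_dir / "timecourses").mkdir(parents=True, exist_ok=True)
    cohort.manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    write_partition(cohort.partition, out_dir / "partition.tsv")
    header = list(cohort.partition.component_ids)
    for i, sid in enumerate(cohort.subject_ids):
        pd.DataFrame(cohort.data[i], columns=header).to_csv(
            out_dir / "timecourses" / f"{sid}.tsv", sep="\t", index=False
        )
    (out_dir / "meta.json").write_text(json.dumps({"tr_seconds": cohort.tr_seconds}))
    if truth is not None:
        payload = {
            "state_cov": truth.state_cov.tolist(),
            "state_seq": truth.state_seq.tolist(),
            "true_fw": truth.true_fw.tolist(),
            "true_dt": truth.true_dt.tolist(),
            "true_transitions": truth.true_transitions.tolist(),
        }
        (out_dir / "ground_truth.json").write_text(json.dumps(payload))
    return out_dir


def read_cohort(in_dir: Path) -> CohortTimecourses:
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.tsv"
    if not manifest_path.exists():
        raise CohortFormatError(f"missing manifest: {manifest_path}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    partition = read_partition(in_dir / "partition.tsv")
    n = partition.n_components
    tr = 2.0
    meta_path = in_dir / "meta.json"
    if meta_path.exists():
        tr = float(json.loads(meta_path.read_text()).get("tr_seconds", 2.0))

    data, T = [], None
    for sid in manifest["subject_id"]:
        f = in_dir / "timecourses" / f"{sid}.tsv"
        if not f.exists():
            raise CohortFormatError(f"missing time-course file for subject {sid}: {f}")
        df = pd.read_csv(f, sep="\t", float_precision="round_trip")
        if df.shape[1] != n:
            raise CohortFormatError(
                f"{f}: expected {n} components, found {df.shape[1]}"
            )
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.all(np.isfinite(arr)):
            raise CohortFormatError(f"{f}: non-numeric or non-finite values")
        if T is None:
            T = arr.shape[0]
        elif arr.shape[0] != T:
            raise CohortFormatError(
                f"{f}: expected {T} time points, found {arr.shape[0]}"
            )
        data.append(arr)
    return CohortTimecourses(
        list(manifest["subject_id"]), np.stack(data), manifest, partition, tr
    )


def write_fnc(fnc: WindowedFNC, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = [f"{a}|{b}" for a, b in fnc.pair_ids]
    for i, sid in enumerate(fnc.subject_ids):
        pd.DataFrame(fnc.values[i], columns=cols).to_csv(
            out_dir / f"{sid}.tsv", sep="\t", index=False, float_format="%.6g"
        )
    sidecar = {
        "subject_ids": fnc.subject_ids,
        "pair_ids": cols,
        "taper": {
            "window_len_tr": fnc.taper.window_len_tr,
            "gauss_sigma_tr": fnc.taper.gauss_sigma_tr,
            "step_tr": fnc.taper.step_tr,
        },
        "lambda": list(map(float, fnc.lam)),
        "n_windows": int(fnc.n_windows),
        "meta": fnc.meta,
    }
    (out_dir / "fnc.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir


def read_fnc(in_dir: Path, partition: NetworkPartition) -> WindowedFNC:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "fnc.json").read_text())
    values = np.stack(
        [
            pd.read_csv(in_dir / f"{sid}.tsv", sep="\t").to_numpy()
            for sid in sidecar["subject_ids"]
        ]
    )
    pair_ids = [tuple(p.split("|")) for p in sidecar["pair_ids"]]
    t = sidecar["taper"]
    return WindowedFNC(
        values=values,
        subject_ids=sidecar["subject_ids"],
        pair_ids=pair_ids,
        partition=partition,
        taper=TaperSpec(t["window_len_tr"], t["gauss_sigma_tr"], t["step_tr"]),
        lam=np.asarray(sidecar["lambda"]),
        meta=sidecar.get("meta", {}),
    )


def write_state_model(model: StateModel, out_dir: Path, pair_ids=None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = [f"{a}|{b}" for a, b in pair_ids] if pair_ids else None
    pd.DataFrame(model.centroids, columns=cols).to_csv(
        out_dir / "centroids.tsv", sep="\t", index=False
    )
    pd.DataFrame(model.labels).to_csv(
        out_dir / "labels.tsv", sep="\t", index=False, header=False
    )
    meta = {
        "k": model.k,
        "objective": model.objective,
        "seed": model.seed,
        "validity_curve": (
            {str(k): v for k, v in model.validity_curve.items()}
            if model.validity_curve
            else None
        ),
    }
    (out_dir / "state_model.json").write_text(json.dumps(meta, indent=1))
    return out_dir


def read_state_model(in_dir: Path) -> StateModel:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "state_model.json").read_text())
    centroids = pd.read_csv(in_dir / "centroids.tsv", sep="\t").to_numpy()
    labels = pd.read_csv(in_dir / "labels.tsv", sep="\t", header=None).to_numpy()
    curve = meta["validity_curve"]
    return StateModel(
        k=int(meta["k"]),
        centroids=centroids,
        labels=labels.astype(np.int64),
        validity_curve={int(k): v for k, v in curve.items()} if curve else None,
        objective=meta["objective"],
        seed=meta["seed"],
    )
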
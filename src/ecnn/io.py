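"""Readers and writers for the on-disk formats.

Event matrices live in a directory of plain-text files: MatrixMarket
counts plus TSV sidecars for feature names and labels (and a JSON manifest
of planted features for synthetic cohorts).  Tiny fixtures can instead use
a single dense TSV.  Fold plans and configs round-trip through JSON/YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .cohort import EventLog, EventMatrix, FoldAssignment, FoldPlan
from .config import TrainConfig
from .network import NetworkParams
from .training import ScheduleConfig, SnapshotEnsemble

__all__ = [
    "read_event_log",
    "write_event_log",
    "read_matrix",
    "write_matrix",
    "read_dense_tsv",
    "write_dense_tsv",
    "read_fold_plan",
    "write_fold_plan",
    "read_config",
    "write_config",
    "save_params",
    "load_params",
    "save_ensemble",
    "load_ensemble",
]

_COUNTS = "counts.mtx"
_FEATURES = "features.tsv"
_LABELS = "labels.tsv"
_PLANTED = "planted.json"


def read_event_log(path: str | Path) -> EventLog:
    """Read a TSV with header patient_id / event_code / count."""
    frame = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "event_code": str})
    expected = ["patient_id", "event_code", "count"]
    if list(frame.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(frame.columns)}")
    return EventLog(records=[
        (row.patient_id, row.event_code, int(row.count))
        for row in frame.itertuples()
    ])


def write_event_log(log: EventLog, path: str | Path) -> None:
    pd.DataFrame(log.records, columns=["patient_id", "event_code", "count"]).to_csv(
        path, sep="\t", index=False
    )


def write_matrix(matrix: EventMatrix, directory: str | Path) -> Path:
    """Write counts.mtx + features.tsv (+ labels.tsv, planted.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / _COUNTS, sp.coo_matrix(matrix.values))
    pd.Series(matrix.feature_names, name="feature_name").to_csv(
        directory / _FEATURES, sep="\t", index=False
    )
    if matrix.labels is not None:
        pd.Series(matrix.labels, name="label").to_csv(
            directory / _LABELS, sep="\t", index=False
        )
    if matrix.planted_features is not None:
        (directory / _PLANTED).write_text(
            json.dumps({"planted_features": [int(i) for i in matrix.planted_features]})
        )
    return directory


def read_matrix(directory: str | Path) -> EventMatrix:
    """Inverse of :func:`write_matrix`; errors name the offending file."""
    directory = Path(directory)
    counts_path = directory / _COUNTS
    features_path = directory / _FEATURES
    if not counts_path.exists():
        raise FileNotFoundError(f"missing counts file: {counts_path}")
    if not features_path.exists():
        raise FileNotFoundError(f"missing feature-name sidecar: {features_path}")
    values = sp.csr_matrix(scipy.io.mmread(counts_path))
    names = pd.read_csv(features_path, sep="\t")["feature_name"].astype(str).tolist()
    if len(names) != values.shape[1]:
        raise ValueError(
            f"{features_path}: {len(names)} names for {values.shape[1]} columns"
        )
    labels = None
    labels_path = directory / _LABELS
    if labels_path.exists():
        labels = pd.read_csv(labels_path, sep="\t")["label"].to_numpy()
        if labels.shape[0] != values.shape[0]:
            raise ValueError(
                f"{labels_path}: {labels.shape[0]} labels for {values.shape[0]} rows"
            )
    planted = None
    planted_path = directory / _PLANTED
    if planted_path.exists():
        planted = np.array(
            json.loads(planted_path.read_text())["planted_features"], dtype=int
        )
    return EventMatrix(values=values, feature_names=names, labels=labels,
                       planted_features=planted)


def write_dense_tsv(matrix: EventMatrix, path: str | Path) -> None:
    """Single-file dense dialect for tiny fixtures: one column per feature,
    plus a leading ``label`` column when labels are present."""
    frame = pd.DataFrame(matrix.dense(), columns=matrix.feature_names)
    if matrix.labels is not None:
        frame.insert(0, "label", matrix.labels)
    frame.to_csv(path, sep="\t", index=False)


def read_dense_tsv(path: str | Path) -> EventMatrix:
    frame = pd.read_csv(path, sep="\t")
    labels = None
    if "label" in frame.columns:
        labels = frame.pop("label").to_numpy()
    return EventMatrix(
        values=sp.csr_matrix(frame.to_numpy(dtype=float)),
        feature_names=[str(c) for c in frame.columns],
        labels=labels,
    )


def write_fold_plan(plan: FoldPlan, path: str | Path) -> None:
    payload = {
        "k": plan.k,
        "repeats": plan.repeats,
        "seed": plan.seed,
        "assignments": [
            {
                "repeat": a.repeat,
                "fold": a.fold,
                "train": a.train.tolist(),
                "validation": a.validation.tolist(),
                "test": a.test.tolist(),
            }
            for a in plan.assignments
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_fold_plan(path: str | Path) -> FoldPlan:
    payload = json.loads(Path(path).read_text())
    return FoldPlan(
        k=payload["k"],
        repeats=payload["repeats"],
        seed=payload["seed"],
        assignments=[
            FoldAssignment(
                repeat=a["repeat"],
                fold=a["fold"],
                train=np.array(a["train"], dtype=int),
                validation=np.array(a["validation"], dtype=int),
                test=np.array(a["test"], dtype=int),
            )
            for a in payload["assignments"]
        ],
    )


def save_params(params: NetworkParams, path: str | Path) -> None:
    """JSON checkpoint of one parameter set (layer shapes self-describing)."""
    Path(path).write_text(json.dumps({
        "hidden_activation": params.hidden_activation,
        "layer_sizes": params.layer_sizes,
        "weights": [W.tolist() for W in params.weights],
        "biases": [b.tolist() for b in params.biases],
    }))


def load_params(path: str | Path) -> NetworkParams:
    data = json.loads(Path(path).read_text())
    params = NetworkParams(
        weights=[np.asarray(W, dtype=float) for W in data["weights"]],
        biases=[np.asarray(b, dtype=float) for b in data["biases"]],
        hidden_activation=data["hidden_activation"],
    )
    if params.layer_sizes != data["layer_sizes"]:
        raise ValueError(f"{path}: layer shapes do not match checkpoint header")
    return params


def save_ensemble(ensemble: SnapshotEnsemble, directory: str | Path,
                  config: TrainConfig | None = None) -> Path:
    """Checkpoint directory: one params file per snapshot, the training
    history as TSV, and a manifest with the schedule (and config if given)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, snap in enumerate(ensemble.snapshots):
        save_params(snap, directory / f"snapshot_{i}.json")
    ensemble.train_history.to_csv(directory / "history.tsv", sep="\t", index=False)
    manifest = {
        "n_snapshots": ensemble.n_members,
        "schedule": {"alpha0": ensemble.schedule.alpha0,
                     "T": ensemble.schedule.T, "M": ensemble.schedule.M},
    }
    if config is not None:
        manifest["config"] = config.to_dict(flag_provenance=True)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_ensemble(directory: str | Path) -> SnapshotEnsemble:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing ensemble manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    snapshots = [load_params(directory / f"snapshot_{i}.json")
                 for i in range(manifest["n_snapshots"])]
    history = pd.read_csv(directory / "history.tsv", sep="\t")
    sched = manifest["schedule"]
    return SnapshotEnsemble(
        snapshots=snapshots,
        schedule=ScheduleConfig(alpha0=sched["alpha0"], T=sched["T"], M=sched["M"]),
        train_history=history,
    )


def write_config(config: TrainConfig, path: str | Path) -> None:
    """YAML dump with per-field provenance flags (method_fixed)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(flag_provenance=True)))


def read_config(path: str | Path) -> TrainConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: malformed config")
    return TrainConfig.from_dict(data)
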
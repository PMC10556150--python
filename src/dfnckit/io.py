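"""Readers and writers for every pipeline artifact.

All artifacts are plain delimited text (TSV) plus JSON sidecars that
record parameters and seeds, so no result file exists without
provenance. Conventions: timepoint and window indices are 0-based;
state labels are 1-based ("State 1..k").
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ComponentTimecourses, NetworkPartition, WindowedFNCSeries, pair_names


def _component_names(n: int) -> list[str]:
    return [f"c{i + 1:02d}" for i in range(n)]


def write_timecourses(tc: ComponentTimecourses, path) -> None:
    df = pd.DataFrame(tc.data, columns=_component_names(tc.n_components))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "subject_id": tc.subject_id,
        "tr_seconds": tc.tr_seconds,
        "partition_sizes": list(tc.partition.sizes),
        "partition_names": list(tc.partition.names),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def _read_numeric_tsv(path, expect_columns: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if expect_columns is not None and list(df.columns) != expect_columns:
        raise ValueError(
            f"{path}: header mismatch (got {list(df.columns)[:5]}...)"
        )
    bad = df.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.loc[row][bad.loc[row]].index[0]
        raise ValueError(f"{path}: missing/non-numeric cell at row {row}, column {col!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            row = int(pd.to_numeric(df[col], errors="coerce").isna().idxmax())
            raise ValueError(f"{path}: non-numeric cell at row {row}, column {col!r}")
    return df


def read_timecourses(path) -> ComponentTimecourses:
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    partition = NetworkPartition(
        sizes=tuple(sidecar["partition_sizes"]),
        names=tuple(sidecar["partition_names"]),
    )
    df = _read_numeric_tsv(path, _component_names(partition.n_components))
    return ComponentTimecourses(
        data=df.to_numpy(dtype=float),
        tr_seconds=sidecar["tr_seconds"],
        subject_id=sidecar["subject_id"],
        partition=partition,
    )


def write_windowed_fnc(series: WindowedFNCSeries, path) -> None:
    n_comp = int((1 + np.sqrt(1 + 8 * series.n_pairs)) / 2)
    df = pd.DataFrame(series.data, columns=pair_names(n_comp))
    df.insert(0, "window_start", series.window_starts)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "subject_id": series.subject_id,
        "lambda": series.lambda_used,
        "partition_sizes": list(series.partition.sizes),
        "partition_names": list(series.partition.names),
        "pair_order": "upper-triangle row-major, components sorted DMN, CEN, SN",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_windowed_fnc(path) -> WindowedFNCSeries:
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    df = _read_numeric_tsv(path)
    return WindowedFNCSeries(
        subject_id=sidecar["subject_id"],
        data=df.drop(columns="window_start").to_numpy(dtype=float),
        window_starts=df["window_start"].to_numpy(dtype=int),
        lambda_used=sidecar["lambda"],
        partition=NetworkPartition(
            sizes=tuple(sidecar["partition_sizes"]),
            names=tuple(sidecar["partition_names"]),
        ),
    )


def write_labels(labels: dict[str, np.ndarray], path) -> None:
    """State label sequences, one row per subject (1-based labels)."""
    rows = [
        {"subject_id": sid, "labels": ",".join(map(str, seq))}
        for sid, seq in labels.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_labels(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        row.subject_id: np.array([int(x) for x in row.labels.split(",")])
        for row in df.itertuples()
    }


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: clinical table needs subject_id and group columns")
    return df


def write_centroids(centroids: np.ndarray, path) -> None:
    n_comp = int((1 + np.sqrt(1 + 8 * centroids.shape[1])) / 2)
    df = pd.DataFrame(centroids, columns=pair_names(n_comp))
    df.insert(0, "state", np.arange(1, centroids.shape[0] + 1))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_centroids(path) -> np.ndarray:
    df = _read_numeric_tsv(path)
    return df.drop(columns="state").to_numpy(dtype=float)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
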
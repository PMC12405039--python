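"""Readers and writers for the package's delimited-text interchange formats.

Conventions: comma-separated UTF-8, "." decimal, no thousands
separators; time series may also be tab-separated (sniffed from the
extension).  Missing values are empty cells or "NaN".  Connectivity
matrices carry ROI labels as both the header row and the first column;
embeddings are a CSV of coordinates plus a small JSON sidecar recording
how they were fitted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .brain_space import DistanceMatrix, Embedding
from .k_operator import KOperator, ReducedPath
from .state_builder import BrainState, ConnectivityMatrix, ROITimeSeries
from .subspaces import SubspaceModel, TrajectoryVerdict

__all__ = [
    "read_timeseries",
    "read_connectivity",
    "write_connectivity",
    "read_manifest",
    "load_cohort",
    "write_manifest",
    "write_embedding",
    "read_embedding",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_k_operator",
    "read_k_operator",
    "write_reduced_path",
    "write_subspace",
    "write_verdicts",
]

_MANIFEST_FIELDS = [
    "state_id",
    "subject_id",
    "timepoint",
    "diagnosis",
    "age",
    "sex",
    "path",
    "input_kind",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_timeseries(path: str | Path, state_id: str | None = None) -> ROITimeSeries:
    """Read a T x N ROI time series; header row = ROI labels."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), na_values=["NaN", "nan", ""])
    return ROITimeSeries(
        state_id=state_id or path.stem,
        roi_labels=tuple(str(c) for c in df.columns),
        samples=df.to_numpy(dtype=float),
    )


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    """Read a labelled square connectivity matrix (labels in row 0 / col 0)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, na_values=["NaN", "nan", ""])
    labels = tuple(str(c).strip() for c in df.columns)
    row_labels = tuple(str(i).strip() for i in df.index)
    if labels != row_labels:
        raise ValueError(
            f"{path}: row labels do not match column labels "
            f"(first mismatch: {next((a, b) for a, b in zip(row_labels, labels) if a != b)})"
        )
    return ConnectivityMatrix(labels, df.to_numpy(dtype=float))


def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.values, index=cm.roi_labels, columns=cm.roi_labels)
    df.to_csv(path)


def read_manifest(path: str | Path) -> list[dict]:
    """Cohort manifest, CSV or YAML, one record per state."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            records = yaml.safe_load(fh)
        if isinstance(records, dict):
            records = records.get("states", records.get("cohort", []))
    else:
        records = pd.read_csv(path, dtype=str).to_dict("records")
    out = []
    for rec in records:
        missing = [f for f in ("state_id", "subject_id", "timepoint", "diagnosis", "path") if f not in rec or rec[f] in (None, "")]
        if missing:
            raise ValueError(f"manifest record missing fields {missing}: {rec}")
        rec.setdefault("input_kind", "matrix")
        out.append(dict(rec))
    return out


def write_manifest(records: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(list(records), columns=_MANIFEST_FIELDS).to_csv(path, index=False)


def load_cohort(
    manifest_path: str | Path, transform: str = "raw_pearson"
) -> list[BrainState]:
    """Materialize every state listed in a manifest.

    ``input_kind`` selects per record whether ``path`` holds a raw time
    series (connectivity computed here) or a precomputed matrix (same
    validators, no recomputation).
    """
    from .state_builder import compute_connectivity

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    states = []
    for rec in read_manifest(manifest_path):
        p = Path(rec["path"])
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing file: {p}")
        kind = rec.get("input_kind", "matrix")
        if kind == "timeseries":
            matrix = compute_connectivity(
                read_timeseries(p, state_id=rec["state_id"]), transform=transform
            )
        elif kind == "matrix":
            matrix = read_connectivity(p)
        else:
            raise ValueError(f"unknown input_kind {kind!r} for state {rec['state_id']}")
        age = rec.get("age")
        states.append(
            BrainState(
                state_id=str(rec["state_id"]),
                subject_id=str(rec["subject_id"]),
                timepoint=str(rec["timepoint"]),
                diagnosis=str(rec["diagnosis"]),
                age=float(age) if age not in (None, "", "NA") else None,
                sex=str(rec["sex"]) if rec.get("sex") not in (None, "") else None,
                matrix=matrix,
            )
        )
    return states


def write_embedding(emb: Embedding, csv_path: str | Path) -> None:
    """Coordinates CSV + JSON sidecar {method, seed, stress, dims, warnings}."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        emb.coords, columns=[f"dim_{i + 1}" for i in range(emb.dims)]
    )
    df.insert(0, "state_id", list(emb.state_ids))
    df.to_csv(csv_path, index=False)
    sidecar = {
        "method": emb.method,
        "seed": emb.seed,
        "stress": emb.stress,
        "dims": emb.dims,
        "metric": "frobenius",
        "warnings": list(emb.warnings),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_embedding(csv_path: str | Path) -> Embedding:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    dims = sum(1 for c in df.columns if c.startswith("dim_"))
    sidecar_path = csv_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return Embedding(
        state_ids=tuple(df["state_id"].astype(str)),
        coords=df[[f"dim_{i + 1}" for i in range(dims)]].to_numpy(),
        dims=dims,
        stress=float(meta.get("stress", np.nan)),
        method=str(meta.get("method", "unknown")),
        seed=meta.get("seed"),
        warnings=tuple(meta.get("warnings", ())),
    )


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(d.values, index=d.state_ids, columns=d.state_ids).to_csv(path)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def write_k_operator(k: KOperator, path: str | Path) -> None:
    df = pd.DataFrame(k.values, index=k.roi_labels, columns=k.roi_labels)
    df.to_csv(path)


def read_k_operator(
    path: str | Path, source_id: str, target_id: str, mode: str = "additive"
) -> KOperator:
    df = pd.read_csv(path, index_col=0)
    return KOperator(
        source_state_id=source_id,
        target_state_id=target_id,
        mode=mode,
        values=df.to_numpy(dtype=float),
        roi_labels=tuple(str(c) for c in df.columns),
    )


def write_reduced_path(path_obj: ReducedPath, path: str | Path) -> None:
    Path(path).write_text(json.dumps(path_obj.as_dict(), indent=2))


def write_subspace(s: SubspaceModel, path: str | Path) -> None:
    payload = {
        "label": s.label,
        "member_state_ids": list(s.member_state_ids),
        "vertices": s.hull_vertices.tolist(),
        "dims": s.dims,
        "degenerate": s.degenerate,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_verdicts(verdicts: Sequence[TrajectoryVerdict], path: str | Path) -> None:
    rows = []
    for v in verdicts:
        rows.append(
            {
                "subject_id": v.subject_id,
                "verdict": v.verdict,
                "trajectory": ";".join(
                    f"{t}:{r}" for t, r in zip(v.timepoints, v.regions)
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
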
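"""Readers and writers for the pipeline's delimited-text formats.

Conventions: ROI indices are 1-based in every external file; time-series
files are T rows x N columns with a header of 1-based ROI indices;
adjacency files are N x N with NaN on the diagonal; labels and ROI metadata
are TSV. Outputs are deterministic: edge lists sorted by (i, j), JSON keys
sorted, floats at six significant figures. BrainNet Viewer ``.node`` /
``.edge`` exports follow the whitespace-delimited convention.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import (
    ECP,
    LCP,
    UNKNOWN,
    FunctionalNetwork,
    NetworkCohort,
    RoiMetadata,
    RoiTimeSeriesSet,
    SubjectSeries,
)
from .nbs import DysconnectedNetwork

_FLOAT_FMT = "%.6g"
VALID_LABELS = {ECP, LCP, UNKNOWN}


# ---------------------------------------------------------------- labels

def write_labels(path: str | Path, subject_ids: Iterable[str], labels: Iterable[str]) -> None:
    pd.DataFrame({"subject_id": list(subject_ids), "label": list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"subject_id", "label"} <= set(df.columns):
        raise ValueError(f"labels file {path} must have subject_id and label columns")
    bad = sorted(set(df["label"]) - VALID_LABELS)
    if bad:
        raise ValueError(f"labels file {path}: unknown label token(s) {bad}")
    ids = df["subject_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"labels file {path}: duplicate subject id(s) {dupes}")
    return dict(zip(ids, df["label"]))


# ----------------------------------------------------------- time series

def write_time_series(directory: str | Path, cohort: RoiTimeSeriesSet) -> None:
    """One file per subject (<id>.tsv, T x N, 1-based ROI header) plus labels.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in cohort:
        cols = [str(k + 1) for k in range(s.n_rois)]
        pd.DataFrame(s.series, columns=cols).to_csv(
            directory / f"{s.subject_id}.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )
    write_labels(directory / "labels.tsv", cohort.subject_ids, cohort.labels)


def read_time_series(
    directory: str | Path, labels_path: str | Path | None = None
) -> RoiTimeSeriesSet:
    """Read a directory of per-subject T x N files with a labels table."""
    directory = Path(directory)
    labels_path = Path(labels_path) if labels_path else directory / "labels.tsv"
    labels = read_labels(labels_path)
    files = sorted(p for p in directory.glob("*.tsv") if p.name != "labels.tsv")
    subjects = []
    n_expected: int | None = None
    found_ids = set()
    for f in files:
        sid = f.stem
        if sid not in labels:
            raise ValueError(f"labels file does not cover subject {sid} ({f})")
        found_ids.add(sid)
        df = pd.read_csv(f, sep="\t")
        series = df.to_numpy(dtype=float)
        if n_expected is None:
            n_expected = series.shape[1]
        elif series.shape[1] != n_expected:
            raise ValueError(
                f"dimension mismatch: {f} has {series.shape[1]} ROI columns, "
                f"expected {n_expected}"
            )
        if series.shape[0] < series.shape[1]:
            import warnings

            warnings.warn(
                f"{f}: fewer timepoints than ROIs — check the file is not "
                "transposed (expected rows = timepoints)",
                stacklevel=2,
            )
        subjects.append(SubjectSeries(subject_id=sid, label=labels[sid], series=series))
    missing = sorted(set(labels) - found_ids)
    if missing:
        raise ValueError(f"labels list subjects with no time-series file: {missing}")
    return RoiTimeSeriesSet(subjects)


# ------------------------------------------------------------- networks

def write_networks(directory: str | Path, cohort: NetworkCohort) -> None:
    """One N x N adjacency file per subject (NaN diagonal) plus labels.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for net in cohort:
        np.savetxt(directory / f"{net.subject_id}.adj.tsv", net.weights,
                   fmt=_FLOAT_FMT, delimiter="\t")
    write_labels(directory / "labels.tsv", cohort.subject_ids, cohort.labels)


def read_networks(
    directory: str | Path, labels_path: str | Path | None = None
) -> NetworkCohort:
    """Read per-subject adjacency matrices, validating symmetry and bounds.

    A zero (or absent) diagonal is accepted and converted to NaN with a
    warning; anything else on the diagonal is rejected.
    """
    import warnings

    directory = Path(directory)
    labels_path = Path(labels_path) if labels_path else directory / "labels.tsv"
    labels = read_labels(labels_path)
    files = sorted(directory.glob("*.adj.tsv"))
    networks = []
    n_expected: int | None = None
    found_ids = set()
    for f in files:
        sid = f.name[: -len(".adj.tsv")]
        if sid not in labels:
            raise ValueError(f"labels file does not cover subject {sid} ({f})")
        found_ids.add(sid)
        w = np.loadtxt(f, delimiter="\t")
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"dimension mismatch: {f} is not a square matrix")
        if n_expected is None:
            n_expected = w.shape[0]
        elif w.shape[0] != n_expected:
            raise ValueError(
                f"dimension mismatch: {f} is {w.shape[0]}x{w.shape[1]}, "
                f"expected {n_expected}x{n_expected}"
            )
        if not np.allclose(w, w.T, atol=1e-8, equal_nan=True):
            raise ValueError(f"{f}: adjacency matrix is not symmetric (tol 1e-8)")
        diag = np.diag(w)
        if np.all(diag == 0):
            warnings.warn(f"{f}: zero diagonal converted to NaN", stacklevel=2)
            np.fill_diagonal(w, np.nan)
        elif not np.isnan(diag).all():
            raise ValueError(f"{f}: diagonal must be NaN (or all zero)")
        off = w[~np.eye(w.shape[0], dtype=bool)]
        if np.nanmax(np.abs(off)) > 1.0 + 1e-8:
            raise ValueError(f"{f}: off-diagonal weights outside [-1, 1]")
        networks.append(FunctionalNetwork(np.clip(w, -1.0, 1.0), subject_id=sid,
                                          label=labels[sid]))
    missing = sorted(set(labels) - found_ids)
    if missing:
        raise ValueError(f"labels list subjects with no adjacency file: {missing}")
    return NetworkCohort(networks)


# --------------------------------------------------------- ROI metadata

def read_roi_metadata(path: str | Path) -> RoiMetadata:
    """TSV with columns: index (1-based), name, x, y, z[, network]."""
    df = pd.read_csv(path, sep="\t")
    required = {"index", "name", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"ROI metadata {path} must have columns {sorted(required)}")
    return RoiMetadata(
        indices=df["index"].to_numpy(int),
        names=df["name"].astype(str).tolist(),
        coords=df[["x", "y", "z"]].to_numpy(float),
        networks=df["network"].astype(str).tolist() if "network" in df.columns else [],
    )


# ------------------------------------------------------------- results

def write_edge_list(path: str | Path, net: DysconnectedNetwork) -> None:
    """Edge list (roi_i, roi_j, t_value) with 1-based indices, sorted by (i, j)."""
    rows = [
        {"roi_i": i + 1, "roi_j": j + 1, "t_value": t}
        for (i, j), t in sorted(net.edges.items())
    ]
    pd.DataFrame(rows, columns=["roi_i", "roi_j", "t_value"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def _round6(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    return x


def write_summary_json(path: str | Path, payload: dict) -> None:
    """Deterministic JSON: sorted keys, floats at six significant figures."""

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating,)):
            return _round6(float(obj))
        if isinstance(obj, (np.integer,)):
            return int(obj)
        return _round6(obj)

    Path(path).write_text(json.dumps(clean(payload), sort_keys=True, indent=2) + "\n")


def network_summary(net: DysconnectedNetwork | None) -> dict:
    if net is None:
        return {"n_edges": 0, "n_nodes": 0, "intensity": 0.0, "p_value": None,
                "threshold": None}
    return {
        "threshold": net.threshold,
        "n_edges": net.n_edges,
        "n_nodes": net.n_nodes,
        "intensity": net.intensity,
        "p_value": net.p_value,
    }


def write_brainnet(
    stem: str | Path,
    net: DysconnectedNetwork,
    metadata: RoiMetadata,
    node_size_by_degree: bool = True,
) -> tuple[Path, Path]:
    """Write BrainNet Viewer ``.node`` and ``.edge`` files.

    ``.edge``: N x N whitespace-delimited matrix carrying the selected
    edges' t-values (0 elsewhere). ``.node``: one row per ROI,
    "x y z color size label"; color encodes network membership rank, size
    the node degree within the selected component (1 when disabled).
    """
    stem = Path(stem)
    n = metadata.n_rois
    mat = np.zeros((n, n))
    degrees = np.zeros(n, dtype=int)
    for (i, j), t in net.edges.items():
        mat[i, j] = mat[j, i] = t
        degrees[i] += 1
        degrees[j] += 1
    edge_path = stem.with_suffix(".edge")
    np.savetxt(edge_path, mat, fmt=_FLOAT_FMT, delimiter=" ")
    if metadata.networks:
        ranks = {name: k + 1 for k, name in enumerate(dict.fromkeys(metadata.networks))}
        colors = [ranks[name] for name in metadata.networks]
    else:
        colors = [1] * n
    sizes = degrees if node_size_by_degree else np.ones(n, dtype=int)
    node_path = stem.with_suffix(".node")
    with open(node_path, "w") as fh:
        for k in range(n):
            x, y, z = metadata.coords[k]
            label = metadata.names[k].replace(" ", "_")
            fh.write(f"{x:g} {y:g} {z:g} {colors[k]} {sizes[k]} {label}\n")
    return node_path, edge_path
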
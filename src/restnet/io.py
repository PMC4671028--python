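"""Plain-text readers and writers for the pipeline's file formats.

Time series and matrices are delimited text with a header row of ROI
labels; motion is 7 columns (6 parameters + outlier fraction); graphs
are 0-based 2-column edge lists; everything structured goes to JSON.
Floats are written with 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .graphs import BinaryGraph
from .preprocess import ConnectivityMatrix
from .synthetic import MotionTrace

FLOAT_FMT = "%.6g"


def write_timeseries(path: str | Path, ts: np.ndarray, labels: list[str]) -> None:
    header = ",".join(labels)
    np.savetxt(path, np.asarray(ts, dtype=float), fmt=FLOAT_FMT, delimiter=",",
               header=header, comments="")


def read_timeseries(path: str | Path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        labels = fh.readline().strip().split(",")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != len(labels):
        raise ValueError(f"{path}: {data.shape[1]} columns but {len(labels)} labels")
    return data, labels


def write_motion(path: str | Path, motion: MotionTrace) -> None:
    table = np.column_stack([motion.params, motion.outlier_fraction])
    header = "trans_x,trans_y,trans_z,rot_x,rot_y,rot_z,outlier_fraction"
    np.savetxt(path, table, fmt=FLOAT_FMT, delimiter=",", header=header, comments="")


def read_motion(path: str | Path) -> MotionTrace:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 7:
        raise ValueError(f"{path}: motion file needs 7 columns, got {data.shape[1]}")
    return MotionTrace(params=data[:, :6], outlier_fraction=data[:, 6])


def write_matrix(path: str | Path, matrix: ConnectivityMatrix) -> None:
    header = ",".join(matrix.labels)
    np.savetxt(path, matrix.values, fmt=FLOAT_FMT, delimiter=",", header=header, comments="")


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    with open(path) as fh:
        labels = fh.readline().strip().split(",")
    values = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({values.shape})")
    # re-symmetrize: 6-sig-digit round trips break exact symmetry
    values = (values + values.T) / 2.0
    return ConnectivityMatrix(values=values, labels=labels)


def write_edge_list(path: str | Path, graph: BinaryGraph) -> None:
    with open(path, "w") as fh:
        fh.write(f"# nodes={graph.n_nodes}\n")
        for i, j in graph.edge_list():
            fh.write(f"{i}\t{j}\n")


def read_edge_list(path: str | Path) -> BinaryGraph:
    n_nodes = None
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "nodes=" in line:
                    n_nodes = int(line.split("nodes=")[1])
                continue
            i, j = map(int, line.split())
            edges.append((i, j))
    if n_nodes is None:
        n_nodes = 1 + max((max(e) for e in edges), default=0)
    A = np.zeros((n_nodes, n_nodes), dtype=np.uint8)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return BinaryGraph(A)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dict__"):
        return _jsonable(vars(obj))
    return obj


def write_json(path: str | Path, payload) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
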
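"""Reading and writing the pipeline's file formats.

Recordings: CSV (first column time in seconds or frame index, one column
per cell, header row = cell ids) or HDF5 (datasets ``traces``, ``fs``,
``coords``, ``cell_ids``).  Coordinates: CSV with columns
``cell_id, x_um, y_um``.  Intervals: YAML or JSON list of
``{name, start_s, end_s}``.  Similarity matrices: square CSV with a cell-id
header row/column, or an HDF5 dataset with a ``method`` attribute.  Edge
lists: CSV with columns ``cell_i, cell_j, similarity, distance_um`` plus a
JSON sidecar holding the construction record.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .construct import FunctionalNetwork
from .exceptions import ParameterError
from .recording import CalciumRecording, Interval
from .similarity import SimilarityMatrix

__all__ = [
    "read_recording_csv", "write_recording_csv",
    "read_recording_hdf5", "write_recording_hdf5",
    "read_coords_csv", "write_coords_csv",
    "read_intervals", "write_intervals",
    "read_similarity_csv", "write_similarity_csv",
    "read_similarity_hdf5", "write_similarity_hdf5",
    "read_edge_list", "write_edge_list",
]


# ---------------------------------------------------------------- recordings

def write_recording_csv(rec: CalciumRecording, path: str | Path) -> None:
    df = pd.DataFrame(rec.traces, columns=rec.cell_ids)
    df.insert(0, "time_s", rec.time_s)
    df.to_csv(path, index=False)


def read_recording_csv(
    path: str | Path,
    fs: float | None = None,
    coords: np.ndarray | None = None,
) -> CalciumRecording:
    """Read traces from CSV.

    The first column is time in seconds (fs inferred from its spacing) or a
    frame index (then ``fs`` must be given).
    """
    df = pd.read_csv(path)
    tcol = df.iloc[:, 0].to_numpy(dtype=float)
    steps = np.diff(tcol)
    if fs is None:
        if steps.size == 0 or not np.allclose(steps, steps[0]) or steps[0] <= 0:
            raise ParameterError("cannot infer fs: first column is not evenly spaced time")
        if np.allclose(steps[0], 1.0) and np.allclose(tcol, np.round(tcol)):
            raise ParameterError("first column looks like a frame index; pass fs explicitly")
        fs = 1.0 / steps[0]
    return CalciumRecording(
        traces=df.iloc[:, 1:].to_numpy(dtype=float),
        fs=float(fs),
        cell_ids=list(df.columns[1:]),
        coords=coords,
    )


def write_recording_hdf5(rec: CalciumRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=rec.traces)
        f.create_dataset("fs", data=rec.fs)
        f.create_dataset("cell_ids", data=np.array(rec.cell_ids, dtype="S"))
        if rec.coords is not None:
            f.create_dataset("coords", data=rec.coords)


def read_recording_hdf5(path: str | Path) -> CalciumRecording:
    with h5py.File(path, "r") as f:
        return CalciumRecording(
            traces=f["traces"][()],
            fs=float(f["fs"][()]),
            cell_ids=[c.decode() for c in f["cell_ids"][()]],
            coords=f["coords"][()] if "coords" in f else None,
        )


def write_coords_csv(cell_ids: list[str], coords: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"cell_id": cell_ids, "x_um": coords[:, 0], "y_um": coords[:, 1]}
    ).to_csv(path, index=False)


def read_coords_csv(path: str | Path, cell_ids: list[str] | None = None) -> np.ndarray:
    df = pd.read_csv(path).set_index("cell_id")
    df.index = df.index.astype(str)
    if cell_ids is not None:
        df = df.loc[cell_ids]
    return df[["x_um", "y_um"]].to_numpy(dtype=float)


# ---------------------------------------------------------------- intervals

def write_intervals(intervals: list[Interval], path: str | Path) -> None:
    items = [{"name": iv.name, "start_s": iv.start_s, "end_s": iv.end_s} for iv in intervals]
    path = Path(path)
    text = json.dumps(items, indent=1) if path.suffix == ".json" else yaml.safe_dump(items)
    path.write_text(text)


def read_intervals(path: str | Path) -> list[Interval]:
    path = Path(path)
    raw = path.read_text()
    items = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    return [Interval(d["name"], float(d["start_s"]), float(d["end_s"])) for d in items]


# ------------------------------------------------------------- similarities

def write_similarity_csv(S: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(S.values, index=S.cell_ids, columns=S.cell_ids).to_csv(path)


def read_similarity_csv(path: str | Path, method: str) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return SimilarityMatrix(
        values=df.to_numpy(dtype=float), method=method, cell_ids=[str(c) for c in df.columns]
    )


def write_similarity_hdf5(S: SimilarityMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("similarity", data=S.values)
        d.attrs["method"] = S.method
        f.create_dataset("cell_ids", data=np.array(S.cell_ids, dtype="S"))


def read_similarity_hdf5(path: str | Path) -> SimilarityMatrix:
    with h5py.File(path, "r") as f:
        d = f["similarity"]
        return SimilarityMatrix(
            values=d[()],
            method=d.attrs["method"],
            cell_ids=[c.decode() for c in f["cell_ids"][()]],
        )


# ---------------------------------------------------------------- edge lists

def write_edge_list(
    net: FunctionalNetwork,
    path: str | Path,
    S: SimilarityMatrix | None = None,
) -> None:
    """Write edges as CSV plus a JSON sidecar with the construction record.

    The similarity column is filled from ``S`` when given; the physical
    edge length requires coordinates on the network.
    """
    idx = {c: i for i, c in enumerate(net.cell_ids)}
    rows = []
    for u, v in sorted((tuple(sorted(e)) for e in net.graph.edges)):
        sim = float(S.values[idx[u], idx[v]]) if S is not None else np.nan
        if net.coords is not None:
            dist = float(np.linalg.norm(net.coords[idx[u]] - net.coords[idx[v]]))
        else:
            dist = np.nan
        rows.append({"cell_i": u, "cell_j": v, "similarity": sim, "distance_um": dist})
    pd.DataFrame(rows, columns=["cell_i", "cell_j", "similarity", "distance_um"]).to_csv(
        path, index=False
    )
    sidecar = Path(path).with_suffix(".json")
    record = dict(net.construction)
    record.pop("layers", None)
    record["cell_ids"] = net.cell_ids
    sidecar.write_text(json.dumps(record, indent=1))


def read_edge_list(path: str | Path, coords: np.ndarray | None = None) -> FunctionalNetwork:
    """Reconstruct a network from an edge-list CSV and its JSON sidecar."""
    import networkx as nx

    df = pd.read_csv(path)
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        record = json.loads(sidecar.read_text())
        cell_ids = [str(c) for c in record.pop("cell_ids")]
    else:
        cell_ids = sorted(set(df["cell_i"].astype(str)) | set(df["cell_j"].astype(str)))
        record = {}
    g = nx.Graph()
    g.add_nodes_from(cell_ids)
    g.add_edges_from(zip(df["cell_i"].astype(str), df["cell_j"].astype(str)))
    return FunctionalNetwork(graph=g, cell_ids=cell_ids, coords=coords, construction=record)
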
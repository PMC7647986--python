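"""Readers and writers for surfaces, scalars, streamlines and matrices.

Surfaces: GIFTI (.gii / .surf.gii) through nibabel, PLY and OFF through
trimesh.  Per-vertex scalars: GIFTI functional files or 1-column text.
Streamlines: TCK and TRK through nibabel.streamlines.  Connectivity:
dense delimited matrices or sparse (i, j, weight) edge lists.  All
coordinates are millimetres.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .connectome import StreamlineSet, WeightedNetwork
from .hinges import CrestGraph
from .surface import SurfaceMesh

__all__ = ["read_surface", "write_surface", "read_scalar", "write_scalar",
           "read_streamlines", "write_streamlines", "read_matrix",
           "write_matrix", "write_crest_graph", "read_crest_graph"]


def read_surface(path: str | Path) -> SurfaceMesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.name.lower()
    if suffix.endswith(".gii"):
        img = nib.load(str(path))
        pointset = [d for d in img.darrays
                    if d.intent == nib.nifti1.intent_codes["pointset"]]
        triangle = [d for d in img.darrays
                    if d.intent == nib.nifti1.intent_codes["triangle"]]
        if not pointset or not triangle:
            raise ValueError(f"{path}: GIFTI file lacks pointset/triangle "
                             "arrays")
        return SurfaceMesh(vertices=pointset[0].data.astype(float),
                           faces=triangle[0].data.astype(int))
    if suffix.endswith((".ply", ".off")):
        tm = trimesh.load(str(path), process=False)
        return SurfaceMesh(vertices=np.asarray(tm.vertices),
                           faces=np.asarray(tm.faces))
    raise ValueError(f"unsupported surface format: {path}")


def write_surface(mesh: SurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    suffix = path.name.lower()
    if suffix.endswith(".gii"):
        coords = nib.gifti.GiftiDataArray(
            mesh.vertices.astype(np.float32), intent="pointset")
        faces = nib.gifti.GiftiDataArray(
            mesh.faces.astype(np.int32), intent="triangle")
        nib.save(nib.gifti.GiftiImage(darrays=[coords, faces]), str(path))
    elif suffix.endswith((".ply", ".off")):
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                             process=False)
        tm.export(str(path))
    else:
        raise ValueError(f"unsupported surface format: {path}")


def read_scalar(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.name.lower().endswith(".gii"):
        img = nib.load(str(path))
        return np.asarray(img.darrays[0].data, dtype=float)
    return np.loadtxt(path, dtype=float).ravel()


def write_scalar(values: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.name.lower().endswith(".gii"):
        arr = nib.gifti.GiftiDataArray(
            np.asarray(values, dtype=np.float32), intent="none")
        nib.save(nib.gifti.GiftiImage(darrays=[arr]), str(path))
    else:
        np.savetxt(path, np.asarray(values, dtype=float))


def read_streamlines(path: str | Path) -> StreamlineSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:  # malformed/truncated files
        raise ValueError(f"{path}: failed to parse streamlines "
                         f"({exc})") from exc
    return StreamlineSet(polylines=[np.asarray(s, dtype=float)
                                    for s in tf.streamlines])


def write_streamlines(streamlines: StreamlineSet, path: str | Path) -> None:
    path = Path(path)
    seq = nib.streamlines.ArraySequence(streamlines.polylines)
    tractogram = nib.streamlines.Tractogram(seq, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(path))


def read_matrix(path: str | Path) -> WeightedNetwork:
    """Dense delimited matrix, or edge-list CSV with columns i, j, weight."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    if header.replace(" ", "").lower().startswith(("i,j,", "i\tj")):
        df = pd.read_csv(path, sep=None, engine="python")
        n = int(max(df["i"].max(), df["j"].max())) + 1
        w = np.zeros((n, n))
        w[df["i"], df["j"]] = df["weight"]
        w[df["j"], df["i"]] = df["weight"]
        return WeightedNetwork(weights=w)
    w = np.loadtxt(path, delimiter=",")
    return WeightedNetwork(weights=w)


def write_matrix(net: WeightedNetwork, path: str | Path,
                 edge_list: bool = False) -> None:
    path = Path(path)
    if edge_list:
        i, j = np.nonzero(np.triu(net.weights, k=1))
        pd.DataFrame({"i": i, "j": j,
                      "weight": net.weights[i, j]}).to_csv(path, index=False)
    else:
        np.savetxt(path, net.weights, delimiter=",")


def write_crest_graph(crest: CrestGraph, path: str | Path) -> None:
    payload = {
        "nodes": [int(v) for v in crest.nodes],
        "edges": [[int(a), int(b)] for a, b in crest.edges],
        "hinges": [[int(v), int(a)] for v, a in crest.hinges],
        "distance": {str(k): v for k, v in crest.distance.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_crest_graph(path: str | Path) -> CrestGraph:
    payload = json.loads(Path(path).read_text())
    return CrestGraph(
        nodes=np.array(payload["nodes"], dtype=np.int64),
        edges=np.array(payload["edges"], dtype=np.int64).reshape(-1, 2),
        hinges=[(int(v), int(a)) for v, a in payload["hinges"]],
        distance={int(k): float(v)
                  for k, v in payload.get("distance", {}).items()})
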
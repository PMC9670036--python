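"""WSI graph construction from patch features and grid coordinates.

Each kept patch is a node; two nodes are joined when their grid coordinates
are neighbours (8-connectivity: Chebyshev distance 1; 4-connectivity:
Manhattan distance 1).  The binary adjacency A is then self-looped and
symmetrically degree-normalised,

    A_hat = D̃^{-1/2} (A + I) D̃^{-1/2},   D̃_ii = Σ_j (A + I)_ij,

which is the propagation operator used by the graph-convolution layers.

With 8-connectivity every interior node has degree 8 and every node of a
connected multi-patch slide has degree >= 1; isolated tissue islands (degree
0) can still occur after aggressive background filtering and are permitted
with a warning — they carry only their self-loop in A_hat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

__all__ = ["WSIGraph", "build_adjacency", "normalize_adjacency", "build_graph",
           "save_graph", "load_graph"]


@dataclass
class WSIGraph:
    slide_id: str
    F: np.ndarray                      # (N, D) node features
    A: np.ndarray                      # (N, N) binary symmetric, zero diagonal
    A_hat: np.ndarray                  # (N, N) normalized with self-loops
    coords: list[tuple[int, int]]
    label: int | None = None
    connectivity: int = 8
    patch_size: int = 0
    slide_shape: tuple[int, int] = (0, 0)
    stride: int = 0

    @property
    def n_nodes(self) -> int:
        return self.F.shape[0]


def build_adjacency(coords, connectivity: int = 8) -> np.ndarray:
    """Binary grid adjacency: A_ij = 1 iff coords i, j are neighbours."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    coords = [tuple(c) for c in coords]
    n = len(coords)
    if len(set(coords)) != n:
        raise ValueError("duplicate coordinates")
    index = {c: i for i, c in enumerate(coords)}
    if connectivity == 8:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    A = np.zeros((n, n), dtype=np.int8)
    for i, (r, c) in enumerate(coords):
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                A[i, j] = 1
    if n >= 2 and (A.sum(axis=1) == 0).any():
        warnings.warn("graph contains isolated nodes (self-loop only)", stacklevel=2)
    return A


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Self-looped symmetric degree normalisation of a (possibly weighted) A."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.allclose(A, A.T):
        raise ValueError("A must be symmetric")
    A_tilde = A + np.eye(A.shape[0])
    deg = A_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def build_graph(
    F: np.ndarray,
    coords,
    connectivity: int = 8,
    label: int | None = None,
    slide_id: str = "",
    patch_size: int = 0,
    slide_shape: tuple[int, int] = (0, 0),
    stride: int = 0,
) -> WSIGraph:
    F = np.asarray(F, dtype=np.float64)
    coords = [tuple(c) for c in coords]
    if F.ndim != 2 or F.shape[0] != len(coords):
        raise ValueError("rows of F must align with coords")
    A = build_adjacency(coords, connectivity)
    return WSIGraph(
        slide_id=slide_id,
        F=F,
        A=A,
        A_hat=normalize_adjacency(A),
        coords=coords,
        label=label,
        connectivity=connectivity,
        patch_size=patch_size,
        slide_shape=tuple(slide_shape),
        stride=stride or patch_size,
    )


def save_graph(graph: WSIGraph, path: str | Path):
    """HDF5 bundle: /F, sparse /edges (E, 2), /coords, metadata as attrs."""
    ii, jj = np.nonzero(np.triu(graph.A, k=1))
    with h5py.File(path, "w") as f:
        f.create_dataset("F", data=graph.F)
        f.create_dataset("edges", data=np.stack([ii, jj], axis=1).astype(np.int64))
        f.create_dataset("coords", data=np.asarray(graph.coords, dtype=np.int64))
        f.attrs["slide_id"] = graph.slide_id
        f.attrs["connectivity"] = graph.connectivity
        f.attrs["label"] = -1 if graph.label is None else int(graph.label)
        f.attrs["patch_size"] = graph.patch_size
        f.attrs["slide_shape"] = list(graph.slide_shape)
        f.attrs["stride"] = graph.stride


def load_graph(path: str | Path) -> WSIGraph:
    with h5py.File(path, "r") as f:
        F = f["F"][...]
        edges = f["edges"][...]
        coords = [tuple(int(v) for v in row) for row in f["coords"][...]]
        n = F.shape[0]
        A = np.zeros((n, n), dtype=np.int8)
        if len(edges):
            A[edges[:, 0], edges[:, 1]] = 1
            A[edges[:, 1], edges[:, 0]] = 1
        label = int(f.attrs["label"])
        return WSIGraph(
            slide_id=str(f.attrs["slide_id"]),
            F=F,
            A=A,
            A_hat=normalize_adjacency(A),
            coords=coords,
            label=None if label < 0 else label,
            connectivity=int(f.attrs["connectivity"]),
            patch_size=int(f.attrs["patch_size"]),
            slide_shape=tuple(int(v) for v in f.attrs["slide_shape"]),
            stride=int(f.attrs["stride"]),
        )
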
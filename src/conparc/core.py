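"""Domain types and I/O for vertex-resolution ("dense") connectomes.

A dense connectome is a symmetric nonnegative vertex-by-vertex weight matrix
defined on a shared two-hemisphere cortical surface mesh: the discrete analogue
of the intensity function of a symmetric Poisson point process over the
cortical surface.  A parcellation assigns every mesh vertex to exactly one
region; two parcellations are equivalent when one is a relabeling of the other.

Conventions used throughout the package:

* vertex indices are 0-based;
* label values are arbitrary nonnegative integers, with a canonical form
  defined by order of first appearance (:func:`relabel_canonical`);
* connectomes are stored as dense ``float64`` arrays with zero diagonal;
* Matrix Market (symmetric coordinate) is the canonical on-disk connectome
  format, with whitespace-delimited TSV edge lists accepted as a dialect;
* meshes are ASCII PLY plus a sidecar TSV carrying hemisphere membership and
  the left<->right mirror correspondence (PLY has no standard slot for them).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "LEFT",
    "RIGHT",
    "Partition",
    "HierarchicalPartition",
    "SurfaceMesh",
    "DenseConnectome",
    "CoarseConnectome",
    "relabel_canonical",
    "sparsify",
    "mesh_adjacency",
    "load_connectome",
    "save_connectome",
    "load_labels",
    "save_labels",
    "load_mesh",
    "save_mesh",
    "write_provenance",
]

logger = logging.getLogger("conparc")

#: hemisphere codes used in ``SurfaceMesh.hemisphere``
LEFT, RIGHT = 0, 1

_VERSION = "0.1.0"


def write_provenance(path: str | Path, **fields) -> Path:
    """Write a JSON sidecar ``<path>.json`` recording how a file was produced."""
    out = Path(str(path) + ".json")
    payload = {"conparc_version": _VERSION}
    payload.update(fields)
    out.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return out


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Partition:
    """A hard assignment of every vertex to exactly one region.

    Equivalence is up to relabeling: ``[1,1,1,0,0]``, ``[0,0,0,1,1]`` and
    ``[2,2,2,5,5]`` all represent the same partition of five vertices.
    """

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a nonempty 1-D integer vector")
        if labels.min() < 0:
            raise ValueError("labels must be nonnegative integers")
        object.__setattr__(self, "labels", labels)

    @property
    def n_vertices(self) -> int:
        return int(self.labels.size)

    @property
    def n_regions(self) -> int:
        return int(np.unique(self.labels).size)

    def region_labels(self) -> np.ndarray:
        return np.unique(self.labels)

    def region(self, label: int) -> np.ndarray:
        """Vertex indices belonging to ``label``."""
        return np.flatnonzero(self.labels == label)

    def sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def is_equivalent_to(self, other: "Partition") -> bool:
        if self.n_vertices != other.n_vertices:
            return False
        a = relabel_canonical(self).labels
        b = relabel_canonical(other).labels
        return bool(np.array_equal(a, b))


def relabel_canonical(p: Partition | np.ndarray) -> Partition:
    """Relabel to consecutive integers 0..L-1 in order of first appearance.

    Idempotent; the canonical form is the unique representative of a
    partition's relabeling-equivalence class, so two partitions are equivalent
    iff their canonical label vectors are equal.
    """
    labels = p.labels if isinstance(p, Partition) else np.asarray(p, dtype=np.int64)
    _, first, inverse = np.unique(labels, return_index=True, return_inverse=True)
    # rank unique values by their first appearance in the vector
    rank = np.argsort(np.argsort(first))
    return Partition(rank[inverse])


@dataclass(frozen=True)
class HierarchicalPartition:
    """An ordered list of partitions C^I, C^II, ... of the same vertex set.

    Subject-level outputs are nested refinements (every level-(t+1) region lies
    inside one level-t region); ensemble outputs need not be, so nesting is
    checked by :meth:`is_nested` but not asserted at construction.
    """

    levels: tuple[Partition, ...]

    def __post_init__(self):
        levels = tuple(self.levels)
        if not levels:
            raise ValueError("need at least one level")
        K = levels[0].n_vertices
        if any(l.n_vertices != K for l in levels):
            raise ValueError("all levels must cover the same vertex set")
        object.__setattr__(self, "levels", levels)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_vertices(self) -> int:
        return self.levels[0].n_vertices

    def level(self, i: int) -> Partition:
        """1-based level access (level(1) is the coarsest, C^I)."""
        return self.levels[i - 1]

    def is_nested(self) -> bool:
        """True iff every level refines the one before it."""
        for coarse, fine in zip(self.levels, self.levels[1:]):
            for lab in fine.region_labels():
                parents = np.unique(coarse.labels[fine.labels == lab])
                if parents.size != 1:
                    return False
        return True


# ---------------------------------------------------------------------------
# Surface meshes
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class SurfaceMesh:
    """Triangulated two-hemisphere surface with mirror correspondence.

    ``hemisphere[v]`` is LEFT (0) or RIGHT (1); ``mirror_map`` is a full-length
    involution mapping each vertex to its mirror image in the other hemisphere.
    """

    positions: np.ndarray  # (K, 3) float
    triangles: np.ndarray  # (F, 3) int
    hemisphere: np.ndarray  # (K,) int8, LEFT/RIGHT
    mirror_map: np.ndarray  # (K,) int64 involution across hemispheres
    _adjacency: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.hemisphere = np.asarray(self.hemisphere, dtype=np.int8)
        self.mirror_map = np.asarray(self.mirror_map, dtype=np.int64)
        self.validate()

    @property
    def vertex_count(self) -> int:
        return int(self.positions.shape[0])

    @property
    def adjacency(self) -> sp.csr_matrix:
        if self._adjacency is None:
            self._adjacency = mesh_adjacency(self)
        return self._adjacency

    def vertices_of(self, hemi: int) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    def validate(self) -> None:
        K = self.vertex_count
        if self.positions.shape != (K, 3):
            raise ValueError("positions must be (K, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (F, 3)")
        if self.triangles.min() < 0 or self.triangles.max() >= K:
            raise ValueError("triangle vertex index out of range")
        if self.hemisphere.shape != (K,) or not np.isin(self.hemisphere, [LEFT, RIGHT]).all():
            raise ValueError("hemisphere must assign LEFT/RIGHT to every vertex")
        left = self.vertices_of(LEFT)
        right = self.vertices_of(RIGHT)
        if left.size == 0 or right.size == 0 or left.size != right.size:
            raise ValueError("hemispheres must be nonempty and of equal size")
        mm = self.mirror_map
        if mm.shape != (K,):
            raise ValueError("mirror_map must cover every vertex")
        if not np.array_equal(mm[mm], np.arange(K)):
            raise ValueError("mirror_map must be an involution")
        if not np.array_equal(self.hemisphere[mm], 1 - self.hemisphere):
            raise ValueError("mirror_map must map across hemispheres")
        # connectivity: exactly two components, matching the hemisphere split,
        # each a closed 2-manifold triangulation with Euler characteristic 2
        adj = mesh_adjacency(self)
        self._adjacency = adj
        n_comp, comp = connected_components(adj, directed=False)
        if n_comp != 2:
            raise ValueError(f"mesh must have exactly two components, found {n_comp}")
        if np.unique(comp[left]).size != 1 or np.unique(comp[right]).size != 1:
            raise ValueError("each hemisphere must be one connected component")
        tri_comp = comp[self.triangles[:, 0]]
        for c in (0, 1):
            V = int((comp == c).sum())
            F = int((tri_comp == c).sum())
            E = int(adj[comp == c][:, comp == c].nnz // 2)
            if V - E + F != 2:
                raise ValueError(
                    f"component {c} is not a closed sphere triangulation "
                    f"(V-E+F = {V - E + F})"
                )


def mesh_adjacency(m: SurfaceMesh | np.ndarray, n_vertices: int | None = None) -> sp.csr_matrix:
    """Undirected vertex adjacency: u ~ v iff they share a triangle edge.

    Accepts a :class:`SurfaceMesh` or a raw (F, 3) triangle array.  Returns a
    symmetric boolean CSR matrix.
    """
    if isinstance(m, SurfaceMesh):
        tri = m.triangles
        K = m.vertex_count
    else:
        tri = np.asarray(m, dtype=np.int64)
        K = int(tri.max()) + 1 if n_vertices is None else n_vertices
    e = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]])
    e = np.sort(e, axis=1)
    e = np.unique(e, axis=0)
    data = np.ones(len(e), dtype=bool)
    a = sp.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(K, K))
    a = a + a.T
    return a.tocsr()


# ---------------------------------------------------------------------------
# Connectomes
# ---------------------------------------------------------------------------


@dataclass
class DenseConnectome:
    """Symmetric nonnegative vertex-by-vertex weight matrix, zero diagonal."""

    weights: np.ndarray
    sparsity_fraction: float = 1.0
    subject_id: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        self.weights = w
        self.validate()

    def validate(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, rtol=1e-10, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diagonal(w) != 0):
            raise ValueError("diagonal must be zero")
        if not (0 < self.sparsity_fraction <= 1):
            raise ValueError("sparsity_fraction must be in (0, 1]")

    @property
    def n_vertices(self) -> int:
        return int(self.weights.shape[0])

    @property
    def total_weight(self) -> float:
        """Total over ordered vertex pairs (each undirected edge counted twice)."""
        return float(self.weights.sum())

    @property
    def n_edges(self) -> int:
        """Number of nonzero unordered edges."""
        return int(np.count_nonzero(np.triu(self.weights, 1)))


@dataclass
class CoarseConnectome:
    """Region-by-region weight matrix obtained by block-summing a dense one.

    ``omega[a, b]`` is the expected number of observed tracts between regions
    a and b; ``region_sizes`` are vertex counts.  Total mass equals the total
    mass of the source dense connectome.
    """

    omega: np.ndarray
    region_sizes: np.ndarray

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=np.float64)
        self.region_sizes = np.asarray(self.region_sizes, dtype=np.int64)
        if self.omega.ndim != 2 or self.omega.shape[0] != self.omega.shape[1]:
            raise ValueError("omega must be square")
        if self.omega.shape[0] != self.region_sizes.size:
            raise ValueError("region_sizes must match omega")
        if not np.allclose(self.omega, self.omega.T, rtol=1e-10, atol=1e-9):
            raise ValueError("omega must be symmetric")
        if np.any(self.omega < -1e-12):
            raise ValueError("omega must be nonnegative")
        if np.any(self.region_sizes <= 0):
            raise ValueError("region sizes must be positive")

    @property
    def n_regions(self) -> int:
        return int(self.omega.shape[0])

    @property
    def total_weight(self) -> float:
        return float(self.omega.sum())


def sparsify(w: DenseConnectome, q: float) -> DenseConnectome:
    """Keep the heaviest fraction ``q`` of nonzero unordered edges.

    The threshold is the per-subject global quantile over nonzero
    upper-triangle weights; ties at the threshold are all retained, so the
    output may contain slightly more than ``q`` of the edges.  ``q = 1``
    returns an identical copy.
    """
    if not (0 < q <= 1):
        raise ValueError(f"sparsity fraction must be in (0, 1], got {q}")
    if q == 1.0:
        return replace(w, weights=w.weights.copy(), sparsity_fraction=1.0)
    iu = np.triu_indices(w.n_vertices, 1)
    vals = w.weights[iu]
    nz = vals[vals > 0]
    if nz.size == 0:
        return replace(w, weights=w.weights.copy(), sparsity_fraction=q)
    keep = int(np.ceil(q * nz.size))
    thr = np.sort(nz)[::-1][keep - 1]
    out = np.where(w.weights >= thr, w.weights, 0.0)
    np.fill_diagonal(out, 0.0)
    return replace(w, weights=out, sparsity_fraction=q)


# ---------------------------------------------------------------------------
# Connectome I/O
# ---------------------------------------------------------------------------


def _from_raw_matrix(w: np.ndarray, path, subject_id: str) -> DenseConnectome:
    if np.any(w < 0):
        raise ValueError(f"{path}: negative weight encountered")
    w = np.maximum(w, w.T)  # symmetrize by max if only one triangle stored
    if np.any(np.diagonal(w) != 0):
        logger.warning("%s: nonzero diagonal entries dropped", path)
        np.fill_diagonal(w, 0.0)
    return DenseConnectome(w, subject_id=subject_id)


def load_connectome(
    path: str | Path,
    format: str | None = None,
    n_vertices: int | None = None,
) -> DenseConnectome:
    """Read a connectome from Matrix Market or a whitespace TSV edge list.

    The format is inferred from the suffix (``.mtx`` -> Matrix Market) unless
    given explicitly as ``"matrix-market"`` or ``"tsv-edgelist"``.  Matrices
    stored as one triangle are symmetrized by the elementwise maximum and any
    diagonal entries are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "matrix-market" if path.suffix == ".mtx" else "tsv-edgelist"
    if format == "matrix-market":
        try:
            raw = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy reports its own context
            raise ValueError(f"{path}: failed to parse Matrix Market file: {exc}") from exc
        w = np.asarray(raw.toarray() if sp.issparse(raw) else raw, dtype=np.float64)
        if n_vertices is not None and w.shape[0] != n_vertices:
            raise ValueError(f"{path}: expected {n_vertices} vertices, found {w.shape[0]}")
        return _from_raw_matrix(w, path, path.stem)
    if format == "tsv-edgelist":
        rows: list[tuple[int, int, float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 'u v w', got {line!r}")
                try:
                    u, v, wt = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                if wt < 0:
                    raise ValueError(f"{path}:{lineno}: negative weight {wt}")
                if u < 0 or v < 0:
                    raise ValueError(f"{path}:{lineno}: negative vertex index")
                rows.append((u, v, wt))
        if not rows:
            raise ValueError(f"{path}: empty edge list")
        arr = np.array(rows)
        K = n_vertices if n_vertices is not None else int(arr[:, :2].max()) + 1
        if arr[:, :2].max() >= K:
            raise ValueError(f"{path}: vertex index exceeds n_vertices={K}")
        w = np.zeros((K, K))
        for u, v, wt in rows:
            w[int(u), int(v)] = max(w[int(u), int(v)], wt)
        return _from_raw_matrix(w, path, path.stem)
    raise ValueError(f"unknown connectome format {format!r}")


def save_connectome(w: DenseConnectome, path: str | Path, **provenance) -> Path:
    """Write as symmetric coordinate Matrix Market (round-trips bit-exactly)."""
    path = Path(path)
    lower = sp.coo_matrix(np.tril(w.weights))
    scipy.io.mmwrite(path, lower, symmetry="symmetric", precision=17)
    write_provenance(
        path,
        format="matrix-market symmetric coordinate",
        subject_id=w.subject_id,
        sparsity_fraction=w.sparsity_fraction,
        **provenance,
    )
    return path


# ---------------------------------------------------------------------------
# Label I/O
# ---------------------------------------------------------------------------


def load_labels(path: str | Path, n_vertices: int | None = None) -> Partition:
    """Read a per-vertex TSV of (vertex_id, label) records; canonicalize."""
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, names=["vertex_id", "label"])
    ids = df["vertex_id"].to_numpy()
    K = n_vertices if n_vertices is not None else int(ids.max()) + 1
    if len(ids) != K or not np.array_equal(np.sort(ids), np.arange(K)):
        raise ValueError(
            f"{path}: expected exactly one record per vertex 0..{K - 1} "
            f"(got {len(ids)} rows)"
        )
    labels = np.empty(K, dtype=np.int64)
    labels[ids] = df["label"].to_numpy()
    if labels.min() < 0:
        raise ValueError(f"{path}: negative label value")
    return relabel_canonical(labels)


def save_labels(p: Partition, path: str | Path, **provenance) -> Path:
    path = Path(path)
    canon = relabel_canonical(p)
    df = pd.DataFrame(
        {"vertex_id": np.arange(canon.n_vertices), "label": canon.labels}
    )
    df.to_csv(path, sep="\t", header=False, index=False)
    write_provenance(path, format="per-vertex label TSV", n_regions=canon.n_regions, **provenance)
    return path


# ---------------------------------------------------------------------------
# Mesh I/O: ASCII PLY + hemisphere sidecar TSV
# ---------------------------------------------------------------------------


def save_mesh(m: SurfaceMesh, path: str | Path, sidecar: str | Path | None = None, **provenance) -> Path:
    import trimesh

    path = Path(path)
    tm = trimesh.Trimesh(vertices=m.positions, faces=m.triangles, process=False)
    path.write_bytes(tm.export(file_type="ply", encoding="ascii"))
    sidecar = Path(sidecar) if sidecar is not None else Path(str(path) + ".hemi.tsv")
    df = pd.DataFrame(
        {
            "vertex_id": np.arange(m.vertex_count),
            "hemisphere": np.where(m.hemisphere == LEFT, "L", "R"),
            "mirror_vertex_id": m.mirror_map,
        }
    )
    df.to_csv(sidecar, sep="\t", index=False)
    write_provenance(path, format="ascii PLY + hemisphere sidecar", sidecar=str(sidecar), **provenance)
    return path


def load_mesh(path: str | Path, sidecar: str | Path | None = None) -> SurfaceMesh:
    import trimesh

    path = Path(path)
    tm = trimesh.load(path, file_type="ply", process=False)
    sidecar = Path(sidecar) if sidecar is not None else Path(str(path) + ".hemi.tsv")
    df = pd.read_csv(sidecar, sep="\t")
    K = len(tm.vertices)
    if len(df) != K:
        raise ValueError(f"{sidecar}: {len(df)} rows for a {K}-vertex mesh")
    hemi = np.where(df.sort_values("vertex_id")["hemisphere"].to_numpy() == "L", LEFT, RIGHT)
    mirror = df.sort_values("vertex_id")["mirror_vertex_id"].to_numpy()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), hemi, mirror)


def load_gifti_surface(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Optional GIFTI reader for real data (requires nibabel): (positions, triangles)."""
    import nibabel as nib

    img = nib.load(str(path))
    pos = img.darrays[0].data.astype(np.float64)
    tri = img.darrays[1].data.astype(np.int64)
    return pos, tri


def load_annot_labels(path: str | Path) -> np.ndarray:
    """Optional FreeSurfer .annot reader for real data (requires nibabel)."""
    import nibabel.freesurfer as fs

    labels, _, _ = fs.read_annot(str(path))
    return np.asarray(labels, dtype=np.int64)
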
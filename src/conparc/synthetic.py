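"""Synthetic meshes and connectome cohorts with known ground truth.

The generator emulates the regime the pipeline is designed for: a cohort of
mirrored, spatially smooth, block-structured connectomes on a subdivided
icosahedral two-sphere mesh.  A planted two-level hierarchy (super-regions
subdivided into sub-regions, both built as geodesic Voronoi cells and
mirrored across hemispheres) defines block intensities; each subject gets an
independently perturbed copy of the planted partition (a fraction of vertices
flipped to a neighboring region) and edge weights drawn as Poisson counts —
honoring the Poisson point-process framing of the dense connectome — with
optional multiplicative lognormal noise for subject variability.

Everything is bit-reproducible from the spec and its seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import trimesh
from scipy.sparse.csgraph import dijkstra

from .core import (
    LEFT,
    RIGHT,
    DenseConnectome,
    HierarchicalPartition,
    Partition,
    SurfaceMesh,
    relabel_canonical,
    save_connectome,
    save_labels,
    save_mesh,
)

__all__ = [
    "CohortSpec",
    "Cohort",
    "icosphere",
    "planted_parcellation",
    "planted_hierarchy",
    "noisy_partition",
    "simulate_connectome",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults give a 20-subject cohort on an order-3 two-sphere mesh (642
    vertices per hemisphere) with 8 mirrored super-regions each split into 3
    sub-regions, Poisson edge intensities 8 (within sub-region) /
    2 (within super-region, across sub-regions) / 0.5 (between
    super-regions), 10% label noise and 10% multiplicative edge noise.
    """

    mesh_order: int = 3
    n_subjects: int = 20
    n_super_regions: int = 8
    n_sub_regions: int = 3
    within_intensity: float = 8.0
    between_intensity: float = 0.5
    within_super_intensity: float | None = None  # default: geometric mean
    label_noise: float = 0.1
    edge_noise: float = 0.1
    mirrored: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (self.within_intensity > self.between_intensity >= 0):
            raise ValueError("need within_intensity > between_intensity >= 0")
        if not (0 <= self.label_noise < 1 and 0 <= self.edge_noise < 1):
            raise ValueError("label_noise and edge_noise must be in [0, 1)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def mid_intensity(self) -> float:
        """Within-super / between-sub intensity tier."""
        if self.within_super_intensity is not None:
            return self.within_super_intensity
        return float(np.sqrt(self.within_intensity * max(self.between_intensity, 1e-12)))


@dataclass
class Cohort:
    """A simulated cohort: connectomes, planted truth, mesh, and provenance."""

    connectomes: list[DenseConnectome]
    ground_truth: HierarchicalPartition
    mesh: SurfaceMesh
    subject_partitions: list[HierarchicalPartition]
    manifest: dict


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------


def icosphere(order: int) -> SurfaceMesh:
    """Two mirrored unit icospheres assembled as a LEFT/RIGHT mesh.

    Each sphere is a regular icosahedron subdivided ``order`` times and
    projected to the unit sphere: V = 10*4^order + 2 vertices, E = 30*4^order
    edges, F = 20*4^order faces per hemisphere.  The right hemisphere mirrors
    the left through the x = 0 plane; ``mirror_map`` pairs vertices by index.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if order > 7:
        raise ValueError("order > 7 refused (mesh would be impractically large)")
    s = trimesh.creation.icosphere(subdivisions=order, radius=1.0)
    v = np.asarray(s.vertices, dtype=np.float64)
    f = np.asarray(s.faces, dtype=np.int64)
    K = len(v)
    positions = np.vstack([v, v * np.array([-1.0, 1.0, 1.0])])
    triangles = np.vstack([f, f[:, ::-1] + K])  # reversed winding after mirroring
    hemisphere = np.r_[np.full(K, LEFT, dtype=np.int8), np.full(K, RIGHT, dtype=np.int8)]
    mirror_map = np.r_[np.arange(K) + K, np.arange(K)]
    return SurfaceMesh(positions, triangles, hemisphere, mirror_map)


def _edge_length_graph(m: SurfaceMesh) -> sp.csr_matrix:
    """Mesh adjacency weighted by Euclidean edge length (geodesic proxy)."""
    a = m.adjacency.tocoo()
    lengths = np.linalg.norm(m.positions[a.row] - m.positions[a.col], axis=1)
    return sp.csr_matrix((lengths, (a.row, a.col)), shape=a.shape)


def _farthest_point_seeds(
    g: sp.csr_matrix, candidates: np.ndarray, n_seeds: int, rng: np.random.Generator
) -> np.ndarray:
    """Greedy farthest-point sampling in the graph metric, restricted to candidates."""
    seeds = [int(rng.choice(candidates))]
    dmin = dijkstra(g, indices=seeds[0])
    for _ in range(n_seeds - 1):
        masked = dmin[candidates]
        nxt = int(candidates[int(np.argmax(masked))])
        seeds.append(nxt)
        dmin = np.minimum(dmin, dijkstra(g, indices=nxt))
    return np.asarray(seeds)


def _voronoi_assign(g: sp.csr_matrix, seeds: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Nearest-seed (graph geodesic) label for each vertex; ties to lower seed index.

    Every cell is connected: the shortest path from a vertex to its nearest
    seed stays within that seed's cell.
    """
    d = dijkstra(g, indices=seeds)
    return np.argmin(d[:, vertices], axis=0)


def planted_parcellation(
    m: SurfaceMesh, n_regions: int, seed: int = 0, mirrored: bool = True
) -> Partition:
    """Geodesic Voronoi parcellation from farthest-point-sampled seeds.

    With ``mirrored`` (requires even ``n_regions``) cells are grown on the
    left hemisphere and copied to the right through the mirror map, with
    distinct labels per hemisphere; otherwise each hemisphere is seeded
    independently.  Every region is spatially contiguous by construction.
    """
    K = m.vertex_count
    if n_regions > K // 2:
        raise ValueError("n_regions must be at most K/2")
    if n_regions < 2:
        raise ValueError("need at least one region per hemisphere")
    rng = np.random.default_rng(seed)
    g = _edge_length_graph(m)
    labels = np.empty(K, dtype=np.int64)
    left = m.vertices_of(LEFT)
    right = m.vertices_of(RIGHT)
    if mirrored:
        if n_regions % 2:
            raise ValueError("mirrored parcellation needs an even n_regions")
        per = n_regions // 2
        seeds = _farthest_point_seeds(g, left, per, rng)
        labels[left] = _voronoi_assign(g, seeds, left)
        labels[m.mirror_map[left]] = labels[left] + per
    else:
        per_l = n_regions // 2
        per_r = n_regions - per_l
        sl = _farthest_point_seeds(g, left, per_l, rng)
        sr = _farthest_point_seeds(g, right, per_r, rng)
        labels[left] = _voronoi_assign(g, sl, left)
        labels[right] = _voronoi_assign(g, sr, right) + per_l
    return relabel_canonical(labels)


def planted_hierarchy(m: SurfaceMesh, spec: CohortSpec) -> HierarchicalPartition:
    """Two-level planted truth: super-regions, each subdivided into sub-regions.

    Subdivision runs geodesic Voronoi within each left super-region and is
    mirrored to the right, so the hierarchy is nested and (when mirrored)
    perfectly symmetric.
    """
    rng = np.random.default_rng(spec.seed)
    supers = planted_parcellation(m, spec.n_super_regions, seed=spec.seed, mirrored=spec.mirrored)
    g = _edge_length_graph(m)
    K = m.vertex_count
    sub_labels = np.empty(K, dtype=np.int64)
    left = m.vertices_of(LEFT)
    left_mask = np.zeros(K, dtype=bool)
    left_mask[left] = True
    offset = 0
    left_supers = np.unique(supers.labels[left])
    for lab in left_supers:
        idx = np.flatnonzero((supers.labels == lab) & left_mask)
        sub_g = g[np.ix_(idx, idx)]
        local = np.arange(idx.size)
        seeds_local = _farthest_point_seeds(sub_g, local, spec.n_sub_regions, rng)
        assign = _voronoi_assign(sub_g, seeds_local, local)
        sub_labels[idx] = assign + offset
        offset += spec.n_sub_regions
    if spec.mirrored:
        sub_labels[m.mirror_map[left]] = sub_labels[left] + offset
    else:
        # subdivide right supers independently
        right_mask = ~left_mask
        for lab in np.unique(supers.labels[m.vertices_of(RIGHT)]):
            idx = np.flatnonzero((supers.labels == lab) & right_mask)
            sub_g = g[np.ix_(idx, idx)]
            local = np.arange(idx.size)
            seeds_local = _farthest_point_seeds(sub_g, local, spec.n_sub_regions, rng)
            sub_labels[idx] = _voronoi_assign(sub_g, seeds_local, local) + offset
            offset += spec.n_sub_regions
    return HierarchicalPartition((supers, relabel_canonical(sub_labels)))


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------


def noisy_partition(
    p: Partition, m: SurfaceMesh, noise_fraction: float, rng: np.random.Generator
) -> Partition:
    """Flip a fraction of vertices to the label of a random unlike mesh neighbor.

    Reads labels from the unperturbed partition, so flips are independent;
    vertices with no differently-labeled neighbor (parcel interiors) keep
    their label, concentrating the noise at region boundaries as in real
    segmentation jitter.
    """
    K = p.n_vertices
    labels = p.labels.copy()
    n_flip = int(round(noise_fraction * K))
    if n_flip == 0:
        return Partition(labels)
    adj = m.adjacency
    victims = rng.choice(K, size=n_flip, replace=False)
    for v in victims:
        nbrs = adj.indices[adj.indptr[v] : adj.indptr[v + 1]]
        other = np.unique(p.labels[nbrs])
        other = other[other != p.labels[v]]
        if other.size:
            labels[v] = rng.choice(other)
    return Partition(labels)


def _noisy_hierarchy(
    truth: HierarchicalPartition, m: SurfaceMesh, spec: CohortSpec, rng: np.random.Generator
) -> HierarchicalPartition:
    """Per-subject hierarchy: noise on the deepest level, parents follow."""
    deepest = truth.levels[-1]
    noisy = noisy_partition(deepest, m, spec.label_noise, rng)
    levels = []
    for lvl in truth.levels[:-1]:
        # map each deepest label to its planted parent at this level
        parent = np.zeros(int(deepest.labels.max()) + 1, dtype=np.int64)
        parent[deepest.labels] = lvl.labels
        levels.append(Partition(parent[noisy.labels]))
    levels.append(noisy)
    return HierarchicalPartition(tuple(levels))


def simulate_connectome(
    m: SurfaceMesh,
    hierarchy: HierarchicalPartition,
    spec: CohortSpec,
    subject_seed: int,
    subject_id: str = "",
) -> DenseConnectome:
    """Draw one subject's connectome from the block-intensity model.

    The subject's partition is the planted one with ``label_noise`` boundary
    flips; each unordered vertex pair gets a Poisson count with mean set by
    the deepest tier separating the pair (within-sub / within-super /
    between), then multiplied by lognormal noise with unit mean.
    """
    return simulate_subject(m, hierarchy, spec, subject_seed, subject_id)[0]


def simulate_subject(
    m: SurfaceMesh,
    hierarchy: HierarchicalPartition,
    spec: CohortSpec,
    subject_seed: int,
    subject_id: str = "",
) -> tuple[DenseConnectome, HierarchicalPartition]:
    if not hierarchy.is_nested():
        raise ValueError("planted hierarchy must be nested")
    rng = np.random.default_rng(subject_seed)
    subj = _noisy_hierarchy(hierarchy, m, spec, rng)
    sub = subj.levels[-1].labels
    sup = subj.levels[0].labels
    K = m.vertex_count
    same_sub = sub[:, None] == sub[None, :]
    same_sup = sup[:, None] == sup[None, :]
    mean = np.where(same_sub, spec.within_intensity, np.where(same_sup, spec.mid_intensity, spec.between_intensity))
    iu = np.triu_indices(K, 1)
    counts = rng.poisson(mean[iu]).astype(np.float64)
    if spec.edge_noise > 0:
        sigma = spec.edge_noise
        counts *= rng.lognormal(-sigma**2 / 2, sigma, size=counts.size)
    W = np.zeros((K, K))
    W[iu] = counts
    W = W + W.T
    return DenseConnectome(W, subject_id=subject_id or f"sub-{subject_seed}"), subj


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate N subjects sharing one planted hierarchy on one mesh."""
    m = icosphere(spec.mesh_order)
    truth = planted_hierarchy(m, spec)
    ss = np.random.SeedSequence(spec.seed)
    subject_seeds = [int(s >> 1) for s in ss.generate_state(spec.n_subjects)]
    connectomes, partitions = [], []
    for i, sd in enumerate(subject_seeds):
        w, subj = simulate_subject(m, truth, spec, sd, subject_id=f"sub-{i:03d}")
        connectomes.append(w)
        partitions.append(subj)
    manifest = {"spec": asdict(spec), "subject_seeds": subject_seeds}
    return Cohort(connectomes, truth, m, partitions, manifest)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort to disk: .mtx connectomes, PLY mesh, label TSVs, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_mesh(cohort.mesh, out / "mesh.ply")
    for i, lvl in enumerate(cohort.ground_truth.levels, start=1):
        save_labels(lvl, out / f"ground_truth_level{i}.tsv")
    for w in cohort.connectomes:
        save_connectome(w, out / f"{w.subject_id}.mtx")
    (out / "manifest.json").write_text(json.dumps(cohort.manifest, indent=2) + "\n")
    return out
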
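"""Subject-level parcellation by hierarchical modularity clustering.

A dense connectome is clustered by greedy modularity maximization (Louvain
multilevel); each resulting parcel is then re-clustered as an independent
graph, recursively, yielding a nested three-level hierarchy C^I, C^II, C^III.
Parcels holding fewer than a fixed fraction of all vertices (1% by default)
are never subdivided, which keeps regions from fragmenting into noise-scale
islands.  Coarsening block-sums the dense weights over region pairs, giving
the expected number of observed tracts between regions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np

from .core import CoarseConnectome, DenseConnectome, HierarchicalPartition, Partition, relabel_canonical

__all__ = [
    "ParcellationConfig",
    "modularity",
    "louvain_communities",
    "hierarchical_parcellation",
    "coarsen",
]


@dataclass(frozen=True)
class ParcellationConfig:
    """Settings for hierarchical parcellation.

    ``min_parcel_fraction`` is the subdivision floor: a parcel with fewer than
    ``min_parcel_fraction * K`` vertices is copied unchanged to deeper levels.
    """

    n_levels: int = 3
    min_parcel_fraction: float = 0.01
    random_seed: int = 0

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if not (0 <= self.min_parcel_fraction < 1):
            raise ValueError("min_parcel_fraction must be in [0, 1)")


def modularity(w: DenseConnectome | np.ndarray, c: Partition) -> float:
    """Newman modularity Q of partition ``c`` on weighted graph ``w``.

    Q = (1/m) sum_{u,v} (W_uv - d_u d_v / m) delta(c_u, c_v) with
    d_u = sum_v W_uv and m = sum_{u,v} W_uv over ordered pairs, so the
    one-community partition scores exactly 0 and Q is in [-1, 1].
    """
    W = w.weights if isinstance(w, DenseConnectome) else np.asarray(w, dtype=np.float64)
    labels = c.labels
    if labels.size != W.shape[0]:
        raise ValueError("partition must cover all vertices")
    m = float(W.sum())
    if m == 0:
        raise ValueError("modularity is undefined on an empty graph (m = 0)")
    d = W.sum(axis=1)
    q = 0.0
    for lab in np.unique(labels):
        idx = labels == lab
        w_in = float(W[np.ix_(idx, idx)].sum())  # ordered pairs within the block
        d_in = float(d[idx].sum())
        q += w_in / m - (d_in / m) ** 2
    return q


def _singleton_modularity(W: np.ndarray) -> float:
    m = float(W.sum())
    d = W.sum(axis=1)
    return float(np.trace(W) / m - np.sum(d**2) / m**2)


def louvain_communities(w: DenseConnectome | np.ndarray, seed: int = 0) -> Partition:
    """Multilevel greedy modularity maximization (Louvain), seeded.

    Node-visit order is randomized by ``seed`` (a seeded vertex permutation
    plus seeding of igraph's RNG); the same seed reproduces the same partition
    bit-exactly.  Isolated vertices each become their own community.  The
    delegated optimizer's result is validated against our own modularity: it
    must score at least as high as the all-singleton partition.
    """
    W = w.weights if isinstance(w, DenseConnectome) else np.asarray(w, dtype=np.float64)
    K = W.shape[0]
    if float(W.sum()) == 0:
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(K)
    Wp = W[np.ix_(perm, perm)]
    ig.set_random_number_generator(random.Random(int(seed)))
    g = ig.Graph.Weighted_Adjacency(Wp, mode="undirected", attr="weight", loops=False)
    clustering = g.community_multilevel(weights="weight")
    labels = np.empty(K, dtype=np.int64)
    labels[perm] = np.asarray(clustering.membership, dtype=np.int64)
    part = relabel_canonical(labels)
    q = modularity(W, part)
    q_singleton = _singleton_modularity(W)
    if q < q_singleton - 1e-12:
        raise RuntimeError(
            f"delegated Louvain result (Q={q:.6f}) scores below the "
            f"all-singleton partition (Q={q_singleton:.6f})"
        )
    return part


def _subseed(base: int, level: int, parcel: int) -> int:
    ss = np.random.SeedSequence([int(base) & 0x7FFFFFFF, level, parcel])
    return int(ss.generate_state(1)[0] >> 1)  # keep below 2**31


def hierarchical_parcellation(
    w: DenseConnectome, cfg: ParcellationConfig = ParcellationConfig()
) -> HierarchicalPartition:
    """Recursive Louvain clustering into nested levels C^I..C^{n_levels}.

    Level 1 clusters the full graph; each deeper level re-clusters every
    parcel's induced subgraph independently (edges leaving the parcel are
    dropped).  Parcels below the minimum-size floor, or whose induced subgraph
    has no edges, are copied unchanged.  Output levels are nested refinements
    by construction.
    """
    K = w.n_vertices
    min_size = cfg.min_parcel_fraction * K
    levels = [louvain_communities(w, seed=cfg.random_seed)]
    for lvl in range(1, cfg.n_levels):
        prev = levels[-1]
        new_labels = np.empty(K, dtype=np.int64)
        offset = 0
        for lab in prev.region_labels():
            idx = prev.region(lab)
            sub = w.weights[np.ix_(idx, idx)]
            if idx.size < min_size or float(sub.sum()) == 0:
                new_labels[idx] = offset  # too small or edgeless: copy unchanged
                offset += 1
                continue
            sub_part = louvain_communities(sub, seed=_subseed(cfg.random_seed, lvl, int(lab)))
            new_labels[idx] = sub_part.labels + offset
            offset += sub_part.n_regions
        levels.append(relabel_canonical(new_labels))
    return HierarchicalPartition(tuple(levels))


def coarsen(w: DenseConnectome, c: Partition) -> CoarseConnectome:
    """Block-sum the dense weights over region pairs.

    ``omega[a, b] = sum_{u in E_a} sum_{v in E_b} W_uv``; total mass is
    conserved exactly.  Region order follows canonical label order.
    """
    if c.n_vertices != w.n_vertices:
        raise ValueError("partition must cover all vertices")
    canon = relabel_canonical(c)
    L = canon.n_regions
    P = np.zeros((w.n_vertices, L))
    P[np.arange(w.n_vertices), canon.labels] = 1.0
    omega = P.T @ w.weights @ P
    omega = (omega + omega.T) / 2  # enforce exact symmetry against float drift
    sizes = np.bincount(canon.labels, minlength=L)
    return CoarseConnectome(omega, sizes)
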
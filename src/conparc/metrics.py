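"""Parcellation quality metrics.

Covers (1) fidelity of the piecewise-constant connectome approximation via KL
divergence on edge-weight distributions, (2) partition agreement via mutual
information adjusted for chance under the permutation model (AMImax),
(3) minimal-cover Dice overlap against anatomical regions, (4) hemispheric
symmetry and spatial contiguity on the mesh, (5) weighted graph
characteristics (clustering coefficient, average path length) of the coarse
connectome, and (6) ensemble goodness (mean AMI of a consensus to the
individual partitions it aggregates).

All partition metrics are invariant to relabeling and to consistent vertex
reordering.  Natural logarithms are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln

from .core import (
    LEFT,
    CoarseConnectome,
    DenseConnectome,
    Partition,
    SurfaceMesh,
    relabel_canonical,
)
from .parcellation import coarsen

__all__ = [
    "ContingencyTable",
    "MetricsReport",
    "piecewise_constant",
    "kl_divergence",
    "mutual_information",
    "expected_mi",
    "ami",
    "dice_min_cover",
    "hemispheric_symmetry",
    "contiguity",
    "graph_characteristics",
    "ensemble_goodness",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of two partitions: counts[i, j] = |X_i ∩ Y_j|."""

    counts: np.ndarray
    total: int

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or np.any(c < 0):
            raise ValueError("counts must be a nonnegative 2-D table")
        if int(c.sum()) != self.total:
            raise ValueError("table must sum to the vertex count")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_partitions(cls, x: Partition, y: Partition) -> "ContingencyTable":
        if x.n_vertices != y.n_vertices:
            raise ValueError("partitions must cover the same vertex set")
        a = relabel_canonical(x).labels
        b = relabel_canonical(y).labels
        t = np.zeros((int(a.max()) + 1, int(b.max()) + 1), dtype=np.int64)
        np.add.at(t, (a, b), 1)
        return cls(t, x.n_vertices)

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class MetricsReport:
    """Named scalar metrics with their parameters and provenance."""

    values: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def record(self, name: str, value: float) -> None:
        v = float(value)
        if not np.isfinite(v):
            raise ValueError(f"metric {name!r} is not finite: {v}")
        self.values[name] = v

    def to_dict(self) -> dict:
        return {"values": dict(self.values), "params": dict(self.params)}


# ---------------------------------------------------------------------------
# Connectome-approximation fidelity
# ---------------------------------------------------------------------------


def piecewise_constant(w: DenseConnectome, c: Partition) -> np.ndarray:
    """Block-constant approximation gamma of the dense connectome.

    gamma[u, v] = omega(E_i, E_j) / (|E_i| |E_j|) for u in E_i, v in E_j,
    where omega is the coarse block sum and |E| are region vertex counts —
    the block mean of the dense weights.
    """
    canon = relabel_canonical(c)
    cc = coarsen(w, canon)
    sizes = cc.region_sizes.astype(np.float64)
    block = cc.omega / np.outer(sizes, sizes)
    return block[np.ix_(canon.labels, canon.labels)]


def kl_divergence(w: DenseConnectome | np.ndarray, gamma: np.ndarray) -> float:
    """KL divergence between the dense weights and their block approximation.

    Both arrays are restricted to off-diagonal unordered vertex pairs and
    normalized to probability distributions; KL(lambda || gamma) with the
    convention 0 log 0 = 0.  Zero iff the dense matrix is block-constant on
    the partition the approximation was built from.
    """
    W = w.weights if isinstance(w, DenseConnectome) else np.asarray(w, dtype=np.float64)
    if W.shape != gamma.shape:
        raise ValueError("shape mismatch between connectome and approximation")
    iu = np.triu_indices(W.shape[0], 1)
    lam = W[iu]
    g = np.asarray(gamma)[iu]
    if np.any((g <= 0) & (lam > 0)):
        raise ValueError("approximation is zero at a pair with positive weight")
    lam_hat = lam / lam.sum()
    g_hat = g / g.sum()
    mask = lam_hat > 0
    return float(np.sum(lam_hat[mask] * np.log(lam_hat[mask] / g_hat[mask])))


# ---------------------------------------------------------------------------
# Partition agreement: MI / expected MI / AMImax
# ---------------------------------------------------------------------------


def _entropy(marginals: np.ndarray, total: int) -> float:
    p = marginals[marginals > 0] / total
    return float(-np.sum(p * np.log(p)))


def mutual_information(
    x: Partition, y: Partition
) -> tuple[float, float, float, ContingencyTable]:
    """MI(X, Y) in nats, plus the entropies H(X), H(Y) and the table."""
    t = ContingencyTable.from_partitions(x, y)
    K = t.total
    pij = t.counts / K
    pi = t.row_marginals / K
    pj = t.col_marginals / K
    mask = pij > 0
    outer = np.outer(pi, pj)
    mi = float(np.sum(pij[mask] * np.log(pij[mask] / outer[mask])))
    return mi, _entropy(t.row_marginals, K), _entropy(t.col_marginals, K), t


def expected_mi(
    row_marginals: Sequence[int], col_marginals: Sequence[int], n: int
) -> float:
    """Expected MI under the fixed-marginal permutation (hypergeometric) model.

    For each cluster pair (a_i, b_j) the overlap n_ij follows a hypergeometric
    distribution; the expectation sums n_ij/n * log(n n_ij / (a_i b_j))
    weighted by the hypergeometric pmf, evaluated in log space for stability.
    """
    a = np.asarray(row_marginals, dtype=np.int64)
    b = np.asarray(col_marginals, dtype=np.int64)
    a = a[a > 0]
    b = b[b > 0]
    if int(a.sum()) != n or int(b.sum()) != n:
        raise ValueError("marginals must sum to the vertex count")
    log_n = np.log(n)
    emi = 0.0
    for ai in a:
        # terms shared across the inner loop
        base_i = gammaln(ai + 1) + gammaln(n - ai + 1) - gammaln(n + 1)
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1, dtype=np.float64)
            log_pmf = (
                base_i
                + gammaln(bj + 1)
                + gammaln(n - bj + 1)
                - gammaln(nij + 1)
                - gammaln(ai - nij + 1)
                - gammaln(bj - nij + 1)
                - gammaln(n - ai - bj + nij + 1)
            )
            term = (nij / n) * (log_n + np.log(nij) - np.log(float(ai) * float(bj)))
            emi += float(np.sum(term * np.exp(log_pmf)))
    return emi


def ami(x: Partition, y: Partition) -> float:
    """AMImax: (MI - E[MI]) / (max(H(X), H(Y)) - E[MI]).

    Equals exactly 1 on equivalent (relabeled) partitions, is symmetric and
    relabeling-invariant, and is close to 0 for independent partitions.
    """
    if x.n_vertices != y.n_vertices:
        raise ValueError("partitions must cover the same vertex set")
    if x.is_equivalent_to(y):
        return 1.0
    mi, hx, hy, t = mutual_information(x, y)
    emi = expected_mi(t.row_marginals, t.col_marginals, t.total)
    denom = max(hx, hy) - emi
    if abs(denom) < 1e-15:
        return 0.0
    return (mi - emi) / denom


# ---------------------------------------------------------------------------
# Overlap, symmetry, contiguity
# ---------------------------------------------------------------------------


def dice_min_cover(x_region: Sequence[int] | np.ndarray, y: Partition) -> float:
    """Dice overlap between a region X and its minimal cover in partition y.

    The minimal cover Y* is the union of all regions of ``y`` intersecting X
    (for a partition this is the unique minimal union containing X), so
    Dice = 2|X| / (|X| + |Y*|).
    """
    x = np.unique(np.asarray(x_region, dtype=np.int64))
    if x.size == 0:
        raise ValueError("region must be nonempty")
    if x.min() < 0 or x.max() >= y.n_vertices:
        raise ValueError("region vertex index out of range")
    cover_labels = np.unique(y.labels[x])
    cover_size = int(np.isin(y.labels, cover_labels).sum())
    return 2.0 * x.size / (x.size + cover_size)


def hemispheric_symmetry(c: Partition, m: SurfaceMesh) -> float:
    """AMI between left-hemisphere labels and the labels of their mirrors."""
    if c.n_vertices != m.vertex_count:
        raise ValueError("partition must cover the mesh")
    left = m.vertices_of(LEFT)
    x = relabel_canonical(c.labels[left])
    y = relabel_canonical(c.labels[m.mirror_map[left]])
    return ami(x, y)


def contiguity(c: Partition, m: SurfaceMesh) -> float:
    """Fraction of vertices whose parcel is one connected patch on the mesh."""
    if c.n_vertices != m.vertex_count:
        raise ValueError("partition must cover the mesh")
    adj = m.adjacency
    good = 0
    for lab in c.region_labels():
        idx = c.region(lab)
        n_comp, _ = connected_components(adj[np.ix_(idx, idx)], directed=False)
        if n_comp == 1:
            good += idx.size
    return good / c.n_vertices


# ---------------------------------------------------------------------------
# Coarse-graph characteristics
# ---------------------------------------------------------------------------


def graph_characteristics(cc: CoarseConnectome) -> tuple[float, float]:
    """Weighted clustering coefficient and average path length.

    CC is the mean over nodes of the geometric-mean triangle intensity
    (Onnela form) with weights rescaled by the maximum weight; APL is the
    mean shortest-path length over connected unordered node pairs with edge
    length 1/weight.
    """
    L = cc.n_regions
    if L < 3:
        raise ValueError("clustering coefficient needs at least 3 nodes")
    W = cc.omega.copy()
    np.fill_diagonal(W, 0.0)
    G = nx.from_numpy_array(W)
    clustering = nx.clustering(G, weight="weight")  # Onnela: weights / max weight
    cc_mean = float(np.mean(list(clustering.values())))
    for u, v, d in G.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    total, n_pairs = 0.0, 0
    for u, dists in nx.all_pairs_dijkstra_path_length(G, weight="length"):
        for v, dist in dists.items():
            if v > u:
                total += dist
                n_pairs += 1
    apl = total / n_pairs if n_pairs else float("inf")
    return cc_mean, float(apl)


def ensemble_goodness(c_star: Partition, cohort: Sequence[Partition]) -> float:
    """Mean AMI between a consensus partition and each individual partition."""
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    return float(np.mean([ami(c, c_star) for c in cohort]))
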
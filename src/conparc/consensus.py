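"""Label-correspondence-free consensus over cohorts of partitions.

Individual connectome parcellations carry arbitrary region labels, so a
consensus cannot average label vectors directly.  Partitions are encoded as
binary membership matrices P (one row per vertex, one column per region),
defined up to column permutation; the distance between two partitions is the
squared Frobenius difference of their membership matrices minimized over
column permutations, solved exactly by linear assignment.  The consensus is
the (pseudo-)Karcher mean — the partition minimizing the summed distance to
the cohort — approximated greedily by the hard-ensemble (HE) algorithm:
successively permutation-align each subject's membership matrix to the
running soft average, update the running mean with weights (t-1):1, and
finally harden by per-row argmax.

Two aggregate-graph baselines are provided: CSPA (cluster the vertex
co-occurrence matrix) and average-graph clustering (cluster the mean
connectome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import DenseConnectome, HierarchicalPartition, Partition, relabel_canonical
from .parcellation import ParcellationConfig, hierarchical_parcellation

__all__ = [
    "MembershipMatrix",
    "EnsembleState",
    "membership_matrix",
    "partition_distance",
    "karcher_objective",
    "hard_ensemble",
    "cooccurrence",
    "cspa",
    "average_graph_parcellation",
]


@dataclass
class MembershipMatrix:
    """K x L membership encoding of a partition.

    Hard matrices are binary with exactly one nonzero per row; soft matrices
    (HE running averages) are row-stochastic.
    """

    entries: np.ndarray
    hard: bool = True

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=np.float64)
        if e.ndim != 2:
            raise ValueError("membership matrix must be 2-D")
        if np.any(e < 0):
            raise ValueError("membership entries must be nonnegative")
        if self.hard and not np.all(np.isin(e, [0.0, 1.0])):
            raise ValueError("hard membership matrix must be binary")
        if not np.allclose(e.sum(axis=1), 1.0):
            raise ValueError("membership rows must sum to 1")
        self.entries = e

    @property
    def n_vertices(self) -> int:
        return self.entries.shape[0]

    @property
    def n_columns(self) -> int:
        return self.entries.shape[1]

    def padded(self, L: int) -> np.ndarray:
        """Entries zero-padded on the right to L columns."""
        if L < self.n_columns:
            raise ValueError("cannot pad to fewer columns")
        out = np.zeros((self.n_vertices, L))
        out[:, : self.n_columns] = self.entries
        return out


def membership_matrix(c: Partition, L: int | None = None) -> MembershipMatrix:
    """Binary K x L membership matrix of a partition (canonical labels).

    Columns beyond the partition's region count are all-zero padding.
    """
    canon = relabel_canonical(c)
    n = canon.n_regions
    if L is None:
        L = n
    if L < n:
        raise ValueError(f"L={L} is smaller than the number of regions ({n})")
    P = np.zeros((canon.n_vertices, L))
    P[np.arange(canon.n_vertices), canon.labels] = 1.0
    return MembershipMatrix(P, hard=True)


def _contingency(ci: Partition, cj: Partition) -> np.ndarray:
    a = relabel_canonical(ci).labels
    b = relabel_canonical(cj).labels
    La, Lb = int(a.max()) + 1, int(b.max()) + 1
    t = np.zeros((La, Lb), dtype=np.int64)
    np.add.at(t, (a, b), 1)
    return t


def partition_distance(ci: Partition, cj: Partition) -> float:
    """Permutation-minimal squared membership distance between two partitions.

    min over column permutations pi of ||P_i - P_j pi||_F^2, with both
    matrices zero-padded to the larger column count.  For hard partitions
    ||P||_F^2 = K, so the minimum equals 2K - 2 * (maximal assignment over the
    contingency-overlap matrix), solved exactly by the Hungarian algorithm.
    Zero iff the partitions are equivalent up to relabeling; symmetric.
    """
    if ci.n_vertices != cj.n_vertices:
        raise ValueError("partitions must cover the same vertex set")
    K = ci.n_vertices
    t = _contingency(ci, cj)
    L = max(t.shape)
    cost = np.zeros((L, L))
    cost[: t.shape[0], : t.shape[1]] = t
    rows, cols = linear_sum_assignment(-cost)
    overlap = float(cost[rows, cols].sum())
    return 2.0 * K - 2.0 * overlap


def karcher_objective(c_star: Partition, cohort: Sequence[Partition]) -> float:
    """Summed partition distance from ``c_star`` to every cohort member.

    The (pseudo-)Karcher mean is the partition minimizing this objective;
    it is invariant to relabeling of any argument and to cohort order.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    return float(sum(partition_distance(c_star, c) for c in cohort))


class EnsembleState:
    """Running soft membership average over successively absorbed partitions."""

    def __init__(self, first: Partition):
        self._running = membership_matrix(first).entries
        self.n_absorbed = 1

    @property
    def running_membership(self) -> MembershipMatrix:
        return MembershipMatrix(self._running, hard=False)

    def absorb(self, c: Partition) -> None:
        """Align ``c`` to the running average and fold it into the mean.

        Both matrices are zero-padded to the larger column count; the column
        permutation maximizing the overlap with the running average (the same
        assignment solve as the partition distance) is applied to the new
        member before the (t-1):1 weighted-mean update.
        """
        P = membership_matrix(c).entries
        L = max(self._running.shape[1], P.shape[1])
        R = np.zeros((self._running.shape[0], L))
        R[:, : self._running.shape[1]] = self._running
        Q = np.zeros((P.shape[0], L))
        Q[:, : P.shape[1]] = P
        overlap = R.T @ Q
        rows, cols = linear_sum_assignment(-overlap)
        aligned = np.zeros_like(Q)
        aligned[:, rows] = Q[:, cols]
        t = self.n_absorbed + 1
        self._running = ((t - 1) * R + aligned) / t
        self.n_absorbed = t

    def harden(self) -> Partition:
        """Per-row argmax (ties break to the lower column index), canonicalized."""
        labels = np.argmax(self._running, axis=1)
        return relabel_canonical(labels)


def hard_ensemble(cohort: Sequence[Partition], order_seed: int | None = None) -> Partition:
    """Hard-ensemble consensus: greedy successive averaging of memberships.

    Partitions are absorbed in input order, or in an order shuffled by
    ``order_seed`` when given (the procedure is order-dependent).  The result
    approximately minimizes the Karcher objective over the cohort.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    K = cohort[0].n_vertices
    if any(c.n_vertices != K for c in cohort):
        raise ValueError("all partitions must cover the same vertex set")
    order = list(range(len(cohort)))
    if order_seed is not None:
        np.random.default_rng(order_seed).shuffle(order)
    state = EnsembleState(cohort[order[0]])
    for i in order[1:]:
        state.absorb(cohort[i])
    return state.harden()


def cooccurrence(cohort: Sequence[Partition]) -> np.ndarray:
    """K x K co-occurrence counts: S[a, b] = #partitions with c(a) == c(b)."""
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    K = cohort[0].n_vertices
    S = np.zeros((K, K))
    for c in cohort:
        if c.n_vertices != K:
            raise ValueError("all partitions must cover the same vertex set")
        P = membership_matrix(c).entries
        S += P @ P.T
    return S


def cspa(
    cohort: Sequence[Partition], cfg: ParcellationConfig = ParcellationConfig()
) -> HierarchicalPartition:
    """Cluster-based similarity partitioning: cluster the co-occurrence graph.

    The co-occurrence matrix S (diagonal zeroed) is treated as a dense
    weighted graph and clustered with the same three-level Louvain hierarchy
    used for individual connectomes; S is not thresholded.
    """
    S = cooccurrence(cohort)
    np.fill_diagonal(S, 0.0)
    return hierarchical_parcellation(DenseConnectome(S, subject_id="cspa"), cfg)


def average_graph_parcellation(
    cohort: Sequence[DenseConnectome], cfg: ParcellationConfig = ParcellationConfig()
) -> HierarchicalPartition:
    """Cluster the mean connectome W* = (1/N) sum_i W_i hierarchically."""
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    K = cohort[0].n_vertices
    if any(w.n_vertices != K for w in cohort):
        raise ValueError("all connectomes must share the same vertex set")
    mean = np.mean([w.weights for w in cohort], axis=0)
    return hierarchical_parcellation(DenseConnectome(mean, subject_id="average"), cfg)
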
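"""Experimental harness: sparsity sweep, stability studies, classification.

Implements the evaluation protocol around the consensus methods: a sweep over
network sparsity levels (keeping the heaviest 10%..100% of edges), split-half
stability (ensembles of random half-cohorts compared pairwise by AMI),
order-permutation stability of the order-dependent hard-ensemble procedure,
minimal-cover overlap against an anatomical labeling, and a bilevel k-fold
L1-logistic classification of a binary phenotype from coarse edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .consensus import average_graph_parcellation, cspa, hard_ensemble
from .core import DenseConnectome, HierarchicalPartition, Partition, SurfaceMesh, sparsify
from .metrics import (
    MetricsReport,
    ami,
    contiguity,
    dice_min_cover,
    ensemble_goodness,
    graph_characteristics,
    hemispheric_symmetry,
    kl_divergence,
    piecewise_constant,
)
from .parcellation import ParcellationConfig, coarsen, hierarchical_parcellation

__all__ = [
    "ExperimentConfig",
    "sparsity_sweep",
    "split_half_stability",
    "order_permutation_stability",
    "classification_eval",
    "atlas_overlap_report",
]

_DEFAULT_SPARSITY = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid and seeds for the evaluation harness."""

    sparsity_levels: tuple[float, ...] = _DEFAULT_SPARSITY
    n_splits: int = 100
    n_order_perms: int = 100
    methods: tuple[str, ...] = ("HE", "CSPA", "Average")
    levels: tuple[int, ...] = (1, 2, 3)
    seed: int = 0

    def __post_init__(self):
        if any(not (0 < q <= 1) for q in self.sparsity_levels):
            raise ValueError("sparsity levels must be in (0, 1]")
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        unknown = set(self.methods) - {"HE", "CSPA", "Average"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def _pairwise_ami(partitions: Sequence[Partition]) -> np.ndarray:
    return np.array([ami(a, b) for a, b in combinations(partitions, 2)])


def _consensus_partitions(
    indiv: Sequence[HierarchicalPartition],
    sparsified: Sequence[DenseConnectome],
    method: str,
    levels: Sequence[int],
    pcfg: ParcellationConfig,
) -> dict[int, Partition]:
    """One consensus partition per requested hierarchy level for a method."""
    if method == "HE":
        # each level's individual partitions are ensembled separately
        return {lvl: hard_ensemble([h.level(lvl) for h in indiv]) for lvl in levels}
    if method == "CSPA":
        hp = cspa([h.levels[-1] for h in indiv], pcfg)
        return {lvl: hp.level(min(lvl, hp.n_levels)) for lvl in levels}
    if method == "Average":
        hp = average_graph_parcellation(sparsified, pcfg)
        return {lvl: hp.level(min(lvl, hp.n_levels)) for lvl in levels}
    raise ValueError(f"unknown method {method!r}")


def sparsity_sweep(
    cohort: Sequence[DenseConnectome],
    cfg: ExperimentConfig = ExperimentConfig(),
    mesh: SurfaceMesh | None = None,
) -> dict:
    """Run every consensus method across the sparsity grid and score it.

    For each sparsity level and (method, level) cell the report records the
    number of regions, mean KL fidelity over subjects, ensemble goodness,
    hemispheric symmetry and contiguity (when a mesh is given), and weighted
    CC/APL of per-subject coarse graphs.  The summary adds intramethod
    similarity: the mean pairwise AMI of each method's partitions across
    sparsity levels.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    n_levels = max(cfg.levels)
    reports: list[dict] = []
    by_cell: dict[tuple[str, int], list[Partition]] = {}
    for qi, q in enumerate(cfg.sparsity_levels):
        sparsified = [sparsify(w, q) for w in cohort]
        pcfg = ParcellationConfig(n_levels=n_levels, random_seed=cfg.seed)
        indiv = [hierarchical_parcellation(w, pcfg) for w in sparsified]
        for method in cfg.methods:
            parts = _consensus_partitions(indiv, sparsified, method, cfg.levels, pcfg)
            for lvl, part in parts.items():
                by_cell.setdefault((method, lvl), []).append(part)
                rep = MetricsReport(
                    params={
                        "method": method,
                        "level": lvl,
                        "sparsity": float(q),
                        "seed": cfg.seed,
                        "cc_apl_definition": "weighted Onnela CC / Dijkstra APL (length=1/weight)",
                    }
                )
                rep.record("n_regions", part.n_regions)
                rep.record(
                    "kl_mean",
                    float(np.mean([kl_divergence(w, piecewise_constant(w, part)) for w in sparsified])),
                )
                rep.record("goodness", ensemble_goodness(part, [h.level(lvl) for h in indiv]))
                if mesh is not None:
                    rep.record("symmetry", hemispheric_symmetry(part, mesh))
                    rep.record("contiguity", contiguity(part, mesh))
                if part.n_regions >= 3:
                    chars = [graph_characteristics(coarsen(w, part)) for w in sparsified]
                    rep.record("cc_mean", float(np.mean([c for c, _ in chars])))
                    rep.record("apl_mean", float(np.mean([a for _, a in chars])))
                reports.append(rep.to_dict())
    intramethod = {
        f"{method}{lvl}": float(np.mean(_pairwise_ami(parts))) if len(parts) > 1 else 1.0
        for (method, lvl), parts in by_cell.items()
    }
    return {"schema_version": 1, "reports": reports, "intramethod_similarity": intramethod}


def split_half_stability(
    cohort: Sequence[Partition], cfg: ExperimentConfig = ExperimentConfig()
) -> np.ndarray:
    """Pairwise AMI between ensembles of random disjoint half-cohorts.

    Draws ``n_splits`` random halves (without replacement), ensembles each,
    and returns all n_splits*(n_splits-1)/2 unordered pairwise AMI values.
    """
    N = len(cohort)
    if N < 4:
        raise ValueError("split-half stability needs at least 4 subjects")
    rng = np.random.default_rng(cfg.seed)
    ensembles = []
    for _ in range(cfg.n_splits):
        half = rng.choice(N, size=N // 2, replace=False)
        ensembles.append(hard_ensemble([cohort[i] for i in half]))
    return _pairwise_ami(ensembles)


def order_permutation_stability(
    cohort: Sequence[Partition], cfg: ExperimentConfig = ExperimentConfig()
) -> np.ndarray:
    """Pairwise AMI between HE runs that absorb subjects in shuffled orders."""
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects")
    ss = np.random.SeedSequence(cfg.seed)
    order_seeds = [int(s >> 1) for s in ss.generate_state(cfg.n_order_perms)]
    ensembles = [hard_ensemble(cohort, order_seed=sd) for sd in order_seeds]
    return _pairwise_ami(ensembles)


def classification_eval(
    cohort: Sequence[DenseConnectome],
    labels: Sequence[int],
    cfg: ExperimentConfig = ExperimentConfig(),
    n_levels: int = 3,
) -> dict:
    """Bilevel k-fold L1-logistic classification from coarse edge weights.

    One half of the subjects (stratified) drives the consensus parcellation
    (individual hierarchical parcellations, HE at the deepest level); the
    fixed consensus is then applied to the held-out half via coarsening, and
    the upper-triangle coarse weights (within-region mass included) are the
    features.  Outer 5-fold stratified CV yields the AUC distribution; inner
    5-fold CV selects the L1 penalty on a logarithmic grid; features are
    standardized on training folds only.
    """
    y = np.asarray(labels)
    if len(cohort) != y.size:
        raise ValueError("one label per subject required")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary labels required")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 subjects per class")
    rng = np.random.default_rng(cfg.seed)
    # stratified half split: consensus half vs evaluation half
    fit_idx, eval_idx = [], []
    for c in classes:
        idx = rng.permutation(np.flatnonzero(y == c))
        fit_idx.extend(idx[: len(idx) // 2])
        eval_idx.extend(idx[len(idx) // 2 :])
    fit_idx, eval_idx = np.sort(fit_idx), np.sort(eval_idx)

    pcfg = ParcellationConfig(n_levels=n_levels, random_seed=cfg.seed)
    indiv = [hierarchical_parcellation(cohort[i], pcfg) for i in fit_idx]
    consensus = hard_ensemble([h.levels[-1] for h in indiv])

    L = consensus.n_regions
    iu = np.triu_indices(L, 0)  # within-region mass on the diagonal included
    X = np.array([coarsen(cohort[i], consensus).omega[iu] for i in eval_idx])
    y_eval = y[eval_idx]

    Cs = np.logspace(-2, 2, 10)
    outer = StratifiedKFold(n_splits=5, shuffle=True, random_state=int(cfg.seed) % (2**31))
    aucs = []
    for train, test in outer.split(X, y_eval):
        pipe = make_pipeline(
            StandardScaler(),
            LogisticRegressionCV(
                Cs=Cs, cv=5, penalty="l1", solver="liblinear",
                scoring="roc_auc", max_iter=2000,
                random_state=int(cfg.seed) % (2**31),
            ),
        )
        pipe.fit(X[train], y_eval[train])
        score = pipe.predict_proba(X[test])[:, 1]
        aucs.append(float(roc_auc_score(y_eval[test], score)))
    return {
        "aucs": aucs,
        "n_regions": L,
        "n_features": int(iu[0].size),
        "penalty_grid": [float(c) for c in Cs],
        "n_fit_subjects": int(fit_idx.size),
        "n_eval_subjects": int(eval_idx.size),
        "seed": cfg.seed,
    }


def atlas_overlap_report(anatomical: Partition, ensemble: Partition) -> pd.DataFrame:
    """Minimal-cover Dice of every anatomical region, sorted descending."""
    if anatomical.n_vertices != ensemble.n_vertices:
        raise ValueError("partitions must cover the same vertex set")
    rows = []
    for lab in anatomical.region_labels():
        region = anatomical.region(lab)
        cover_labels = np.unique(ensemble.labels[region])
        rows.append(
            {
                "region": int(lab),
                "size": int(region.size),
                "n_cover_regions": int(cover_labels.size),
                "dice": dice_min_cover(region, ensemble),
            }
        )
    df = pd.DataFrame(rows).sort_values("dice", ascending=False).reset_index(drop=True)
    return df
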
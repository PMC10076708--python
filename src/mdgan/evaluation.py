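"""Cross-validated evaluation of association scorers.

Known associations are split into k balanced folds.  For each fold the test
positives are zeroed out of the training matrix, every similarity view and
the heterogeneous network are recomputed from the masked matrix (so no test
edge can leak into the features), the model is trained, and the held-out
positives are scored against all unknown pairs.  Unknown pairs serve as the
negative class throughout — there are no experimentally verified negative
associations in this setting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import roc_curve as _sk_roc_curve

from .data import AssociationMatrix, DiseaseDAG, DiseaseGeneAnnotation, GeneNetwork
from .model import DegreeProductBaseline, GANLinkPredictor, ScoreMatrix
from .similarity import build_heterogeneous_network, integrated_similarities


@dataclass
class FoldPlan:
    """Balanced random partition of the known-positive cells into k folds."""

    k: int
    positives: list[tuple[int, int]]
    assignments: np.ndarray
    seed: int

    def fold_positives(self, fold: int) -> list[tuple[int, int]]:
        return [p for p, a in zip(self.positives, self.assignments) if a == fold]


@dataclass
class ROCCurve:
    """Threshold sweep of TPR/FPR plus the trapezoidal area under it."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class CVReport:
    """Per-fold AUCs with aggregate statistics and the configuration echo."""

    fold_aucs: list[float]
    curves: list[ROCCurve]
    config: dict
    failed_folds: list[int] = field(default_factory=list)
    ranked: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.fold_aucs))


def make_folds(am: AssociationMatrix, k: int, seed: int) -> FoldPlan:
    """Randomly partition the positive cells into k folds of near-equal size."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ii, jj = np.nonzero(am.A)
    positives = list(zip(ii.tolist(), jj.tolist()))
    if len(positives) < k:
        raise ValueError(f"k={k} exceeds the {len(positives)} known positives")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    assignments = np.empty(len(positives), dtype=int)
    assignments[order] = np.arange(len(positives)) % k
    return FoldPlan(k, positives, assignments, seed)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC curve by threshold sweep and its trapezoidal area.

    Tied scores share a threshold, so the trapezoidal area equals the
    tie-corrected Mann-Whitney rank statistic.  Requires both classes.
    """
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thr, fpr, tpr, area)


def degree_baseline(am: AssociationMatrix) -> ScoreMatrix:
    """Degree-product scores on the training matrix (sanity baseline)."""
    return DegreeProductBaseline().fit(am).scores_


def _mask_fold(am: AssociationMatrix, cells: Sequence[tuple[int, int]]) -> AssociationMatrix:
    masked = am.copy()
    for i, j in cells:
        masked.A[i, j] = 0.0
    return masked


def run_cv(
    am: AssociationMatrix,
    estimator: GANLinkPredictor | DegreeProductBaseline | None = None,
    k: int = 5,
    seed: int = 0,
    gene_net: GeneNetwork | None = None,
    annotations: DiseaseGeneAnnotation | None = None,
    dag: DiseaseDAG | None = None,
    scorer: Callable[[AssociationMatrix], np.ndarray] | None = None,
    static_similarity: bool = False,
) -> CVReport:
    """k-fold cross-validation of an association scorer.

    Each fold trains on the masked matrix and scores its held-out positives
    against every pair that is unknown in the *full* matrix; positives kept
    in the training fold are excluded from test scoring.  Similarities are
    recomputed per fold from the masked matrix unless ``static_similarity``
    deliberately reuses the full-matrix similarities (the leaky variant,
    kept for comparison only).

    ``scorer`` overrides model training with a direct scoring function of
    the masked training matrix — used for evaluation controls such as the
    leakage canary (score with the training matrix itself) or the cheat
    oracle (score with the held-out truth).
    """
    plan = make_folds(am, k, seed)
    fold_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(k) % (2**31)]
    negatives = am.A == 0.0
    if static_similarity:
        static_DS, static_MS = integrated_similarities(am, gene_net, annotations, dag)

    fold_aucs: list[float] = []
    curves: list[ROCCurve] = []
    failed: list[int] = []
    for fold in range(k):
        test_cells = plan.fold_positives(fold)
        train_am = _mask_fold(am, test_cells)
        try:
            if scorer is not None:
                S = np.asarray(scorer(train_am), float)
            else:
                est = clone(estimator) if estimator is not None else GANLinkPredictor()
                if hasattr(est, "random_state"):
                    est.set_params(random_state=fold_seeds[fold])
                if static_similarity:
                    DS, MS = static_DS, static_MS
                else:
                    DS, MS = integrated_similarities(train_am, gene_net, annotations, dag)
                est.fit(train_am, DS, MS)
                S = est.scores_.S
        except (FloatingPointError, ValueError) as exc:  # pragma: no cover
            warnings.warn(f"fold {fold} failed: {exc}; aggregating over remaining folds")
            failed.append(fold)
            continue
        test_mask = np.zeros_like(am.A, dtype=bool)
        for i, j in test_cells:
            test_mask[i, j] = True
        eval_mask = test_mask | negatives
        labels = test_mask[eval_mask].astype(int)
        curve = roc_auc(S[eval_mask], labels)
        fold_aucs.append(curve.auc)
        curves.append(curve)
    config = {
        "k": k,
        "seed": seed,
        "static_similarity": static_similarity,
        "estimator": (estimator.get_params() if estimator is not None else None),
        "scorer": getattr(scorer, "__name__", None) if scorer else None,
    }
    return CVReport(fold_aucs, curves, config, failed)


def rank_candidates(
    scores: ScoreMatrix,
    am: AssociationMatrix,
    disease: str,
    top_k: int = 20,
) -> list[tuple[str, float]]:
    """Top-k unknown microbes for one disease, by descending score.

    Known positives are filtered out; ties break lexicographically by
    microbe identifier so rankings are stable across runs.
    """
    i = am.disease_index(disease)
    candidates = [
        (am.microbes[j], float(scores.S[i, j]))
        for j in range(am.nm)
        if am.A[i, j] == 0.0
    ]
    if not candidates:
        warnings.warn(f"disease {disease!r} has no unknown pairs to rank")
        return []
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return candidates[:top_k]
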
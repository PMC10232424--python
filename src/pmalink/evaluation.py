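"""Cross-validation, metrics, and case-study ranking.

The CV protocol partitions the known positives into k folds.  In the default
``masked`` leakage mode, each fold's training adjacency matrix has the test
positives zeroed *before* the interaction-profile kernels and the fusion are
computed, so no test association can leak into the features.  The
``full-matrix`` mode computes kernels from the complete matrix once, which
matches the apparent protocol of most published association predictors and
yields optimistic estimates.

Metrics: precision, sensitivity, accuracy, F1, MCC from the strict >0.5
soft-vote labels, plus threshold-free AUC (ROC) and AUPR (trapezoidal area
under the precision-recall curve).  Ratios with zero denominators are
reported as NaN, never silently as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_auc_score

from .data import AssociationMatrix, DatasetBundle
from .ensemble import (
    LearnerConfig,
    member_scores,
    predict_pairs,
    sample_training_subsets,
    train_ensemble,
)
from .fusion import FusedSimilarity, FusionConfig, skf_fuse
from .kernels import (
    SimilarityMatrix,
    cosine_similarity,
    expression_similarity,
    functional_similarity,
    gip_kernel,
    hamming_similarity,
)

__all__ = [
    "CVConfig",
    "MetricsReport",
    "RankedCandidates",
    "confusion_metrics",
    "auc_roc",
    "auc_pr",
    "run_kfold_cv",
    "rank_mirnas_for_pseudogene",
    "fold_training_matrix",
]

METRIC_NAMES = ("precision", "sensitivity", "accuracy", "f1", "mcc", "auc", "aupr")


@dataclass
class CVConfig:
    """k-fold CV settings."""

    k: int = 5
    seed: int = 0
    leakage_mode: str = "masked"
    training_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.leakage_mode not in ("masked", "full-matrix"):
            raise ValueError("leakage_mode must be 'masked' or 'full-matrix'")
        if not (0 < self.training_fraction <= 1):
            raise ValueError("training_fraction must be in (0, 1]")


@dataclass
class MetricsReport:
    """Per-fold and mean metrics for one CV run."""

    per_fold: list[dict]
    mean: dict
    fold_assignments: list[list[int]]
    individual_learner_auc: list[list[float]]
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "mean": self.mean,
                "per_fold": self.per_fold,
                "individual_learner_auc": self.individual_learner_auc,
                "fold_assignments": self.fold_assignments,
            },
            indent=2,
            sort_keys=True,
            allow_nan=True,
        )

    def to_tsv(self) -> str:
        lines = ["fold\t" + "\t".join(METRIC_NAMES)]
        for f, row in enumerate(self.per_fold):
            lines.append(
                f"{f}\t" + "\t".join(format(row[m], ".6f") for m in METRIC_NAMES)
            )
        lines.append(
            "mean\t" + "\t".join(format(self.mean[m], ".6f") for m in METRIC_NAMES)
        )
        return "\n".join(lines) + "\n"


@dataclass
class RankedCandidates:
    """Descending-score miRNA ranking for one held-out pseudogene."""

    pseudogene_id: str
    mirna_ids: list[str]
    scores: np.ndarray
    hits: list[bool] | None = None

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        return [(self.mirna_ids[i], float(self.scores[i])) for i in range(min(k, len(self.mirna_ids)))]

    def to_tsv(self) -> str:
        lines = ["rank\tmirna_id\tscore\thit"]
        for r, (mid, s) in enumerate(zip(self.mirna_ids, self.scores), start=1):
            hit = "" if self.hits is None else str(int(self.hits[r - 1]))
            lines.append(f"{r}\t{mid}\t{s:.6f}\t{hit}")
        return "\n".join(lines) + "\n"


def confusion_metrics(labels, predicted_labels) -> dict:
    """Precision, sensitivity, accuracy, F1 and MCC from binary labels.

    Zero-denominator ratios come back as NaN so an undefined metric is never
    mistaken for a zero one.
    """
    y = np.asarray(labels, dtype=int).ravel()
    p = np.asarray(predicted_labels, dtype=int).ravel()
    if y.shape != p.shape:
        raise ValueError("label vectors differ in length")
    if y.size == 0:
        raise ValueError("empty label vectors")
    tp = int(((y == 1) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())

    def ratio(num: float, den: float) -> float:
        return num / den if den else math.nan

    pre = ratio(tp, tp + fp)
    sen = ratio(tp, tp + fn)
    acc = (tp + tn) / (tp + tn + fp + fn)
    f1 = ratio(2 * sen * pre, sen + pre) if not (math.isnan(sen) or math.isnan(pre)) else math.nan
    mcc_den = math.sqrt((tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den else math.nan
    return {
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
        "precision": pre,
        "sensitivity": sen,
        "accuracy": acc,
        "f1": f1,
        "mcc": mcc,
    }


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auc_roc(labels, scores) -> float:
    """Area under the ROC curve (equals pairwise concordance with tie credit)."""
    labels = np.asarray(labels, dtype=int).ravel()
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float).ravel()))


def auc_pr(labels, scores) -> float:
    """Trapezoidal area under the precision-recall curve."""
    labels = np.asarray(labels, dtype=int).ravel()
    _check_two_classes(labels)
    precision, recall, _ = precision_recall_curve(labels, np.asarray(scores, float).ravel())
    # recall is returned in decreasing order
    return float(abs(np.trapezoid(precision, recall)))


def fold_training_matrix(
    pm: AssociationMatrix, test_positives: np.ndarray
) -> AssociationMatrix:
    """Training copy of the adjacency matrix with the test positives zeroed."""
    out = pm.copy()
    tp = np.asarray(test_positives, dtype=int).reshape(-1, 2)
    out.values[tp[:, 0], tp[:, 1]] = 0
    return out


def _fuse_axes(
    pm: AssociationMatrix,
    expr_kernel: SimilarityMatrix | None,
    func_kernel: SimilarityMatrix | None,
    fusion: FusionConfig,
) -> tuple[FusedSimilarity, FusedSimilarity]:
    p_stack = ([expr_kernel] if expr_kernel is not None else []) + [
        gip_kernel(pm, "pseudogene"),
        hamming_similarity(pm, "pseudogene"),
        cosine_similarity(pm, "pseudogene"),
    ]
    m_stack = ([func_kernel] if func_kernel is not None else []) + [
        gip_kernel(pm, "mirna"),
        hamming_similarity(pm, "mirna"),
        cosine_similarity(pm, "mirna"),
    ]
    return skf_fuse(p_stack, fusion), skf_fuse(m_stack, fusion)


def run_kfold_cv(
    bundle: DatasetBundle,
    cv: CVConfig | None = None,
    fusion: FusionConfig | None = None,
    learner: LearnerConfig | None = None,
) -> MetricsReport:
    """Seeded k-fold cross-validation over the known positives.

    Per fold: test set = held-out positives plus an equal number of unlabeled
    pairs sampled for testing only; training subsets are balanced resamples
    that exclude those test negatives.  With ``training_fraction < 1`` only a
    seeded subsample of the training positives is used (and, in masked mode,
    the unused ones are removed from the training matrix as well).
    """
    cv = cv or CVConfig()
    fusion = fusion or FusionConfig()
    learner = learner or LearnerConfig()
    pm = bundle.associations
    positives = pm.positive_pairs()
    n_pos = len(positives)
    if n_pos < cv.k:
        raise ValueError(f"k={cv.k} exceeds the number of positives ({n_pos})")

    # side-information kernels never touch PM: compute once
    expr_kernel = (
        expression_similarity(bundle.expression, pm.pseudogene_ids)
        if bundle.expression is not None
        else None
    )
    func_kernel = (
        functional_similarity(bundle.targets, pm.mirna_ids)
        if bundle.targets is not None
        else None
    )

    rng_folds = np.random.default_rng([int(cv.seed), 11])
    perm = rng_folds.permutation(n_pos)
    folds = [sorted(perm[f :: cv.k].tolist()) for f in range(cv.k)]

    unlabeled_full = np.argwhere(pm.values == 0)

    if cv.leakage_mode == "full-matrix":
        sp_full, sm_full = _fuse_axes(pm, expr_kernel, func_kernel, fusion)

    per_fold, learner_aucs = [], []
    for f, test_idx in enumerate(folds):
        test_pos = positives[test_idx]
        train_idx = [i for i in range(n_pos) if i not in set(test_idx)]
        train_pos = positives[train_idx]

        if cv.training_fraction < 1:
            rng_tf = np.random.default_rng([int(cv.seed), 101 + f])
            n_keep = max(1, int(round(cv.training_fraction * len(train_pos))))
            keep = np.sort(rng_tf.choice(len(train_pos), size=n_keep, replace=False))
            dropped_pos = np.delete(train_pos, keep, axis=0)
            train_pos = train_pos[keep]
        else:
            dropped_pos = np.empty((0, 2), dtype=int)

        if cv.leakage_mode == "masked":
            train_pm = fold_training_matrix(pm, np.vstack([test_pos, dropped_pos]))
            sp, sm = _fuse_axes(train_pm, expr_kernel, func_kernel, fusion)
        else:
            train_pm = pm
            sp, sm = sp_full, sm_full

        rng_neg = np.random.default_rng([int(cv.seed), 201 + f])
        pick = rng_neg.choice(len(unlabeled_full), size=len(test_pos), replace=False)
        test_neg = unlabeled_full[np.sort(pick)]

        subsets = sample_training_subsets(
            pm,
            n_subsets=learner.n_learners,
            seed=int(cv.seed) * 1000 + f,
            positives=train_pos,
            exclude_negatives=[tuple(x) for x in test_neg]
            + [tuple(x) for x in dropped_pos.tolist()],
        )
        model = train_ensemble(subsets, sp, sm, learner)

        test_pairs = np.vstack([test_pos, test_neg])
        y_true = np.r_[np.ones(len(test_pos), int), np.zeros(len(test_neg), int)]
        per_learner = member_scores(model, test_pairs)
        scores = per_learner.mean(axis=0)
        y_pred = (scores > 0.5).astype(int)

        row = confusion_metrics(y_true, y_pred)
        row["auc"] = auc_roc(y_true, scores)
        row["aupr"] = auc_pr(y_true, scores)
        per_fold.append(row)
        learner_aucs.append([auc_roc(y_true, s) for s in per_learner])

    mean = {
        m: float(np.mean([row[m] for row in per_fold])) for m in METRIC_NAMES
    }
    return MetricsReport(
        per_fold=per_fold,
        mean=mean,
        fold_assignments=folds,
        individual_learner_auc=learner_aucs,
        config={
            "k": cv.k,
            "seed": cv.seed,
            "leakage_mode": cv.leakage_mode,
            "training_fraction": cv.training_fraction,
            "fusion": vars(fusion).copy(),
            "learner": vars(learner).copy(),
        },
    )


def rank_mirnas_for_pseudogene(
    bundle: DatasetBundle,
    pseudogene_id: str,
    fusion: FusionConfig | None = None,
    learner: LearnerConfig | None = None,
    validation_pairs: list[tuple[str, str]] | None = None,
    seed: int = 0,
) -> RankedCandidates:
    """Hold out one pseudogene's associations, retrain, and rank all miRNAs.

    The target pseudogene's row of the adjacency matrix is zeroed before the
    interaction-profile kernels are computed, so its ranking is driven only
    by side information and network structure.  Ties are broken by ascending
    miRNA index.
    """
    fusion = fusion or FusionConfig()
    learner = learner or LearnerConfig()
    pm = bundle.associations
    if pseudogene_id not in pm.pseudogene_ids:
        raise KeyError(f"unknown pseudogene {pseudogene_id!r}")
    i = pm.pseudogene_ids.index(pseudogene_id)

    train_pm = pm.copy()
    train_pm.values[i, :] = 0

    expr_kernel = (
        expression_similarity(bundle.expression, pm.pseudogene_ids)
        if bundle.expression is not None
        else None
    )
    func_kernel = (
        functional_similarity(bundle.targets, pm.mirna_ids)
        if bundle.targets is not None
        else None
    )
    sp, sm = _fuse_axes(train_pm, expr_kernel, func_kernel, fusion)

    # the held-out row is the prediction target: keep it out of the negatives
    subsets = sample_training_subsets(
        train_pm,
        n_subsets=learner.n_learners,
        seed=seed,
        exclude_negatives=[(i, j) for j in range(pm.n_mirnas)],
    )
    model = train_ensemble(subsets, sp, sm, learner)

    pairs = [(i, j) for j in range(pm.n_mirnas)]
    scores, _ = predict_pairs(model, pairs)
    order = np.lexsort((np.arange(pm.n_mirnas), -scores))
    ranked_ids = [pm.mirna_ids[j] for j in order]
    ranked_scores = scores[order]

    hits = None
    if validation_pairs is not None:
        valid = {m for p, m in validation_pairs if p == pseudogene_id}
        hits = [mid in valid for mid in ranked_ids]
    return RankedCandidates(
        pseudogene_id=pseudogene_id,
        mirna_ids=ranked_ids,
        scores=ranked_scores,
        hits=hits,
    )
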
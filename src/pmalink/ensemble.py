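"""Balanced resampling ensemble over fused similarity features.

Known associations form a positive-unlabeled problem: 1570 positives against
~81k unlabeled pairs at the scale of the real data.  Each ensemble member is
trained on a balanced subset containing *all* positives plus an equal number
of negatives sampled (without replacement, independently per subset) from the
unlabeled pairs.  A pair (i, j) is represented by concatenating row i of the
fused pseudogene similarity with row j of the fused miRNA similarity.
Member scores are aggregated by soft voting: the arithmetic mean, with a pair
called associated iff the mean score strictly exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .data import AssociationMatrix
from .fusion import FusedSimilarity

__all__ = [
    "SubsetSpec",
    "LearnerConfig",
    "EnsembleModel",
    "sample_training_subsets",
    "build_pair_features",
    "make_learner",
    "train_ensemble",
    "soft_vote",
    "predict_pairs",
]

_LEARNER_KINDS = ("xgb", "rf", "ert", "ab")


@dataclass
class SubsetSpec:
    """One balanced training subset: all positives + equally many negatives."""

    positive_pairs: np.ndarray  # (n, 2) int indices
    negative_pairs: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.positive_pairs = np.asarray(self.positive_pairs, dtype=int).reshape(-1, 2)
        self.negative_pairs = np.asarray(self.negative_pairs, dtype=int).reshape(-1, 2)
        if len(self.positive_pairs) != len(self.negative_pairs):
            raise ValueError("subset must be balanced")


@dataclass
class LearnerConfig:
    """Individual-learner and ensemble-width settings.

    Defaults (10 learners, 400 boosting rounds, learning rate 0.2) are the
    tuned gradient-boosted-tree operating point; ``max_depth=None`` defers to
    the library default.  ``learner_kind`` selects gradient-boosted trees
    (``xgb``), random forest (``rf``), extremely randomized trees (``ert``)
    or AdaBoost (``ab``) for ablation.
    """

    learner_kind: str = "xgb"
    n_estimators: int = 400
    learning_rate: float = 0.2
    max_depth: int | None = None
    n_learners: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner_kind not in _LEARNER_KINDS:
            raise ValueError(f"learner_kind must be one of {_LEARNER_KINDS}")
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass
class EnsembleModel:
    """Trained learners plus the fused similarities used for features."""

    learners: list
    sp: FusedSimilarity
    sm: FusedSimilarity
    config: LearnerConfig
    subsets: list[SubsetSpec] = field(default_factory=list)


def _subset_seed(seed: int, index: int) -> int:
    return int((int(seed) * 100003 + 7919 * index + 1) % (2**31))


def sample_training_subsets(
    pm: AssociationMatrix,
    n_subsets: int,
    seed: int,
    positives: np.ndarray | None = None,
    exclude_negatives: Iterable[tuple[int, int]] = (),
) -> list[SubsetSpec]:
    """Draw ``n_subsets`` balanced subsets from a positive-unlabeled matrix.

    Every subset contains all positives; negatives are sampled uniformly
    without replacement from the unlabeled pairs (zeros of ``pm``), minus any
    ``exclude_negatives`` (e.g. a test fold's negatives).  Draws are
    independent across subsets and fully determined by ``seed``.
    """
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    if positives is None:
        positives = pm.positive_pairs()
    positives = np.asarray(positives, dtype=int).reshape(-1, 2)
    n_pos = len(positives)
    if n_pos < 1:
        raise ValueError("no positive pairs to train on")

    unlabeled = np.argwhere(pm.values == 0)
    if len(unlabeled):
        excl = set((int(i), int(j)) for i, j in exclude_negatives)
        if excl:
            keep = [k for k, (i, j) in enumerate(unlabeled) if (int(i), int(j)) not in excl]
            unlabeled = unlabeled[keep]
    if len(unlabeled) < n_pos:
        raise ValueError(
            f"only {len(unlabeled)} unlabeled pairs available for {n_pos} positives"
        )

    subsets = []
    for s in range(n_subsets):
        sub_seed = _subset_seed(seed, s)
        rng = np.random.default_rng(sub_seed)
        pick = rng.choice(len(unlabeled), size=n_pos, replace=False)
        subsets.append(
            SubsetSpec(positives.copy(), unlabeled[np.sort(pick)], seed=sub_seed)
        )
    return subsets


def build_pair_features(
    sp: FusedSimilarity, sm: FusedSimilarity, pairs: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Feature rows: fused pseudogene row i concatenated with fused miRNA row j."""
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    n_p, n_m = sp.values.n, sm.values.n
    if len(pairs) and (
        pairs[:, 0].min() < 0
        or pairs[:, 0].max() >= n_p
        or pairs[:, 1].min() < 0
        or pairs[:, 1].max() >= n_m
    ):
        raise IndexError("pair index out of range")
    return np.hstack([sp.values.values[pairs[:, 0]], sm.values.values[pairs[:, 1]]])


def make_learner(cfg: LearnerConfig, seed: int):
    """Instantiate one individual learner behind the config contract."""
    if cfg.learner_kind == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=cfg.n_estimators,
            learning_rate=cfg.learning_rate,
            max_depth=cfg.max_depth if cfg.max_depth is not None else 6,
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
        )
    if cfg.learner_kind == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=cfg.n_estimators, max_depth=cfg.max_depth, random_state=seed, n_jobs=1
        )
    if cfg.learner_kind == "ert":
        from sklearn.ensemble import ExtraTreesClassifier

        return ExtraTreesClassifier(
            n_estimators=cfg.n_estimators, max_depth=cfg.max_depth, random_state=seed, n_jobs=1
        )
    from sklearn.ensemble import AdaBoostClassifier

    return AdaBoostClassifier(
        n_estimators=cfg.n_estimators, learning_rate=cfg.learning_rate, random_state=seed
    )


def train_ensemble(
    subsets: list[SubsetSpec],
    sp: FusedSimilarity,
    sm: FusedSimilarity,
    cfg: LearnerConfig,
) -> EnsembleModel:
    """Fit one individual learner per balanced subset."""
    if not subsets:
        raise ValueError("no training subsets")
    learners = []
    for idx, sub in enumerate(subsets):
        if len(sub.positive_pairs) == 0 or len(sub.negative_pairs) == 0:
            raise ValueError(f"subset {idx} is single-class")
        X = build_pair_features(
            sp, sm, np.vstack([sub.positive_pairs, sub.negative_pairs])
        )
        y = np.r_[
            np.ones(len(sub.positive_pairs), dtype=int),
            np.zeros(len(sub.negative_pairs), dtype=int),
        ]
        learner = make_learner(cfg, seed=cfg.seed + idx)
        learner.fit(X, y)
        learners.append(learner)
    return EnsembleModel(learners=learners, sp=sp, sm=sm, config=cfg, subsets=subsets)


def soft_vote(per_learner_scores: Sequence[float]) -> tuple[float, bool]:
    """Mean member score; associated iff the mean strictly exceeds 0.5."""
    scores = np.asarray(per_learner_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no learner scores to aggregate")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("learner scores must lie in [0, 1]")
    final = float(scores.mean())
    return final, final > 0.5


def member_scores(model: EnsembleModel, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    """(n_learners, n_pairs) matrix of individual-learner scores."""
    if not model.learners:
        raise ValueError("model has no trained learners")
    X = build_pair_features(model.sp, model.sm, pairs)
    out = np.vstack([lrn.predict_proba(X)[:, 1] for lrn in model.learners])
    return np.clip(out, 0.0, 1.0)


def predict_pairs(
    model: EnsembleModel, pairs: Sequence[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-voted scores and strict >0.5 labels for the given index pairs."""
    per_learner = member_scores(model, pairs)
    scores = per_learner.mean(axis=0)
    return scores, scores > 0.5
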
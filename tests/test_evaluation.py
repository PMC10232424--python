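import math

import numpy as np
import pytest

from pmalink import (
    CVConfig,
    FusionConfig,
    LearnerConfig,
    auc_pr,
    auc_roc,
    confusion_metrics,
    rank_mirnas_for_pseudogene,
    run_kfold_cv,
)
from pmalink.evaluation import fold_training_matrix

from oracles import aupr_trapezoid_oracle, auc_concordance_oracle, confusion_oracle


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        m = confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        for key in ("precision", "sensitivity", "accuracy", "f1", "mcc"):
            assert m[key] == pytest.approx(1.0)

    def test_hand_worked_confusion_table(self):
        # TP=2, TN=3, FP=1, FN=0
        y_true = [1, 1, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 0]
        m = confusion_metrics(y_true, y_pred)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["sensitivity"] == pytest.approx(1.0)
        assert m["accuracy"] == pytest.approx(5 / 6)
        assert m["f1"] == pytest.approx(0.8)
        assert m["mcc"] == pytest.approx(6 / math.sqrt(72))

    def test_zero_denominator_flagged_not_zero(self):
        m = confusion_metrics([1, 0, 1], [0, 0, 0])
        assert m["sensitivity"] == 0.0
        assert math.isnan(m["precision"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics([1, 0], [1])

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 30))
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            got = confusion_metrics(y, p)
            expect = confusion_oracle(y, p)
            for key, val in expect.items():
                if isinstance(val, float) and math.isnan(val):
                    assert math.isnan(got[key]), key
                else:
                    assert got[key] == pytest.approx(val), key


class TestAreaMetrics:
    def test_perfect_separation_gives_auc_one(self):
        assert auc_roc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_roc([0, 1, 0, 1], [0.5] * 4) == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc_roc([1, 1], [0.2, 0.4])
        with pytest.raises(ValueError):
            auc_pr([0, 0], [0.2, 0.4])

    def test_auc_matches_concordance_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # induce ties
            assert auc_roc(y, scores) == pytest.approx(
                auc_concordance_oracle(y, scores), abs=1e-12
            )

    def test_aupr_matches_trapezoid_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 2)
            assert auc_pr(y, scores) == pytest.approx(
                aupr_trapezoid_oracle(y, scores), abs=1e-10
            )


class TestFoldMasking:
    def test_test_positives_cannot_reach_training_kernels(self, small_bundle):
        pm = small_bundle.associations
        positives = pm.positive_pairs()
        test_pos = positives[:5]
        masked = fold_training_matrix(pm, test_pos)
        assert masked.values[test_pos[:, 0], test_pos[:, 1]].sum() == 0
        # perturbing only the held-out entries of the input leaves the
        # training matrix untouched
        perturbed = pm.copy()
        perturbed.values[test_pos[:, 0], test_pos[:, 1]] = 0
        np.testing.assert_array_equal(
            masked.values, fold_training_matrix(perturbed, test_pos).values
        )
        # and nothing else was changed
        diff = pm.values.astype(int) - masked.values.astype(int)
        assert diff.sum() == len(test_pos) and (diff >= 0).all()


class TestKFoldCV:
    def test_deterministic_reports(self, small_bundle, fast_fusion, fast_learner):
        kwargs = dict(
            cv=CVConfig(k=3, seed=2),
            fusion=fast_fusion,
            learner=fast_learner,
        )
        a = run_kfold_cv(small_bundle, **kwargs)
        b = run_kfold_cv(small_bundle, **kwargs)
        assert a.to_json() == b.to_json()

    def test_planted_structure_is_learnable(self, small_bundle, fast_fusion, fast_learner):
        rep = run_kfold_cv(
            small_bundle, CVConfig(k=3, seed=2), fast_fusion, fast_learner
        )
        assert rep.mean["auc"] > 0.6
        assert all(0 <= row["auc"] <= 1 for row in rep.per_fold)
        assert len(rep.fold_assignments) == 3
        # folds partition the positives
        all_idx = sorted(i for fold in rep.fold_assignments for i in fold)
        assert all_idx == list(range(int(small_bundle.associations.values.sum())))

    def test_full_matrix_mode_is_optimistic(self, small_bundle, fast_fusion, fast_learner):
        masked = run_kfold_cv(
            small_bundle, CVConfig(k=3, seed=2), fast_fusion, fast_learner
        )
        leaky = run_kfold_cv(
            small_bundle,
            CVConfig(k=3, seed=2, leakage_mode="full-matrix"),
            fast_fusion,
            fast_learner,
        )
        assert leaky.mean["auc"] >= masked.mean["auc"] - 0.02

    def test_k_larger_than_positives_errors(self, small_bundle, fast_fusion, fast_learner):
        with pytest.raises(ValueError):
            run_kfold_cv(
                small_bundle,
                CVConfig(k=10**6, seed=0),
                fast_fusion,
                fast_learner,
            )

    def test_training_fraction_validated(self):
        with pytest.raises(ValueError):
            CVConfig(training_fraction=0.0)
        with pytest.raises(ValueError):
            CVConfig(training_fraction=1.5)


class TestCaseStudyRanking:
    def test_ranking_is_deterministic_and_sorted(self, small_bundle, fast_fusion, fast_learner):
        pid = small_bundle.associations.pseudogene_ids[0]
        a = rank_mirnas_for_pseudogene(
            small_bundle, pid, fast_fusion, fast_learner, seed=4
        )
        b = rank_mirnas_for_pseudogene(
            small_bundle, pid, fast_fusion, fast_learner, seed=4
        )
        assert a.mirna_ids == b.mirna_ids
        np.testing.assert_array_equal(a.scores, b.scores)
        assert (np.diff(a.scores) <= 1e-12).all()
        assert a.hits is None

    def test_unknown_pseudogene_errors(self, small_bundle, fast_fusion, fast_learner):
        with pytest.raises(KeyError):
            rank_mirnas_for_pseudogene(
                small_bundle, "nope", fast_fusion, fast_learner
            )

    def test_top_candidates_recover_block_membership(self, small_bundle, fast_fusion, fast_learner):
        # the held-out pseudogene's strongest candidates should come from its
        # own planted block
        pm = small_bundle.associations
        p_blocks = small_bundle.metadata["pseudogene_blocks"]
        m_blocks = dict(zip(pm.mirna_ids, small_bundle.metadata["mirna_blocks"]))
        # pick the pseudogene with the most associations for a strong signal
        i = int(np.argmax(pm.values.sum(axis=1)))
        ranked = rank_mirnas_for_pseudogene(
            small_bundle, pm.pseudogene_ids[i], fast_fusion, fast_learner, seed=0
        )
        top_blocks = [m_blocks[mid] for mid in ranked.mirna_ids[:10]]
        assert sum(b == p_blocks[i] for b in top_blocks) > 5

    def test_validation_pairs_flag_hits(self, small_bundle, fast_fusion, fast_learner):
        pm = small_bundle.associations
        i = int(np.argmax(pm.values.sum(axis=1)))
        pid = pm.pseudogene_ids[i]
        truth = [(pid, pm.mirna_ids[j]) for j in np.where(pm.values[i] == 1)[0]]
        ranked = rank_mirnas_for_pseudogene(
            small_bundle, pid, fast_fusion, fast_learner,
            validation_pairs=truth, seed=0,
        )
        assert ranked.hits is not None and len(ranked.hits) == pm.n_mirnas
        assert sum(ranked.hits) == len(truth)
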
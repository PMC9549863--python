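"""Classifiers, transition-aware metrics, nested LOSO protocol, correlations."""

import numpy as np
import pytest

import gaitwear as gw
from gaitwear.evaluation import GRIDS, _inner_select, permute_window_labels


def _win(label, subject="s", start=0, pair=None, dominant=None):
    is_tr = label.startswith("trans_")
    if is_tr and pair is None:
        from gaitwear.recordings import TRANSITION_PAIRS
        pair = TRANSITION_PAIRS[label]
        dominant = dominant or pair[0]
    return gw.LabeledWindow(start=start, length=128, majority_label=label,
                            is_transition=is_tr, subject_id=subject,
                            adjoining_pair=pair, dominant_adjacent=dominant)


class TestGrids:
    def test_sizes_match_declared_grids(self):
        assert len(gw.expand_grid("svm")) == 4
        assert len(gw.expand_grid("lr")) == 6
        assert len(gw.expand_grid("knn")) == 20

    def test_svm_c_values(self):
        assert [p["C"] for p in GRIDS["svm"]] == [0.01, 0.1, 1.0, 10.0]

    def test_unknown_model_errors(self):
        with pytest.raises(ValueError):
            gw.expand_grid("random_forest")

    def test_params_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="not in the svm grid"):
            gw.fit_classifier("svm", {"C": 3.0}, np.zeros((4, 2)),
                              ["a", "a", "b", "b"])


class TestFitClassifier:
    def test_lr_separable_clusters(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)),
                       rng.normal(3, 0.3, (20, 2))])
        y = ["a"] * 20 + ["b"] * 20
        est = gw.fit_classifier("lr", {"C": 0.1, "l1_ratio": 0.01}, X, y)
        assert (est.predict(X) == np.asarray(y)).mean() == 1.0

    def test_1nn_memorizes_training_set(self, rng):
        X = rng.normal(0, 1, (30, 3))
        y = rng.choice(["a", "b"], 30)
        est = gw.fit_classifier("knn", {"n_neighbors": 1, "weights": "distance"},
                                X, y)
        assert (est.predict(X) == y).all()

    def test_rbf_svm_solves_xor(self, rng):
        centers = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        labels = ["a", "a", "b", "b"]
        X = np.vstack([c + rng.normal(0, 0.2, (25, 2)) for c in centers])
        y = np.repeat(labels, 25)
        est = gw.fit_classifier("svm", {"C": 10.0}, X, y)
        pred = est.predict(X)
        accs = [(pred[y == c] == c).mean() for c in ("a", "b")]
        assert np.mean(accs) > 0.9

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single class"):
            gw.fit_classifier("svm", {"C": 1.0}, np.zeros((5, 2)), ["a"] * 5)


class TestTransitionAwareCorrect:
    def test_either_adjoining_class_is_correct(self):
        w = _win("trans_sit_stand")
        assert gw.transition_aware_correct(w, "sitting", "gait_posture")
        assert gw.transition_aware_correct(w, "standing", "gait_posture")
        assert not gw.transition_aware_correct(w, "walking", "gait_posture")

    def test_non_transition_exact_match(self):
        w = _win("walking")
        assert gw.transition_aware_correct(w, "walking", "gait_posture")
        assert not gw.transition_aware_correct(w, "standing", "gait_posture")

    def test_gait_task_literal_consequences(self):
        # stand->walk straddles the gait boundary: any prediction counts
        sw = _win("trans_stand_walk")
        assert gw.transition_aware_correct(sw, "gait", "gait")
        assert gw.transition_aware_correct(sw, "no_gait", "gait")
        # posture-posture transitions map to (no_gait, no_gait)
        ss = _win("trans_sit_stand")
        assert gw.transition_aware_correct(ss, "no_gait", "gait")
        assert not gw.transition_aware_correct(ss, "gait", "gait")


class TestComputeMetrics:
    def test_perfect_predictions(self):
        wins = [_win(lab) for lab in
                ["lying", "sitting", "standing", "walking", "stairs"] * 3]
        preds = [w.majority_label for w in wins]
        m = gw.compute_metrics(wins, preds, "gait_posture")
        assert m.accuracy == 100.0
        assert m.balanced_accuracy == 100.0

    def test_definitional_binary_counts(self):
        # TP=9 FN=1 (gait truth), TN=8 FP=2 (no_gait truth)
        wins = [_win("walking")] * 10 + [_win("sitting")] * 10
        preds = (["gait"] * 9 + ["no_gait"]) + (["gait"] * 2 + ["no_gait"] * 8)
        m = gw.compute_metrics(wins, preds, "gait")
        g = m.per_class["gait"]
        assert g["sensitivity"] == pytest.approx(90.0)
        assert g["specificity"] == pytest.approx(80.0)
        assert g["balanced_accuracy"] == pytest.approx(85.0)
        assert g["ppv"] == pytest.approx(81.82, abs=0.01)
        assert m.balanced_accuracy == pytest.approx(85.0)

    def test_constant_predictor_has_chance_balanced_accuracy(self):
        wins = [_win("walking")] * 7 + [_win("sitting")] * 13
        m = gw.compute_metrics(wins, ["gait"] * 20, "gait")
        assert m.balanced_accuracy == pytest.approx(50.0)

    def test_matches_brute_force_confusion_oracle(self, rng):
        """Random label/prediction pairs agree with a direct tally."""
        classes = list(gw.windows.TASK_CLASSES["gait_posture"])
        for _ in range(200):
            n = int(rng.integers(5, 40))
            wins = [_win(str(rng.choice(classes))) for _ in range(n)]
            preds = [str(c) for c in rng.choice(classes, n)]
            m = gw.compute_metrics(wins, preds, "gait_posture")
            acc_oracle = np.mean([p == w.majority_label
                                  for w, p in zip(wins, preds)])
            assert m.accuracy == pytest.approx(100 * acc_oracle)
            for c in classes:
                tp = sum(1 for w, p in zip(wins, preds)
                         if w.majority_label == c and p == c)
                fn = sum(1 for w, p in zip(wins, preds)
                         if w.majority_label == c and p != c)
                if tp + fn == 0:
                    assert np.isnan(m.per_class[c]["sensitivity"])
                else:
                    assert m.per_class[c]["sensitivity"] == \
                        pytest.approx(100 * tp / (tp + fn))

    def test_correct_transition_credited_to_predicted_class(self):
        wins = [_win("trans_sit_stand"), _win("standing")]
        m = gw.compute_metrics(wins, ["sitting", "standing"], "gait_posture")
        assert m.confusion.loc["sitting", "sitting"] == 1
        assert m.accuracy == 100.0

    def test_incorrect_transition_attributed_to_dominant_adjacent(self):
        w = _win("trans_sit_stand", dominant="standing")
        m = gw.compute_metrics([w, _win("lying")], ["walking", "lying"],
                               "gait_posture")
        assert m.confusion.loc["standing", "walking"] == 1


class TestPooledConfusion:
    def test_single_fold_identity(self):
        wins = [_win(lab) for lab in ["walking", "sitting"] * 5]
        m = gw.compute_metrics(wins, [w.majority_label for w in wins],
                               "gait_posture")
        pooled = gw.pooled_confusion([m])
        assert pooled.loc["walking", "walking"] == pytest.approx(100.0)
        assert np.isnan(pooled.loc["lying"]).all()  # empty row undefined

    def test_two_folds_match_hand_pooling(self):
        wins1 = [_win("walking")] * 4
        wins2 = [_win("walking")] * 4
        m1 = gw.compute_metrics(wins1, ["walking"] * 4, "gait_posture")
        m2 = gw.compute_metrics(wins2, ["walking", "standing", "standing",
                                        "standing"], "gait_posture")
        pooled = gw.pooled_confusion([m1, m2])
        assert pooled.loc["walking", "walking"] == pytest.approx(62.5)
        assert pooled.loc["walking", "standing"] == pytest.approx(37.5)

    def test_rows_sum_to_100(self, gait_report_a14):
        pooled = gait_report_a14.pooled_confusion
        sums = pooled.sum(axis=1, skipna=False).dropna()
        assert np.allclose(sums, 100.0, atol=0.1)


class TestInnerSelect:
    def _dataset(self, rng, n_subjects=4):
        sessions = gw.default_cohort(n_subjects, seed=11, minutes=2.0)
        return gw.build_dataset(sessions, "E")

    def test_single_point_grid_selected_directly(self, rng):
        ds = self._dataset(rng)
        out = _inner_select(ds, ds.subjects(), [{"C": 0.1}], "gait", "svm", 0)
        assert out == {"C": 0.1}

    def test_exact_tie_takes_first_in_grid_order(self, rng):
        ds = self._dataset(rng)
        grid = [{"n_neighbors": 4, "weights": "uniform"},
                {"n_neighbors": 4, "weights": "uniform"}]
        # duplicate entries tie exactly; the earlier must win
        out = _inner_select(ds, ds.subjects(), grid, "gait", "knn", 0)
        assert out is grid[0] or out == grid[0]

    def test_fewer_than_two_subjects_errors(self, rng):
        ds = self._dataset(rng)
        with pytest.raises(ValueError, match="at least 2"):
            _inner_select(ds, ds.subjects()[:1], [{"C": 1.0}, {"C": 0.1}],
                          "gait", "svm", 0)


class TestNestedLoso:
    def test_determinism_bit_exact(self):
        sessions = gw.default_cohort(4, seed=5, minutes=2.0)
        kwargs = dict(task="gait", config_id="E", model_kind="knn",
                      grid=gw.reduced_grid("knn"), seed=1)
        r1 = gw.nested_loso(sessions, **kwargs)
        r2 = gw.nested_loso(sessions, **kwargs)
        assert r1.to_json() == r2.to_json()

    def test_no_leakage_and_fold_structure(self, gait_report_a14):
        subjects = [f.held_out_subject for f in gait_report_a14.folds]
        assert len(subjects) == len(set(subjects)) == 14
        agg = gait_report_a14.aggregate["balanced_accuracy"]
        fold_vals = [f.balanced_accuracy for f in gait_report_a14.folds]
        assert agg["mean"] == pytest.approx(np.mean(fold_vals))

    def test_too_few_subjects(self):
        sessions = gw.default_cohort(3, seed=5, minutes=2.0)[:2]
        with pytest.raises(ValueError, match="at least 3"):
            gw.nested_loso(sessions, "gait", "E", "knn",
                           grid=gw.reduced_grid("knn"))


class TestPermuteWindowLabels:
    def test_preserves_per_subject_marginals(self, small_cohort):
        ds = gw.build_dataset(small_cohort, "E")
        perm = permute_window_labels(ds.windows, np.random.default_rng(3))
        for subject in {w.subject_id for w in ds.windows}:
            orig = sorted(w.majority_label for w in ds.windows
                          if w.subject_id == subject)
            new = sorted(w.majority_label for w in perm
                         if w.subject_id == subject)
            assert orig == new


class TestCorrelatePerformanceImpairment:
    def test_monotone_heavy_tail_uses_spearman(self):
        scores = [1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 1000.0, 5000.0, 1e5, 1e6]
        clinical = list(range(10))
        coef, p, method = gw.correlate_performance_impairment(scores, clinical)
        assert method == "spearman"
        assert coef == pytest.approx(1.0)

    def test_bivariate_normal_recovers_correlation(self, rng):
        cov = [[1.0, 0.8], [0.8, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=200)
        coef, p, method = gw.correlate_performance_impairment(xy[:, 0], xy[:, 1])
        assert method == "pearson"
        assert coef == pytest.approx(0.8, abs=0.1)

    def test_constant_values_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            gw.correlate_performance_impairment([1, 2, 3, 4], [5, 5, 5, 5])

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            gw.correlate_performance_impairment([1, 2], [3, 4])


def test_balanced_accuracy_robust_to_transition_inclusion(gait_report_a14,
                                                          dataset_a14):
    """Scoring with vs without transition windows differs by < 5 points."""
    by_subject = {}
    for w in dataset_a14.windows:
        by_subject.setdefault(w.subject_id, []).append(w)
    with_t, without_t = [], []
    for fold in gait_report_a14.folds:
        wins = by_subject[fold.held_out_subject]
        with_t.append(gw.compute_metrics(
            wins, fold.predictions, "gait").balanced_accuracy)
        without_t.append(gw.compute_metrics(
            wins, fold.predictions, "gait",
            include_transitions=False).balanced_accuracy)
    assert abs(np.mean(with_t) - np.mean(without_t)) < 5.0
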
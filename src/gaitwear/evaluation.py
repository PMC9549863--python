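"""Model fitting, nested leave-one-subject-out evaluation, and metrics.

The protocol: the outer loop holds out one subject; the inner loop runs
leave-one-subject-out over the remaining subjects for every hyperparameter
combination, scoring transition-aware balanced accuracy on the inner test
subject (transitions included) after fitting on the inner training
windows (transitions removed). The best grid point (ties to the first in
declared grid order) is refit on the whole outer training set and scored
on the held-out subject. No window of the held-out subject ever reaches a
fit — asserted at runtime.

Scoring is transition-aware: a window whose majority label is a
transition between classes A and B counts as correct if the model
predicts either A or B. For confusion counting, a correctly classified
transition window is credited to the predicted class; an incorrect one to
the adjoining class dominant within the window.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import extract_features, standardize_per_subject
from .preprocessing import FilterConfig, DEFAULT_FILTERS
from .recordings import RecordingSession
from .windows import (DEFAULT_HOP, DEFAULT_WINDOW, LabeledWindow, TASK_CLASSES,
                      make_windows, map_adjoining_pair, map_task_labels)

DEFAULT_SEED = 20220926

MODEL_KINDS = ("svm", "lr", "knn")

#: Hyperparameter grids, in declared order (ties resolve to the first point).
GRIDS = {
    "svm": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
    "lr": [{"C": c, "l1_ratio": r}
           for c in (0.001, 0.01, 0.1) for r in (0.01, 0.1)],
    "knn": [{"n_neighbors": n, "weights": w}
            for n in (1, 2, 4, 8, 12, 16, 20, 24, 28, 32)
            for w in ("uniform", "distance")],
}


def expand_grid(model_kind: str) -> list[dict]:
    if model_kind not in GRIDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    return [dict(p) for p in GRIDS[model_kind]]


#: Single representative mid-grid point per model for quick runs. The
#: extreme first grid entries (e.g. SVM C = 0.01) underfit so strongly
#: that a one-point grid built from them would not exercise the pipeline
#: meaningfully.
REDUCED_GRID_POINTS = {
    "svm": {"C": 1.0},
    "lr": {"C": 0.01, "l1_ratio": 0.1},
    "knn": {"n_neighbors": 8, "weights": "uniform"},
}


def reduced_grid(model_kind: str) -> list[dict]:
    """One representative grid point — the quick single-point grid."""
    if model_kind not in REDUCED_GRID_POINTS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    return [dict(REDUCED_GRID_POINTS[model_kind])]


def make_estimator(model_kind: str, params: dict, seed: int = DEFAULT_SEED):
    """Instantiate the scikit-learn estimator for a grid point."""
    if params not in expand_grid(model_kind):
        raise ValueError(f"params {params!r} not in the {model_kind} grid")
    if model_kind == "svm":
        return SVC(kernel="rbf", class_weight="balanced", C=params["C"],
                   cache_size=256)
    if model_kind == "lr":
        return LogisticRegression(penalty="elasticnet", solver="saga",
                                  class_weight="balanced", fit_intercept=True,
                                  C=params["C"], l1_ratio=params["l1_ratio"],
                                  max_iter=2000, random_state=seed)
    return KNeighborsClassifier(n_neighbors=params["n_neighbors"],
                                weights=params["weights"])


def fit_classifier(model_kind: str, params: dict, X: np.ndarray, y,
                   seed: int = DEFAULT_SEED):
    """Fit one grid point; requires at least two classes in y."""
    y = np.asarray(y, dtype=object)
    if len(np.unique(y.astype(str))) < 2:
        raise ValueError("training labels contain a single class")
    est = make_estimator(model_kind, params, seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        est.fit(X, y.astype(str))
    return est


# ---------------------------------------------------------------------------
# Transition-aware scoring

def transition_aware_correct(window: LabeledWindow, predicted: str,
                             task: str) -> bool:
    """Is a prediction correct under the A-or-B transition rule?"""
    if window.is_transition:
        return predicted in map_adjoining_pair(window.adjoining_pair, task)
    return predicted == map_task_labels(window.majority_label, task)


def _effective_truth(window: LabeledWindow, predicted: str, task: str) -> str:
    """True class used for confusion counting (transition convention)."""
    if not window.is_transition:
        return map_task_labels(window.majority_label, task)
    if predicted in map_adjoining_pair(window.adjoining_pair, task):
        return predicted
    return map_task_labels(window.dominant_adjacent, task)


@dataclasses.dataclass
class FoldResult:
    """Per-held-out-subject metrics from one outer fold."""

    held_out_subject: str
    selected_params: dict
    per_class: dict          # class -> {sensitivity, specificity, ppv, balanced_accuracy} in %
    accuracy: float          # % correct under the transition rule
    balanced_accuracy: float  # % macro mean of per-class (sens+spec)/2
    confusion: pd.DataFrame  # true x predicted counts
    n_windows: int
    predictions: np.ndarray | None = None


def compute_metrics(eval_windows: list[LabeledWindow], predictions,
                    task: str, include_transitions: bool = True) -> FoldResult:
    """One-vs-rest metrics with transition-aware crediting.

    A class absent from the effective truth has undefined sensitivity/PPV;
    it is recorded as NaN and excluded from the macro balanced accuracy
    (with a warning).
    """
    predictions = np.asarray(predictions, dtype=object)
    if len(predictions) != len(eval_windows):
        raise ValueError("predictions and windows length mismatch")
    classes = list(TASK_CLASSES[task])
    bad = set(predictions.astype(str)) - set(classes)
    if bad:
        raise ValueError(f"predictions outside class set: {sorted(bad)}")
    if not include_transitions:
        keep = [i for i, w in enumerate(eval_windows) if not w.is_transition]
        eval_windows = [eval_windows[i] for i in keep]
        predictions = predictions[keep]

    correct = np.array([transition_aware_correct(w, p, task)
                        for w, p in zip(eval_windows, predictions)])
    truth = np.array([_effective_truth(w, p, task)
                      for w, p in zip(eval_windows, predictions)], dtype=object)

    n = len(eval_windows)
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(truth, predictions):
        conf.loc[t, p] += 1

    per_class: dict = {}
    balances = []
    for c in classes:
        tp = int(conf.loc[c, c])
        fn = int(conf.loc[c].sum()) - tp
        fp = int(conf[c].sum()) - tp
        tn = n - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"class {c!r} absent from truth; metrics undefined")
            per_class[c] = {"sensitivity": np.nan, "specificity": np.nan,
                            "ppv": np.nan, "balanced_accuracy": np.nan}
            continue
        sens = 100.0 * tp / (tp + fn)
        spec = 100.0 * tn / (tn + fp) if tn + fp > 0 else np.nan
        ppv = 100.0 * tp / (tp + fp) if tp + fp > 0 else np.nan
        bal = (sens + spec) / 2.0
        per_class[c] = {"sensitivity": sens, "specificity": spec,
                        "ppv": ppv, "balanced_accuracy": bal}
        balances.append(bal)

    subject = eval_windows[0].subject_id if eval_windows else ""
    return FoldResult(
        held_out_subject=subject,
        selected_params={},
        per_class=per_class,
        accuracy=100.0 * float(correct.mean()) if n else np.nan,
        balanced_accuracy=float(np.mean(balances)) if balances else np.nan,
        confusion=conf,
        n_windows=n,
        predictions=predictions)


def pooled_confusion(fold_results: list[FoldResult]) -> pd.DataFrame:
    """Sum fold confusions, then row-normalize each true class to 100 %.

    Rows with no windows are reported as NaN (undefined), not 0.
    """
    if not fold_results:
        raise ValueError("no folds to pool")
    total = sum(f.confusion for f in fold_results)
    sums = total.sum(axis=1).to_numpy(dtype=float)
    out = total.astype(float)
    for i, s in enumerate(sums):
        out.iloc[i] = out.iloc[i] * 100.0 / s if s > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# Dataset assembly

@dataclasses.dataclass
class WindowDataset:
    """Standardized features + windows for a cohort under one sensor config."""

    X: np.ndarray
    windows: list[LabeledWindow]
    subject_ids: np.ndarray
    feature_names: list[str]
    task_ready: bool = True

    def subjects(self) -> list[str]:
        return list(pd.unique(self.subject_ids))


def build_dataset(sessions: list[RecordingSession], config_id: str,
                  window: int = DEFAULT_WINDOW, hop: int = DEFAULT_HOP,
                  filter_config: FilterConfig = DEFAULT_FILTERS,
                  standardize: bool = True) -> WindowDataset:
    """Windows -> per-sensor features -> per-subject standardization."""
    blocks, all_windows, subj = [], [], []
    names: list[str] | None = None
    for session in sessions:
        wins = make_windows(session.label_track.labels, session.subject_id,
                            window, hop)
        fm = extract_features(session, config_id, wins, filter_config)
        if standardize:
            fm, _ = standardize_per_subject(fm)
        if names is None:
            names = fm.feature_names
        elif names != fm.feature_names:
            raise ValueError("feature name mismatch across sessions")
        blocks.append(fm.values)
        all_windows.extend(wins)
        subj.extend([session.subject_id] * len(wins))
    return WindowDataset(X=np.vstack(blocks), windows=all_windows,
                         subject_ids=np.asarray(subj, dtype=object),
                         feature_names=names or [])


def _train_arrays(dataset: WindowDataset, subjects: set, task: str
                  ) -> tuple[np.ndarray, np.ndarray]:
    idx = [i for i, w in enumerate(dataset.windows)
           if w.subject_id in subjects and not w.is_transition]
    if not idx:
        raise ValueError("no trainable windows for the requested subjects")
    X = dataset.X[idx]
    y = np.array([map_task_labels(dataset.windows[i].majority_label, task)
                  for i in idx], dtype=object)
    return X, y


def _eval_arrays(dataset: WindowDataset, subject: str
                 ) -> tuple[np.ndarray, list[LabeledWindow]]:
    idx = [i for i, w in enumerate(dataset.windows) if w.subject_id == subject]
    return dataset.X[idx], [dataset.windows[i] for i in idx]


# ---------------------------------------------------------------------------
# Nested leave-one-subject-out

def _inner_select(dataset: WindowDataset, train_subjects: list[str],
                  grid: list[dict], task: str, model_kind: str,
                  seed: int) -> dict:
    """LOSO grid search over the outer training subjects.

    Returns the grid point with the best mean transition-aware balanced
    accuracy across inner folds; ties resolve to the first point in
    declared grid order. A single-point grid is returned directly.
    """
    if len(train_subjects) < 2:
        raise ValueError("inner selection needs at least 2 subjects")
    if len(grid) == 1:
        return dict(grid[0])
    best_params, best_score = None, -np.inf
    for params in grid:
        scores = []
        for inner_test in train_subjects:
            inner_train = [s for s in train_subjects if s != inner_test]
            X_tr, y_tr = _train_arrays(dataset, set(inner_train), task)
            est = fit_classifier(model_kind, params, X_tr, y_tr, seed)
            X_te, wins_te = _eval_arrays(dataset, inner_test)
            preds = est.predict(X_te)
            scores.append(compute_metrics(wins_te, preds, task).balanced_accuracy)
        mean_score = float(np.nanmean(scores))
        if mean_score > best_score:  # strict: ties keep the earlier point
            best_score, best_params = mean_score, dict(params)
    return best_params


def inner_select(outer_train_sessions: list[RecordingSession],
                 grid: list[dict], task: str, config_id: str,
                 model_kind: str, seed: int = DEFAULT_SEED) -> dict:
    """Public wrapper of the inner LOSO grid search over raw sessions."""
    dataset = build_dataset(outer_train_sessions, config_id)
    return _inner_select(dataset, dataset.subjects(), grid, task,
                         model_kind, seed)


@dataclasses.dataclass
class EvaluationReport:
    """Aggregated nested-LOSO outcome for one task/config/model triple."""

    task: str
    config_id: str
    model_kind: str
    folds: list[FoldResult]
    aggregate: dict          # metric -> {"mean": ..., "sd": ...} in %
    pooled_confusion: pd.DataFrame
    seed: int

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "config_id": self.config_id,
            "model_kind": self.model_kind,
            "seed": self.seed,
            "aggregate": self.aggregate,
            "folds": [{
                "held_out_subject": f.held_out_subject,
                "selected_params": f.selected_params,
                "accuracy": f.accuracy,
                "balanced_accuracy": f.balanced_accuracy,
                "per_class": f.per_class,
                "n_windows": f.n_windows,
                "confusion": f.confusion.to_dict(),
            } for f in self.folds],
            "pooled_confusion": json.loads(
                self.pooled_confusion.to_json(orient="index")),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _aggregate(folds: list[FoldResult]) -> dict:
    out = {}
    for metric in ("accuracy", "balanced_accuracy"):
        vals = np.array([getattr(f, metric) for f in folds], dtype=float)
        out[metric] = {"mean": float(np.nanmean(vals)),
                       "sd": float(np.nanstd(vals))}
    return out


def nested_loso(sessions: list[RecordingSession] | None, task: str,
                config_id: str, model_kind: str,
                grid: list[dict] | None = None, seed: int = DEFAULT_SEED,
                dataset: WindowDataset | None = None,
                keep_predictions: bool = True) -> EvaluationReport:
    """Nested leave-one-subject-out evaluation.

    Either raw ``sessions`` or a prebuilt ``dataset`` may be given. The
    held-out subject's windows are excluded from every fit by
    construction, and this is re-asserted at runtime.
    """
    if dataset is None:
        if sessions is None:
            raise ValueError("either sessions or dataset is required")
        dataset = build_dataset(sessions, config_id)
    grid = grid if grid is not None else expand_grid(model_kind)
    subjects = dataset.subjects()
    if len(subjects) < 3:
        raise ValueError("nested LOSO needs at least 3 subjects")

    folds = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="class .* absent")
        for held_out in subjects:
            outer_train = [s for s in subjects if s != held_out]
            params = _inner_select(dataset, outer_train, grid, task,
                                   model_kind, seed)
            X_tr, y_tr = _train_arrays(dataset, set(outer_train), task)
            # leakage guard: no held-out window may reach the fit
            train_idx = [i for i, w in enumerate(dataset.windows)
                         if w.subject_id in set(outer_train) and not w.is_transition]
            assert all(dataset.windows[i].subject_id != held_out
                       for i in train_idx), "leakage: held-out subject in fit"
            est = fit_classifier(model_kind, params, X_tr, y_tr, seed)
            X_te, wins_te = _eval_arrays(dataset, held_out)
            preds = est.predict(X_te).astype(object)
            fold = compute_metrics(wins_te, preds, task)
            fold.held_out_subject = held_out
            fold.selected_params = params
            if not keep_predictions:
                fold.predictions = None
            folds.append(fold)

    return EvaluationReport(task=task, config_id=config_id,
                            model_kind=model_kind, folds=folds,
                            aggregate=_aggregate(folds),
                            pooled_confusion=pooled_confusion(folds),
                            seed=seed)


# ---------------------------------------------------------------------------
# Label permutation (chance-level checks)

def permute_window_labels(windows: list[LabeledWindow],
                          rng: np.random.Generator) -> list[LabeledWindow]:
    """Shuffle each subject's window-label assignments among its windows.

    The (label, transition status, adjoining pair) tuples travel together,
    breaking any feature-label association while preserving per-subject
    label marginals.
    """
    windows = list(windows)
    by_subject: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_subject.setdefault(w.subject_id, []).append(i)
    out = [None] * len(windows)
    for subject, idx in by_subject.items():
        perm = rng.permutation(len(idx))
        for k, i in enumerate(idx):
            src = windows[idx[perm[k]]]
            out[i] = dataclasses.replace(src, start=windows[i].start)
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Impairment correlation

def correlate_performance_impairment(per_subject_scores, clinical_values
                                     ) -> tuple[float, float, str]:
    """Pearson if both variables pass Shapiro-Wilk (alpha 0.05), else Spearman.

    Returns (coefficient, two-sided p-value, method). No multiple-testing
    correction is applied; p-values are raw.
    """
    x = np.asarray(per_subject_scores, dtype=float)
    y = np.asarray(clinical_values, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired inputs must share length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing values are not allowed")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    normal = (sstats.shapiro(x).pvalue > 0.05
              and sstats.shapiro(y).pvalue > 0.05)
    if normal:
        r, p = sstats.pearsonr(x, y)
        return float(r), float(p), "pearson"
    rho, p = sstats.spearmanr(x, y)
    return float(rho), float(p), "spearman"
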
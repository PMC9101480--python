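"""Binary classification of task condition from oculomotor features.

Three binary contrasts x four feature sets x four classifiers, each
evaluated with stratified 5-fold cross-validation reporting Accuracy and
binary F1 (positive class = the first-named condition group).  Inside each
fold, NaN cells are imputed with the training-fold median and features are
min-max scaled on the training fold only, so no test-fold information leaks
into the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .anova import CLASSIFICATION_CONTRASTS, CONTRASTS, ContrastSpec
from .features import FEATURE_SETS
from .normalize import apply_minmax, fit_minmax, subject_center
from .records import ValidationError

log = logging.getLogger(__name__)

CLASSIFIER_NAMES: tuple[str, ...] = ("RF", "Logistic", "ANN", "SVM")


def make_classifier(name: str, seed: int):
    """Instantiate one of the four classifiers with its fixed defaults.

    Hyperparameters: RF = 100 bootstrapped trees, majority vote; Logistic =
    L2 penalty, C=1; ANN = one hidden layer of 32 units, early stopping,
    at most 1000 epochs; SVM = RBF kernel, C=1, gamma scaled to feature
    count.
    """
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, bootstrap=True, random_state=seed)
    if name == "Logistic":
        # default penalty is L2
        return LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    if name == "ANN":
        # learning rate and patience sized for datasets of ~100 rows
        return MLPClassifier(hidden_layer_sizes=(32,), early_stopping=True,
                             max_iter=1000, learning_rate_init=0.01,
                             n_iter_no_change=25, random_state=seed)
    if name == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    raise ValidationError(f"unknown classifier {name!r}; expected one of {CLASSIFIER_NAMES}")


@dataclass(frozen=True)
class ExperimentSpec:
    """One cell of the experiment grid."""

    contrast: str  # key into anova.CONTRASTS
    feature_set: str  # key into features.FEATURE_SETS
    classifier: str  # key into CLASSIFIER_NAMES
    folds: int = 5
    seed: int = 0
    clip_test: bool = False
    f1_average: str = "binary"
    group_by_subject: bool = False


@dataclass
class CVResult:
    """Fold-wise and summary scores of one cross-validated experiment."""

    spec: ExperimentSpec
    fold_accuracy: list[float]
    fold_f1: list[float]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    @property
    def sd_f1(self) -> float:
        return float(np.std(self.fold_f1, ddof=1))


def make_dataset(
    table: pd.DataFrame,
    contrast: ContrastSpec | str,
    feature_set: str,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Build (X, y, subjects) for one binary contrast.

    One row per subject per included condition; label 1 marks the
    first-named condition group of the contrast.  The ``fix+saccades-norm``
    set applies subject-wise centering (over each subject's four conditions)
    before selecting rows.
    """
    if isinstance(contrast, str):
        contrast = CONTRASTS[contrast]
    if feature_set not in FEATURE_SETS:
        raise ValidationError(f"unknown feature set {feature_set!r}")
    columns = list(FEATURE_SETS[feature_set])
    data = subject_center(table) if feature_set == "fix+saccades-norm" else table
    mask = data["condition"].isin(contrast.group_a | contrast.group_b)
    data = data.loc[mask]
    y = data["condition"].isin(contrast.group_a).to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError(
            f"contrast {contrast.name}: one class is empty "
            f"({int(y.sum())} of {len(y)} rows in class 1)"
        )
    return data[columns].reset_index(drop=True), y, data["subject"].to_numpy()


def _impute_median(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    fill = lambda a: np.where(np.isnan(a), med, a)  # noqa: E731
    return fill(train), fill(test)


def run_cv(spec: ExperimentSpec, X: pd.DataFrame, y: np.ndarray,
           subjects: np.ndarray | None = None) -> CVResult:
    """Stratified k-fold cross-validation of one experiment cell.

    Per fold: impute with training medians, fit the min-max scaler on the
    training rows, fit the classifier, and score Accuracy and F1 on the
    held-out rows.  Deterministic for a fixed spec and seed.
    """
    if len(y) < 10:
        raise ValidationError("run_cv requires a dataset of at least 10 rows")
    if spec.group_by_subject and subjects is None:
        raise ValidationError("group_by_subject requires the subjects array")
    Xv = X.to_numpy(dtype=float)
    features = list(X.columns)
    if spec.group_by_subject:
        from sklearn.model_selection import StratifiedGroupKFold
        splitter = StratifiedGroupKFold(n_splits=spec.folds, shuffle=True,
                                        random_state=spec.seed)
        splits = splitter.split(Xv, y, groups=subjects)
    else:
        splitter = StratifiedKFold(n_splits=spec.folds, shuffle=True,
                                   random_state=spec.seed)
        splits = splitter.split(Xv, y)

    accs, f1s = [], []
    for train_idx, test_idx in splits:
        if len(set(y[test_idx])) < 2:
            log.warning("a fold has a single class in its test rows")
        tr, te = _impute_median(Xv[train_idx], Xv[test_idx])
        tr_df = pd.DataFrame(tr, columns=features)
        te_df = pd.DataFrame(te, columns=features)
        state = fit_minmax(tr_df, features)
        tr_s = apply_minmax(state, tr_df).to_numpy(dtype=float)
        te_s = apply_minmax(state, te_df, clip=spec.clip_test).to_numpy(dtype=float)
        clf = make_classifier(spec.classifier, spec.seed)
        clf.fit(tr_s, y[train_idx])
        pred = clf.predict(te_s)
        accs.append(float(accuracy_score(y[test_idx], pred)))
        f1s.append(float(f1_score(y[test_idx], pred, average=spec.f1_average,
                                  pos_label=1, zero_division=0)))
    return CVResult(spec=spec, fold_accuracy=accs, fold_f1=f1s)


def run_experiment(table: pd.DataFrame, spec: ExperimentSpec) -> CVResult:
    X, y, subjects = make_dataset(table, spec.contrast, spec.feature_set)
    return run_cv(spec, X, y, subjects)


def run_grid(
    table: pd.DataFrame,
    seed: int = 0,
    contrasts: tuple[str, ...] = CLASSIFICATION_CONTRASTS,
    feature_sets: tuple[str, ...] = tuple(FEATURE_SETS),
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
    folds: int = 5,
) -> list[CVResult]:
    """The full contrasts x feature-sets x classifiers grid (48 cells by default)."""
    results = []
    for contrast in contrasts:
        for fs in feature_sets:
            X, y, subjects = make_dataset(table, contrast, fs)
            for clf in classifiers:
                spec = ExperimentSpec(contrast=contrast, feature_set=fs,
                                      classifier=clf, folds=folds, seed=seed)
                results.append(run_cv(spec, X, y, subjects))
    return results


def results_frame(results: list[CVResult]) -> pd.DataFrame:
    """Long-form frame: one row per fold plus a summary row per cell."""
    rows = []
    for r in results:
        base = {"contrast": r.spec.contrast, "feature_set": r.spec.feature_set,
                "classifier": r.spec.classifier, "seed": r.spec.seed}
        for i, (a, f) in enumerate(zip(r.fold_accuracy, r.fold_f1)):
            rows.append({**base, "fold": str(i), "accuracy": a, "f1": f})
        rows.append({**base, "fold": "mean", "accuracy": r.mean_accuracy, "f1": r.mean_f1})
        rows.append({**base, "fold": "sd", "accuracy": r.sd_accuracy, "f1": r.sd_f1})
    return pd.DataFrame(rows)


def summary_frame(results: list[CVResult]) -> pd.DataFrame:
    """One row per grid cell with mean and sd of Accuracy and F1."""
    return pd.DataFrame([
        {"contrast": r.spec.contrast, "feature_set": r.spec.feature_set,
         "classifier": r.spec.classifier,
         "mean_accuracy": r.mean_accuracy, "sd_accuracy": r.sd_accuracy,
         "mean_f1": r.mean_f1, "sd_f1": r.sd_f1}
        for r in results
    ])
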
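"""Group-level statistics and cross-validated proficiency classification.

The feature table holds one row per epoch (36 graph features plus subject
ID and Hp/Lp group label).  Statistics: point-biserial Pearson correlation
of each feature against the binary group indicator, and a two-sample
t-test per feature (pooled-variance Student by default, Welch optional;
epoch-level by default, subject-mean level optional).  Classification: a
registry of standard classifier presets (k-NN, SVM kernels, decision
trees, logistic regression, discriminants, tree ensembles) evaluated with
stratified k-fold cross-validation, features standardized inside each
training fold only, predictions pooled across folds, Hp as the positive
class.

Cross-validation is at the epoch level by default, matching the study
design this package emulates; note that epochs of one subject may then
span folds, which leaks subject identity and inflates accuracy.  A
subject-grouped mode (``cv="subject"``) is provided for honest
generalization estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

GROUP_COL = "group"
SUBJECT_COL = "subject_id"
POSITIVE = "Hp"
META_COLS = (SUBJECT_COL, GROUP_COL)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


#: Disconnection ceiling for undefined L: with 8 nodes and tau = 0.3 every
#: finite directed shortest path is < (n - 1)/tau, so this value encodes
#: "worse than any connected graph" while staying on the L scale.
DEFAULT_L_CEILING = (8 - 1) / 0.3


def clean_feature_table(
    table: pd.DataFrame,
    policy: str = "impute",
    ceiling: float = DEFAULT_L_CEILING,
) -> pd.DataFrame:
    """Resolve undefined feature values (disconnected-graph L).

    ``policy="impute"`` (default) replaces non-finite path-length values
    with ``ceiling``, a strict upper bound on any finite shortest path in
    a thresholded graph — fully disconnected networks are themselves a
    group signal, so their epochs are kept.  ``policy="drop"`` removes the
    affected rows instead, logging the count.
    """
    feats = feature_columns(table)
    vals = table[feats].to_numpy(float)
    bad = ~np.isfinite(vals)
    if policy == "impute":
        if bad.any():
            logger.info(
                "imputing %d undefined feature values at ceiling %.3f",
                int(bad.sum()), ceiling,
            )
        out = table.copy()
        out[feats] = np.where(bad, ceiling, vals)
        return out.reset_index(drop=True)
    if policy == "drop":
        mask = ~bad.any(axis=1)
        dropped = int((~mask).sum())
        if dropped:
            logger.info("dropping %d epoch rows with undefined features", dropped)
        return table.loc[mask].reset_index(drop=True)
    raise ValueError("policy must be 'impute' or 'drop'")


def _check_groups(table: pd.DataFrame) -> None:
    counts = table[GROUP_COL].value_counts()
    if len(counts) < 2:
        raise ValueError(f"need both groups present, got {list(counts.index)}")


def feature_target_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Point-biserial Pearson correlation of each feature with the group label.

    Returns a frame indexed by feature with columns ``r`` and ``p``
    (two-sided), plus per-group means.  A constant feature yields
    ``r = NaN`` (undefined, not silently zero).
    """
    _check_groups(table)
    y = (table[GROUP_COL] == POSITIVE).astype(float).to_numpy()
    rows = {}
    for col in feature_columns(table):
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            r, p = float("nan"), float("nan")
        else:
            with warnings.catch_warnings():
                # near-constant features (e.g. imputed L) trip scipy's
                # precision-loss warning; the values are still well-defined
                warnings.simplefilter("ignore", RuntimeWarning)
                r, p = stats.pearsonr(x, y)
        rows[col] = {
            "r": r,
            "p": p,
            "mean_Hp": x[y == 1].mean(),
            "mean_Lp": x[y == 0].mean(),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def group_ttest(
    table: pd.DataFrame,
    per_subject: bool = False,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per feature between Hp and Lp.

    Epoch-level by default; ``per_subject=True`` first averages epochs
    within subject.  ``equal_var=False`` switches to Welch's t-test.
    """
    _check_groups(table)
    data = table
    if per_subject:
        data = (
            table.groupby([SUBJECT_COL, GROUP_COL], as_index=False)[
                feature_columns(table)
            ].mean()
        )
    hp = data[data[GROUP_COL] == POSITIVE]
    lp = data[data[GROUP_COL] != POSITIVE]
    if len(hp) < 2 or len(lp) < 2:
        raise ValueError("each group needs at least two rows for a t-test")
    rows = {}
    for col in feature_columns(table):
        a = hp[col].to_numpy(float)
        b = lp[col].to_numpy(float)
        if a.std() == 0 and b.std() == 0:
            # degenerate: no within-group variance
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t = float(np.inf) * np.sign(a.mean() - b.mean())
                p = 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows[col] = {"t": float(t), "p": float(p)}
    return pd.DataFrame.from_dict(rows, orient="index")


def benjamini_hochberg(pvals: pd.Series) -> pd.Series:
    """BH-adjusted q-values (optional; off by default in reports)."""
    p = pvals.to_numpy(float)
    order = np.argsort(p)
    m = len(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        q[order[rank]] = running
    return pd.Series(q, index=pvals.index)


# ---------------------------------------------------------------------------
# Classifier registry

def classifier_registry(seed: int = 0) -> dict[str, object]:
    """Named classifier presets spanning k-NN, SVM, trees, and functional models.

    Tree "fine/medium/coarse" granularity is controlled by the maximum
    number of leaves (100/20/4); Gaussian-SVM granularity by the kernel
    scale s in gamma = 1/s^2 with s = sqrt(P)/4, sqrt(P), 4 sqrt(P) for P
    features (evaluated at fit time via gamma="scale" multipliers is not
    possible, so P=36 is baked in for the defaults).
    """
    P = 36.0
    return {
        "fine_tree": DecisionTreeClassifier(max_leaf_nodes=100, random_state=seed),
        "medium_tree": DecisionTreeClassifier(max_leaf_nodes=20, random_state=seed),
        "coarse_tree": DecisionTreeClassifier(max_leaf_nodes=4, random_state=seed),
        "linear_discriminant": LinearDiscriminantAnalysis(),
        "quadratic_discriminant": QuadraticDiscriminantAnalysis(reg_param=1e-6),
        "logistic_regression": LogisticRegression(max_iter=2000),
        "linear_svm": SVC(kernel="linear", C=1.0),
        "quadratic_svm": SVC(kernel="poly", degree=2, coef0=1.0, C=1.0),
        "cubic_svm": SVC(kernel="poly", degree=3, coef0=1.0, C=1.0),
        "fine_gaussian_svm": SVC(kernel="rbf", gamma=16.0 / P, C=1.0),
        "medium_gaussian_svm": SVC(kernel="rbf", gamma=1.0 / P, C=1.0),
        "coarse_gaussian_svm": SVC(kernel="rbf", gamma=1.0 / (16.0 * P), C=1.0),
        "fine_knn": KNeighborsClassifier(n_neighbors=1),
        "medium_knn": KNeighborsClassifier(n_neighbors=10),
        "coarse_knn": KNeighborsClassifier(n_neighbors=100),
        "cosine_knn": KNeighborsClassifier(n_neighbors=10, metric="cosine"),
        "cubic_knn": KNeighborsClassifier(n_neighbors=10, p=3),
        "weighted_knn": KNeighborsClassifier(n_neighbors=10, weights="distance"),
        "boosted_trees": AdaBoostClassifier(n_estimators=30, random_state=seed),
        "bagged_trees": RandomForestClassifier(n_estimators=30, random_state=seed),
    }


@dataclass
class ClassificationReport:
    """Pooled cross-validation metrics per preset, plus fold bookkeeping."""

    metrics: pd.DataFrame  # index preset; accuracy, precision, recall, f1, auc
    fold_assignments: np.ndarray
    seed: int
    k_folds: int
    predictions: dict[str, np.ndarray] = field(default_factory=dict)
    scores: dict[str, np.ndarray] = field(default_factory=dict)


def _pooled_metrics(y: np.ndarray, yhat: np.ndarray, score: np.ndarray) -> dict:
    tp = int(np.sum((y == 1) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    acc = (tp + tn) / len(y)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    auc = roc_auc_score(y, score)
    return {
        "accuracy": acc,
        "precision": prec,
        "recall": rec,
        "f1": f1,
        "auc": auc,
    }


def run_classifiers(
    table: pd.DataFrame,
    presets: list[str] | None = None,
    k_folds: int = 10,
    seed: int = 0,
    cv: str = "epoch",
) -> ClassificationReport:
    """Cross-validated evaluation of classifier presets on the feature table.

    Stratified k-fold (default 10) at the epoch level, or subject-grouped
    folds with ``cv="subject"``.  Within each fold, a StandardScaler is
    fitted on the training rows only and applied to the held-out rows; the
    held-out predictions and scores are pooled across folds before
    computing accuracy, precision, recall, F1 and AUC with Hp positive.
    """
    table = clean_feature_table(table)
    _check_groups(table)
    registry = classifier_registry(seed)
    if presets is None:
        presets = list(registry)
    unknown = [p for p in presets if p not in registry]
    if unknown:
        raise KeyError(f"unknown preset(s) {unknown}; registry: {list(registry)}")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")

    X = table[feature_columns(table)].to_numpy(float)
    y = (table[GROUP_COL] == POSITIVE).astype(int).to_numpy()
    if cv == "epoch":
        # stratified folds need at least one member of each class per fold
        n_splits = min(k_folds, int(np.bincount(y).min()))
        if n_splits < 2:
            raise ValueError("too few epochs per class for cross-validation")
        if n_splits < k_folds:
            logger.info("reducing folds from %d to %d (small class)", k_folds, n_splits)
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))
        k_folds = n_splits
    elif cv == "subject":
        groups = table[SUBJECT_COL].to_numpy()
        splitter = GroupKFold(n_splits=min(k_folds, len(np.unique(groups))))
        splits = list(splitter.split(X, y, groups))
    else:
        raise ValueError("cv must be 'epoch' or 'subject'")

    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(splits):
        folds[test_idx] = f

    rows = {}
    predictions: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray] = {}
    for name in presets:
        yhat = np.empty(len(y), dtype=int)
        score = np.empty(len(y), dtype=float)
        for train_idx, test_idx in splits:
            est = clone(registry[name])
            # k-NN presets with fixed large k stay runnable on small tables
            if hasattr(est, "n_neighbors") and est.n_neighbors > len(train_idx):
                est.set_params(n_neighbors=len(train_idx))
            pipe = Pipeline(
                [("scale", StandardScaler()), ("clf", est)]
            )
            pipe.fit(X[train_idx], y[train_idx])
            yhat[test_idx] = pipe.predict(X[test_idx])
            if hasattr(pipe, "predict_proba"):
                score[test_idx] = pipe.predict_proba(X[test_idx])[:, 1]
            else:
                score[test_idx] = pipe.decision_function(X[test_idx])
        rows[name] = _pooled_metrics(y, yhat, score)
        predictions[name] = yhat
        scores[name] = score
    metrics = pd.DataFrame.from_dict(rows, orient="index")
    return ClassificationReport(metrics, folds, seed, k_folds, predictions, scores)


def permute_labels(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Return a copy of the table with group labels randomly permuted."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    out[GROUP_COL] = rng.permutation(out[GROUP_COL].to_numpy())
    return out
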
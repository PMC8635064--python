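"""Classification of loneliness / social-support targets from the feature
table.

The workflow mirrors small-cohort clinical ML practice: binarize a scale
score (fixed cutoff, median, or 75th-percentile split), evaluate a model
family by leave-one-subject-out cross-validation with per-fold z-scoring,
pool the held-out decision scores into one confusion matrix / weighted F1 /
ROC AUC, rank features by Gini impurity reduction, and grow the feature set
incrementally along that ranking.

F1 is support-weighted over the two classes; that convention uniquely
reconciles the confusion matrices with the F1 values this package's worked
examples assert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

# ---------------------------------------------------------------------------
# Feature table assembly


@dataclass
class FeatureTable:
    """Participant x feature matrix plus the raw target scores."""

    features: pd.DataFrame  # indexed by participant id, numeric columns
    targets: pd.DataFrame   # indexed by participant id, scale scores
    imputation_log: List[Tuple[str, str]] = field(default_factory=list)
    dropped_ids: List[str] = field(default_factory=list)

    @property
    def participant_ids(self) -> List[str]:
        return list(self.features.index)

    @property
    def feature_names(self) -> List[str]:
        return list(self.features.columns)


def assemble_feature_table(
    features: pd.DataFrame,
    demographics: pd.DataFrame,
    scores: pd.DataFrame,
) -> FeatureTable:
    """Inner-join features, demographics and target scores on participant id.

    Categorical demographics are one-hot encoded; missing numeric feature
    values are imputed by the column median (and logged).  Participants
    missing from any input are dropped (and logged); duplicate ids raise.
    """
    for name, frame in (("features", features), ("demographics", demographics),
                        ("scores", scores)):
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate participant ids in {name}: {dupes}")
    demo = pd.get_dummies(demographics, dtype=float)
    joined = features.join(demo, how="inner")
    common = joined.index.intersection(scores.index)
    all_ids = features.index.union(demo.index).union(scores.index)
    dropped = sorted(set(all_ids) - set(common))
    joined = joined.loc[common]
    log: List[Tuple[str, str]] = []
    for column in joined.columns:
        col = pd.to_numeric(joined[column], errors="coerce")
        missing = col.isna()
        if missing.any():
            col = col.fillna(col.median())
            log.extend((str(pid), str(column))
                       for pid in joined.index[missing])
        joined[column] = col
    return FeatureTable(features=joined, targets=scores.loc[common].copy(),
                        imputation_log=log, dropped_ids=[str(i) for i in dropped])


# ---------------------------------------------------------------------------
# Target binarization


@dataclass
class BinaryTarget:
    name: str
    rule: str                 # "fixed" | "median" | "pct75"
    cutoff_value: float
    labels: np.ndarray        # 0/1, aligned with the scores passed in

    @property
    def positive_count(self) -> int:
        return int(self.labels.sum())


def binarize_target(
    scores: Sequence[float],
    rule: str,
    cutoff: Optional[float] = None,
    name: str = "target",
) -> BinaryTarget:
    """Label 1 iff score strictly greater than the cutoff.

    ``fixed`` uses the supplied cutoff (e.g. 40 for the UCLA-3 loneliness
    scale); ``median``/``pct75`` use the empirical quantile of the observed
    scores.  A split that leaves one class empty raises (degenerate target).
    """
    arr = np.asarray(scores, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("scores contain missing values; drop them first")
    if rule == "fixed":
        if cutoff is None:
            raise ValueError("fixed rule requires a cutoff value")
        cut = float(cutoff)
    elif rule == "median":
        cut = float(np.median(arr))
    elif rule == "pct75":
        cut = float(np.quantile(arr, 0.75))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if rule in ("median", "pct75") and np.unique(arr).size < 2:
        raise ValueError("all scores identical under a split rule")
    labels = (arr > cut).astype(int)
    if labels.min() == labels.max():
        raise ValueError(
            f"degenerate target {name!r}: cutoff {cut} leaves one class empty")
    return BinaryTarget(name=name, rule=rule, cutoff_value=cut, labels=labels)


# ---------------------------------------------------------------------------
# Model zoo

#: Hyperparameter defaults per model family (single hidden layer ANNs with
#: Adam; RBF-kernel SVM; distance-weighted Chebyshev kNN; shallow forest).
MODEL_FAMILIES = ("ann_logistic", "ann_tanh", "ann_relu", "svm_rbf", "knn",
                  "tree", "random_forest")

_ANN_COMMON = dict(hidden_layer_sizes=(200,), solver="adam", max_iter=1000,
                   tol=1e-4)

FAMILY_DEFAULTS: Dict[str, Dict] = {
    "ann_logistic": dict(_ANN_COMMON, activation="logistic"),
    "ann_tanh": dict(_ANN_COMMON, activation="tanh"),
    "ann_relu": dict(_ANN_COMMON, activation="relu",
                     hidden_layer_sizes=(100,)),
    "svm_rbf": dict(C=1.0, tol=0.001, kernel="rbf", gamma="auto"),
    "knn": dict(n_neighbors=9, metric="chebyshev", weights="distance"),
    "tree": dict(max_depth=100, min_samples_leaf=1),
    "random_forest": dict(n_estimators=8, max_features=4, max_depth=7,
                          min_samples_split=2),
}


@dataclass
class ModelSpec:
    family: str
    hyperparameters: Dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        merged = dict(FAMILY_DEFAULTS[self.family])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged


def make_classifier(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a model spec."""
    params = dict(spec.hyperparameters)
    if spec.family.startswith("ann"):
        return MLPClassifier(random_state=spec.seed, **params)
    if spec.family == "svm_rbf":
        return SVC(random_state=spec.seed, **params)
    if spec.family == "knn":
        return KNeighborsClassifier(**params)
    if spec.family == "tree":
        return DecisionTreeClassifier(random_state=spec.seed, **params)
    if spec.family == "random_forest":
        n_feat = params.pop("max_features", None)
        return RandomForestClassifier(random_state=spec.seed,
                                      max_features=n_feat, **params)
    raise AssertionError(spec.family)


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    f1_weighted: float
    flags: List[str] = field(default_factory=list)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Sensitivity, specificity and support-weighted two-class F1.

    The weighted F1 averages the per-class F1 scores with supports TP+FN
    (positive class) and TN+FP (negative class).  Zero-denominator metrics
    are reported as 0 with a flag.
    """
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValueError("invalid confusion counts")
    flags: List[str] = []

    def safe_div(num: float, den: float, label: str) -> float:
        if den == 0:
            flags.append(label)
            return 0.0
        return num / den

    sensitivity = safe_div(tp, tp + fn, "sensitivity_undefined")
    specificity = safe_div(tn, tn + fp, "specificity_undefined")
    f1_pos = safe_div(2 * tp, 2 * tp + fp + fn, "f1_pos_undefined")
    f1_neg = safe_div(2 * tn, 2 * tn + fn + fp, "f1_neg_undefined")
    support_pos, support_neg = tp + fn, tn + fp
    f1_weighted = safe_div(support_pos * f1_pos + support_neg * f1_neg,
                           support_pos + support_neg, "f1_undefined")
    return ConfusionMetrics(sensitivity, specificity, f1_weighted, flags)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie) over all +/- pairs.

    Computed via the midrank (Mann-Whitney) identity, which equals the
    all-pairs definition exactly, ties included.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Leave-one-subject-out evaluation


@dataclass
class EvalResult:
    predictions: np.ndarray      # held-out predicted labels, fold order
    decision_scores: np.ndarray  # held-out decision scores, fold order
    confusion: Dict[str, int]    # TP / FP / TN / FN
    sensitivity: float
    specificity: float
    f1_weighted: float
    auc: float


def _decision_scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def loocv_evaluate(
    table: FeatureTable | pd.DataFrame,
    target: BinaryTarget,
    spec: ModelSpec,
    feature_subset: Optional[Sequence[str]] = None,
) -> EvalResult:
    """Leave-one-subject-out evaluation of one model family.

    For every participant the model is fit on all others — features z-scored
    with training-fold statistics only — and the held-out label and decision
    score recorded.  The confusion matrix is aggregated over folds and the
    pooled decision scores yield a single AUC.  Deterministic given the spec
    seed.
    """
    X_frame = table.features if isinstance(table, FeatureTable) else table
    if feature_subset is not None:
        if not list(feature_subset):
            raise ValueError("feature subset is empty")
        X_frame = X_frame[list(feature_subset)]
    X = X_frame.to_numpy(dtype=float)
    y = np.asarray(target.labels, dtype=int)
    if len(y) != len(X):
        raise ValueError("target labels not aligned with feature rows")
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least 2 participants per class for LOOCV")

    preds = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    base = make_classifier(spec)
    # a forest's per-split feature budget cannot exceed the subset size
    mf = getattr(base, "max_features", None)
    if isinstance(mf, int) and mf > X.shape[1]:
        base.set_params(max_features=X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            X_train, y_train = X[mask], y[mask]
            if y_train.min() == y_train.max():
                raise ValueError("a class is absent from a training fold")
            mu = X_train.mean(axis=0)
            sd = X_train.std(axis=0)
            sd[sd == 0] = 1.0
            clf = clone(base)
            clf.fit((X_train - mu) / sd, y_train)
            X_test = ((X[i] - mu) / sd).reshape(1, -1)
            preds[i] = int(clf.predict(X_test)[0])
            scores[i] = float(_decision_scores(clf, X_test)[0])

    tp = int(np.sum((preds == 1) & (y == 1)))
    fp = int(np.sum((preds == 1) & (y == 0)))
    tn = int(np.sum((preds == 0) & (y == 0)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    metrics = confusion_metrics(tp, fp, tn, fn)
    return EvalResult(
        predictions=preds,
        decision_scores=scores,
        confusion={"TP": tp, "FP": fp, "TN": tn, "FN": fn},
        sensitivity=metrics.sensitivity,
        specificity=metrics.specificity,
        f1_weighted=metrics.f1_weighted,
        auc=roc_auc(scores, y),
    )


# ---------------------------------------------------------------------------
# Gini impurity feature ranking


def _gini_impurity(n1: np.ndarray, n: np.ndarray) -> np.ndarray:
    p1 = n1 / n
    return 1.0 - p1 ** 2 - (1.0 - p1) ** 2


def _best_split_gain(x: np.ndarray, y: np.ndarray) -> float:
    """Impurity reduction of the best single-threshold binary split of x."""
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = len(y)
    n1 = int(ys.sum())
    parent = float(_gini_impurity(np.array(n1), np.array(n)))
    boundaries = np.nonzero(np.diff(xs) > 0)[0]  # split after these positions
    if boundaries.size == 0:
        return 0.0
    left_n = boundaries + 1
    left_1 = np.cumsum(ys)[boundaries]
    right_n = n - left_n
    right_1 = n1 - left_1
    child = (left_n * _gini_impurity(left_1, left_n)
             + right_n * _gini_impurity(right_1, right_n)) / n
    return parent - float(child.min())


def gini_rank(
    table: FeatureTable | pd.DataFrame, target: BinaryTarget
) -> pd.DataFrame:
    """Rank features by Gini gain of their best single-threshold split.

    Returns a frame with columns ``feature`` and ``gain``, sorted by
    descending gain with alphabetical tie-break.  Constant targets raise.
    """
    X = table.features if isinstance(table, FeatureTable) else table
    y = np.asarray(target.labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("constant target")
    rows = [(name, _best_split_gain(X[name].to_numpy(dtype=float), y))
            for name in X.columns]
    frame = pd.DataFrame(rows, columns=["feature", "gain"])
    return (frame.sort_values(["gain", "feature"],
                              ascending=[False, True], kind="mergesort")
            .reset_index(drop=True))


class GiniFeatureRanker(BaseEstimator, TransformerMixin):
    """Feature selector keeping the top-k Gini-ranked features.

    Parameters
    ----------
    k : int or None
        Number of top-ranked features ``transform`` keeps (None keeps all).

    Attributes
    ----------
    ranking_ : list of str
        Feature names in descending-gain order (ties alphabetical).
    gains_ : dict
        Feature name -> Gini gain.
    """

    def __init__(self, k: Optional[int] = None):
        self.k = k

    def fit(self, X: pd.DataFrame, y: Sequence[int]) -> "GiniFeatureRanker":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=int)
        target = BinaryTarget("y", "fixed", 0.5, y)
        if y.min() == y.max():
            raise ValueError("constant target")
        ranked = gini_rank(X, target)
        self.ranking_ = ranked["feature"].tolist()
        self.gains_ = dict(zip(ranked["feature"], ranked["gain"]))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "ranking_"):
            raise RuntimeError("GiniFeatureRanker is not fitted")
        k = len(self.ranking_) if self.k is None else int(self.k)
        return pd.DataFrame(X)[self.ranking_[:k]]


# ---------------------------------------------------------------------------
# Incremental top-k selection


@dataclass
class SelectionResult:
    best_k: int
    best_subset: List[str]
    best_result: EvalResult
    curve: List[Tuple[int, float]]  # (k, AUC)


def incremental_selection(
    table: FeatureTable | pd.DataFrame,
    target: BinaryTarget,
    spec: ModelSpec,
    ranked: Sequence[str],
    k_max: int,
) -> SelectionResult:
    """Evaluate the top-1..top-k_max ranked feature subsets by LOOCV.

    Returns the k maximizing the pooled AUC (ties favor the smaller k), the
    winning subset/result and the full (k, AUC) curve.  The ranking is
    computed once on the full table and frozen, so the curve carries the
    optimistic selection bias inherent to that procedure.
    """
    ranked = list(ranked)
    if not 1 <= k_max <= len(ranked):
        raise ValueError("k_max out of range")
    curve: List[Tuple[int, float]] = []
    best: Tuple[int, EvalResult] | None = None
    for k in range(1, k_max + 1):
        result = loocv_evaluate(table, target, spec, ranked[:k])
        curve.append((k, result.auc))
        if best is None or result.auc > best[1].auc:
            best = (k, result)
    assert best is not None
    return SelectionResult(best_k=best[0], best_subset=ranked[:best[0]],
                           best_result=best[1], curve=curve)
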
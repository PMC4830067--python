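"""Effect-size-ranked incremental feature selection with a linear SVM.

Features (original discrete variables or PC scores) are ranked by
descending Cohen's d between the two groups. A linear soft-margin SVM
(c = 1) is then evaluated by stratified 10-fold cross-validation on the
top-k features for k = 1..K; the optimal k is the smallest k attaining the
maximum mean CV accuracy.

Two ranking modes are provided. ``paper-faithful`` ranks once on the full
data set before cross-validation — the procedure as commonly described,
which lets label information leak into the ranking and optimistically
biases the curve on uninformative data. ``leakage-safe`` re-ranks within
every training fold. Standardization is fitted inside the training folds in
both modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import EmptyFeatureError, InvalidLabelsError, StratificationError
from .schema import PLANES
from .stats import cohens_d, fit_pca

SOFT_MARGIN = 1.0
CV_FOLDS = 10


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise InvalidLabelsError(
            "need exactly two classes with >=2 members each"
        )
    return y


def rank_by_effect_size(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Column indices sorted by descending Cohen's d between the two label
    groups; ties broken by ascending original column index."""
    X = np.asarray(features, dtype=float)
    y = _check_labels(labels)
    a, b = np.unique(y)
    ia, ib = y == a, y == b
    d = np.array(
        [
            cohens_d(
                X[ia, j].mean(), X[ia, j].std(ddof=1), int(ia.sum()),
                X[ib, j].mean(), X[ib, j].std(ddof=1), int(ib.sum()),
            )
            for j in range(X.shape[1])
        ]
    )
    # stable sort on -d keeps original order among ties
    return np.argsort(-d, kind="stable")


def _make_svm():
    return make_pipeline(
        StandardScaler(), SVC(kernel="linear", C=SOFT_MARGIN)
    )


def _folds(y: np.ndarray, folds: int, seed: int):
    if np.unique(y).size != 2:
        raise InvalidLabelsError("need exactly two classes")
    if min(np.bincount(pd.factorize(y)[0])) < folds:
        raise StratificationError(
            "smallest class has fewer members than the fold count; a test "
            "fold would miss it"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(y.size), y))


def svm_cv_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = CV_FOLDS,
    seed: int = 0,
) -> float:
    """Mean stratified k-fold CV accuracy of the linear soft-margin SVM.

    Standardization statistics and the SVM are fitted on training folds
    only; the returned value is the unweighted mean of per-fold accuracies.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _check_labels(labels)
    if y.size < folds:
        raise StratificationError(f"n={y.size} < {folds} folds")
    accs = []
    for train, test in _folds(y, folds, seed):
        if np.unique(y[train]).size < 2:
            raise StratificationError("a class is absent from a training fold")
        clf = _make_svm()
        clf.fit(X[train], y[train])
        accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    return float(np.mean(accs))


@dataclass
class SelectionResult:
    """Outcome of incremental effect-size-ranked SVM selection."""

    ranking: np.ndarray  # feature indices, descending d
    accuracy_curve: np.ndarray  # mean CV accuracy for k = 1..K
    optimal_k: int  # smallest maximizer
    max_accuracy: float
    feature_names: list[str] = field(default_factory=list)  # top optimal_k
    mode: str = "paper-faithful"
    plane_fractions: dict[str, float] = field(default_factory=dict)
    variance_explained: float | None = None  # cumulative, PC pathway only


def _provenance(feature_names: list[str]) -> dict[str, float]:
    """Fraction of selected variables per anatomical plane (original
    variables only; names follow joint_plane_variable)."""
    if not feature_names:
        return {}
    counts = {p: 0 for p in PLANES}
    for name in feature_names:
        parts = name.split("_")
        if len(parts) >= 2 and parts[1] in counts:
            counts[parts[1]] += 1
    total = len(feature_names)
    return {p: c / total for p, c in counts.items() if c}


def incremental_selection(
    features: np.ndarray,
    labels: np.ndarray,
    ranking: np.ndarray | None = None,
    mode: str = "paper-faithful",
    folds: int = CV_FOLDS,
    seed: int = 0,
    feature_names: list[str] | None = None,
    max_features: int | None = None,
) -> SelectionResult:
    """Evaluate the accuracy-vs-k curve and pick the optimal feature count.

    ``paper-faithful`` uses one ranking computed on the full data (passed in
    or recomputed); ``leakage-safe`` re-ranks inside each training fold, so
    the top-k set may differ between folds.
    """
    X = np.asarray(features, dtype=float)
    y = _check_labels(labels)
    if X.shape[1] == 0:
        raise EmptyFeatureError("no candidate features")
    if mode not in ("paper-faithful", "leakage-safe"):
        raise ValueError(f"unknown mode: {mode}")
    K = X.shape[1] if max_features is None else min(max_features, X.shape[1])
    if ranking is None:
        ranking = rank_by_effect_size(X, y)
    ranking = np.asarray(ranking, dtype=int)

    splits = _folds(y, folds, seed)
    fold_rankings = []
    for train, _ in splits:
        if mode == "leakage-safe":
            fold_rankings.append(rank_by_effect_size(X[train], y[train]))
        else:
            fold_rankings.append(ranking)

    curve = np.empty(K)
    for k in range(1, K + 1):
        accs = []
        for (train, test), rk in zip(splits, fold_rankings):
            cols = rk[:k]
            clf = _make_svm()
            clf.fit(X[np.ix_(train, cols)], y[train])
            accs.append(float(np.mean(clf.predict(X[np.ix_(test, cols)]) == y[test])))
        curve[k - 1] = np.mean(accs)

    optimal_k = int(np.argmax(curve)) + 1  # argmax returns the first (smallest) maximizer
    names = list(feature_names) if feature_names is not None else []
    top_names = [names[j] for j in ranking[:optimal_k]] if names else []
    return SelectionResult(
        ranking=ranking,
        accuracy_curve=curve,
        optimal_k=optimal_k,
        max_accuracy=float(curve[optimal_k - 1]),
        feature_names=top_names,
        mode=mode,
        plane_fractions=_provenance(top_names),
    )


def run_pc_pathway(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    mode: str = "paper-faithful",
    folds: int = CV_FOLDS,
    seed: int = 0,
    max_features: int | None = None,
) -> SelectionResult:
    """PC-score pathway: standardize, decompose, then rank and
    incrementally select PC scores. Reports the cumulative variance
    explained by the selected components."""
    y = _check_labels(labels)
    model = fit_pca(features)
    Z = model.scores
    result = incremental_selection(
        Z, y, mode=mode, folds=folds, seed=seed,
        feature_names=[f"PC{j + 1}" for j in range(Z.shape[1])],
        max_features=max_features,
    )
    # variance explained by the selected (not necessarily leading) PCs
    total = model.column_sds.size
    sel = result.ranking[: result.optimal_k]
    result.variance_explained = float(model.eigenvalues[sel].sum() / total)
    return result
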
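"""Cross-validated classification benchmark on a feature matrix.

The benchmark mirrors standard biomarker-panel evaluation: a linear
support vector machine (cost 100, tolerance 0.01) and a random forest
(500 trees, sqrt-of-features subsets) are evaluated by balanced
(stratified) ten-fold cross-validation, repeated with fresh fold
assignments; held-out scores are pooled per repeat into one metric set
(accuracy, AUC, sensitivity, specificity, PPV, NPV; positive class D).
A tuning grid over the SVM's cost and tolerance — optionally on
permuted class labels — probes susceptibility to overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .model import FeatureMatrix

POSITIVE_CLASS = "D"

DEFAULT_COSTS = (0.1, 1.0, 100.0, 1000.0)
DEFAULT_TOLERANCES = (0.01, 0.1, 1.0)


@dataclass
class ModelSpec:
    family: str = "linear_svm"  # or "random_forest"
    cost: float = 100.0
    tolerance: float = 0.01
    n_trees: int = 500
    seed: int = 0

    def validate(self) -> None:
        if self.family not in ("linear_svm", "random_forest"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.cost <= 0 or self.tolerance <= 0 or self.n_trees < 1:
            raise ValueError("invalid model parameters")


@dataclass
class MetricSet:
    acc: Optional[float]
    auc: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "acc": self.acc,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def _derive_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2 ** 31))


def balanced_folds(labels: Sequence[str], k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (0..k-1 per sample); per-fold class
    proportions are within one member of the global proportions."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.zeros(len(labels), dtype=int)
    small = classes[counts < k]
    if len(small):
        raise ValueError(
            f"class(es) {list(small)} have fewer than k={k} members"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        assignment[test_idx] = fold
    return assignment


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> Optional[float]:
    """AUC as the Mann–Whitney rank statistic; ties count one half."""
    pos = y_true
    n_pos = int(pos.sum())
    n_neg = len(pos) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_metrics(
    truth: Sequence[str],
    scores: Sequence[float],
    threshold: float = 0.5,
    positive: str = POSITIVE_CLASS,
) -> MetricSet:
    """Confusion-matrix metrics at a score threshold plus rank AUC.

    Metrics with a zero denominator are reported as None.
    """
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    y = truth == positive
    pred = scores >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    return MetricSet(
        acc=ratio(tp + tn, tp + tn + fp + fn),
        auc=rank_auc(y, scores),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )


# ------------------------------------------------------------- backends

ScoreFn = Callable[[np.ndarray], np.ndarray]


def _fit_scorer(spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int) -> ScoreFn:
    """Train a classifier and return a score function mapping feature
    rows to probabilities of the positive class in [0, 1]."""
    if spec.family == "linear_svm":
        scaler = StandardScaler().fit(X)
        svm = SVC(kernel="linear", C=spec.cost, tol=spec.tolerance)
        svm.fit(scaler.transform(X), y)
        dec = svm.decision_function(scaler.transform(X)).reshape(-1, 1)
        # Platt-style calibration of decision values on the training fold
        calib = LogisticRegression(max_iter=1000).fit(dec, y)

        def score(Xt: np.ndarray) -> np.ndarray:
            d = svm.decision_function(scaler.transform(Xt)).reshape(-1, 1)
            return calib.predict_proba(d)[:, list(calib.classes_).index(True)]

        return score

    rf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features="sqrt",
        random_state=seed,
    )
    rf.fit(X, y)

    def score(Xt: np.ndarray) -> np.ndarray:
        return rf.predict_proba(Xt)[:, list(rf.classes_).index(True)]

    return score


def _single_cv(
    fm: FeatureMatrix, spec: ModelSpec, k: int, fold_seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """One balanced k-fold CV pass; returns pooled (truth, scores) in
    measurement order."""
    X = fm.values
    labels = fm.y
    y = labels == POSITIVE_CLASS
    folds = balanced_folds(labels, k=k, seed=fold_seed)
    scores = np.empty(len(labels))
    for fold in range(folds.max() + 1):
        test = folds == fold
        train = ~test if k > 1 else test  # k=1: train == test == all data
        score_fn = _fit_scorer(spec, X[train], y[train], seed=fold_seed + fold)
        scores[test] = score_fn(X[test])
    return labels, scores


def repeated_cv(
    fm: FeatureMatrix,
    model: ModelSpec | None = None,
    repeats: int = 100,
    k: int = 10,
    seed: int = 0,
) -> List[MetricSet]:
    """Repeated balanced k-fold CV; one pooled MetricSet per repeat."""
    model = model or ModelSpec()
    model.validate()
    fm.validate()
    results = []
    for rep in range(repeats):
        truth, scores = _single_cv(fm, model, k, _derive_seed(seed, rep))
        results.append(compute_metrics(truth, scores))
    return results


def tuning_grid(
    fm: FeatureMatrix,
    costs: Sequence[float] = DEFAULT_COSTS,
    tolerances: Sequence[float] = DEFAULT_TOLERANCES,
    k: int = 10,
    seed: int = 0,
    permute: bool = False,
) -> Dict[Tuple[float, float], MetricSet]:
    """Single balanced k-fold CV of the linear SVM per (cost, tolerance)
    combination; optionally with permuted class labels."""
    fm.validate()
    if permute:
        fm = FeatureMatrix(
            measurement_ids=fm.measurement_ids,
            cluster_ids=fm.cluster_ids,
            values=fm.values,
            labels=permute_labels(fm.labels, seed=seed),
        )
    fold_seed = _derive_seed(seed, 0)
    results: Dict[Tuple[float, float], MetricSet] = {}
    for cost in costs:
        for tol in tolerances:
            spec = ModelSpec(family="linear_svm", cost=cost, tolerance=tol)
            truth, scores = _single_cv(fm, spec, k, fold_seed)
            results[(cost, tol)] = compute_metrics(truth, scores)
    return results


def permute_labels(labels: Dict[str, str], seed: int = 0) -> Dict[str, str]:
    """Uniform random permutation of the label values; counts preserved."""
    keys = list(labels)
    values = [labels[m] for m in keys]
    rng = np.random.default_rng(seed)
    permuted = [values[i] for i in rng.permutation(len(values))]
    return dict(zip(keys, permuted))


def summarize(results: Sequence[MetricSet]) -> Dict[str, Dict[str, float]]:
    """Mean and SD per metric over repeats, skipping undefined values."""
    out: Dict[str, Dict[str, float]] = {}
    for name in ("acc", "auc", "sensitivity", "specificity", "ppv", "npv"):
        vals = [getattr(m, name) for m in results if getattr(m, name) is not None]
        if vals:
            out[name] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
    return out
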
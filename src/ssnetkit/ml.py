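"""Treatment-response prediction from expression and network features.

Binary classification of responders (clinical benefit, CB) versus
nonresponders (no clinical benefit, NCB); intermediate (ICB) patients are
excluded.  The protocol is leave-one-out cross-validation with in-fold
ANOVA-F feature selection (k swept from 10 to 100 in steps of 10) feeding a
balanced L2 logistic regression; performance is accuracy and F1 with
responder as the positive class.  An across-study variant trains on one
cohort and reports test-set ROC AUC on another after intersecting the
feature spaces.  Feature selection and standardisation statistics are
always recomputed inside the training fold — never on the full data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io_formats import ClinicalTable

DEFAULT_K_GRID = tuple(range(10, 101, 10))
POSITIVE_LABEL = "CB"


@dataclass
class ResponseDataset:
    """Features aligned to CB/NCB-labelled samples (ICB excluded)."""

    features: pd.DataFrame  # samples x features
    labels: pd.Series  # sample_id -> {"CB", "NCB"}

    def __post_init__(self) -> None:
        if list(self.features.index) != list(self.labels.index):
            raise ValueError("features and labels must be aligned on the same samples")
        bad = set(self.labels.unique()) - {"CB", "NCB"}
        if bad:
            raise ValueError(f"labels must be CB/NCB only, got extra {bad}")

    @property
    def y(self) -> np.ndarray:
        return (self.labels == POSITIVE_LABEL).to_numpy(dtype=int)


def make_response_dataset(fm: pd.DataFrame, clinical: ClinicalTable) -> ResponseDataset:
    """Restrict a feature matrix to CB/NCB samples present in the clinic table."""
    clin = clinical.to_frame()
    keep = [s for s in fm.index if s in clin.index and clin.loc[s, "benefit"] in ("CB", "NCB")]
    labels = clin.loc[keep, "benefit"].rename("label")
    return ResponseDataset(features=fm.loc[keep], labels=labels)


@dataclass
class PredictionResult:
    k: int
    accuracy: float
    f1: float
    auc: float
    predictions: pd.Series
    scores: pd.Series
    confusion: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Feature selection


def anova_f_select(train_features: pd.DataFrame, train_labels: np.ndarray, k: int) -> list[str]:
    """Top-k features by one-way ANOVA F between classes.

    Constant features get F = 0 (ranked last); ties break lexicographically
    by feature id.
    """
    if k > train_features.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {train_features.shape[1]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        F, _ = f_classif(train_features.to_numpy(dtype=float), train_labels)
    F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)
    order = sorted(train_features.columns, key=lambda c: (-F[train_features.columns.get_loc(c)], c))
    return order[:k]


def _make_model(C: float = 1.0) -> LogisticRegression:
    # balanced class weights w_c = n / (2 * n_c); deterministic lbfgs solver
    return LogisticRegression(
        C=C,
        class_weight="balanced",
        solver="lbfgs",
        tol=1e-6,
        max_iter=1000,
    )


def _standardize(train: np.ndarray, *others: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return tuple((arr - mu) / sd for arr in (train, *others))


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray):
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = (tp + tn) / y_true.size
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    auc = float(roc_auc_score(y_true, scores)) if len(np.unique(y_true)) == 2 else float("nan")
    return acc, f1, auc, {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


# ---------------------------------------------------------------------------
# LOOCV


def loocv_evaluate(
    ds: ResponseDataset,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    C: float = 1.0,
    leak_selection: bool = False,
) -> tuple[dict[int, PredictionResult], PredictionResult]:
    """Leave-one-out evaluation with in-fold selection for every k.

    Per held-out sample: select k features and standardise on the remaining
    samples, fit balanced logistic regression, score the held-out sample.
    The best k is the one with highest accuracy (ties -> smaller k).
    ``leak_selection=True`` deliberately selects features on the full data
    first — only for demonstrating selection leakage, never for reporting.
    """
    X, y = ds.features, ds.y
    n = len(X)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need >=2 samples per class for LOOCV")
    k_grid = tuple(k for k in k_grid if k <= X.shape[1]) or (X.shape[1],)
    results: dict[int, PredictionResult] = {}
    for k in k_grid:
        leaked = anova_f_select(X, y, k) if leak_selection else None
        preds = np.empty(n, dtype=int)
        scores = np.empty(n, dtype=float)
        for i in range(n):
            tr = np.delete(np.arange(n), i)
            if len(np.unique(y[tr])) < 2:
                raise ValueError("a training fold lost one class entirely")
            feats = leaked if leaked is not None else anova_f_select(X.iloc[tr], y[tr], k)
            Xtr = X.iloc[tr][feats].to_numpy(dtype=float)
            Xte = X.iloc[[i]][feats].to_numpy(dtype=float)
            Xtr, Xte = _standardize(Xtr, Xte)
            model = _make_model(C).fit(Xtr, y[tr])
            preds[i] = int(model.predict(Xte)[0])
            scores[i] = float(model.decision_function(Xte)[0])
        acc, f1, auc, conf = _binary_metrics(y, preds, scores)
        results[k] = PredictionResult(
            k=k,
            accuracy=acc,
            f1=f1,
            auc=auc,
            predictions=pd.Series(preds, index=X.index),
            scores=pd.Series(scores, index=X.index),
            confusion=conf,
        )
    best_k = min(results, key=lambda k: (-results[k].accuracy, k))
    return results, results[best_k]


# ---------------------------------------------------------------------------
# Feature combination and across-study evaluation


def combine_features(fms: list[pd.DataFrame], kinds: list[str] | None = None) -> pd.DataFrame:
    """Horizontally merge feature matrices over an identical sample set.

    Feature ids are prefixed by kind to keep them disjoint.  Standardisation
    happens later, inside training folds.
    """
    fms = [fm for fm in fms if fm.shape[1] > 0]
    if not fms:
        raise ValueError("no non-empty feature matrices to combine")
    if kinds is None:
        kinds = [f"m{i}" for i in range(len(fms))]
    base = list(fms[0].index)
    for fm in fms[1:]:
        if sorted(fm.index) != sorted(base):
            raise ValueError("feature matrices cover different sample sets")
    out = pd.concat(
        [fm.loc[base].add_prefix(f"{kind}:") for fm, kind in zip(fms, kinds)], axis=1
    )
    if out.columns.duplicated().any():
        raise ValueError("duplicate feature ids after prefixing")
    return out


def across_study_evaluate(
    train_ds: ResponseDataset, test_ds: ResponseDataset, n_features: int, C: float = 1.0
) -> float:
    """Train on one cohort, report ROC AUC on another.

    Feature spaces are intersected first; selection and standardisation use
    the training cohort only.
    """
    shared = sorted(set(train_ds.features.columns) & set(test_ds.features.columns))
    if not shared:
        raise ValueError("no shared features between cohorts")
    k = min(n_features, len(shared))
    feats = anova_f_select(train_ds.features[shared], train_ds.y, k)
    Xtr = train_ds.features[feats].to_numpy(dtype=float)
    Xte = test_ds.features[feats].to_numpy(dtype=float)
    Xtr, Xte = _standardize(Xtr, Xte)
    model = _make_model(C).fit(Xtr, train_ds.y)
    scores = model.decision_function(Xte)
    return float(roc_auc_score(test_ds.y, scores))


def tune_hyperparameters(
    ds: ResponseDataset,
    grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11)),
    n_splits: int = 5,
    seed: int = 0,
    n_features: int | None = None,
) -> float:
    """Pick C by stratified 5-fold CV mean accuracy (ties -> smallest C)."""
    X, y = ds.features, ds.y
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best_c, best_acc = None, -1.0
    for C in grid:
        accs = []
        for tr, te in folds:
            feats = (
                anova_f_select(X.iloc[tr], y[tr], n_features)
                if n_features is not None
                else list(X.columns)
            )
            Xtr = X.iloc[tr][feats].to_numpy(dtype=float)
            Xte = X.iloc[te][feats].to_numpy(dtype=float)
            Xtr, Xte = _standardize(Xtr, Xte)
            model = _make_model(C).fit(Xtr, y[tr])
            accs.append(float((model.predict(Xte) == y[te]).mean()))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc + 1e-12:
            best_acc, best_c = mean_acc, C
    return float(best_c)
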
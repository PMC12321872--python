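"""LASSO feature selection, SMOTE oversampling, kernel-SVM classification.

All leakage-prone steps (standardization, LASSO selection, SMOTE) are fit
inside each training fold of the stratified cross-validation; validation
data only ever meet the frozen fold model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.metrics import log_loss, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ModelSpec",
    "LassoSelection",
    "CVReport",
    "lasso_select",
    "smote_oversample",
    "train_svm",
    "cross_validate",
    "roc_auc",
]

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 1, 15))


@dataclass
class ModelSpec:
    """SVM kernel + regularization, LASSO grid, and SMOTE settings."""

    kernel: str = "rbf"
    C: float = 1.0
    degree: int = 3
    gamma: str | float = "scale"
    coef0: float = 0.0
    lasso: bool = True
    lasso_lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    smote: bool = False
    smote_k: int = 5

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "poly", "polynomial", "rbf", "sigmoid"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.kernel == "polynomial":
            self.kernel = "poly"
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.lasso and len(self.lasso_lambda_grid) == 0:
            raise ValueError("lasso_lambda_grid must be nonempty")


@dataclass
class LassoSelection:
    selected: np.ndarray  # indices of nonzero-coefficient features
    chosen_lambda: float
    coef: np.ndarray  # coefficients at the chosen lambda (standardized scale)
    path: pd.DataFrame  # lambda, n_selected, cv_score


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid=None,
    cv_folds: int = 5,
    seed: int = 0,
    mode: str = "logistic",
) -> LassoSelection:
    """L1-penalized feature selection with CV-chosen regularization.

    ``mode='logistic'`` (default for class labels) fits L1 logistic
    regression; lambda is chosen by mean cross-validated deviance.
    ``mode='regression'`` fits the least-squares LASSO (objective
    (1/2n)||y - Xb||^2 + lambda*||b||_1), whose orthonormal-design solution
    is the soft-threshold of the OLS fit. Features are standardized
    internally; selection is the nonzero-coefficient set at the chosen
    lambda. Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    lambdas = sorted(float(l) for l in lambda_grid)
    if mode == "logistic" and min(np.bincount(pd.factorize(y)[0])) < 2:
        raise ValueError("need >= 2 subjects per class")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)

    def _fit(lmb: float, Xtr, ytr):
        if mode == "logistic":
            model = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (lmb * len(ytr)), solver="liblinear",
                max_iter=2000, random_state=seed,
            )
        elif mode == "regression":
            model = Lasso(alpha=lmb, max_iter=50000)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return model.fit(Xtr, ytr)

    rows = []
    if len(lambdas) == 1:
        chosen = lambdas[0]
        rows.append((chosen, np.nan))
    else:
        if mode == "logistic":
            cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            splits = list(cv.split(Xs, y))
        else:
            from sklearn.model_selection import KFold

            cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            splits = list(cv.split(Xs))
        for lmb in lambdas:
            scores = []
            for tr, va in splits:
                m = _fit(lmb, Xs[tr], y[tr])
                if mode == "logistic":
                    prob = m.predict_proba(Xs[va])
                    scores.append(log_loss(y[va], prob, labels=m.classes_))
                else:
                    scores.append(float(np.mean((y[va] - m.predict(Xs[va])) ** 2)))
            rows.append((lmb, float(np.mean(scores))))
        chosen = min(rows, key=lambda t: t[1])[0]

    final = _fit(chosen, Xs, y)
    coef = final.coef_.ravel()
    selected = np.flatnonzero(np.abs(coef) > 1e-10)
    if selected.size == 0:
        warnings.warn("LASSO selected no features at any lambda", RuntimeWarning)
    path = pd.DataFrame(rows, columns=["lambda", "cv_score"])
    path["n_selected"] = [
        int(np.sum(np.abs(_fit(l, Xs, y).coef_.ravel()) > 1e-10)) for l in path["lambda"]
    ]
    return LassoSelection(selected=selected, chosen_lambda=chosen, coef=coef, path=path)


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    target: str = "parity",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling.

    Each synthetic point is x_i + u * (x_nn - x_i) with u ~ Uniform(0, 1) and
    x_nn one of the k nearest minority-class neighbours of x_i. Every
    minority class is raised to the majority count (``target='parity'``).
    k is reduced with a warning when a minority class has <= k members.
    Apply to training folds only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    X_out, y_out = [X], [y]
    for cls, cnt in zip(classes, counts):
        n_new = n_max - cnt
        if n_new == 0:
            continue
        pts = X[y == cls]
        k_eff = k
        if cnt <= k:
            k_eff = cnt - 1
            warnings.warn(
                f"minority class {cls!r} has {cnt} samples; reducing k to {k_eff}",
                RuntimeWarning,
            )
        if k_eff < 1:
            raise ValueError(f"class {cls!r} too small for SMOTE (n={cnt})")
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(pts)
        _, idx = nn.kneighbors(pts)  # idx[:, 0] is the point itself
        base = rng.integers(0, cnt, size=n_new)
        pick = rng.integers(1, k_eff + 1, size=n_new)
        u = rng.random(n_new)
        neigh = pts[idx[base, pick]]
        synth = pts[base] + u[:, None] * (neigh - pts[base])
        X_out.append(synth)
        y_out.append(np.full(n_new, cls, dtype=y.dtype))
    return np.vstack(X_out), np.concatenate(y_out)


def train_svm(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> SVC:
    """Fit a kernel SVM (inputs are expected to be already standardized)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    svc = SVC(
        kernel=spec.kernel, C=spec.C, degree=spec.degree, gamma=spec.gamma,
        coef0=spec.coef0, decision_function_shape="ovr",
    )
    return svc.fit(np.asarray(X, dtype=float), y)


def _fit_fold(X_train, y_train, spec: ModelSpec, seed: int):
    """Train-fold pipeline: scaler -> optional LASSO -> optional SMOTE -> SVM.

    Touches only training data; returns (scaler, selected indices, svm).
    """
    scaler = StandardScaler().fit(X_train)
    Xs = scaler.transform(X_train)
    if spec.lasso and Xs.shape[1] > 1:
        sel = lasso_select(
            X_train, y_train, spec.lasso_lambda_grid, cv_folds=3, seed=seed
        ).selected
        if sel.size == 0:
            sel = np.arange(Xs.shape[1])
    else:
        sel = np.arange(Xs.shape[1])
    Xf, yf = Xs[:, sel], y_train
    if spec.smote:
        Xf, yf = smote_oversample(Xf, yf, k=spec.smote_k, seed=seed)
    svm = train_svm(Xf, yf, spec)
    return scaler, sel, svm


def _sens_spec(conf: np.ndarray) -> tuple[float, float]:
    """Macro-averaged one-vs-rest sensitivity and specificity from a confusion
    matrix (rows = true, cols = predicted); binary reduces to the usual pair
    with the second class as positive."""
    k = conf.shape[0]
    sens, spec_ = [], []
    total = conf.sum()
    for c in range(k):
        tp = conf[c, c]
        fn = conf[c].sum() - tp
        fp = conf[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens.append(tp / (tp + fn) if tp + fn else np.nan)
        spec_.append(tn / (tn + fp) if tn + fp else np.nan)
    if k == 2:
        return float(sens[1]), float(spec_[1])
    return float(np.nanmean(sens)), float(np.nanmean(spec_))


@dataclass
class CVReport:
    """Cross-validation performance summary."""

    fold_metrics: pd.DataFrame  # fold, accuracy, sensitivity, specificity
    accuracy: float
    accuracy_sd: float
    sensitivity: float
    sensitivity_sd: float
    specificity: float
    specificity_sd: float
    auc: float
    roc_points: pd.DataFrame
    confusion: pd.DataFrame  # summed over validation folds
    selected_features: list = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_sd": self.accuracy_sd,
            "sensitivity": self.sensitivity,
            "sensitivity_sd": self.sensitivity_sd,
            "specificity": self.specificity,
            "specificity_sd": self.specificity_sd,
            "auc": self.auc,
            "confusion": self.confusion.values.tolist(),
            "classes": list(self.confusion.columns),
            "n_folds": int(len(self.fold_metrics)),
            "selected_features": [str(f) for f in self.selected_features],
            "seed": self.seed,
        }


def cross_validate(
    X,
    y,
    spec: ModelSpec | None = None,
    folds: int = 10,
    seed: int = 0,
    feature_names=None,
) -> CVReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Standardization, LASSO selection and SMOTE are refit inside every
    training fold. Binary problems report the pooled validation-score ROC;
    multiclass problems report macro one-vs-rest AUC.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    spec = spec or ModelSpec()
    classes = np.unique(y)
    counts = np.bincount(pd.factorize(y, sort=True)[0])
    if counts.min() < folds:
        raise ValueError(
            f"smallest class ({counts.min()}) < folds ({folds}); use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    cls_index = {c: i for i, c in enumerate(classes)}
    fold_rows = []
    pooled_scores, pooled_labels = [], []
    selected_union: set = set()
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training fold has a single class; use fewer folds")
        scaler, sel, svm = _fit_fold(X[tr], y[tr], spec, seed + fold)
        Xv = scaler.transform(X[va])[:, sel]
        pred = svm.predict(Xv)
        fconf = np.zeros_like(conf)
        for t, pr in zip(y[va], pred):
            fconf[cls_index[t], cls_index[pr]] += 1
        conf += fconf
        acc = float((pred == y[va]).mean())
        sens, spc = _sens_spec(fconf)
        fold_rows.append({"fold": fold, "accuracy": acc, "sensitivity": sens, "specificity": spc})
        scores = svm.decision_function(Xv)
        pooled_scores.append(scores)
        pooled_labels.append(y[va])
        if feature_names is not None:
            selected_union.update(np.asarray(feature_names)[sel])
        else:
            selected_union.update(sel.tolist())
    fold_metrics = pd.DataFrame(fold_rows)
    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    if len(classes) == 2:
        auc, roc_points = roc_auc(scores, (labels == classes[1]).astype(int))
    else:
        aucs = []
        for i, c in enumerate(classes):
            a, _ = roc_auc(scores[:, i], (labels == c).astype(int))
            aucs.append(a)
        auc = float(np.mean(aucs))
        roc_points = pd.DataFrame(columns=["fpr", "tpr", "threshold"])
    confusion = pd.DataFrame(conf, index=classes, columns=classes)
    return CVReport(
        fold_metrics=fold_metrics,
        accuracy=float(fold_metrics["accuracy"].mean()),
        accuracy_sd=float(fold_metrics["accuracy"].std(ddof=1)),
        sensitivity=float(fold_metrics["sensitivity"].mean()),
        sensitivity_sd=float(fold_metrics["sensitivity"].std(ddof=1)),
        specificity=float(fold_metrics["specificity"].mean()),
        specificity_sd=float(fold_metrics["specificity"].std(ddof=1)),
        auc=auc,
        roc_points=roc_points,
        confusion=confusion,
        selected_features=sorted(selected_union, key=str),
        seed=seed,
    )


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC with midrank tie handling plus the ROC curve points.

    AUC equals the normalized Mann-Whitney U statistic; the curve is the
    standard threshold sweep.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    pos = labels == classes[1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(pos.astype(int), scores)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return float(auc), points
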
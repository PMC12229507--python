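"""Gaussian-kernel SVM classification of high- vs low-Cx43 spectra.

The classifier follows the protocol of the source workflow: classes are
balanced by seeded subsampling to the smaller class, 80% of the balanced
data train a soft-margin SVM with a Gaussian kernel

    K(u, v) = exp(-||u - v||² / s²),

where the kernel scale is s = sqrt(P) ("medium") or s = 4 sqrt(P)
("coarse") for P predictors, features are standardized on the training
data and the box constraint is C = 1.  Training performance is reported
as stratified five-fold cross-validation on the 80% portion; held-out
and external scenario sets are scored with the fitted model.  The
positive class is high Cx43 content throughout, so sensitivity =
TP/(TP+FN) refers to detecting high-Cx43 cells.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn.metrics
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .spectra import SpectraSet
from .stats import FeatureMask, double_sd_mask, group_mean_sd

__all__ = [
    "SVMConfig",
    "SVMModel",
    "EvalReport",
    "ExperimentSpec",
    "kernel_scale",
    "balance_classes",
    "balance_and_split",
    "train_svm",
    "predict_scores",
    "cross_validate",
    "evaluate_predictions",
    "run_experiment",
]

POSITIVE_LABEL = "high"
NEGATIVE_LABEL = "low"


def kernel_scale(p: int, kind: str) -> float:
    """Gaussian kernel scale: sqrt(P) for medium, 4 sqrt(P) for coarse."""
    if p < 1:
        raise ValueError("need at least one predictor")
    if kind == "medium":
        return math.sqrt(p)
    if kind == "coarse":
        return 4.0 * math.sqrt(p)
    raise ValueError(f"unknown kernel kind {kind!r}")


@dataclass(frozen=True)
class SVMConfig:
    kernel_kind: str = "coarse"  # "medium" | "coarse"
    box_constraint: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be > 0")
        kernel_scale(1, self.kernel_kind)  # validates the kind


@dataclass
class SVMModel:
    svc: SVC
    scaler: StandardScaler | None
    config: SVMConfig
    n_features: int
    kernel_scale: float
    classes: tuple[str, str] = (NEGATIVE_LABEL, POSITIVE_LABEL)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got shape {X.shape}"
            )
        return self.scaler.transform(X) if self.scaler is not None else X


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float  # percent
    sensitivity: float  # percent
    specificity: float  # percent
    roc: np.ndarray  # (n, 2) ordered (FPR, TPR)
    auc: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


@dataclass(frozen=True)
class ExperimentSpec:
    kernels: tuple[str, ...] = ("coarse", "medium")
    feature_modes: tuple[str, ...] = ("all", "selected")
    train_frac: float = 0.8
    cv_folds: int = 5
    sd_multiplier: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        for mode in self.feature_modes:
            if mode not in ("all", "selected"):
                raise ValueError(f"unknown feature mode {mode!r}")


# ---------------------------------------------------------------------------
# Balancing and splitting


def balance_classes(
    sset: SpectraSet,
    labels: tuple[str, str],
    seed: int,
    min_per_class: int = 5,
) -> SpectraSet:
    """Seeded subsample (without replacement) to the smaller class size."""
    rng = np.random.default_rng(seed)
    per_class = []
    for lab in labels:
        idx = np.array([i for i, L in enumerate(sset.labels) if L == lab])
        if idx.size < min_per_class:
            raise ValueError(
                f"class {lab!r} has {idx.size} spectra (< {min_per_class})"
            )
        per_class.append(idx)
    n = min(idx.size for idx in per_class)
    chosen = np.concatenate(
        [np.sort(rng.choice(idx, size=n, replace=False)) for idx in per_class]
    )
    return sset.subset(chosen)


def balance_and_split(
    sset: SpectraSet,
    labels: tuple[str, str],
    train_frac: float = 0.8,
    seed: int = 0,
) -> tuple[SpectraSet, SpectraSet]:
    """Balance the classes, then stratified-split into train and holdout."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    balanced = balance_classes(sset, labels, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    train_idx: list[int] = []
    hold_idx: list[int] = []
    for lab in labels:
        idx = np.array([i for i, L in enumerate(balanced.labels) if L == lab])
        perm = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(perm[:n_train])
        hold_idx.extend(perm[n_train:])
    return balanced.subset(sorted(train_idx)), balanced.subset(sorted(hold_idx))


# ---------------------------------------------------------------------------
# Training and scoring


def _encode(labels: list[str | None]) -> np.ndarray:
    y = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab == POSITIVE_LABEL:
            y[i] = 1
        elif lab == NEGATIVE_LABEL:
            y[i] = 0
        else:
            raise ValueError(
                f"label {lab!r} outside class set "
                f"({NEGATIVE_LABEL!r}, {POSITIVE_LABEL!r})"
            )
    return y


def train_svm(
    features: np.ndarray, y: np.ndarray, cfg: SVMConfig = SVMConfig()
) -> SVMModel:
    """Fit the Gaussian-kernel soft-margin SVM.

    ``y`` is binary with 1 = high Cx43 (positive).  Standardization
    (when on) learns center/scale on these training data; zero-variance
    features get a unit scale floor (sklearn's behaviour).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("training data contain a single class")
    for cls in (0, 1):
        if np.sum(y == cls) < 2:
            raise ValueError("need >= 2 examples per class")
    scaler = None
    if cfg.standardize:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    s = kernel_scale(X.shape[1], cfg.kernel_kind)
    svc = SVC(C=cfg.box_constraint, kernel="rbf", gamma=1.0 / s**2)
    svc.fit(X, y)
    return SVMModel(
        svc=svc,
        scaler=scaler,
        config=cfg,
        n_features=X.shape[1],
        kernel_scale=s,
    )


def predict_scores(
    model: SVMModel, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Decision-function scores and hard labels (score > 0 -> high Cx43).

    A tie at score == 0 predicts the negative (low-Cx43) class.
    """
    X = np.asarray(features, dtype=float)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    Xt = model._transform(X)
    scores = model.svc.decision_function(Xt)
    labels = (scores > 0).astype(int)
    return labels, scores


def cross_validate(
    features: np.ndarray,
    y: np.ndarray,
    cfg: SVMConfig = SVMConfig(),
    k: int = 5,
    return_oof: bool = False,
):
    """Stratified k-fold CV accuracy (%) with seeded fold assignment.

    With ``return_oof=True`` additionally returns the pooled out-of-fold
    predicted labels and decision scores (aligned with ``y``), from which
    CV ROC/AUC and confusion metrics can be derived.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=int)
    for cls in np.unique(y):
        if np.sum(y == cls) < k:
            raise ValueError(f"class {cls} has fewer than k={k} examples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    oof_pred = np.empty_like(y)
    oof_score = np.empty(y.size, dtype=float)
    for tr, te in skf.split(X, y):
        model = train_svm(X[tr], y[tr], cfg)
        pred, score = predict_scores(model, X[te])
        oof_pred[te] = pred
        oof_score[te] = score
    acc = 100.0 * float(np.mean(oof_pred == y))
    if return_oof:
        return acc, oof_pred, oof_score
    return acc


# ---------------------------------------------------------------------------
# Evaluation


def evaluate_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray
) -> EvalReport:
    """Confusion counts, percent metrics, full-sweep ROC and trapezoid AUC."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not (y_true.size == y_pred.size == scores.size):
        raise ValueError("labels and scores must have equal lengths")
    if np.any((y_true != 0) & (y_true != 1)) or np.any(
        (y_pred != 0) & (y_pred != 1)
    ):
        raise ValueError("labels must be binary (0 = low, 1 = high)")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    total = tp + fn + tn + fp
    accuracy = 100.0 * (tp + tn) / total if total else float("nan")
    sensitivity = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    if np.unique(y_true).size == 2:
        fpr, tpr, _ = sklearn.metrics.roc_curve(y_true, scores)
        auc = float(np.trapezoid(tpr, fpr))
        roc = np.column_stack([fpr, tpr])
    else:
        roc = np.array([[0.0, 0.0], [1.0, 1.0]])
        auc = float("nan")
    return EvalReport(
        tp=tp, fn=fn, tn=tn, fp=fp,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        roc=roc, auc=auc,
    )


# ---------------------------------------------------------------------------
# Experiment grid


def run_experiment(
    train_set: SpectraSet,
    test_sets: dict[str, SpectraSet],
    spec: ExperimentSpec = ExperimentSpec(),
    mask: FeatureMask | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Train/evaluate the kernel x feature-mode grid over named scenarios.

    ``train_set`` must contain both classes; it is balanced and split
    80/20.  The "training" scenario reports stratified 5-fold CV on the
    80% portion.  Each entry of ``test_sets`` is evaluated with the
    fitted models; a test set lacking one class is completed with the
    held-out 20% spectra of the missing class, and every evaluation set
    is balanced by seeded subsampling.  When no ``mask`` is given and a
    "selected" feature mode is requested, the double-SD mask is derived
    from the 80% training portion.

    Returns the metric table (one row per kernel x mode x scenario) and a
    manifest of seeds, feature counts and ROC curves.
    """
    labels = (POSITIVE_LABEL, NEGATIVE_LABEL)
    train, holdout = balance_and_split(
        train_set, labels, spec.train_frac, spec.seed
    )
    if mask is None and "selected" in spec.feature_modes:
        a = group_mean_sd(train, POSITIVE_LABEL)
        b = group_mean_sd(train, NEGATIVE_LABEL)
        mask = double_sd_mask(a, b, multiplier=spec.sd_multiplier)

    # assemble evaluation scenarios
    scenarios: dict[str, SpectraSet] = {}
    for name, sset in test_sets.items():
        present = {lab for lab in sset.labels}
        completed = sset
        for lab in labels:
            if lab not in present:
                completed = completed.concat(holdout.select_label(lab))
        name_tag = zlib.crc32(name.encode("utf-8")) % (2**31)
        scenarios[name] = balance_classes(
            completed, labels, seed=int(
                np.random.default_rng(
                    np.random.SeedSequence([spec.seed, name_tag])
                ).integers(2**31)
            ),
        )

    y_train = _encode(train.labels)
    rows = []
    rocs: dict[str, np.ndarray] = {}
    for kind in spec.kernels:
        for mode in spec.feature_modes:
            if mode == "selected":
                if mask is None:
                    raise ValueError("feature mode 'selected' needs a mask")
                cols = mask.mask
            else:
                cols = np.ones(train.n_channels, dtype=bool)
            cfg = SVMConfig(kernel_kind=kind, seed=spec.seed)
            X_train = train.intensities[:, cols]
            acc, oof_pred, oof_score = cross_validate(
                X_train, y_train, cfg, k=spec.cv_folds, return_oof=True
            )
            model = train_svm(X_train, y_train, cfg)
            cv_report = evaluate_predictions(y_train, oof_pred, oof_score)
            key = f"{kind}_{mode}"
            rows.append(
                {
                    "kernel": kind,
                    "feature_mode": mode,
                    "scenario": "training",
                    "n_features": int(np.sum(cols)),
                    "accuracy": acc,
                    "auc": cv_report.auc,
                    "sensitivity": cv_report.sensitivity,
                    "specificity": cv_report.specificity,
                }
            )
            rocs[f"{key}_training"] = cv_report.roc
            for name, sset in scenarios.items():
                X = sset.intensities[:, cols]
                y = _encode(sset.labels)
                pred, score = predict_scores(model, X)
                rep = evaluate_predictions(y, pred, score)
                rows.append(
                    {
                        "kernel": kind,
                        "feature_mode": mode,
                        "scenario": name,
                        "n_features": int(np.sum(cols)),
                        "accuracy": rep.accuracy,
                        "auc": rep.auc,
                        "sensitivity": rep.sensitivity,
                        "specificity": rep.specificity,
                    }
                )
                rocs[f"{key}_{name}"] = rep.roc
    table = pd.DataFrame(rows)
    manifest = {
        "seed": spec.seed,
        "train_frac": spec.train_frac,
        "cv_folds": spec.cv_folds,
        "n_train": train.n_spectra,
        "n_holdout": holdout.n_spectra,
        "n_selected": mask.n_selected if mask is not None else None,
        "scenario_sizes": {k: v.n_spectra for k, v in scenarios.items()},
        "rocs": rocs,
    }
    return table, manifest
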
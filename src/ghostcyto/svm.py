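"""Binary classification and evaluation stack.

Featurization concatenates the selected waveform segments and scalar
channels into one high-dimensional vector per event; a grid-searched SVM
(linear or RBF) predicts the fluorescence-defined label from the stain-free
features.  Evaluation repeats a balanced train/test sampling n_trials times
and reports both the mean +/- std of per-trial AUCs and the AUC of the
vertically averaged mean ROC curve — two distinct summaries that coincide
only approximately.  A sorting simulation thresholds the decision function
and reports purity and yield.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn import metrics
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .gating import balanced_split
from .signal_chain import Event

__all__ = [
    "SvmConfig",
    "SvmModel",
    "RocCurve",
    "EvalResult",
    "SortReport",
    "featurize",
    "train_svm",
    "svm_score",
    "roc_auc",
    "repeated_eval",
    "mean_roc",
    "recovery_at_fpr",
    "simulate_sort",
    "export_linear_scorer",
    "estimate_throughput",
]

SCALAR_FEATURES = ("fsc_height", "fsc_width", "fsc_area", "ssc", "bsc")


@dataclass(frozen=True)
class SvmConfig:
    """SVM kernel, hyperparameter grids, and evaluation protocol."""

    kernel: str = "rbf"
    C_grid: tuple[float, ...] = (1e-2, 1e-1, 1.0, 10.0, 100.0, 1000.0)
    gamma_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0)
    inner_folds: int = 5
    modality_set: tuple[str, ...] = ("dGMI",)
    n_trials: int = 10
    n_train_per_class: int = 300
    n_test_per_class: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be linear or rbf, got {self.kernel!r}")
        if not self.C_grid or (self.kernel == "rbf" and not self.gamma_grid):
            raise ValueError("hyperparameter grids must be nonempty")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


@dataclass
class SvmModel:
    """A trained SVM with its normalizer and hyperparameter provenance."""

    kernel: str
    C: float
    gamma: float | None
    estimator: SVC
    scaler: StandardScaler  # fitted on training data only
    modality_set: tuple[str, ...]


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray

    def validate(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < -1e-12):
            raise ValueError("ROC coordinates must be nondecreasing")


@dataclass
class EvalResult:
    aucs: np.ndarray
    mean_auc: float
    std_auc: float
    mean_curve: RocCurve
    auc_of_mean_roc: float


@dataclass
class SortReport:
    pre_fraction: float
    purity: float | None  # None when nothing was kept
    sort_yield: float
    threshold: float


def featurize(
    events: list[Event],
    modality_set: tuple[str, ...],
    scaler: StandardScaler | None = None,
) -> np.ndarray:
    """Stack selected waveforms then scalars, in the declared order.

    Names in ``modality_set`` may be waveform modalities or scalar channels
    (fsc_height / fsc_width / fsc_area / ssc / bsc).  If a fitted ``scaler``
    is given the matrix is standardized with it (the scaler must come from
    training data only).
    """
    rows = []
    for ev in events:
        parts = []
        for name in modality_set:
            if name in ev.waveforms:
                parts.append(np.asarray(ev.waveforms[name], dtype=float))
            elif name in SCALAR_FEATURES:
                if name not in ev.scalars:
                    raise KeyError(f"event {ev.event_id} lacks scalar {name!r}")
                parts.append(np.array([ev.scalars[name]]))
            else:
                raise KeyError(f"event {ev.event_id} lacks modality {name!r}")
        rows.append(np.concatenate(parts))
    X = np.vstack(rows)
    if scaler is not None:
        X = scaler.transform(X)
    return X


def _binary_y(labels: np.ndarray, positive_class: str) -> np.ndarray:
    return (np.asarray(labels, dtype=object) == positive_class).astype(int)


def train_svm(
    events: list[Event],
    labels: np.ndarray,
    config: SvmConfig,
    positive_class: str | None = None,
) -> SvmModel:
    """Grid-search by inner stratified k-fold mean AUC, then refit on all data.

    Ties break toward smaller C, then smaller gamma (simpler models).  The
    feature normalizer is fitted on the training data only.
    """
    config.validate()
    classes = sorted(set(np.asarray(labels, dtype=object).tolist()))
    if len(classes) != 2:
        raise ValueError(f"binary SVM needs exactly 2 classes, got {classes}")
    positive_class = positive_class or classes[1]
    y = _binary_y(labels, positive_class)

    scaler = StandardScaler()
    X = scaler.fit_transform(featurize(events, config.modality_set))

    gammas: tuple[float | None, ...] = (
        tuple(sorted(config.gamma_grid)) if config.kernel == "rbf" else (None,)
    )
    cv = StratifiedKFold(n_splits=config.inner_folds, shuffle=True, random_state=config.seed)
    folds = list(cv.split(X, y))

    best: tuple[float, float, float | None] | None = None  # (auc, C, gamma)
    for C, gamma in itertools.product(sorted(config.C_grid), gammas):
        fold_aucs = []
        for tr, va in folds:
            est = _make_svc(config.kernel, C, gamma)
            est.fit(X[tr], y[tr])
            fold_aucs.append(metrics.roc_auc_score(y[va], est.decision_function(X[va])))
        score = float(np.mean(fold_aucs))
        if best is None or score > best[0]:  # strict >: ties keep the smaller C/gamma
            best = (score, C, gamma)

    _, C, gamma = best
    est = _make_svc(config.kernel, C, gamma)
    est.fit(X, y)
    return SvmModel(
        kernel=config.kernel, C=C, gamma=gamma, estimator=est,
        scaler=scaler, modality_set=config.modality_set,
    )


def _make_svc(kernel: str, C: float, gamma: float | None) -> SVC:
    if kernel == "linear":
        return SVC(kernel="linear", C=C)
    return SVC(kernel="rbf", C=C, gamma=gamma)


def svm_score(model: SvmModel, events: list[Event]) -> np.ndarray:
    """Signed decision-function values; higher means more positive-class."""
    X = featurize(events, model.modality_set, scaler=model.scaler)
    return model.estimator.decision_function(X)


def roc_auc(scores: np.ndarray, labels: np.ndarray, positive_class: str | None = None) -> tuple[RocCurve, float]:
    """Threshold-sweep ROC and trapezoidal AUC.

    The trapezoid rule on the step curve equals the Mann-Whitney
    probability that a random positive outscores a random negative, with
    ties counted one half.
    """
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"ROC needs exactly two classes, got {classes}")
    positive_class = positive_class or classes[1]
    y = _binary_y(labels, positive_class)
    fpr, tpr, _ = metrics.roc_curve(y, scores)
    curve = RocCurve(fpr=fpr, tpr=tpr)
    curve.validate()
    return curve, float(metrics.auc(fpr, tpr))


DEFAULT_FPR_GRID = np.linspace(0.0, 1.0, 101)


def mean_roc(rocs: list[RocCurve], fpr_grid: np.ndarray | None = None) -> RocCurve:
    """Vertical averaging: interpolate each TPR at the grid FPRs, then average."""
    if not rocs:
        raise ValueError("need at least one ROC curve")
    grid = DEFAULT_FPR_GRID if fpr_grid is None else np.asarray(fpr_grid, dtype=float)
    stack = np.vstack([np.interp(grid, r.fpr, r.tpr) for r in rocs])
    return RocCurve(fpr=grid, tpr=stack.mean(axis=0))


def recovery_at_fpr(roc: RocCurve, fpr: float) -> float:
    """TPR (recovery rate) read off a ROC curve at a fixed FPR, by linear interpolation."""
    if not 0.0 <= fpr <= 1.0:
        raise ValueError("fpr must be in [0, 1]")
    return float(np.interp(fpr, roc.fpr, roc.tpr))


def repeated_eval(
    events: list[Event],
    labels: np.ndarray,
    config: SvmConfig,
    positive_class: str | None = None,
) -> EvalResult:
    """n_trials balanced samplings; per-trial held-out AUC plus the mean ROC.

    Reports the mean and standard deviation of the per-trial AUCs and,
    separately, the AUC of the vertically averaged ROC — the two summaries
    differ slightly by construction.
    """
    config.validate()
    labels = np.asarray(labels, dtype=object)
    aucs, curves = [], []
    for trial in range(config.n_trials):
        tr, te = balanced_split(
            events, labels, config.n_train_per_class, config.n_test_per_class,
            seed=config.seed + 1000 * trial,
        )
        model = train_svm([events[i] for i in tr], labels[tr], config, positive_class)
        scores = svm_score(model, [events[i] for i in te])
        curve, auc = roc_auc(scores, labels[te], positive_class)
        aucs.append(auc)
        curves.append(curve)
    aucs = np.array(aucs)
    mcurve = mean_roc(curves)
    auc_mean_roc = float(np.trapezoid(mcurve.tpr, mcurve.fpr))
    return EvalResult(
        aucs=aucs,
        mean_auc=float(aucs.mean()),
        std_auc=float(aucs.std(ddof=0)),
        mean_curve=mcurve,
        auc_of_mean_roc=auc_mean_roc,
    )


def simulate_sort(
    events: list[Event],
    model: SvmModel | None,
    threshold: float,
    target_class: str,
    scores: np.ndarray | None = None,
) -> SortReport:
    """In-silico sort: keep events scoring above threshold; report purity and yield.

    Scores come from the model's decision function unless precomputed
    ``scores`` are supplied (e.g. from an exported linear scorer).
    """
    if scores is None:
        if model is None:
            raise ValueError("either a model or precomputed scores is required")
        scores = svm_score(model, events)
    scores = np.asarray(scores, dtype=float)
    truth = np.array([ev.true_class for ev in events], dtype=object)
    is_target = truth == target_class
    kept = scores > threshold
    pre = float(is_target.mean())
    n_kept = int(kept.sum())
    purity = float(is_target[kept].mean()) if n_kept else None
    sort_yield = float((kept & is_target).sum() / max(is_target.sum(), 1))
    return SortReport(pre_fraction=pre, purity=purity, sort_yield=sort_yield, threshold=threshold)


def export_linear_scorer(model: SvmModel) -> tuple[np.ndarray, float]:
    """Fold the normalizer into (w, b) so scores = w . raw_features + b.

    This is the deployable real-time decision function: one dot product per
    event.  Only linear kernels are exportable.
    """
    if model.kernel != "linear":
        raise ValueError("only linear-kernel models export to (w, b)")
    w = model.estimator.coef_[0]
    b = float(model.estimator.intercept_[0])
    scale = model.scaler.scale_
    mean = model.scaler.mean_
    w_raw = w / scale
    b_raw = b - float(np.dot(w, mean / scale))
    return w_raw, b_raw


def estimate_throughput(acquisition_time_per_cell_s: float) -> float:
    """Ideal throughput: cells evenly spaced one illumination length apart,
    so the rate is exactly the inverse of the per-cell acquisition time."""
    if acquisition_time_per_cell_s <= 0:
        raise ValueError("acquisition time must be > 0")
    return 1.0 / acquisition_time_per_cell_s
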
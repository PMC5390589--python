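"""Class-weighted linear-SVM evaluation for imbalanced two-class problems.

The classifier is an L2-regularized linear SVM (liblinear backend) with
per-class misclassification weights; the minority class (normal, label 0)
is given an integer weight 1..9 while the majority class (abnormal, label
1) stays at 1, countering the ~85:15 imbalance.  Evaluation follows a
repeated stratified k-fold protocol (default 10 rounds of 5-fold CV) with
confusion-matrix metrics and a sensitivity/specificity balance metric.

The positive class is abnormal (label 1) throughout: sensitivity is the
recall of abnormal cases, specificity the recall of normal cases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace
from itertools import product
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import LinearSVC

from .cascade import HyperParams

POSITIVE_CLASS = 1  # abnormal


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: int = POSITIVE_CLASS

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Confusion counts plus the six ratio metrics and the balance metric.

    Undefined metrics (zero denominator) are NaN, never silently 0.
    """

    acc: float
    sen: float
    spe: float
    ppv: float
    npv: float
    f1: float
    g: float
    counts: ConfusionCounts | None = None
    weights: tuple[float, float] | None = None  # (w_minority, w_majority)
    provenance: str = ""

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("acc", "sen", "spe", "ppv", "npv", "f1", "g")}

    def summary(self) -> str:
        cells = []
        for k, v in self.as_dict().items():
            cells.append(f"{k.upper()}={'undef' if math.isnan(v) else format(v, '.4f')}")
        return "  ".join(cells)


@dataclass
class CVConfig:
    """Repeated stratified k-fold protocol configuration."""

    k: int = 5
    repeats: int = 10
    stratified: bool = True
    seed: int = 0
    w_minority: float = 1.0
    w_majority: float = 1.0
    cost: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.repeats < 1:
            raise ValueError(f"repeats must be >= 1, got {self.repeats}")
        if self.w_minority <= 0 or self.w_majority <= 0:
            raise ValueError("class weights must be > 0")


def fit_weighted_linear_svm(
    features: np.ndarray,
    labels: np.ndarray,
    weights: Mapping[int, float] | None = None,
    cost: float = 1.0,
    seed: int = 0,
) -> LinearSVC:
    """L2-regularized hinge-loss linear SVM with per-class weights.

    weights maps class label to its misclassification weight (penalty
    w_y * cost); missing classes default to 1.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    present = np.unique(labels)
    if present.size < 2:
        raise ValueError(f"both classes required for training, got {present.tolist()}")
    cw = {int(c): float((weights or {}).get(int(c), 1.0)) for c in present}
    model = LinearSVC(
        C=cost,
        loss="hinge",
        dual=True,
        class_weight=cw,
        random_state=seed,
        max_iter=20000,
        tol=1e-5,
    )
    model.fit(features, labels)
    return model


def predict(model: LinearSVC, features: np.ndarray) -> np.ndarray:
    """Binary labels from the decision function; a 0 value maps to the
    positive class (tie rule)."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if features.shape[1] != model.coef_.shape[1]:
        raise ValueError(
            f"feature dimension {features.shape[1]} does not match model "
            f"dimension {model.coef_.shape[1]}"
        )
    return np.where(model.decision_function(features) >= 0, POSITIVE_CLASS, 1 - POSITIVE_CLASS)


def confusion(
    y_true: Sequence[int], y_pred: Sequence[int], positive_class: int = POSITIVE_CLASS
) -> ConfusionCounts:
    yt, yp = np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    pos_t, pos_p = yt == positive_class, yp == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        positive_class=positive_class,
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def compute_metrics(c: ConfusionCounts, g_mode: str = "product") -> MetricsReport:
    """ACC, SEN, SPE, PPV, NPV, F1 from the confusion counts; zero-denominator
    metrics come out NaN (undefined)."""
    acc = _ratio(c.tp + c.tn, c.total)
    sen = _ratio(c.tp, c.tp + c.fn)
    spe = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    f1 = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    g = balance_metric(sen, spe, g_mode) if not (math.isnan(sen) or math.isnan(spe)) else float("nan")
    return MetricsReport(acc, sen, spe, ppv, npv, f1, g, counts=c)


def balance_metric(sen: float, spe: float, mode: str = "product") -> float:
    """Balance of sensitivity and specificity.

    mode "product" returns sen * spe; mode "sqrt" returns
    sqrt(sen * spe), the geometric mean proper.  The product is the
    default because the reference weight-sweep table tabulates it.
    """
    if not (0.0 <= sen <= 1.0 and 0.0 <= spe <= 1.0):
        raise ValueError(f"sen/spe must lie in [0, 1], got {(sen, spe)}")
    if mode == "product":
        return sen * spe
    if mode == "sqrt":
        return math.sqrt(sen * spe)
    raise ValueError(f"unknown balance-metric mode {mode!r}")


def _mean_report(reports: list[MetricsReport], weights=None, provenance="") -> MetricsReport:
    with warnings.catch_warnings():
        # an all-undefined metric averages to NaN, which is the intent
        warnings.simplefilter("ignore", category=RuntimeWarning)
        avg = {
            k: float(np.nanmean([r.as_dict()[k] for r in reports]))
            for k in ("acc", "sen", "spe", "ppv", "npv", "f1", "g")
        }
    return MetricsReport(**avg, weights=weights, provenance=provenance)


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: CVConfig,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Repeated stratified k-fold evaluation.

    Each repeat draws fresh stratified folds from a seeded shuffle; the
    model is fit on k-1 folds and evaluated on the held-out fold; metrics
    are averaged over all k * repeats fold evaluations (NaN-aware).
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if counts.min() < cfg.k:
        raise ValueError(
            f"class with {counts.min()} members cannot be split into {cfg.k} stratified folds"
        )
    weights = {0: cfg.w_minority, 1: cfg.w_majority}
    fold_reports: list[MetricsReport] = []
    for rep in range(cfg.repeats):
        splitter = StratifiedKFold(n_splits=cfg.k, shuffle=True, random_state=cfg.seed + rep)
        for fold, (tr, te) in enumerate(splitter.split(features, labels)):
            model = fit_weighted_linear_svm(
                features[tr], labels[tr], weights=weights, cost=cfg.cost, seed=cfg.seed
            )
            rpt = compute_metrics(confusion(labels[te], predict(model, features[te])))
            rpt.weights = (cfg.w_minority, cfg.w_majority)
            rpt.provenance = f"repeat={rep} fold={fold}"
            fold_reports.append(rpt)
    avg = _mean_report(
        fold_reports,
        weights=(cfg.w_minority, cfg.w_majority),
        provenance=f"mean of {cfg.repeats}x{cfg.k}-fold CV",
    )
    return avg, fold_reports


def weight_sweep(
    features: np.ndarray,
    labels: np.ndarray,
    weights: Sequence[float] = tuple(range(1, 10)),
    cfg: CVConfig | None = None,
) -> pd.DataFrame:
    """One averaged CV row per minority-class weight (majority fixed at 1).

    Returns a table with ACC/SEN/SPE/g columns; the row with the highest
    balance metric g is flagged `best`.
    """
    cfg = cfg or CVConfig()
    rows = []
    for w in weights:
        avg, _ = cross_validate(features, labels, replace(cfg, w_minority=float(w), w_majority=1.0))
        rows.append({"w_minority": w, "w_majority": 1.0, "acc": avg.acc,
                     "sen": avg.sen, "spe": avg.spe, "g": avg.g})
    df = pd.DataFrame(rows)
    df["best"] = df["g"] == df["g"].max()
    return df


def default_grids() -> dict[str, list]:
    """Hyperparameter search grids for the pooling stage.

    eps spans 1e-10..1 in decade steps; a is the NT branch selector;
    gamma 0..10 step 2; alpha 1e-6..1e2 in decade steps; beta 0..1 step
    0.25; sigma the two values of 315*t/84 for t in {0.59, 0.60}; n_lrn
    odd window sizes 1..9 (integer step).
    """
    return {
        "eps": [10.0**e for e in range(-10, 1)],
        "a": [0, 1],
        "gamma": [float(g) for g in range(0, 11, 2)],
        "alpha": [10.0**e for e in range(-6, 3)],
        "beta": [0.0, 0.25, 0.5, 0.75, 1.0],
        "sigma": [315 * 0.59 / 84, 315 * 0.60 / 84],
        "n_lrn": [1, 2, 3, 4, 5, 6, 7, 8, 9],
    }


_HP_FIELDS = {f.name for f in fields(HyperParams)}


def grid_search_hyperparams(
    train_features_fn: Callable[[HyperParams], np.ndarray],
    train_labels: np.ndarray,
    grids: Mapping[str, Sequence],
    base_hp: HyperParams | None = None,
    objective: Callable[[MetricsReport], float] | None = None,
    val_fraction: float = 0.25,
    seed: int = 0,
    cost: float = 1.0,
) -> HyperParams:
    """Exhaustive grid search over pooling hyperparameters.

    For every grid point, `train_features_fn` turns the candidate
    HyperParams into features for the training subset; a stratified
    validation split is scored with `objective` (default: the balance
    metric g).  Ties keep the first grid point in iteration order.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("empty hyperparameter grid")
    unknown = set(grids) - _HP_FIELDS
    if unknown:
        raise ValueError(f"unknown hyperparameters in grid: {sorted(unknown)}")
    base_hp = base_hp or HyperParams()
    objective = objective or (lambda r: -1.0 if math.isnan(r.g) else r.g)
    labels = np.asarray(train_labels, dtype=int)
    idx = np.arange(labels.size)
    tr, va = train_test_split(
        idx, test_size=val_fraction, stratify=labels, random_state=seed, shuffle=True
    )

    names = list(grids.keys())
    best_hp, best_score = None, -math.inf
    for combo in product(*(grids[n] for n in names)):
        hp = replace(base_hp, **dict(zip(names, combo)))
        feats = train_features_fn(hp)
        model = fit_weighted_linear_svm(feats[tr], labels[tr], cost=cost, seed=seed)
        score = objective(compute_metrics(confusion(labels[va], predict(model, feats[va]))))
        if score > best_score:
            best_hp, best_score = hp, score
    assert best_hp is not None
    return best_hp
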
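"""Group-comparison schemes, WEKA-convention classifiers, and the metric panel.

Four groups generate eleven comparison schemes: one with all groups as
separate classes, four one-vs-rest ("X vs Others"), and six pairwise.
Each scheme is scored by stratified k-fold cross-validation with pooled
out-of-fold predictions, and summarised in a metric panel — per-class and
class-frequency-weighted TP rate, FP rate, precision, recall, F-measure,
MCC, ROC area and PRC area, plus the confusion matrix — the standard
columns of a WEKA evaluation report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._seeding import substream_int
from .fuzzy import PartitionConfig, fit_partition

PANEL_COLUMNS = ["tp_rate", "fp_rate", "precision", "recall",
                 "f_measure", "mcc", "roc_area", "prc_area"]


@dataclass(frozen=True)
class ComparisonScheme:
    """One group-labelling scheme: group label -> scheme class (or excluded)."""

    name: str
    mapping: dict[str, str]          # original group -> scheme class
    class_order: tuple[str, ...]     # display/confusion order

    def apply(self, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(instance mask, mapped labels of kept instances)."""
        groups = np.asarray(groups)
        mask = np.isin(groups, list(self.mapping))
        mapped = np.array([self.mapping[g] for g in groups[mask]])
        return mask, mapped


def build_comparisons(groups: tuple[str, ...] | list[str]) -> list[ComparisonScheme]:
    """All comparison schemes for g groups: 1 all-groups + g one-vs-rest +
    C(g,2) pairwise — eleven schemes for the four study groups."""
    groups = tuple(groups)
    if len(set(groups)) < 2:
        raise ValueError("need at least 2 distinct group labels")
    if len(set(groups)) != len(groups):
        raise ValueError("group labels must be distinct")
    schemes = [ComparisonScheme("All", {g: g for g in groups}, groups)]
    for g in groups:
        mapping = {h: (g if h == g else "others") for h in groups}
        schemes.append(
            ComparisonScheme(f"{g.capitalize()} vs Others", mapping, (g, "others"))
        )
    for a, b in combinations(groups, 2):
        schemes.append(
            ComparisonScheme(f"{a.capitalize()} vs {b.capitalize()}",
                             {a: a, b: b}, (a, b))
        )
    return schemes


@dataclass
class MetricPanel:
    """Per-class and weighted classification metrics plus the confusion matrix.

    ``per_class`` is indexed by class in confusion-matrix order; ``weighted``
    is the class-frequency-weighted average of each column.  ROC/PRC areas
    are NaN when the panel was derived from a confusion matrix alone.
    """

    classes: tuple[str, ...]
    per_class: pd.DataFrame
    weighted: pd.Series
    confusion: np.ndarray
    scheme: str = ""
    model: str = ""

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        """Report table: one row per class plus a weighted-average row."""
        df = self.per_class.copy()
        df.loc["Weighted Avg"] = self.weighted
        if decimals is not None:
            df = df.map(lambda v: round_half_up(v, decimals))
        return df


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (report convention), NaN-safe."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def metrics_from_confusion(
    cm: np.ndarray,
    classes: tuple[str, ...] | None = None,
) -> MetricPanel:
    """Metric panel (all but ROC/PRC areas) from a c x c confusion matrix.

    Rows are true classes, columns predicted.  Per class, one-vs-rest:
    precision TP/(TP+FP), recall = TP rate = TP/(TP+FN),
    FP rate FP/(FP+TN), F = 2PR/(P+R), and MCC; 0/0 ratios are 0.
    Weighted averages use true-class frequencies.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    c = cm.shape[0]
    classes = classes or tuple(f"class_{i}" for i in range(c))

    rows = []
    for i in range(c):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        prec = _safe_div(tp, tp + fp)
        rec = _safe_div(tp, tp + fn)
        fpr = _safe_div(fp, fp + tn)
        f1 = _safe_div(2 * prec * rec, prec + rec)
        denom = math.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
        mcc = float(tp * tn - fp * fn) / denom if denom > 0 else 0.0
        rows.append([rec, fpr, prec, rec, f1, mcc, np.nan, np.nan])

    per_class = pd.DataFrame(rows, index=list(classes), columns=PANEL_COLUMNS)
    weights = cm.sum(axis=1) / total
    weighted = per_class.mul(weights, axis=0).sum(skipna=False)
    return MetricPanel(classes=tuple(classes), per_class=per_class,
                       weighted=weighted, confusion=cm.copy())


def _safe_div(num: float, den: float) -> float:
    return float(num) / float(den) if den > 0 else 0.0


@dataclass
class ClassifierConfig:
    """Hyperparameters in the defaults of the WEKA tools the study used:
    MLP with one hidden layer of ceil((p + classes)/2) logistic units
    trained by backpropagation (learning rate 0.3, momentum 0.2, 500
    epochs, inputs standardized); SVM with an RBF kernel at default scale."""

    hidden_units: int | None = None   # None -> ceil((p + n_classes) / 2)
    learning_rate: float = 0.3
    momentum: float = 0.2
    epochs: int = 500
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"


def _as_dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = _as_dense(X)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    return X, y


def train_mlp(X, y, config: ClassifierConfig | None = None, seed: int = 0) -> Pipeline:
    """Fit the one-hidden-layer backpropagation MLP (standardized inputs)."""
    config = config or ClassifierConfig()
    X, y = _check_xy(X, y)
    hidden = config.hidden_units or math.ceil((X.shape[1] + len(np.unique(y))) / 2)
    model = Pipeline([
        ("scale", StandardScaler()),
        ("mlp", MLPClassifier(
            hidden_layer_sizes=(hidden,),
            activation="logistic",
            solver="sgd",
            learning_rate_init=config.learning_rate,
            momentum=config.momentum,
            nesterovs_momentum=False,
            batch_size=min(32, len(y)),  # stochastic updates, as in online backprop
            alpha=1e-6,
            max_iter=config.epochs,
            tol=1e-7,
            n_iter_no_change=config.epochs,
            random_state=seed,
        )),
    ])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter at the fixed epoch budget
        model.fit(X, y)
    return model


def train_svm(X, y, config: ClassifierConfig | None = None, seed: int = 0,
              kernel: str = "rbf") -> Pipeline:
    """Fit the RBF-kernel SVM (one-vs-one for multi-class, calibrated scores)."""
    config = config or ClassifierConfig()
    X, y = _check_xy(X, y)
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel=kernel, C=config.svm_c, gamma=config.svm_gamma,
                    probability=True, random_state=seed)),
    ])
    model.fit(X, y)
    return model


_TRAINERS = {"mlp": train_mlp, "svm": train_svm}


def cross_validate(
    X: np.ndarray,
    groups: np.ndarray,
    scheme: ComparisonScheme,
    model: str = "mlp",
    k: int = 10,
    seed: int = 0,
    transform: str | None = None,
    partition_config: PartitionConfig | None = None,
    config: ClassifierConfig | None = None,
) -> MetricPanel:
    """Stratified k-fold cross-validation of one comparison scheme.

    Any fitted transform (the partition-membership filter, scaling) is fit
    on each training fold only and applied to the held-out fold, so no
    information leaks.  Out-of-fold predictions are pooled into a single
    confusion matrix; ROC/PRC areas come from pooled one-vs-rest
    probability scores.  Deterministic given ``seed``.

    Parameters
    ----------
    transform
        ``None`` for raw features, ``"crisp"`` or ``"graded"`` for the
        partition-membership filter fitted per fold.
    """
    if model not in _TRAINERS:
        raise ValueError(f"model must be one of {sorted(_TRAINERS)}")
    X = _as_dense(X)
    mask, y = scheme.apply(groups)
    Xs = X[mask]
    classes = [c for c in scheme.class_order if c in set(y)]
    if len(classes) < 2:
        raise ValueError(f"scheme {scheme.name!r} has fewer than 2 populated classes")
    min_count = min(int((y == c).sum()) for c in classes)
    if min_count < k:
        warnings.warn(
            f"scheme {scheme.name!r}: smallest class has {min_count} < {k} "
            f"instances; using {min_count} folds"
        )
        k = max(2, min_count)

    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=substream_int(seed, "cv", scheme.name))
    y_true = np.empty(len(y), dtype=object)
    y_pred = np.empty(len(y), dtype=object)
    scores = np.zeros((len(y), len(classes)))
    for fold, (tr, te) in enumerate(skf.split(Xs, y)):
        X_tr, X_te = Xs[tr], Xs[te]
        if transform is not None:
            pcfg = partition_config or PartitionConfig()
            part = fit_partition(X_tr, y[tr], pcfg)
            X_tr = part.transform(X_tr, mode=transform).toarray()
            X_te = part.transform(X_te, mode=transform).toarray()
        clf = _TRAINERS[model](X_tr, y[tr], config,
                               seed=substream_int(seed, "fit", scheme.name, model, fold))
        y_true[te] = y[te]
        y_pred[te] = clf.predict(X_te)
        proba = clf.predict_proba(X_te)
        fitted = list(clf.classes_)
        for ci, cls in enumerate(classes):
            if cls in fitted:
                scores[te, ci] = proba[:, fitted.index(cls)]

    cm = np.zeros((len(classes), len(classes)), dtype=int)
    pos = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        cm[pos[t], pos[p]] += 1

    panel = metrics_from_confusion(cm, tuple(classes))
    y_arr = np.array([pos[t] for t in y_true])
    for ci, cls in enumerate(classes):
        ind = (y_arr == ci).astype(int)
        if ind.min() == ind.max():
            continue
        panel.per_class.loc[cls, "roc_area"] = roc_auc_score(ind, scores[:, ci])
        panel.per_class.loc[cls, "prc_area"] = average_precision_score(ind, scores[:, ci])
    weights = cm.sum(axis=1) / cm.sum()
    panel.weighted = panel.per_class.mul(weights, axis=0).sum(skipna=False)
    panel.scheme = scheme.name
    panel.model = model
    return panel
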
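"""Attribute ranking: correlation, chi-squared, PCA-loading and
two-way-significance evaluators, each returning a full ranking of the
attributes (best first) with per-attribute scores.

All four are filter methods scored attribute-by-attribute (ranker-style
search); ties break deterministically toward the lower attribute index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency


@dataclass
class RankedAttributes:
    """A permutation of attribute indices (best first) and their scores."""

    order: np.ndarray   # 0-based attribute indices, best first
    scores: np.ndarray  # per-attribute scores, in original attribute order
    method: str

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


def _rank(scores: np.ndarray, method: str) -> RankedAttributes:
    scores = np.asarray(scores, dtype=float)
    order = np.lexsort((np.arange(len(scores)), -scores))  # score desc, index asc
    return RankedAttributes(order=order, scores=scores, method=method)


def _check(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if len(X) < 3:
        raise ValueError("need at least 3 instances")
    return X, y


def correlation_rank(X: np.ndarray, y: np.ndarray) -> RankedAttributes:
    """Class-frequency-weighted mean |Pearson r| against one-vs-rest indicators.

    A perfectly class-aligned attribute scores 1; a constant attribute 0.
    """
    X, y = _check(X, y)
    classes, counts = np.unique(y, return_counts=True)
    weights = counts / counts.sum()
    scores = np.zeros(X.shape[1])
    sd = X.std(axis=0)
    for cls, w in zip(classes, weights):
        ind = (y == cls).astype(float)
        if ind.std() == 0:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r = ((X - X.mean(axis=0)) * (ind - ind.mean())[:, None]).mean(axis=0) / (
                sd * ind.std()
            )
        r = np.where(sd > 0, r, 0.0)
        scores += w * np.abs(r)
    return _rank(scores, "correlation")


def _discretize(col: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin codes; constant columns collapse to one bin."""
    if np.ptp(col) == 0:
        return np.zeros(len(col), dtype=int)
    binned = pd.qcut(col, q=n_bins, labels=False, duplicates="drop")
    return np.asarray(binned, dtype=int)


def _contingency(col: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    bins = _discretize(col, n_bins)
    classes = np.unique(y)
    table = np.zeros((bins.max() + 1, len(classes)))
    for ci, cls in enumerate(classes):
        sel = bins[y == cls]
        np.add.at(table[:, ci], sel, 1)
    return table


def _effective_bins(n: int, n_bins: int) -> int:
    if n < n_bins:
        warnings.warn(f"only {n} instances; reducing bins from {n_bins} to {n}")
        return max(n, 2)
    return n_bins


def chi2_rank(X: np.ndarray, y: np.ndarray, n_bins: int = 10) -> RankedAttributes:
    """Chi-squared statistic of the (equal-frequency bins x class) table."""
    X, y = _check(X, y)
    n_bins = _effective_bins(len(X), n_bins)
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        table = _contingency(X[:, j], y, n_bins)
        if table.shape[0] < 2:
            continue  # constant attribute -> 0
        stat, _, _, _ = chi2_contingency(table, correction=False)
        scores[j] = stat
    return _rank(scores, "chi2")


def _uncertainty_coefficients(table: np.ndarray) -> tuple[float, float]:
    """Theil's U(row|col) and U(col|row) of a contingency table."""
    n = table.sum()
    p = table / n
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)

    def entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h_r, h_c = entropy(pr), entropy(pc)
    h_rc = entropy(p.ravel())
    mi = h_r + h_c - h_rc
    u_r = mi / h_r if h_r > 0 else 0.0
    u_c = mi / h_c if h_c > 0 else 0.0
    return u_r, u_c


def significance_rank(X: np.ndarray, y: np.ndarray, n_bins: int = 10) -> RankedAttributes:
    """Two-way probabilistic association on the discretized table.

    Score = mean of the two Theil uncertainty coefficients
    U(attribute | class) and U(class | attribute): 1 when the attribute
    determines (and is determined by) the class, 0 for a constant or
    class-independent attribute.
    """
    X, y = _check(X, y)
    n_bins = _effective_bins(len(X), n_bins)
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        table = _contingency(X[:, j], y, n_bins)
        if table.shape[0] < 2:
            continue
        u_attr, u_class = _uncertainty_coefficients(table)
        scores[j] = 0.5 * (u_attr + u_class)
    return _rank(scores, "significance")


def pca_rank(X: np.ndarray, n_components: int | None = None) -> RankedAttributes:
    """Rank attributes by their loadings on the leading principal components.

    The attribute correlation matrix is eigendecomposed; with eigenvalues
    lambda_c sorted descending and eigenvectors v_c, attribute j scores
    sum_c lambda_c * |v_c[j]| over the top ``n_components`` (default: the
    smallest set explaining 95% of total variance).  Zero-variance
    attributes are excluded from the correlation matrix and rank last with
    score 0.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 attributes")
    sd = X.std(axis=0)
    active = np.flatnonzero(sd > 0)
    scores = np.zeros(X.shape[1])
    if len(active) >= 2:
        corr = np.corrcoef(X[:, active], rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(corr)
        idx = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = np.clip(eigvals[idx], 0, None), eigvecs[:, idx]
        if n_components is None:
            cum = np.cumsum(eigvals) / eigvals.sum()
            n_components = int(np.searchsorted(cum, 0.95) + 1)
        n_components = min(n_components, len(eigvals))
        sub = eigvals[:n_components, None] * np.abs(eigvecs[:, :n_components].T)
        scores[active] = sub.sum(axis=0)
    elif len(active) == 1:
        scores[active[0]] = 1.0
    return _rank(scores, "pca")


def rank_table(
    ranked: RankedAttributes,
    attribute_names: list[str],
    montage: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Tidy ranking report: attribute, channel, electrode, score, rank."""
    from .hfd import feature_to_channel
    from .montage import STANDARD_1020_NAMES

    montage = montage or STANDARD_1020_NAMES
    rows = []
    for rank_i, j in enumerate(ranked.order, start=1):
        name = attribute_names[j]
        ch, electrode = (None, None)
        if name.startswith("higu_"):
            ch, electrode = feature_to_channel(int(name.split("_")[1]), montage)
        rows.append({"attribute": name, "channel": ch, "electrode": electrode,
                     "score": ranked.scores[j], "rank": rank_i,
                     "method": ranked.method})
    return pd.DataFrame(rows)
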
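"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pytest

from eegfd.synth import GROUPS, CohortConfig, generate_cohort


def reference_curve_length(x, m, k):
    """Direct transliteration of the Higuchi normalized length formula."""
    x = list(map(float, x))
    n = len(x)
    n_i = (n - m) // k
    total = 0.0
    for i in range(1, n_i + 1):
        total += abs(x[m + i * k - 1] - x[m + (i - 1) * k - 1])
    return total * (n - 1) / (n_i * k) / k


def reference_hfd(x, k_max=8):
    """Triple-loop reference HFD: slope of ln<L(k)> against ln(1/k)."""
    import math

    xs, ys = [], []
    for k in range(1, k_max + 1):
        lengths = [reference_curve_length(x, m, k) for m in range(1, k + 1)]
        xs.append(math.log(1.0 / k))
        ys.append(math.log(sum(lengths) / len(lengths)))
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    sxx = sum((a - mx) ** 2 for a in xs)
    return sxy / sxx


def reference_metrics_2x2(cm):
    """Closed-form one-vs-rest metrics for a 2x2 confusion matrix."""
    import math

    (a, b), (c, d) = cm
    out = []
    for tp, fn, fp, tn in [(a, b, c, d), (d, c, b, a)]:
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        fpr = fp / (fp + tn) if fp + tn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = (tp * tn - fp * fn) / den if den else 0.0
        out.append(dict(precision=prec, recall=rec, fp_rate=fpr, f=f1, mcc=mcc))
    return out


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """A deliberately small cohort for structural tests (fast to generate)."""
    return CohortConfig(
        n_per_group={g: 3 for g in GROUPS},
        duration_s=4.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    return generate_cohort(tiny_cohort_config, clean=True)


@pytest.fixture(scope="session")
def feature_like_table():
    """Synthetic 'HFD-like' feature matrix with a planted informative block.

    Emulates the estimator-level statistics of the planted cohort effect
    (group means stepping by 0.1 on affected-channel features, estimator
    noise SD ~0.03) without the cost of signal synthesis.
    """
    rng = np.random.default_rng(1234)
    n_per_group = 20
    means = {"addict": 1.15, "first": 1.25, "second": 1.35, "normal": 1.45}
    affected_features = [6, 7, 8, 9, 10, 11, 28, 29]  # 0-based: higu_7..12, higu_29/30
    X, y = [], []
    for g in GROUPS:
        block = np.full((n_per_group, 38), 1.30)
        block[:, affected_features] = means[g]
        block += rng.normal(0, 0.03, block.shape)
        X.append(block)
        y += [g] * n_per_group
    return np.vstack(X), np.array(y)
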
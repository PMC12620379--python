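"""Channel-discrimination statistics across the four groups.

Per HFD attribute: Lilliefors-corrected Kolmogorov-Smirnov normality
screening, one-way ANOVA across groups, and Tukey's HSD post hoc on all
six group pairs.  Significant attributes are then attributed to their
scalp channel through the fixed feature -> channel map.

The primary report leaves the 38 per-attribute ANOVA p-values uncorrected
(each attribute is its own family); a Bonferroni-adjusted column is always
reported alongside for the conservative reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.diagnostic import lilliefors

from .hfd import feature_to_channel
from .montage import STANDARD_1020_NAMES


@dataclass
class AnovaResult:
    """One-way ANOVA of one attribute across the groups."""

    attribute: str
    F: float
    p: float
    group_means: dict[str, float]
    significant: bool
    p_bonferroni: float = float("nan")


@dataclass
class TukeyResult:
    """All pairwise studentized-range comparisons for one attribute."""

    attribute: str
    pairwise: pd.DataFrame  # columns: group_a, group_b, mean_diff, p_adj, significant


def ks_normality(values_by_group: dict[str, np.ndarray],
                 lilliefors_correction: bool = True) -> dict[str, float]:
    """Per-group KS normality p-values (mean/SD estimated from the sample).

    With ``lilliefors_correction`` (default) the null distribution accounts
    for the estimated parameters; otherwise a plain KS test against the
    fitted normal is used.  Constant samples report p = 0 with a warning.
    """
    out: dict[str, float] = {}
    for group, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 3:
            raise ValueError(f"group {group!r} has fewer than 3 observations")
        if np.ptp(vals) == 0:
            warnings.warn(f"group {group!r}: constant sample, normality degenerate")
            out[group] = 0.0
            continue
        if lilliefors_correction:
            _, p = lilliefors(vals, dist="norm")
        else:
            _, p = sst.kstest(vals, "norm", args=(vals.mean(), vals.std(ddof=1)))
        out[group] = float(p)
    return out


def _split_by_group(values: np.ndarray, groups: np.ndarray) -> dict[str, np.ndarray]:
    groups = np.asarray(groups)
    return {g: np.asarray(values)[groups == g] for g in pd.unique(groups)}


def anova_per_attribute(
    features: pd.DataFrame,
    groups: np.ndarray,
    alpha: float = 0.05,
    attributes: list[str] | None = None,
) -> list[AnovaResult]:
    """One-way ANOVA of every attribute across the groups.

    Per-attribute p-values are uncorrected; a Bonferroni column over the
    tested attribute family is attached to each result.  Attributes whose
    groups have fewer than 2 members are skipped with a warning.
    """
    groups = np.asarray(groups)
    attrs = attributes or [c for c in features.columns
                           if c not in ("subject_id", "group")]
    results: list[AnovaResult] = []
    for attr in attrs:
        by_group = _split_by_group(features[attr].to_numpy(dtype=float), groups)
        if any(len(v) < 2 for v in by_group.values()):
            warnings.warn(f"attribute {attr}: a group has <2 members; skipped")
            continue
        samples = list(by_group.values())
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = sst.f_oneway(*samples)
            if not np.isfinite(f_stat):  # zero within-group variance edge case
                f_stat, p = 0.0, 1.0
        results.append(AnovaResult(
            attribute=attr, F=float(f_stat), p=float(p),
            group_means={g: float(v.mean()) for g, v in by_group.items()},
            significant=bool(p < alpha),
        ))
    m = len(results)
    for r in results:
        r.p_bonferroni = min(1.0, r.p * m)
    return results


def tukey_hsd(values: np.ndarray, groups: np.ndarray, alpha: float = 0.05,
              attribute: str = "") -> TukeyResult:
    """Tukey HSD over all group pairs (studentized-range adjusted p-values)."""
    by_group = _split_by_group(np.asarray(values, dtype=float), np.asarray(groups))
    names = list(by_group)
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("every group needs at least 2 observations")
    res = sst.tukey_hsd(*by_group.values())
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p_adj = float(res.pvalue[i, j])
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "mean_diff": float(by_group[names[i]].mean() - by_group[names[j]].mean()),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            })
    return TukeyResult(attribute=attribute, pairwise=pd.DataFrame(rows))


def attribute_channel_report(
    results: list[AnovaResult],
    montage: tuple[str, ...] = STANDARD_1020_NAMES,
) -> pd.DataFrame:
    """Map significant attributes to channels; duplicates collapse per channel.

    Returns one row per implicated channel with the significant attributes
    that pointed at it.
    """
    per_channel: dict[int, dict] = {}
    for r in results:
        if not r.significant:
            continue
        j = int(r.attribute.split("_")[1])
        ch, electrode = feature_to_channel(j, montage)
        entry = per_channel.setdefault(ch, {"channel": ch, "electrode": electrode,
                                            "attributes": []})
        entry["attributes"].append(r.attribute)
    rows = [
        {**e, "attributes": ";".join(e["attributes"])}
        for ch, e in sorted(per_channel.items())
    ]
    return pd.DataFrame(rows, columns=["channel", "electrode", "attributes"])


def stats_report(features: pd.DataFrame, groups: np.ndarray,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Full per-attribute report: F, p, Bonferroni p, significant Tukey pairs."""
    anova = anova_per_attribute(features, groups, alpha=alpha)
    rows = []
    for r in anova:
        j = int(r.attribute.split("_")[1])
        ch, electrode = feature_to_channel(j)
        tk = tukey_hsd(features[r.attribute].to_numpy(dtype=float), groups,
                       alpha=alpha, attribute=r.attribute)
        sig_pairs = ";".join(
            f"{a}-{b}" for a, b in
            tk.pairwise.loc[tk.pairwise["significant"], ["group_a", "group_b"]].itertuples(index=False)
        )
        rows.append({"attribute": r.attribute, "channel": ch, "electrode": electrode,
                     "F": r.F, "p": r.p, "p_bonferroni": r.p_bonferroni,
                     "significant": r.significant, "tukey_significant_pairs": sig_pairs})
    return pd.DataFrame(rows)
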
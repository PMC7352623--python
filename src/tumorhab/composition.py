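"""Longitudinal habitat composition and group comparisons.

Tumor composition is the percent of tumor volume (or section area) assigned
to each habitat; unassigned voxels (removed by quality filters) are
excluded from the denominator.  Treatment-response analysis excludes tumors
larger than 500 mm^3 at baseline.  Comparisons follow the study's tests:
two-sided Wilcoxon rank-sum within groups (and between two groups), one-way
ANOVA with Tukey's HSD for three or more groups, all uncorrected for
multiplicity.  Rank-sum p-values are exact for arm sizes up to 10 without
ties and use the normal approximation otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import defaults

__all__ = [
    "percent_tumor_volume",
    "composition_table",
    "exclude_large_tumors",
    "rank_sum_test",
    "compare_within_group",
    "compare_between_groups",
    "compare_habitat_parameter_means",
]


def percent_tumor_volume(habitat_map: np.ndarray,
                         habitat_names: dict[int, str] | None = None) -> dict:
    """Percent of assigned voxels per habitat id (or name).

    The denominator counts assigned (label > 0) voxels only, so percents sum
    to 100 regardless of filter removals.  Raises on an empty map.
    """
    m = np.asarray(habitat_map)
    assigned = m[m > 0]
    if assigned.size == 0:
        raise ValueError("habitat map has no assigned voxels")
    out: dict = {}
    for h in np.unique(assigned):
        key = habitat_names[int(h)] if habitat_names else int(h)
        # distinct clusters can carry the same physiological label; aggregate
        out[key] = out.get(key, 0.0) + \
            100.0 * float((assigned == h).sum()) / assigned.size
    return out


def composition_table(records: list[dict]) -> pd.DataFrame:
    """Long-format composition table: one row per tumor/day/habitat."""
    return pd.DataFrame.from_records(
        records, columns=["tumor", "day", "group", "habitat",
                          "percent", "volume_mm3"])


def exclude_large_tumors(
    table: pd.DataFrame,
    volume_limit_mm3: float = defaults.VOLUME_EXCLUSION_MM3,
    baseline_day=0,
) -> tuple[pd.DataFrame, list]:
    """Drop tumors strictly larger than the limit at baseline.

    Tumors with no baseline record are retained with a warning flag in the
    returned exclusion list (entry ``(tumor, "no-baseline")``).
    """
    excluded, flagged = [], []
    for tumor, sub in table.groupby("tumor"):
        base = sub[sub["day"] == baseline_day]
        if base.empty:
            flagged.append((tumor, "no-baseline"))
            continue
        if float(base["volume_mm3"].iloc[0]) > volume_limit_mm3:
            excluded.append(tumor)
    out = table[~table["tumor"].isin(excluded)].reset_index(drop=True)
    return out, excluded + flagged


def _anova_p(samples) -> float:
    # degenerate between-group variance (identical means) -> F = 0, p = 1
    res = stats.f_oneway(*samples)
    p = float(res.pvalue)
    if np.isnan(p):
        return 1.0 if abs(float(res.statistic)) < 1e-12 else p
    return p


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both arms have <= 10 observations and no
    ties are present; normal approximation otherwise.  Identical samples
    give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compare_within_group(
    table: pd.DataFrame,
    group,
    habitat,
    day,
    baseline_day=0,
) -> float:
    """Rank-sum p-value comparing a habitat's percents at ``day`` vs baseline
    within one treatment group."""
    sub = table[(table["group"] == group) & (table["habitat"] == habitat)]
    base = sub[sub["day"] == baseline_day]["percent"].to_numpy()
    post = sub[sub["day"] == day]["percent"].to_numpy()
    if min(base.size, post.size) < 3:
        raise ValueError("need at least three tumors per arm")
    return rank_sum_test(base, post)


def compare_between_groups(table: pd.DataFrame, habitat, day) -> dict:
    """Between-group comparison of a habitat's percents at one day.

    Two groups dispatch to the rank-sum test; three or more use one-way
    ANOVA with Tukey-adjusted pairwise p-values.  Returns a dict with
    ``omnibus_p``, ``test``, and (ANOVA path) ``pairwise``.
    """
    sub = table[(table["habitat"] == habitat) & (table["day"] == day)]
    groups = sorted(sub["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [sub[sub["group"] == g]["percent"].to_numpy() for g in groups]
    if any(s.size < 3 for s in samples):
        raise ValueError("need at least three tumors per group")
    if len(groups) == 2:
        return {"test": "rank-sum", "omnibus_p": rank_sum_test(*samples)}
    tukey = stats.tukey_hsd(*samples)
    pairwise = {
        (groups[i], groups[j]): float(tukey.pvalue[i, j])
        for i in range(len(groups)) for j in range(i + 1, len(groups))
    }
    return {"test": "anova+tukey", "omnibus_p": _anova_p(samples),
            "pairwise": pairwise}


def compare_habitat_parameter_means(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names,
) -> dict:
    """Per-feature ANOVA + Tukey HSD across cluster labels.

    ``features`` is (n, n_features) in original units, ``labels`` the cluster
    assignment.  Returns {feature: {"omnibus_p":..., "pairwise": {...}}}.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if ids.size < 2:
        raise ValueError("need at least two clusters")
    out = {}
    for j, name in enumerate(feature_names):
        samples = [features[labels == c, j] for c in ids]
        tukey = stats.tukey_hsd(*samples)
        pairwise = {
            (int(ids[i]), int(ids[k])): float(tukey.pvalue[i, k])
            for i in range(ids.size) for k in range(i + 1, ids.size)
        }
        out[name] = {"omnibus_p": _anova_p(samples), "pairwise": pairwise}
    return out
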
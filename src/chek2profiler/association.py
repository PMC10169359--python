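"""Categorical group comparisons and multiple-testing correction.

Binary features (driver gene mutated, whole-genome duplicated,
chromothripsis present, ...) are compared between subgroups with Pearson's
chi-squared test when every expected cell count is at least five and with
the two-sided Fisher exact test otherwise. Scans across many features are
corrected with the Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, SubgroupLabel, ValidationError, group_members

__all__ = [
    "FrequencyComparison",
    "two_by_two_test",
    "hochberg_adjust",
    "frequency_scan",
    "exclusivity_report",
]


@dataclass
class FrequencyComparison:
    feature: str
    group_a: str
    group_b: str
    k_a: int
    n_a: int
    k_b: int
    n_b: int
    test: str            # "chisq" or "fisher"
    p_raw: float
    p_adj: float | None = None

    @property
    def freq_a(self) -> float:
        return self.k_a / self.n_a

    @property
    def freq_b(self) -> float:
        return self.k_b / self.n_b


def two_by_two_test(
    k_a: int, n_a: int, k_b: int, n_b: int,
    feature: str = "", group_a: str = "a", group_b: str = "b",
) -> FrequencyComparison:
    """Compare k_a/n_a with k_b/n_b.

    Uses Pearson's chi-squared without continuity correction when all four
    expected cell counts are >= 5, otherwise the two-sided Fisher exact
    test (sum of hypergeometric point probabilities <= that of the
    observed table).
    """
    if n_a <= 0 or n_b <= 0:
        raise ValidationError("group sizes must be positive")
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ValidationError("event counts must satisfy 0 <= k <= n")
    table = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]], dtype=float)
    # Expected counts under independence.
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if (expected >= 5).all():
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        test = "chisq"
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
        test = "fisher"
    return FrequencyComparison(
        feature=feature, group_a=group_a, group_b=group_b,
        k_a=k_a, n_a=n_a, k_b=k_b, n_b=n_b, test=test, p_raw=float(p),
    )


def hochberg_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Hochberg step-up adjustment.

    Sort ascending; the largest P is unchanged and
    adj_(i) = min(adj_(i+1), (m - i + 1) * p_(i)) walking down, capped at 1;
    values are returned in the original input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p must be a non-empty 1-D vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    adj[m - 1] = sorted_p[m - 1]
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i + 1], (m - i) * sorted_p[i])
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def frequency_scan(
    features: pd.DataFrame,
    cohort: CohortTable,
    reference_group: SubgroupLabel | str,
    groups: list[SubgroupLabel | str] | None = None,
    adjust_scope: str = "within_feature",
) -> pd.DataFrame:
    """Compare each binary feature between a reference group and every other group.

    ``features`` is a samples x features frame (index or a ``sample_id``
    column; entries 0/1/NaN). Adjustment is Hochberg, by default within
    each feature across its group comparisons (``adjust_scope='global'``
    pools everything). Features constant across the cohort are skipped
    with a note column rather than tested.
    """
    if "sample_id" in features.columns:
        features = features.set_index("sample_id")
    reference_group = SubgroupLabel(reference_group)
    if groups is None:
        groups = [
            SubgroupLabel.BRCA1, SubgroupLabel.BRCA2, SubgroupLabel.HRD,
            SubgroupLabel.ERneg, SubgroupLabel.ERpos,
        ]
    ref_ids = group_members(cohort, reference_group)["sample_id"]
    ref_ids = [s for s in ref_ids if s in features.index]
    if len(ref_ids) == 0:
        raise ValidationError(f"reference group {reference_group.value} is empty")
    rows = []
    for feat in features.columns:
        col = features[feat]
        observed = col.dropna()
        if observed.nunique() <= 1:
            rows.append({"feature": feat, "group": None, "note": "constant; skipped"})
            continue
        ref_vals = col.loc[ref_ids].dropna()
        for g in groups:
            g = SubgroupLabel(g)
            ids = [s for s in group_members(cohort, g)["sample_id"] if s in features.index]
            vals = col.loc[ids].dropna()
            if len(vals) == 0 or len(ref_vals) == 0:
                continue
            cmp = two_by_two_test(
                int(ref_vals.sum()), len(ref_vals), int(vals.sum()), len(vals),
                feature=feat, group_a=reference_group.value, group_b=g.value,
            )
            rows.append(
                {
                    "feature": feat, "group": g.value,
                    "k_ref": cmp.k_a, "n_ref": cmp.n_a,
                    "k_group": cmp.k_b, "n_group": cmp.n_b,
                    "test": cmp.test, "p_raw": cmp.p_raw, "note": "",
                }
            )
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    tested = out["group"].notna()
    out["p_adj"] = np.nan
    if tested.any():
        if adjust_scope == "within_feature":
            for feat, idx in out[tested].groupby("feature").groups.items():
                out.loc[idx, "p_adj"] = hochberg_adjust(out.loc[idx, "p_raw"].to_numpy())
        elif adjust_scope == "global":
            out.loc[tested, "p_adj"] = hochberg_adjust(out.loc[tested, "p_raw"].to_numpy())
        else:
            raise ValueError("adjust_scope must be 'within_feature' or 'global'")
    return out


def exclusivity_report(
    features: pd.DataFrame, feature_a: str, feature_b: str
) -> dict:
    """Co-occurrence of two binary features with a Fisher exact test.

    Returns the 2x2 counts over samples where both features are observed,
    the two-sided Fisher P, and a ``mutually_exclusive`` flag set when the
    both-positive cell is empty.
    """
    if "sample_id" in features.columns:
        features = features.set_index("sample_id")
    for f in (feature_a, feature_b):
        if f not in features.columns:
            raise ValidationError(f"feature {f!r} not present")
    sub = features[[feature_a, feature_b]].dropna()
    if len(sub) == 0:
        raise ValidationError("no samples with both features observed")
    a = sub[feature_a].astype(int)
    b = sub[feature_b].astype(int)
    n11 = int(((a == 1) & (b == 1)).sum())
    n10 = int(((a == 1) & (b == 0)).sum())
    n01 = int(((a == 0) & (b == 1)).sum())
    n00 = int(((a == 0) & (b == 0)).sum())
    odds, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return {
        "feature_a": feature_a,
        "feature_b": feature_b,
        "n_both": n11,
        "n_a_only": n10,
        "n_b_only": n01,
        "n_neither": n00,
        "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
        "p_value": float(p),
        "mutually_exclusive": n11 == 0,
    }
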
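"""Tumor mutational burden, insertion/deletion ratio and group comparisons.

TMB is the count of somatic small variants (SNVs + MNVs + insertions +
deletions) per million mappable bases; the mappable-genome constant
defaults to 2,858,674,661 bases. The ID ratio is the per-genome count of
small insertions divided by the count of small deletions. Group-level
comparisons are nonparametric: Kruskal-Wallis across all requested groups,
pairwise Mann-Whitney against a reference group, with Benjamini-Hochberg
or Hochberg step-up adjustment of the pairwise P-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import hochberg_adjust
from .cohort import CohortTable, SubgroupLabel, ValidationError, group_members

__all__ = [
    "MAPPABLE_BASES",
    "BurdenConstants",
    "VariantCatalog",
    "UndefinedRatioError",
    "compute_tmb",
    "compute_id_ratio",
    "add_burden_metrics",
    "group_metric_summary",
    "GroupSummary",
]

#: Mappable autosomal+X bases of the reference genome used for TMB.
MAPPABLE_BASES = 2_858_674_661


class UndefinedRatioError(ZeroDivisionError):
    """ID ratio requested for a genome with zero deletions."""


@dataclass(frozen=True)
class BurdenConstants:
    mappable_bases: int = MAPPABLE_BASES


@dataclass(frozen=True)
class VariantCatalog:
    """Per-sample somatic small-variant counts."""

    sample_id: str
    n_snv: int
    n_mnv: int
    n_ins: int
    n_del: int

    def __post_init__(self) -> None:
        for name in ("n_snv", "n_mnv", "n_ins", "n_del"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.sample_id}: {name} must be >= 0")

    @property
    def total(self) -> int:
        return self.n_snv + self.n_mnv + self.n_ins + self.n_del


def compute_tmb(catalog: VariantCatalog, constants: BurdenConstants = BurdenConstants()) -> float:
    """Somatic variants per million mappable bases."""
    return catalog.total / (constants.mappable_bases / 1e6)


def compute_id_ratio(catalog: VariantCatalog) -> float:
    """Insertions over deletions; undefined when the genome has no deletions."""
    if catalog.n_del == 0:
        raise UndefinedRatioError(
            f"{catalog.sample_id}: ID ratio undefined (0 deletions); "
            "flag the sample and drop it from group summaries"
        )
    return catalog.n_ins / catalog.n_del


def add_burden_metrics(
    cohort: CohortTable,
    variants: pd.DataFrame,
    constants: BurdenConstants = BurdenConstants(),
) -> CohortTable:
    """Attach ``tmb`` and ``id_ratio`` columns from a per-sample count table.

    ``variants`` needs columns sample_id, n_snv, n_mnv, n_ins, n_del.
    Samples with zero deletions get ``id_ratio`` = NaN (excluded from group
    summaries) rather than an error, matching how undefined ratios are
    handled cohort-wide.
    """
    v = variants.set_index("sample_id")
    if (v[["n_snv", "n_mnv", "n_ins", "n_del"]] < 0).any().any():
        raise ValidationError("variant counts must be non-negative")
    total = v[["n_snv", "n_mnv", "n_ins", "n_del"]].sum(axis=1)
    tmb = total / (constants.mappable_bases / 1e6)
    with np.errstate(divide="ignore", invalid="ignore"):
        id_ratio = v["n_ins"] / v["n_del"].replace(0, np.nan)
    df = cohort.df.copy()
    df["tmb"] = df["sample_id"].map(tmb)
    df["id_ratio"] = df["sample_id"].map(id_ratio)
    return CohortTable(df)


@dataclass
class GroupSummary:
    """Result of a nonparametric multi-group metric comparison."""

    metric: str
    per_group: pd.DataFrame          # index: group; columns: n, median
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame           # reference vs other: n, medians, U, p_raw, p_adj
    reference: str
    adjust: str


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney; exact null for small groups, else asymptotic
    with tie correction."""
    method = "exact" if min(len(a), len(b)) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_metric_summary(
    cohort: CohortTable,
    metric: str,
    groups: list[SubgroupLabel | str],
    posthoc_adjust: str = "BH",
    reference: SubgroupLabel | str = SubgroupLabel.CHEK2_star,
) -> GroupSummary:
    """Medians, Kruskal-Wallis omnibus and reference-vs-group Mann-Whitney tests.

    Pairwise P-values are adjusted across the comparisons with the chosen
    method ('BH' = Benjamini-Hochberg FDR, 'hochberg' = Hochberg step-up).
    Groups with no usable observations are dropped with a warning; the
    omnibus requires at least two groups with >= 2 samples each.
    """
    if posthoc_adjust not in ("BH", "hochberg"):
        raise ValueError("posthoc_adjust must be 'BH' or 'hochberg'")
    reference = SubgroupLabel(reference)
    values: dict[str, np.ndarray] = {}
    for g in groups:
        g = SubgroupLabel(g)
        x = group_members(cohort, g)[metric].dropna().to_numpy(dtype=float)
        if len(x) == 0:
            warnings.warn(f"group {g.value} has no {metric} values; dropped", stacklevel=2)
            continue
        values[g.value] = x
    if reference.value not in values:
        raise ValidationError(f"reference group {reference.value} is empty")
    usable = {g: x for g, x in values.items() if len(x) >= 2}
    if len(usable) < 2:
        raise ValidationError(
            "omnibus test needs >= 2 groups with >= 2 samples each "
            f"(got {len(usable)} for metric {metric!r})"
        )
    stat, p = stats.kruskal(*usable.values())
    per_group = pd.DataFrame(
        {
            "n": {g: len(x) for g, x in values.items()},
            "median": {g: float(np.median(x)) for g, x in values.items()},
        }
    )
    rows = []
    ref_x = values[reference.value]
    for g, x in values.items():
        if g == reference.value:
            continue
        u, p_raw = _mannwhitney(ref_x, x)
        rows.append(
            {
                "group": g,
                "n_ref": len(ref_x),
                "n_group": len(x),
                "median_ref": float(np.median(ref_x)),
                "median_group": float(np.median(x)),
                "U": u,
                "p_raw": p_raw,
            }
        )
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        if posthoc_adjust == "BH":
            from statsmodels.stats.multitest import multipletests

            pairwise["p_adj"] = multipletests(pairwise["p_raw"], method="fdr_bh")[1]
        else:
            pairwise["p_adj"] = hochberg_adjust(pairwise["p_raw"].to_numpy())
    else:
        pairwise["p_adj"] = pd.Series(dtype=float)
    return GroupSummary(
        metric=metric,
        per_group=per_group,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        pairwise=pairwise,
        reference=reference.value,
        adjust=posthoc_adjust,
    )
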
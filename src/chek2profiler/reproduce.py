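"""Recompute the published cohort-level analyses from per-sample tables.

The original study distributes two per-sample supplementary tables that
this package can consume directly once exported to TSV:

* a per-sample overview ("overview table"): the standard sample-sheet
  columns (see :mod:`chek2profiler.cohort`) plus somatic variant counts
  (``n_snv``, ``n_mnv``, ``n_ins``, ``n_del``) and, where available,
  ``wgd_flag`` and ``chromothripsis_flag`` columns;
* an SV size table: one row per structural variant with ``sample_id``,
  ``svtype`` (DEL/TD/INV/TRA) and ``size_bp``.

Place them under ``data/paper_tables/`` as ``overview.tsv`` and
``sv_sizes.tsv`` (any path works programmatically). Every function here
takes such tables and reruns the corresponding analysis: group burden
medians, WGD frequencies by TP53 stratum, chromothripsis frequencies,
TP53 x CHEK2* exclusivity, the bootstrap Fréchet comparison of SV size
spectra and the characteristic-peak detection with its bandwidth sweep.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import svprofile
from .association import exclusivity_report
from .burden import add_burden_metrics
from .cohort import CohortTable, SubgroupLabel, ValidationError, assign_subgroups, group_members, load_cohort

__all__ = [
    "PAPER_TABLE_DIR",
    "load_overview",
    "burden_medians",
    "wgd_frequencies",
    "chromothripsis_frequencies",
    "tp53_chek2star_exclusivity",
    "sv_fd_comparison",
    "characteristic_peaks",
]

#: Default location for user-supplied per-sample tables (repo-relative).
PAPER_TABLE_DIR = Path("data") / "paper_tables"

_COUNT_COLUMNS = ["n_snv", "n_mnv", "n_ins", "n_del"]


def load_overview(path) -> CohortTable:
    """Load a per-sample overview table, assign subgroups, derive burden."""
    cohort = assign_subgroups(load_cohort(path))
    df = cohort.df
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"overview table lacks count column(s): {missing}")
    variants = df[["sample_id", *_COUNT_COLUMNS]]
    return add_burden_metrics(cohort, variants)


_BURDEN_GROUPS = [
    SubgroupLabel.CHEK2_star, SubgroupLabel.BRCA1, SubgroupLabel.BRCA2,
    SubgroupLabel.HRD, SubgroupLabel.ERneg, SubgroupLabel.ERpos,
]


def _cohort_subset(cohort: CohortTable, which: str) -> CohortTable:
    return CohortTable(cohort.df[cohort.df["cohort"] == which].reset_index(drop=True))


def burden_medians(cohort: CohortTable, metric: str = "tmb",
                   which: str = "pBC") -> pd.Series:
    """Per-group medians of a burden metric within one cohort (pBC or mBC)."""
    sub = _cohort_subset(cohort, which)
    out = {}
    for g in _BURDEN_GROUPS:
        vals = group_members(sub, g)[metric].dropna()
        if len(vals):
            out[g.value] = float(vals.median())
    return pd.Series(out, name=f"{metric}_{which}")


def tmb_cohort_fold(cohort: CohortTable) -> float:
    """Median TMB fold of the metastatic over the primary cohort."""
    p = _cohort_subset(cohort, "pBC").df["tmb"].dropna().median()
    m = _cohort_subset(cohort, "mBC").df["tmb"].dropna().median()
    return float(m / p)


def wgd_frequencies(cohort: CohortTable, which: str = "pBC") -> pd.DataFrame:
    """WGD frequency by TP53 stratum, plus CHEK2* among TP53 wild-type."""
    sub = _cohort_subset(cohort, which).df
    if "wgd_flag" not in sub.columns:
        raise ValidationError("overview table lacks a wgd_flag column")
    rows = []
    for stratum in ("mutant", "wildtype"):
        flags = sub.loc[sub["tp53_somatic"] == stratum, "wgd_flag"].dropna().astype(bool)
        rows.append({"group": f"TP53_{stratum}", "k": int(flags.sum()), "n": len(flags)})
    star = sub[sub["is_chek2_star"] & (sub["tp53_somatic"] == "wildtype")]
    flags = star["wgd_flag"].dropna().astype(bool)
    rows.append({"group": "CHEK2_star", "k": int(flags.sum()), "n": len(flags)})
    out = pd.DataFrame(rows)
    out["freq"] = out["k"] / out["n"]
    return out


def chromothripsis_frequencies(cohort: CohortTable, which: str = "mBC") -> pd.DataFrame:
    """Chromothripsis frequency per comparison group plus the CHEK2 overlay."""
    sub = _cohort_subset(cohort, which)
    if "chromothripsis_flag" not in sub.df.columns:
        raise ValidationError("overview table lacks a chromothripsis_flag column")
    rows = []
    for g in [SubgroupLabel.CHEK2, SubgroupLabel.CHEK2_star, SubgroupLabel.HRDplus,
              SubgroupLabel.ERneg, SubgroupLabel.ERpos]:
        flags = group_members(sub, g)["chromothripsis_flag"].dropna().astype(bool)
        if len(flags):
            rows.append({"group": g.value, "k": int(flags.sum()), "n": len(flags),
                         "freq": float(flags.mean())})
    return pd.DataFrame(rows)


def tp53_chek2star_exclusivity(cohort: CohortTable, which: str = "pBC") -> dict:
    """Co-occurrence of bi-allelic CHEK2 inactivation and somatic TP53 mutation."""
    sub = _cohort_subset(cohort, which).df
    feats = pd.DataFrame({
        "sample_id": sub["sample_id"],
        "chek2_star": sub["is_chek2_star"].astype(int),
        "tp53_mutant": sub["tp53_somatic"].map(
            {"mutant": 1, "wildtype": 0}).astype("float"),
    })
    return exclusivity_report(feats, "chek2_star", "tp53_mutant")


def sv_fd_comparison(
    cohort: CohortTable,
    svs: pd.DataFrame,
    svtype: str,
    which: str = "pBC",
    group_a: SubgroupLabel | str = SubgroupLabel.CHEK2,
    group_b: SubgroupLabel | str = SubgroupLabel.ERpos,
    n_boot: int = 100,
    seed: int = 17,
) -> svprofile.FDComparison:
    """Bootstrap Fréchet comparison of two groups' SV size spectra.

    The baseline curve pools all samples of the chosen cohort; the two
    groups' size vectors are bootstrapped against it with a shared
    Silverman bandwidth.
    """
    sub = _cohort_subset(cohort, which)
    ids = set(sub.df["sample_id"])
    svs = svs[svs["sample_id"].isin(ids)]
    baseline = svprofile.size_density(svprofile.collect_sizes(svs, svtype))
    sizes_a = svprofile.collect_sizes(
        svs, svtype, list(group_members(sub, group_a)["sample_id"]))
    sizes_b = svprofile.collect_sizes(
        svs, svtype, list(group_members(sub, group_b)["sample_id"]))
    return svprofile.compare_profiles(
        sizes_a, sizes_b, baseline, n_boot=n_boot, seed=seed,
        group_a=str(SubgroupLabel(group_a)), group_b=str(SubgroupLabel(group_b)),
        svtype=svtype,
    )


def characteristic_peaks(
    cohort: CohortTable,
    svs: pd.DataFrame,
    svtype: str = "INV",
    group: SubgroupLabel | str = SubgroupLabel.CHEK2,
    which: str = "pBC",
    bandwidth_sweep: tuple[float, ...] = (1.0, 0.75, 1.25),
) -> dict[float, list[float]]:
    """Peak locations (Mb) of a group's size spectrum at 0.05-log10 resolution.

    Peak detection is bandwidth-sensitive, so the Silverman bandwidth is
    swept over the given multipliers; the result maps each multiplier to
    the detected peak locations.
    """
    sub = _cohort_subset(cohort, which)
    ids = set(sub.df["sample_id"])
    svs = svs[svs["sample_id"].isin(ids)]
    pooled = svprofile.collect_sizes(svs, svtype)
    sizes = svprofile.collect_sizes(
        svs, svtype, list(group_members(sub, group)["sample_id"]))
    from .density import silverman_bandwidth

    bw0 = silverman_bandwidth(np.log10(pooled / 1e6))
    out = {}
    for mult in bandwidth_sweep:
        curve = svprofile.size_density(sizes, bandwidth=mult * bw0)
        ps = svprofile.find_density_peaks(curve, svtype=svtype, group=str(group))
        out[mult] = ps.locations_mb
    return out
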
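"""Whole-genome duplication calling from allele-specific copy number.

A tumor genome that has undergone whole-genome duplication (WGD) carries a
major copy number of at least two across most of the genome. Per sample we
compute the fraction of copy-number segments with major CN >= 2 (segments
counted unweighted by length). Across a cohort this fraction is strongly
bimodal; the WGD cut-point is placed at the lowest point of the density
between the two modes, and every sample at or above the cut-point is
flagged WGD.

Subgroup WGD frequencies are reported on TP53 wild-type cases only, since
somatic TP53 mutation is itself strongly associated with WGD and would
otherwise confound the subgroup comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .association import two_by_two_test
from .cohort import CohortTable, SubgroupLabel, ValidationError, group_members
from .density import kde_evaluate, silverman_bandwidth

__all__ = [
    "SegmentSet",
    "WGDCall",
    "NoBimodalStructureError",
    "read_segments",
    "wgd_fraction",
    "wgd_cutpoint",
    "call_wgd",
    "wgd_frequency_table",
]


class NoBimodalStructureError(ValueError):
    """The cohort fraction density shows fewer than two modes."""


@dataclass
class SegmentSet:
    """Allele-specific copy-number segments of one sample."""

    sample_id: str
    segments: pd.DataFrame  # columns: chrom, start, end, major_cn, minor_cn

    def __post_init__(self) -> None:
        seg = self.segments
        if len(seg):
            if (seg["start"] >= seg["end"]).any():
                raise ValidationError(f"{self.sample_id}: segment start must be < end")
            if (seg["major_cn"] < seg["minor_cn"]).any():
                raise ValidationError(f"{self.sample_id}: major_cn must be >= minor_cn")
            if (seg["minor_cn"] < 0).any():
                raise ValidationError(f"{self.sample_id}: copy numbers must be >= 0")


@dataclass
class WGDCall:
    sample_id: str
    wgd_fraction: float
    wgd_flag: bool
    cohort_cutpoint: float


def read_segments(path, sample_id: str) -> SegmentSet:
    """Read a copy-number segment TSV (chrom, start, end, major_cn, minor_cn;
    1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "major_cn", "minor_cn"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"segment table missing columns: {sorted(missing)}")
    return SegmentSet(sample_id=sample_id, segments=df)


def wgd_fraction(segments: SegmentSet) -> float:
    """Fraction of segments with major CN >= 2 (unweighted by length)."""
    seg = segments.segments
    if len(seg) == 0:
        raise ValidationError(f"{segments.sample_id}: no segments")
    return float((seg["major_cn"] >= 2).sum() / len(seg))


def wgd_cutpoint(
    fractions: np.ndarray,
    min_samples: int = 20,
    grid_points: int = 512,
    prominence_frac: float = 0.05,
    method: str = "kde",
    bins: int = 40,
) -> float:
    """Valley of the bimodal cohort density of WGD fractions.

    The density of per-sample fractions on [0, 1] is estimated (Gaussian
    KDE, Silverman bandwidth, 512-point grid by default; ``method='hist'``
    uses raw histogram bins instead). The two local maxima of highest
    prominence are located and the grid position of the minimum density
    strictly between them is returned.

    Raises :class:`NoBimodalStructureError` when fewer than two maxima
    clear the prominence floor — supply a manual cut-point in that case.
    """
    x = np.asarray(fractions, dtype=float)
    if len(x) < min_samples:
        raise ValidationError(
            f"cut-point estimation needs >= {min_samples} samples (got {len(x)})"
        )
    if method == "kde":
        grid = np.linspace(0.0, 1.0, grid_points)
        dens = kde_evaluate(x, grid, silverman_bandwidth(x))
    elif method == "hist":
        counts, edges = np.histogram(x, bins=bins, range=(0.0, 1.0), density=True)
        grid = 0.5 * (edges[:-1] + edges[1:])
        dens = counts.astype(float)
    else:
        raise ValueError("method must be 'kde' or 'hist'")
    peaks, props = find_peaks(dens, prominence=prominence_frac * dens.max())
    if len(peaks) < 2:
        raise NoBimodalStructureError(
            "no bimodal structure in WGD fractions; supply --cutpoint manually"
        )
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    lo, hi = sorted(top2)
    between = np.arange(lo + 1, hi)
    valley = between[np.argmin(dens[between])]
    return float(grid[valley])


def call_wgd(
    cohort: CohortTable,
    cutpoint: float | None = None,
    **cutpoint_kwargs,
) -> tuple[CohortTable, float]:
    """Flag every sample with ``wgd_fraction`` >= cut-point.

    The cohort must already carry a ``wgd_fraction`` column (see
    :func:`wgd_fraction`); with ``cutpoint=None`` the bimodal cut-point is
    estimated from the cohort itself. Returns the cohort with a
    ``wgd_flag`` column plus the cut-point used.
    """
    df = cohort.df.copy()
    if "wgd_fraction" not in df.columns:
        raise ValidationError("cohort lacks a wgd_fraction column")
    fractions = df["wgd_fraction"].dropna().to_numpy()
    if cutpoint is None:
        cutpoint = wgd_cutpoint(fractions, **cutpoint_kwargs)
    df["wgd_flag"] = (df["wgd_fraction"] >= cutpoint).astype("boolean")
    df.loc[df["wgd_fraction"].isna(), "wgd_flag"] = pd.NA
    return CohortTable(df), float(cutpoint)


def wgd_frequency_table(
    cohort: CohortTable,
    groups: list[SubgroupLabel | str],
    reference: SubgroupLabel | str = SubgroupLabel.CHEK2_star,
    tp53_wildtype_only: bool = True,
) -> pd.DataFrame:
    """WGD frequency per subgroup with 2x2 tests against the reference group.

    Subgroup rows are restricted to TP53 wild-type cases by default; two
    extra rows stratify the whole cohort by TP53 somatic status (those
    ignore the restriction by construction).
    """
    df = cohort.df
    if "wgd_flag" not in df.columns:
        raise ValidationError("run call_wgd first")
    reference = SubgroupLabel(reference)

    def _counts(sub: pd.DataFrame) -> tuple[int, int]:
        flags = sub["wgd_flag"].dropna()
        return int(flags.sum()), len(flags)

    rows = []
    for stratum in ("mutant", "wildtype"):
        k, n = _counts(df[df["tp53_somatic"] == stratum])
        rows.append({"group": f"TP53_{stratum}", "k_wgd": k, "n": n,
                     "freq": k / n if n else np.nan, "p_vs_reference": np.nan})
    ref_sub = group_members(cohort, reference)
    if tp53_wildtype_only:
        ref_sub = ref_sub[ref_sub["tp53_somatic"] == "wildtype"]
    k_ref, n_ref = _counts(ref_sub)
    for g in groups:
        g = SubgroupLabel(g)
        sub = group_members(cohort, g)
        if tp53_wildtype_only:
            sub = sub[sub["tp53_somatic"] == "wildtype"]
        k, n = _counts(sub)
        if g is reference or n == 0 or n_ref == 0:
            p = np.nan
        else:
            p = two_by_two_test(k_ref, n_ref, k, n).p_raw
        rows.append({"group": g.value, "k_wgd": k, "n": n,
                     "freq": k / n if n else np.nan, "p_vs_reference": p})
    return pd.DataFrame(rows)
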
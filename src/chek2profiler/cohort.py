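"""Cohort data model, sample-sheet I/O and subgroup assignment.

Breast-cancer genomes are analysed here as a cohort of annotated samples.
Each sample carries germline status (which susceptibility gene, which
variant, which alleles were retained in the tumor), ER status, an HRD/HRP
phenotype call, somatic TP53 status and the cohort it belongs to (primary
or metastatic disease). The subgroup rules implemented by
:func:`assign_subgroups` partition every retained sample into exactly one
of five comparison groups (BRCA1, BRCA2, HRD, ER-negative, ER-positive),
with CHEK2 c.1100delC carriers additionally flagged by two overlay labels:

* ``CHEK2`` — any retained carrier of the germline c.1100delC allele;
* ``CHEK2*`` — carriers with bi-allelic CHEK2 inactivation, i.e. the
  wild-type allele was somatically lost or the carrier is homozygous.

Carriers of other CHEK2 variants, and carriers whose tumor lost the
*mutant* allele, are excluded from analysis.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "CohortTable",
    "SubgroupLabel",
    "SchemaError",
    "ValidationError",
    "REQUIRED_COLUMNS",
    "CHEK2_FOUNDER_VARIANT",
    "load_cohort",
    "write_cohort",
    "assign_subgroups",
    "group_members",
]

CHEK2_FOUNDER_VARIANT = "c.1100delC"

#: Columns a sample sheet must provide (tab-separated, "NA" for unknown).
REQUIRED_COLUMNS = (
    "sample_id",
    "cohort",
    "germline_gene",
    "germline_variant",
    "wildtype_allele",
    "mutant_allele",
    "er_status",
    "hrd_call",
    "tp53_somatic",
)

#: Optional columns recognised by the loader.
OPTIONAL_COLUMNS = ("zygosity", "tumor_purity")

_ENUM_VALUES = {
    "cohort": {"pBC", "mBC"},
    "germline_gene": {"CHEK2", "BRCA1", "BRCA2", "none"},
    "wildtype_allele": {"retained", "lost", "unknown"},
    "mutant_allele": {"retained", "lost"},
    "er_status": {"pos", "neg", "unknown"},
    "hrd_call": {"HRD", "HRP", "unknown"},
    "tp53_somatic": {"mutant", "wildtype", "unknown"},
    "zygosity": {"het", "hom"},
}


class SchemaError(ValueError):
    """A sample sheet or table is missing required structure."""


class ValidationError(ValueError):
    """Values are structurally valid but violate a cohort invariant."""


class SubgroupLabel(str, enum.Enum):
    """Analysis subgroups; CHEK2/CHEK2* overlay the five-way partition."""

    CHEK2 = "CHEK2"
    CHEK2_star = "CHEK2_star"
    BRCA1 = "BRCA1"
    BRCA2 = "BRCA2"
    HRD = "HRD"
    ERneg = "ERneg"
    ERpos = "ERpos"
    HRDplus = "HRDplus"
    excluded = "excluded"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class SampleRecord:
    """One annotated tumor genome."""

    sample_id: str
    cohort: str
    germline_gene: str = "none"
    germline_variant: str = "NA"
    wildtype_allele: str = "unknown"
    mutant_allele: str = "retained"
    er_status: str = "unknown"
    hrd_call: str = "unknown"
    tp53_somatic: str = "unknown"
    zygosity: str = "het"
    tumor_purity: float | None = None

    def __post_init__(self) -> None:
        for key, allowed in _ENUM_VALUES.items():
            value = getattr(self, key)
            if value not in allowed:
                raise ValidationError(
                    f"sample {self.sample_id!r}: {key}={value!r} not in {sorted(allowed)}"
                )
        if self.tumor_purity is not None and not (0.0 <= self.tumor_purity <= 1.0):
            raise ValidationError(
                f"sample {self.sample_id!r}: tumor_purity must lie in [0, 1]"
            )


@dataclass
class CohortTable:
    """Ordered collection of samples plus derived per-sample columns.

    The backing :class:`pandas.DataFrame` is the canonical representation;
    downstream stages (burden, ploidy, SV profiling) attach derived columns
    such as ``tmb``, ``id_ratio``, ``wgd_fraction``, ``wgd_flag`` and
    ``chromothripsis_flag``.
    """

    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.df):
            dups = self.df["sample_id"][self.df["sample_id"].duplicated()]
            if len(dups):
                raise ValidationError(
                    f"duplicate sample_id values: {sorted(set(dups))}"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"]) if len(self.df) else []

    def records(self) -> list[SampleRecord]:
        known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
        out = []
        for _, row in self.df.iterrows():
            kwargs = {k: row[k] for k in known if k in row.index and pd.notna(row[k])}
            out.append(SampleRecord(**kwargs))
        return out


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col, fallback in (
        ("germline_variant", "NA"),
        ("wildtype_allele", "unknown"),
        ("mutant_allele", "retained"),
        ("er_status", "unknown"),
        ("hrd_call", "unknown"),
        ("tp53_somatic", "unknown"),
        ("zygosity", "het"),
    ):
        if col not in df.columns:
            df[col] = fallback
        else:
            df[col] = df[col].fillna(fallback)
    if "germline_gene" in df.columns:
        df["germline_gene"] = df["germline_gene"].fillna("none")
    return df


def load_cohort(path) -> CohortTable:
    """Read a tab-separated sample sheet into a :class:`CohortTable`.

    Unknown values are encoded as ``NA`` in the sheet; columns beyond the
    documented vocabulary are preserved untouched as opaque annotations.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If a sample_id is duplicated or an enum column holds a value
        outside its vocabulary.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample sheet is missing required column(s): {missing}")
    df = _normalise(df)
    for col, allowed in _ENUM_VALUES.items():
        if col not in df.columns:
            continue
        bad = set(df[col].dropna()) - allowed
        if bad:
            raise ValidationError(f"column {col!r} holds invalid value(s): {sorted(bad)}")
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort (including derived columns) as a TSV; NaN becomes NA."""
    cohort.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def _assign_one(row: pd.Series) -> tuple[str, bool, bool]:
    """Return (primary label, is_chek2, is_chek2_star) for one sample."""
    gene = row["germline_gene"]
    is_chek2 = False
    is_star = False
    if gene == "CHEK2":
        if row["germline_variant"] != CHEK2_FOUNDER_VARIANT:
            return SubgroupLabel.excluded.value, False, False
        if row["mutant_allele"] == "lost":
            return SubgroupLabel.excluded.value, False, False
        is_chek2 = True
        is_star = row["wildtype_allele"] == "lost" or row.get("zygosity", "het") == "hom"
    # Rules 1-2: BRCA1/2 carriers count only with loss of the wild-type allele.
    if gene == "BRCA1" and row["wildtype_allele"] == "lost":
        return SubgroupLabel.BRCA1.value, is_chek2, is_star
    if gene == "BRCA2" and row["wildtype_allele"] == "lost":
        return SubgroupLabel.BRCA2.value, is_chek2, is_star
    # Rule 3: HRD phenotype without a qualifying BRCA1/2 germline event.
    if row["hrd_call"] == "HRD":
        return SubgroupLabel.HRD.value, is_chek2, is_star
    # Rules 4-5: ER status.
    if row["er_status"] == "neg":
        return SubgroupLabel.ERneg.value, is_chek2, is_star
    if row["er_status"] == "pos":
        return SubgroupLabel.ERpos.value, is_chek2, is_star
    return SubgroupLabel.excluded.value, False, False


def assign_subgroups(cohort: CohortTable) -> CohortTable:
    """Attach subgroup labels to every sample.

    Adds three columns: ``subgroup`` (one of BRCA1/BRCA2/HRD/ERneg/ERpos/
    excluded — a partition of the cohort), and boolean overlays
    ``is_chek2`` / ``is_chek2_star``. Samples with unknown ER status that
    match no germline/HRD rule are excluded with a warning rather than an
    error so that partially annotated sheets still run.
    """
    df = _normalise(cohort.df)
    if len(df) == 0:
        df = df.assign(subgroup=pd.Series(dtype=str),
                       is_chek2=pd.Series(dtype=bool),
                       is_chek2_star=pd.Series(dtype=bool))
        return CohortTable(df)
    assigned = df.apply(_assign_one, axis=1, result_type="expand")
    df["subgroup"] = assigned[0]
    df["is_chek2"] = assigned[1].astype(bool)
    df["is_chek2_star"] = assigned[2].astype(bool)
    fell_through = df[
        (df["subgroup"] == SubgroupLabel.excluded.value)
        & (df["germline_gene"] != "CHEK2")
        & (df["er_status"] == "unknown")
    ]
    if len(fell_through):
        warnings.warn(
            "excluded sample(s) with unknown ER status and no germline/HRD label: "
            f"{list(fell_through['sample_id'])}",
            stacklevel=2,
        )
    return CohortTable(df)


def group_members(cohort: CohortTable, label: SubgroupLabel | str) -> pd.DataFrame:
    """Rows belonging to one analysis group.

    The five partition groups exclude CHEK2 carriers so that the comparison
    groups are disjoint from the CHEK2/CHEK2* overlays; ``HRDplus`` is the
    union of BRCA1, BRCA2 and HRD.
    """
    label = SubgroupLabel(label)
    df = cohort.df
    if "subgroup" not in df.columns:
        raise ValidationError("run assign_subgroups before selecting groups")
    if label is SubgroupLabel.CHEK2:
        return df[df["is_chek2"]]
    if label is SubgroupLabel.CHEK2_star:
        return df[df["is_chek2_star"]]
    if label is SubgroupLabel.HRDplus:
        keep = df["subgroup"].isin(["BRCA1", "BRCA2", "HRD"]) & ~df["is_chek2"]
        return df[keep]
    if label is SubgroupLabel.excluded:
        return df[df["subgroup"] == "excluded"]
    return df[(df["subgroup"] == label.value) & ~df["is_chek2"]]


def summary_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-sample overview of annotations plus whatever derived metrics exist."""
    cols = [c for c in cohort.df.columns]
    return cohort.df[cols].copy()
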
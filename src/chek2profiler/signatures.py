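"""Mutational-signature refitting, selection and subgroup clustering.

Observed per-sample channel counts (96 SBS trinucleotide channels, 78 DBS,
83 ID or SV channels) are decomposed against a reference signature catalog
by non-negative least squares:

    w* = argmin_{w >= 0} || m - S w ||_2

where ``m`` is the sample profile and ``S`` the channels x signatures
catalog with unit column sums. Contributions are reported both in count
units and as percentage relative contribution (%rc, normalised to sum to
100 per sample). Signatures with >= ``min_rc`` %rc in >= ``min_samples``
genomes of a reference group are the "profound" set used for subgroup
median profiles, which are then compared by cosine similarity and
average-linkage hierarchical clustering.

Refitting is plain NNLS across the full catalog by default; an optional
pruning pass (drop signatures below a floor, refit) is available but off
by default, since relative contributions are reported as a continuum
across all catalog signatures.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import nnls

from .cohort import CohortTable, SchemaError, SubgroupLabel, ValidationError, group_members

__all__ = [
    "SignatureCatalog",
    "load_catalog",
    "toy_catalog",
    "refit_signatures",
    "refit_profiles",
    "select_profound",
    "subgroup_median_profile",
    "cosine_similarity",
    "cluster_subgroups",
    "SubgroupClustering",
]


@dataclass
class SignatureCatalog:
    """Reference signature matrix: channels x signatures, columns sum to 1."""

    sig_class: str
    matrix: pd.DataFrame  # index: channel names; columns: signature names

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(dtype=float)
        if (m < 0).any():
            raise ValidationError("catalog entries must be non-negative")
        sums = m.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValidationError("catalog columns must sum to 1 (±1e-6)")

    @property
    def channels(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def signatures(self) -> list[str]:
        return list(self.matrix.columns)


def load_catalog(path, sig_class: str = "SBS") -> SignatureCatalog:
    """Load a catalog TSV (channel rows, one header row of signature names)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureCatalog(sig_class=sig_class, matrix=df)


def toy_catalog() -> SignatureCatalog:
    """The bundled synthetic 6-signature x 96-channel catalog used for testing."""
    ref = importlib.resources.files("chek2profiler") / "data" / "toy_signatures.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_catalog(path, sig_class="SBS")


def refit_signatures(
    profile: np.ndarray | pd.Series,
    catalog: SignatureCatalog,
    prune_below: float | None = None,
) -> tuple[pd.Series, pd.Series]:
    """NNLS refit of one profile; returns (absolute contributions, %rc).

    ``profile`` is a channel-count vector aligned with the catalog's
    channel set (a Series is checked by name; a bare array by length).
    With ``prune_below`` set (a %rc floor), signatures below the floor are
    dropped and the remainder refit once.
    """
    S = catalog.matrix.to_numpy(dtype=float)
    if isinstance(profile, pd.Series):
        if list(profile.index) != catalog.channels:
            raise SchemaError("profile channels do not match the catalog")
        m = profile.to_numpy(dtype=float)
    else:
        m = np.asarray(profile, dtype=float)
        if m.shape != (S.shape[0],):
            raise SchemaError(
                f"profile has {m.shape[0] if m.ndim == 1 else m.shape} channels, "
                f"catalog has {S.shape[0]}"
            )
    if (m < 0).any():
        raise ValidationError("channel counts must be non-negative")
    if m.sum() == 0:
        raise ValidationError("empty profile")
    w, _ = nnls(S, m)
    if prune_below is not None and w.sum() > 0:
        rc = 100.0 * w / w.sum()
        keep = rc >= prune_below
        if keep.any() and not keep.all():
            w_kept, _ = nnls(S[:, keep], m)
            w = np.zeros_like(w)
            w[keep] = w_kept
    abs_contrib = pd.Series(w, index=catalog.signatures, name="contribution")
    total = w.sum()
    rc = pd.Series(
        100.0 * w / total if total > 0 else np.zeros_like(w),
        index=catalog.signatures,
        name="rc",
    )
    return abs_contrib, rc


def refit_profiles(
    profiles: pd.DataFrame, catalog: SignatureCatalog, prune_below: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Refit a channels x samples matrix; returns (absolute, %rc) as
    samples x signatures frames."""
    if list(profiles.index) != catalog.channels:
        raise SchemaError("profile channels do not match the catalog")
    abs_rows, rc_rows = {}, {}
    for sample in profiles.columns:
        a, r = refit_signatures(profiles[sample], catalog, prune_below=prune_below)
        abs_rows[sample], rc_rows[sample] = a, r
    return pd.DataFrame(abs_rows).T, pd.DataFrame(rc_rows).T


def select_profound(
    rc: pd.DataFrame,
    reference_ids: list[str],
    min_rc: float = 5.0,
    min_samples: int = 2,
) -> list[str]:
    """Signatures with >= min_rc %rc in >= min_samples reference genomes.

    ``rc`` is a samples x signatures %rc frame; selection is evaluated on
    the reference-group rows only.
    """
    ref = [s for s in reference_ids if s in rc.index]
    if len(ref) == 0:
        raise ValidationError("reference group has no refit profiles")
    if min_rc <= 0:
        hits = (rc.loc[ref] > 0).sum(axis=0)
    else:
        hits = (rc.loc[ref] >= min_rc).sum(axis=0)
    return list(hits.index[hits >= min_samples])


def subgroup_median_profile(
    rc: pd.DataFrame,
    cohort: CohortTable,
    groups: list[SubgroupLabel | str],
    signatures: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group median %rc matrix (groups x signatures).

    Empty groups are dropped with a warning. The optional ``signatures``
    list restricts columns to a previously selected profound set.
    """
    cols = signatures if signatures is not None else list(rc.columns)
    rows = {}
    for g in groups:
        g = SubgroupLabel(g)
        ids = [s for s in group_members(cohort, g)["sample_id"] if s in rc.index]
        if len(ids) == 0:
            warnings.warn(f"group {g.value} has no profiles; dropped", stacklevel=2)
            continue
        rows[g.value] = rc.loc[ids, cols].median(axis=0)
    return pd.DataFrame(rows).T


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two non-negative vectors, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


@dataclass
class SubgroupClustering:
    similarity: pd.DataFrame   # groups x groups cosine similarities
    linkage: np.ndarray        # scipy linkage matrix (average, 1 - cosine)
    leaf_order: list[str]


def cluster_subgroups(median_matrix: pd.DataFrame) -> SubgroupClustering:
    """Average-linkage clustering of subgroup median profiles on 1 - cosine.

    Rows are sorted lexicographically before linkage so that tie-breaks in
    leaf ordering are deterministic.
    """
    if len(median_matrix) < 2:
        raise ValidationError("clustering needs at least two groups")
    mat = median_matrix.sort_index()
    names = list(mat.index)
    n = len(names)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = cosine_similarity(
                mat.iloc[i].to_numpy(), mat.iloc[j].to_numpy()
            )
    dist = 1.0 - sim
    condensed = dist[np.triu_indices(n, k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    order = [names[i] for i in hierarchy.leaves_list(Z)]
    return SubgroupClustering(
        similarity=pd.DataFrame(sim, index=names, columns=names),
        linkage=Z,
        leaf_order=order,
    )
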
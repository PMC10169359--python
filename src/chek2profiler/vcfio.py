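"""Optional VCF ingestion: somatic small-variant counting.

Counts SNVs, MNVs, insertions and deletions from a VCF (v4.x) by REF/ALT
length: equal length 1 is an SNV, equal length > 1 an MNV, longer ALT an
insertion, shorter ALT a deletion. Multi-allelic records are counted once,
classified by their first ALT allele.
"""

from __future__ import annotations

import pysam

from .burden import VariantCatalog

__all__ = ["count_variants_from_vcf"]


def count_variants_from_vcf(path, sample_id: str) -> VariantCatalog:
    """Tally SNV/MNV/insertion/deletion counts for one sample's VCF."""
    counts = {"snv": 0, "mnv": 0, "ins": 0, "del": 0}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if alt in (".", "<NON_REF>") or alt.startswith("<"):
                continue
            if len(ref) == len(alt):
                counts["snv" if len(ref) == 1 else "mnv"] += 1
            elif len(alt) > len(ref):
                counts["ins"] += 1
            else:
                counts["del"] += 1
    return VariantCatalog(
        sample_id=sample_id,
        n_snv=counts["snv"], n_mnv=counts["mnv"],
        n_ins=counts["ins"], n_del=counts["del"],
    )
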
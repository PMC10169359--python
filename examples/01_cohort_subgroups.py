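"""Assign analysis subgroups to a small hand-written cohort.

Builds a sample sheet of germline CHEK2 c.1100delC carriers and controls,
applies the subgroup rules and prints the partition. The two carriers who
lost the *mutant* allele are excluded; carriers losing the wild-type
allele (or homozygous) form the bi-allelic CHEK2* overlay.
"""

import pandas as pd

from chek2profiler import CohortTable, SubgroupLabel, assign_subgroups, group_members

rows = []
for i in range(6):
    rows.append({
        "sample_id": f"carrier{i}", "cohort": "pBC", "germline_gene": "CHEK2",
        "germline_variant": "c.1100delC",
        "wildtype_allele": "lost" if i < 3 else "retained",
        "mutant_allele": "lost" if i == 5 else "retained",
        "er_status": "pos", "hrd_call": "HRP", "tp53_somatic": "wildtype",
        "zygosity": "hom" if i == 4 else "het",
    })
rows += [
    {"sample_id": "brca1", "cohort": "pBC", "germline_gene": "BRCA1",
     "germline_variant": "pathogenic", "wildtype_allele": "lost",
     "mutant_allele": "retained", "er_status": "neg", "hrd_call": "HRD",
     "tp53_somatic": "mutant", "zygosity": "het"},
    {"sample_id": "sporadic", "cohort": "pBC", "germline_gene": "none",
     "germline_variant": "NA", "wildtype_allele": "unknown",
     "mutant_allele": "retained", "er_status": "pos", "hrd_call": "HRP",
     "tp53_somatic": "wildtype", "zygosity": "het"},
]

cohort = assign_subgroups(CohortTable(pd.DataFrame(rows)))
print(cohort.df[["sample_id", "subgroup", "is_chek2", "is_chek2_star"]].to_string(index=False))
print()
print(f"CHEK2 carriers retained : {int(cohort.df['is_chek2'].sum())}")
print(f"CHEK2* (bi-allelic)     : {int(cohort.df['is_chek2_star'].sum())}")
print(f"excluded                : {len(group_members(cohort, SubgroupLabel.excluded))}")
# The CHEK2* count includes the homozygous carrier; the carrier who lost
# the mutant allele is excluded from all analyses.
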
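"""Refit mutational profiles and cluster subgroup median signatures.

Each sample's channel-count profile is decomposed against the bundled
6-signature catalog by non-negative least squares; signatures with >= 5 %rc
in >= 2 CHEK2* genomes are kept, subgroup medians are formed and clustered
by cosine similarity (average linkage on 1 - cosine).
"""

from chek2profiler import SubgroupLabel, generate_cohort, group_members
from chek2profiler.signatures import (
    cluster_subgroups,
    refit_profiles,
    select_profound,
    subgroup_median_profile,
)

sim = generate_cohort(seed=17)
_, rc = refit_profiles(sim.profiles, sim.catalog)

star_ids = list(group_members(sim.cohort, SubgroupLabel.CHEK2_star)["sample_id"])
profound = select_profound(rc, star_ids, min_rc=5, min_samples=2)
print(f"profound signatures (>=5 %rc in >=2 CHEK2* genomes): {profound}")

median = subgroup_median_profile(
    rc, sim.cohort,
    [SubgroupLabel.CHEK2_star, SubgroupLabel.ERpos, SubgroupLabel.ERneg,
     SubgroupLabel.BRCA1, SubgroupLabel.HRD],
    signatures=profound,
)
res = cluster_subgroups(median)
print("\npairwise cosine similarity of subgroup median profiles:")
print(res.similarity.round(3).to_string())
print(f"\ndendrogram leaf order: {res.leaf_order}")
# CHEK2* sits next to ER+ with cosine ~1 and far from the BRCA/HRD groups,
# i.e. its mutational-process mixture looks ER+-like, not HRD-like.
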
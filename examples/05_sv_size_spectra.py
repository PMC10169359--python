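"""Compare structural-variant size spectra with bootstrap Fréchet distances.

Pools deletion sizes per subgroup, renders log10-Mb density curves with a
shared Silverman bandwidth, detects the characteristic peaks of the
CHEK2 spectrum, bootstraps each subgroup's curve 100 times against the
all-sample baseline and compares the distance distributions with Welch's
t-test. A subsampling control checks that the multi-peak pattern cannot
be produced by chance from the unimodal ER+ pool.
"""

import numpy as np

from chek2profiler import SubgroupLabel, generate_cohort, group_members
from chek2profiler.density import silverman_bandwidth
from chek2profiler.svprofile import (
    collect_sizes,
    compare_profiles,
    find_density_peaks,
    size_density,
    subsample_control,
)

sim = generate_cohort(seed=17)
chek2 = list(group_members(sim.cohort, SubgroupLabel.CHEK2)["sample_id"])
erpos = list(group_members(sim.cohort, SubgroupLabel.ERpos)["sample_id"])

pooled = collect_sizes(sim.svs, "DEL")
bandwidth = silverman_bandwidth(np.log10(pooled / 1e6))
baseline = size_density(pooled, bandwidth=bandwidth)
print(f"baseline: {baseline.n_obs} deletions, shared bandwidth {bandwidth:.3f} log10 units")

chek2_sizes = collect_sizes(sim.svs, "DEL", chek2)
curve = size_density(chek2_sizes, bandwidth=bandwidth)
peaks = find_density_peaks(curve, svtype="DEL", group="CHEK2")
print(f"CHEK2 deletion peaks (Mb): {peaks.locations_mb}")

cmp = compare_profiles(
    chek2_sizes, collect_sizes(sim.svs, "DEL", erpos), baseline,
    n_boot=100, seed=17, group_a="CHEK2", group_b="ERpos", svtype="DEL")
print(f"mean Fréchet distance to baseline: CHEK2 {cmp.mean_a:.3f} "
      f"vs ER+ {cmp.mean_b:.3f} (Welch P = {cmp.p_value:.3g})")

windows = [(0.55, 0.75), (1.35, 1.55)]  # the two large-deletion peaks
control = subsample_control(
    collect_sizes(sim.svs, "DEL", erpos), n_target=len(chek2_sizes),
    reps=100, seed=17, query_windows=windows)
print(f"ER+ subsamples reproducing the two-peak pattern: "
      f"{100 * control['all_windows'].mean():.0f}% of 100 replicates")
# The CHEK2 spectrum sits farther from the baseline than ER+ and its
# multi-peak pattern almost never arises from subsampled ER+ deletions:
# the pattern is a property of the group, not of its smaller sample size.
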
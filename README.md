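# chek2profiler

Somatic-genome profiling of breast cancers from *CHEK2* c.1100delC
germline mutation carriers — a tested, reusable implementation of the
cohort analyses used to characterise this moderate-risk tumor class:

- **Cohort model & subgroups** — sample-sheet validation and the ordered
  subgroup rules (BRCA1/BRCA2 carriers with wild-type-allele loss, HRD
  phenotype, ER− / ER+), with CHEK2 and CHEK2\* (bi-allelic inactivation)
  as overlay labels and principled exclusions (non-founder variants,
  mutant-allele loss).
- **Burden metrics** — tumor mutational burden, TMB = (SNV + MNV + indel
  events) / mappable Mb with the mappable genome fixed at 2,858,674,661
  bases, and the insertion/deletion ratio; Kruskal–Wallis +
  Mann–Whitney group comparisons with BH or Hochberg adjustment.
- **Mutational signatures** — non-negative least-squares refitting
  `w* = argmin_{w≥0} ||m − S w||₂` against a reference catalog, %rc
  normalisation, profound-signature selection (≥ 5 %rc in ≥ 2 reference
  genomes) and cosine-similarity clustering of subgroup median profiles.
- **Whole-genome duplication** — per-sample fraction of copy-number
  segments with major CN ≥ 2, cohort-level bimodal cut-point at the
  density valley, and TP53-stratified frequency tables.
- **SV size spectra** — the package's core: log10-Mb Gaussian KDE curves
  of deletion/tandem-duplication/inversion sizes on a shared 0.05-log10
  grid, characteristic-peak detection, discrete Fréchet distances
  (Eiter–Mannila dynamic program) of 100 bootstrap curves to the
  all-sample baseline, Welch comparison between subgroups, a subsampling
  control for the multi-peak pattern, and a peak × chromothripsis-region
  Fisher overlap test.
- **Synthetic cohorts** — a generator that emits complete studies
  (sample sheet, variant counts, signature profiles, CN segments, SVs,
  chromothripsis regions) with known ground truth, so every stage is
  testable without any external data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
from chek2profiler import SubgroupLabel, generate_cohort, group_members
from chek2profiler.density import silverman_bandwidth
from chek2profiler.svprofile import (collect_sizes, compare_profiles,
                                     find_density_peaks, size_density)
import numpy as np

sim = generate_cohort(seed=17)
chek2 = list(group_members(sim.cohort, SubgroupLabel.CHEK2)["sample_id"])
erpos = list(group_members(sim.cohort, SubgroupLabel.ERpos)["sample_id"])

pooled = collect_sizes(sim.svs, "DEL")
baseline = size_density(pooled, bandwidth=silverman_bandwidth(np.log10(pooled / 1e6)))
sizes = collect_sizes(sim.svs, "DEL", chek2)
print(find_density_peaks(size_density(sizes, bandwidth=baseline.bandwidth)).locations_mb)
cmp = compare_profiles(sizes, collect_sizes(sim.svs, "DEL", erpos), baseline,
                       n_boot=100, seed=17, group_a="CHEK2", group_b="ERpos")
print(cmp.mean_a, cmp.mean_b, cmp.p_value)
```

prints

```
[0.0794, 4.5, 28.2]
0.38390588024014155 0.2883009571585091 9.28139876736173e-51
```

The CHEK2 deletion spectrum shows its two characteristic large-size peaks
(4.5 and 28.2 Mb, plus the small-event mode at ~80 kb), and its bootstrap
Fréchet distance to the all-sample baseline is significantly larger than
the ER+ group's — the CHEK2 size spectrum deviates more from the cohort
average than the ER+ spectrum does, despite the two groups being similar
in burden and signatures. The `examples/` directory walks through each
capability (subgrouping, burden, signatures, WGD, SV spectra) with short
narrative scripts; `profiler --help` exposes the same steps as a CLI
(`simulate`, `load`, `burden`, `signatures`, `wgd`, `svshape`, `assoc`).

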
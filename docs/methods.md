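# Methods

This note documents the statistical procedures implemented in
`chek2profiler`, the choices made where the design was genuinely open, and
what the synthetic study conditions do and do not establish about real
data.

## Cohort model and subgroups

The unit of analysis is an annotated tumor genome: cohort (primary or
metastatic breast cancer), germline susceptibility-gene status with
per-allele retention, ER status, an HRD/HRP phenotype call, and somatic
TP53 status. Subgroup assignment applies five ordered rules — (1) germline
BRCA1 and (2) BRCA2 carriers with loss of the wild-type allele, (3)
remaining samples with an HRD phenotype, then (4) ER− and (5) ER+ samples —
so that {BRCA1, BRCA2, HRD, ER−, ER+, excluded} partitions every cohort.
CHEK2 c.1100delC carriers are flagged by two overlay labels: CHEK2 (any
retained carrier) and CHEK2\* (bi-allelic inactivation: somatic loss of the
wild-type allele or a homozygous germline carrier). Carriers of other
CHEK2 variants and carriers whose tumor lost the *mutant* allele are
excluded. When a comparison group is selected, the five partition groups
exclude CHEK2 carriers, keeping the comparison groups disjoint from the
overlays. Samples with unknown ER status and no other qualifying label are
excluded with a warning rather than an error so partially annotated sheets
still run.

Because bi-allelic inactivation must distinguish somatic wild-type-allele
loss from germline homozygosity, the sample sheet accepts an optional
`zygosity` column (`het`/`hom`, default `het`); a homozygous carrier counts
as bi-allelic.

## Burden metrics

TMB is (SNV + MNV + insertion + deletion counts) per million mappable
bases; the mappable-genome constant is 2,858,674,661 bases and is
configurable only by explicit override. MNVs count as one event each. The
ID ratio is insertions over deletions; genomes without deletions carry an
undefined ratio and are dropped from group summaries. Group comparisons
are nonparametric: Kruskal–Wallis across all requested groups and pairwise
Mann–Whitney against a reference group (CHEK2\* by default). The
Mann–Whitney null is exact when the smaller group has ≤ 8 observations and
a tie-corrected normal approximation otherwise. Post-hoc adjustment is
Benjamini–Hochberg for burden comparisons; the Hochberg step-up procedure
(implemented from its recursion and cross-checked against statsmodels) is
used for categorical frequency scans.

## Signature refitting

Per-sample channel counts are decomposed against a reference catalog
(channels × signatures, unit column sums) by non-negative least squares,
`w* = argmin_{w≥0} ||m − S w||₂`, via `scipy.optimize.nnls`. Contributions
are reported in count units and as %rc (normalised to 100 per sample).
Plain NNLS over the full catalog is the default because relative
contributions are reported as a continuum; an optional prune-and-refit
pass (drop signatures below a %rc floor, refit once) exists but is off by
default. "Profound" signatures are those with ≥ 5 %rc in ≥ 2 genomes of
the reference group. Subgroup median %rc matrices are compared by cosine
similarity and clustered with average linkage on 1 − cosine; rows are
sorted lexicographically before linkage so leaf-order tie-breaks are
deterministic. A synthetic, near-orthogonal 6 × 96 catalog ships with the
package for testing; real analyses should load a published catalog from
TSV (channels as rows, one signature per column).

## Whole-genome duplication

Per sample, the WGD fraction is the share of allele-specific copy-number
segments with major CN ≥ 2, counted **unweighted by segment length** —
this is deliberate and means the statistic is not invariant to splitting
segments; a length-weighted variant is available and clearly flagged as a
deviation. Across a cohort the fraction is bimodal; the cut-point is the
density minimum strictly between the two highest-prominence modes of a
Gaussian KDE (Silverman bandwidth, 512-point grid on [0, 1], prominence
floor 5% of the maximum). A raw-histogram variant is offered, but the KDE
valley is reproducible and bin-width-free; when the density is unimodal
the caller refuses and asks for a manual cut-point. Subgroup WGD
frequencies are tabulated on TP53 wild-type cases only, since somatic TP53
mutation is itself strongly associated with WGD. Autosomes and X are all
eligible; no chromosome filter is applied.

## SV size spectra and the bootstrap Fréchet comparison

Deletion, tandem-duplication and inversion sizes (translocations have no
size) are pooled per subgroup, floored at 1 kb (caller noise floor,
configurable), log10-transformed to Mb and rendered as Gaussian KDEs on a
shared grid from −3.5 to 3.0 in steps of 0.05 log10 units. The 0.05-step
grid doubles as the peak-reporting resolution: every characteristic peak
size is a grid point (10^(0.05k) Mb), and reported peak locations are
rounded to one decimal in Mb above 1 Mb. One bandwidth per SV type — the
Silverman rule (bw.nrd0) on the pooled baseline sizes — is reused for the
baseline, every subgroup and every bootstrap curve, so distances reflect
shape rather than smoothing differences.

Curves are compared with the discrete Fréchet distance (Eiter–Mannila
dynamic program, Euclidean point distance, max over the optimal monotone
coupling), computed over points (grid position rescaled to [0, 1],
density). The axis convention is configurable (`fd_axes="raw"` keeps raw
grid coordinates); absolute distances depend on it, but orderings and
tests in our experiments do not. The comparison protocol: bootstrap a
subgroup's size vector (resampling individual SV events, with replacement,
at the original subgroup size) 100 times, record each replicate curve's
distance to the all-sample baseline, and compare two subgroups' distance
vectors with Welch's t-test. Replicate RNG streams are derived from a
master seed plus the group and SV-type names, and sizes are sorted before
resampling, so results are order-invariant and fully reproducible.

A caveat inherited from the procedure itself: the bootstrap distance
distributions of two *independent* samples from the same population
concentrate around each sample's own distance to baseline, so the t-test
detects finite-sample differences by construction. The correct null for
calibration is therefore the same size vector under two independent
bootstrap streams, which is how the level of the test is verified here
(measured 5/100 rejections at α = 0.05).

The subsampling control asks whether a multi-peak pattern can arise by
chance from a larger unimodal pool: repeated subsamples at the smaller
group's size are rendered with the same grid/bandwidth policy and scored
for peaks inside the query windows (peak ± 0.1 log10 units). A replicate
"reproduces the pattern" only if **all** windows contain a peak
simultaneously — single-window bumps are common KDE sampling noise
(measured ~5–18% per window) while the joint pattern is rare (measured
2–4%).

The chromothripsis overlap test classifies each SV as in-peak/out-peak
(log10 size inside a peak window) × inside/outside a chromothriptic region
of its own sample (either breakpoint inside any region; BED half-open
convention) and applies Fisher's exact test; with no regions, or no
breakpoint inside any region, the result is vacuous (P = 1, warning).

## Categorical comparisons

Two-proportion comparisons use Pearson's χ² without continuity correction
when all expected cells are ≥ 5 and the two-sided Fisher exact test
otherwise. Frequency scans adjust with Hochberg within each feature across
its group comparisons by default (a pooled scope is available). The
mutual-exclusivity report gives the 2×2 co-occurrence table over samples
with both features observed, a Fisher P, and an exclusivity flag when the
both-positive cell is empty.

## Synthetic study conditions

The generator emits complete cohorts under the default conditions listed
in `GeneratorConfig`: subgroup sizes follow the primary-cohort structure
(21 CHEK2 carriers, 14 bi-allelic including one homozygote; 574 genomes
total, the comparison groups sized realistically where exact counts are
not fixed by the study structure); per-group TMB log-normal around the
observed group medians (σ = 0.5); insertion/deletion splits hitting each
group's target ratio in expectation; signature mixtures drawn from
per-group Dirichlet weights over the toy catalog with Poisson channel
noise (CHEK2 ≈ ER+, distinct from the BRCA/HRD-type weights); WGD
prevalence 63.3%/19.3% by TP53 stratum with fractions from Beta(18,2) vs
Beta(2,18); somatic TP53 rates per group with CHEK2\* forced to zero while
the exclusivity switch is on; chromothripsis prevalence 33.3% for CHEK2;
and SV size mixtures with sharply localized (σ = 0.08 log10) large-size
components at the characteristic sizes — deletions 4.5 and 28.2 Mb,
inversions 5.6 and 28.2 Mb, tandem duplications 8.9 and 22.4 Mb — against
unimodal ER+-like spectra. The sharp component width is what makes the
0.4-log10 TD peak separation resolvable under the shared baseline
bandwidth, mirroring how distinctly the real peaks present.

What the synthetic conditions do **not** emulate: realistic genomic
coordinates or breakpoint mechanics, copy-number segmentation error,
purity/ploidy distortion, caller-specific biases, or the correlation
structure between burden, signatures and SVs within a genome (each layer
is drawn independently given the group). Passing the synthetic-recovery
tests therefore demonstrates that the estimators recover the structure
they target at realistic sample sizes and noise levels — not that any
particular biological claim holds in real cohorts. Cohort-level statistics
from the original study can be recomputed exactly via
`chek2profiler.reproduce` once its per-sample supplementary tables are
supplied (see `data/paper_tables/README.md`); those tables are not
redistributable here.

## Numerical choices and degenerate inputs

- KDE: hand-evaluated Gaussian kernel on the fixed grid (the textbook
  formula), `bw.nrd0` as the "auto" bandwidth with a small positive floor
  for degenerate (zero-IQR) data; verified against `scipy.stats.gaussian_kde`.
- Trapezoidal curve integrals are required to be 1 ± 10⁻³ on the default
  grid; the grid extends half a log10 unit beyond the 1 kb floor so tail
  mass is not clipped.
- Zero-variance bootstrap distance vectors degrade the Welch test to an
  exact-equality check (P = 1 if equal).
- NNLS on an all-zero profile, cosine on a zero vector, ID ratio without
  deletions, Fréchet on mismatched grids, and subsampling beyond the pool
  size are all refused with explicit errors.
- All simulation, bootstrap and subsampling streams derive from explicit
  integer seeds; no global RNG state is used.

## Problem sizes used by the test suite and acceptance script

The bundled checks run the default 574-genome synthetic study (≈ 29,000
SVs), 100 bootstrap replicates per Fréchet comparison, 20 seeded studies
for the power check, 100 replicates for each calibration check, and 1,000
random curve pairs for the dynamic-program-vs-enumeration oracle. These
sizes match the study conditions while keeping the whole suite in the
low minutes on one CPU.
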
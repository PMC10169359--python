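# Per-sample tables for cohort-level reproduction

The functions in `chek2profiler.reproduce` (and the corresponding
acceptance checks) recompute published cohort statistics from two
per-sample tables that are **not redistributed** with this repository.
Export them from the original study's supplementary material as
tab-separated text into this directory:

## `overview.tsv` — one row per genome

Required columns (unknowns encoded as `NA`):

- the standard sample-sheet vocabulary: `sample_id`, `cohort` (pBC/mBC),
  `germline_gene` (CHEK2/BRCA1/BRCA2/none), `germline_variant`,
  `wildtype_allele` (retained/lost/unknown), `mutant_allele`
  (retained/lost), `zygosity` (het/hom, optional), `er_status`
  (pos/neg/unknown), `hrd_call` (HRD/HRP/unknown), `tp53_somatic`
  (mutant/wildtype/unknown)
- somatic small-variant counts: `n_snv`, `n_mnv`, `n_ins`, `n_del`
- genome-state flags where available: `wgd_flag` (0/1),
  `chromothripsis_flag` (0/1)

## `sv_sizes.tsv` — one row per structural variant

Columns: `sample_id`, `svtype` (DEL/TD/INV/TRA), `size_bp`
(translocations may carry `NA`).
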
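"""Recompute published cohort statistics from user-supplied per-sample tables.

The original study's per-sample supplementary tables are not redistributed
here. Export them as TSV to data/paper_tables/ (see that directory's
README for the expected columns) and this script recomputes the group
burden medians, WGD and chromothripsis frequencies, the TP53 x CHEK2*
exclusivity count and the bootstrap Fréchet comparison of deletion size
spectra.
"""

from pathlib import Path

from chek2profiler import reproduce
from chek2profiler.svprofile import read_sv_table

table_dir = Path("data/paper_tables")
overview_path = table_dir / "overview.tsv"
sv_path = table_dir / "sv_sizes.tsv"

if not overview_path.exists() or not sv_path.exists():
    raise SystemExit(
        f"place overview.tsv and sv_sizes.tsv under {table_dir}/ to run this "
        "example (per-sample tables are not redistributed with the package)"
    )

cohort = reproduce.load_overview(overview_path)
svs = read_sv_table(sv_path)

print("primary-cohort TMB medians (variants/Mb):")
print(reproduce.burden_medians(cohort, "tmb", which="pBC").round(2).to_string())
print(f"\nmBC/pBC median TMB fold: {reproduce.tmb_cohort_fold(cohort):.1f}")
print("\nWGD frequencies:")
print(reproduce.wgd_frequencies(cohort, which='pBC').round(3).to_string(index=False))
excl = reproduce.tp53_chek2star_exclusivity(cohort, which="pBC")
print(f"\nCHEK2* genomes with somatic TP53 mutation: "
      f"{excl['n_both']} of {excl['n_both'] + excl['n_a_only']}")
cmp = reproduce.sv_fd_comparison(cohort, svs, "DEL", which="pBC")
print(f"\ndeletions, mean Fréchet distance to baseline: "
      f"CHEK2 {cmp.mean_a:.2f} vs ER+ {cmp.mean_b:.2f} (P = {cmp.p_value:.3g})")
print("\nCHEK2 inversion peaks (Mb) across the bandwidth sweep:")
for mult, peaks in reproduce.characteristic_peaks(cohort, svs, "INV").items():
    print(f"  Silverman x {mult}: {peaks}")
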
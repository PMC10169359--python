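"""Synthetic breast-cancer cohort generator with known ground truth.

Every analysis stage in this package can be exercised without any external
data: the generator emits a complete cohort — sample sheet, per-sample
somatic variant counts, mutational profiles over the bundled toy signature
catalog, allele-specific copy-number segments, structural variants and
chromothripsis regions — together with the generative truth, so that label
recovery, peak recovery and test calibration can be measured.

The default configuration pins the study conditions the analyses assume:

* subgroup sizes follow the primary-cohort structure (21 CHEK2 c.1100delC
  carriers of which 14 with bi-allelic inactivation, one of them a
  homozygous carrier; five comparison groups totalling 574 genomes);
* per-group TMB is log-normal around the observed group medians
  (CHEK2 1.37, BRCA1 3.20, BRCA2 2.55, HRD 3.40, ER− 1.71, ER+ 0.92
  variants/Mb);
* WGD prevalence is 63.3% in TP53-mutant and 19.3% in TP53-wild-type
  genomes, with the WGD fraction drawn from Beta(18,2) (duplicated) or
  Beta(2,18) (diploid-like);
* CHEK2-like SV size spectra are multi-peaked with log-normal components
  at the characteristic sizes (deletions 4.5 and 28.2 Mb, inversions 5.6
  and 28.2 Mb, tandem duplications 8.9 and 22.4 Mb) while ER+-like
  spectra are unimodal; HRD-type groups are dominated by small events;
* somatic TP53 mutations are mutually exclusive with bi-allelic CHEK2
  inactivation (the exclusivity switch can be turned off).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortTable, ValidationError, assign_subgroups
from .signatures import SignatureCatalog, toy_catalog

__all__ = ["GeneratorConfig", "SimulatedCohort", "SyntheticTruth", "generate_cohort",
           "truth_check", "write_simulation"]

_GROUPS = ("CHEK2", "BRCA1", "BRCA2", "HRD", "ERneg", "ERpos")

# Characteristic large-size components are sharply localized (sd 0.08 log10
# units) so the multi-peak structure survives the shared baseline smoothing.
_CHEK2_MULTIPEAK = {
    "DEL": [(0.30, -1.00, 0.45), (0.35, 0.65, 0.08), (0.35, 1.45, 0.08)],
    "INV": [(0.30, -1.00, 0.45), (0.35, 0.75, 0.08), (0.35, 1.45, 0.08)],
    "TD": [(0.30, -1.00, 0.45), (0.35, 0.95, 0.08), (0.35, 1.35, 0.08)],
}
_ERPOS_UNIMODAL = {
    "DEL": [(1.0, 0.95, 0.45)],
    "INV": [(1.0, 0.60, 0.45)],
    "TD": [(1.0, 0.80, 0.45)],
}
_SMALL_EVENTS = {
    "DEL": [(1.0, -1.50, 0.40)],
    "INV": [(1.0, -1.20, 0.40)],
    "TD": [(1.0, -1.96, 0.30)],
}
_INTERMEDIATE = {
    "DEL": [(1.0, -0.60, 0.45)],
    "INV": [(1.0, -0.20, 0.45)],
    "TD": [(1.0, -0.70, 0.40)],
}


def _default_sv_mixture() -> dict:
    return {
        "CHEK2": {k: list(v) for k, v in _CHEK2_MULTIPEAK.items()},
        "ERpos": {k: list(v) for k, v in _ERPOS_UNIMODAL.items()},
        "ERneg": {k: list(v) for k, v in _INTERMEDIATE.items()},
        "BRCA1": {k: list(v) for k, v in _SMALL_EVENTS.items()},
        "BRCA2": {k: list(v) for k, v in _INTERMEDIATE.items()},
        "HRD": {k: list(v) for k, v in _SMALL_EVENTS.items()},
    }


@dataclass
class GeneratorConfig:
    """Tunable study conditions; defaults encode the conditions above."""

    n_per_group: dict = field(default_factory=lambda: {
        "CHEK2": 21, "BRCA1": 25, "BRCA2": 30, "HRD": 40, "ERneg": 90, "ERpos": 368,
    })
    n_chek2_biallelic: int = 14          # includes one homozygous carrier
    tmb_lognormal: dict = field(default_factory=lambda: {
        "CHEK2": (np.log(1.37), 0.5), "BRCA1": (np.log(3.20), 0.5),
        "BRCA2": (np.log(2.55), 0.5), "HRD": (np.log(3.40), 0.5),
        "ERneg": (np.log(1.71), 0.5), "ERpos": (np.log(0.92), 0.5),
    })
    id_ratio_target: dict = field(default_factory=lambda: {
        "CHEK2": 0.80, "BRCA1": 0.30, "BRCA2": 0.35, "HRD": 0.35,
        "ERneg": 0.80, "ERpos": 0.77,
    })
    signature_weights: dict = field(default_factory=lambda: {
        "CHEK2": [8, 4, 2, 1, 1, 1], "ERpos": [8, 4, 2, 1, 1, 1],
        "ERneg": [4, 2, 4, 2, 2, 1], "BRCA1": [1, 1, 2, 8, 4, 1],
        "BRCA2": [1, 1, 2, 6, 5, 2], "HRD": [1, 1, 2, 8, 4, 1],
    })
    signature_depth: int = 2000          # expected mutations entering each profile
    tp53_rate: dict = field(default_factory=lambda: {
        "CHEK2": 0.30, "BRCA1": 0.70, "BRCA2": 0.50, "HRD": 0.60,
        "ERneg": 0.65, "ERpos": 0.30,
    })
    chek2_tp53_exclusive: bool = True
    wgd_prevalence: dict = field(default_factory=lambda: {
        g: {"mutant": 0.633, "wildtype": 0.193} for g in _GROUPS
    } | {"CHEK2": {"mutant": 0.633, "wildtype": 0.357},
         "BRCA1": {"mutant": 1.0, "wildtype": 1.0}})
    wgd_fraction_betas: tuple = ((2.0, 18.0), (18.0, 2.0))   # (non-WGD, WGD)
    n_segments: int = 60
    sv_size_mixture: dict = field(default_factory=_default_sv_mixture)
    sv_rate: dict = field(default_factory=lambda: {"DEL": 15, "TD": 15, "INV": 15, "TRA": 5})
    chromothripsis_prevalence: dict = field(default_factory=lambda: {
        "CHEK2": 0.333, "BRCA1": 0.20, "BRCA2": 0.20, "HRD": 0.12,
        "ERneg": 0.20, "ERpos": 0.20,
    })
    sv_in_chromothripsis_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for g, mix in self.sv_size_mixture.items():
            for svtype, comps in mix.items():
                if len(comps) == 0:
                    raise ValidationError(f"empty SV mixture for ({g}, {svtype})")
                w = np.array([c[0] for c in comps], dtype=float)
                if not np.isclose(w.sum(), 1.0):
                    raise ValidationError(
                        f"mixture weights for ({g}, {svtype}) must sum to 1"
                    )
        for g, p in self.tp53_rate.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"tp53_rate[{g}] outside [0, 1]")


@dataclass
class SyntheticTruth:
    """Per-sample generative labels aligned 1:1 with the emitted cohort."""

    table: pd.DataFrame   # sample_id, group, is_chek2_star, tp53, wgd, wgd_fraction, chromothripsis
    config: GeneratorConfig


@dataclass
class SimulatedCohort:
    cohort: CohortTable
    variants: pd.DataFrame          # sample_id, n_snv, n_mnv, n_ins, n_del
    profiles: pd.DataFrame          # channels x samples
    catalog: SignatureCatalog
    segments: pd.DataFrame          # sample_id, chrom, start, end, major_cn, minor_cn
    svs: pd.DataFrame               # sample_id, svtype, chrom1, pos1, chrom2, pos2, size
    chromothripsis: pd.DataFrame    # sample_id, chrom, start, end
    truth: SyntheticTruth


_CHROMS = [f"chr{i}" for i in range(1, 23)]
_MAPPABLE_MB = 2858.674661


def _sample_sheet_rows(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group in _GROUPS:
        n = int(cfg.n_per_group.get(group, 0))
        for i in range(n):
            sid = f"{group}_{i:03d}"
            row = {
                "sample_id": sid, "cohort": "pBC", "germline_gene": "none",
                "germline_variant": "NA", "wildtype_allele": "unknown",
                "mutant_allele": "retained", "er_status": "pos",
                "hrd_call": "HRP", "tp53_somatic": "wildtype",
                "zygosity": "het", "true_group": group,
            }
            if group == "CHEK2":
                row.update(germline_gene="CHEK2", germline_variant="c.1100delC")
                if i < cfg.n_chek2_biallelic - 1:
                    row["wildtype_allele"] = "lost"
                elif i == cfg.n_chek2_biallelic - 1:
                    row.update(zygosity="hom", wildtype_allele="unknown")
                else:
                    row["wildtype_allele"] = "retained"
            elif group in ("BRCA1", "BRCA2"):
                row.update(germline_gene=group, germline_variant="pathogenic",
                           wildtype_allele="lost", er_status="neg" if group == "BRCA1" else "pos")
            elif group == "HRD":
                row["hrd_call"] = "HRD"
            elif group == "ERneg":
                row["er_status"] = "neg"
            rows.append(row)
    columns = ["sample_id", "cohort", "germline_gene", "germline_variant",
               "wildtype_allele", "mutant_allele", "er_status", "hrd_call",
               "tp53_somatic", "zygosity", "true_group"]
    return pd.DataFrame(rows, columns=columns)


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    """Draw a complete synthetic cohort; fully deterministic given the seed."""
    cfg = config if config is not None else GeneratorConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
    sheet = _sample_sheet_rows(cfg, rng)
    catalog = toy_catalog()
    S = catalog.matrix.to_numpy(dtype=float)

    truth_rows, var_rows, prof_cols = [], [], {}
    seg_rows, sv_rows, ct_rows = [], [], []
    for _, row in sheet.iterrows():
        sid, group = row["sample_id"], row["true_group"]
        is_star = bool(
            group == "CHEK2"
            and (row["wildtype_allele"] == "lost" or row["zygosity"] == "hom")
        )
        # --- somatic TP53, mutually exclusive with CHEK2* when switched on
        p_tp53 = cfg.tp53_rate[group]
        if is_star and cfg.chek2_tp53_exclusive:
            p_tp53 = 0.0
        tp53_mut = bool(rng.random() < p_tp53)
        sheet.loc[sheet["sample_id"] == sid, "tp53_somatic"] = (
            "mutant" if tp53_mut else "wildtype"
        )
        # --- variant counts from the group TMB distribution
        mu, sigma = cfg.tmb_lognormal[group]
        tmb = float(rng.lognormal(mu, sigma))
        total = int(round(tmb * _MAPPABLE_MB))
        n_snv = int(rng.binomial(total, 0.86))
        n_mnv = int(rng.binomial(total - n_snv, 0.01 / 0.14)) if total > n_snv else 0
        n_id = total - n_snv - n_mnv
        r = cfg.id_ratio_target[group]
        n_ins = int(rng.binomial(n_id, r / (1.0 + r))) if n_id > 0 else 0
        var_rows.append({"sample_id": sid, "n_snv": n_snv, "n_mnv": n_mnv,
                         "n_ins": n_ins, "n_del": n_id - n_ins})
        # --- mutational profile: catalog @ Dirichlet weights, Poisson counts
        w = rng.dirichlet(np.asarray(cfg.signature_weights[group], dtype=float))
        prof_cols[sid] = rng.poisson(cfg.signature_depth * (S @ w))
        # --- WGD truth and copy-number segments
        stratum = "mutant" if tp53_mut else "wildtype"
        wgd = bool(rng.random() < cfg.wgd_prevalence[group][stratum])
        a, b = cfg.wgd_fraction_betas[1 if wgd else 0]
        frac = float(rng.beta(a, b))
        n_seg = cfg.n_segments
        n_dup = int(rng.binomial(n_seg, frac))
        major = np.ones(n_seg, dtype=int)
        major[:n_dup] = rng.integers(2, 5, size=n_dup)
        rng.shuffle(major)
        minor = np.minimum(rng.integers(0, 3, size=n_seg), major)
        pos = 1
        for k in range(n_seg):
            length = int(rng.integers(1_000_000, 10_000_000))
            seg_rows.append({"sample_id": sid, "chrom": _CHROMS[k % 22],
                             "start": pos, "end": pos + length,
                             "major_cn": int(major[k]), "minor_cn": int(minor[k])})
            pos += length + 1
        # --- chromothripsis regions
        ct = bool(rng.random() < cfg.chromothripsis_prevalence[group])
        regions = []
        if ct:
            chrom = _CHROMS[int(rng.integers(0, 22))]
            for _ in range(int(rng.integers(1, 4))):
                start = int(rng.integers(0, 100_000_000))
                regions.append((chrom, start, start + int(rng.integers(10_000_000, 50_000_000))))
                ct_rows.append({"sample_id": sid, "chrom": regions[-1][0],
                                "start": regions[-1][1], "end": regions[-1][2]})
        # --- structural variants
        for svtype, lam in cfg.sv_rate.items():
            n_sv = int(rng.poisson(lam))
            if svtype == "TRA":
                for _ in range(n_sv):
                    c1, c2 = rng.choice(22, size=2, replace=False)
                    sv_rows.append({"sample_id": sid, "svtype": "TRA",
                                    "chrom1": _CHROMS[c1],
                                    "pos1": int(rng.integers(0, 100_000_000)),
                                    "chrom2": _CHROMS[c2],
                                    "pos2": int(rng.integers(0, 100_000_000)),
                                    "size": np.nan})
                continue
            comps = cfg.sv_size_mixture[group][svtype]
            weights = np.array([c[0] for c in comps])
            for _ in range(n_sv):
                j = int(rng.choice(len(comps), p=weights))
                log10mb = rng.normal(comps[j][1], comps[j][2])
                size = max(int(round(10 ** (log10mb + 6))), 50)
                if regions and rng.random() < cfg.sv_in_chromothripsis_rate:
                    chrom, lo, hi = regions[int(rng.integers(0, len(regions)))]
                    pos1 = int(rng.integers(lo, hi))
                else:
                    chrom = _CHROMS[int(rng.integers(0, 22))]
                    pos1 = int(rng.integers(0, 100_000_000))
                sv_rows.append({"sample_id": sid, "svtype": svtype, "chrom1": chrom,
                                "pos1": pos1, "chrom2": chrom, "pos2": pos1 + size,
                                "size": size})
        truth_rows.append({"sample_id": sid, "group": group, "is_chek2_star": is_star,
                           "tp53_mutant": tp53_mut, "wgd": wgd, "wgd_fraction": frac,
                           "chromothripsis": ct})

    cohort = assign_subgroups(CohortTable(sheet.drop(columns=["true_group"])))
    profiles = pd.DataFrame(prof_cols, index=catalog.channels)
    truth = SyntheticTruth(table=pd.DataFrame(truth_rows), config=cfg)
    return SimulatedCohort(
        cohort=cohort,
        variants=pd.DataFrame(var_rows, columns=["sample_id", "n_snv", "n_mnv", "n_ins", "n_del"]),
        profiles=profiles,
        catalog=catalog,
        segments=pd.DataFrame(seg_rows),
        svs=pd.DataFrame(sv_rows),
        chromothripsis=pd.DataFrame(ct_rows, columns=["sample_id", "chrom", "start", "end"]),
        truth=truth,
    )


def truth_check(
    sim: SimulatedCohort,
    n_boot: int = 100,
    fd_seed: int = 0,
    peak_tolerance_log10: float = 0.1,
) -> dict:
    """Run the pipeline on a simulated cohort and score recovery against truth.

    Reports WGD label recovery, per-SV-type peak-location recovery for the
    multi-peaked group, the bootstrap-Fréchet comparison of the CHEK2-like
    group against the ER+-like group, and the CHEK2*/TP53 co-occurrence
    count.
    """
    from . import ploidy, svprofile
    from .cohort import SubgroupLabel, group_members

    truth = sim.truth.table.set_index("sample_id")
    cohort_ids = set(sim.cohort.df["sample_id"])
    if cohort_ids != set(truth.index):
        raise ValidationError("truth table does not match the cohort sample set")

    # WGD recovery
    frac = sim.segments.groupby("sample_id").apply(
        lambda s: float((s["major_cn"] >= 2).sum() / len(s)), include_groups=False
    )
    df = sim.cohort.df.copy()
    df["wgd_fraction"] = df["sample_id"].map(frac)
    called, cutpoint = ploidy.call_wgd(CohortTable(df))
    flags = called.df.set_index("sample_id")["wgd_flag"]
    recovery = float((flags == truth["wgd"]).mean())

    # Peak recovery + FD comparison, CHEK2-like vs ER+-like
    grid = svprofile.make_grid()
    chek2_ids = list(group_members(sim.cohort, SubgroupLabel.CHEK2)["sample_id"])
    erpos_ids = list(group_members(sim.cohort, SubgroupLabel.ERpos)["sample_id"])
    peaks_found, fd_results = {}, {}
    for svtype in svprofile.SV_TYPES_WITH_SIZE:
        pooled = svprofile.collect_sizes(sim.svs, svtype)
        baseline = svprofile.size_density(pooled, grid=grid, bandwidth="auto")
        chek2_sizes = svprofile.collect_sizes(sim.svs, svtype, chek2_ids)
        erpos_sizes = svprofile.collect_sizes(sim.svs, svtype, erpos_ids)
        curve = svprofile.size_density(chek2_sizes, grid=grid, bandwidth=baseline.bandwidth)
        ps = svprofile.find_density_peaks(curve, svtype=svtype, group="CHEK2")
        expected = [c[1] for c in sim.truth.config.sv_size_mixture["CHEK2"][svtype]
                    if c[1] > -0.5]  # the characteristic large-size components
        locs = ps.peaks["location_log10mb"].to_numpy()
        peaks_found[svtype] = all(
            (np.abs(locs - e) <= peak_tolerance_log10).any() for e in expected
        )
        fd_results[svtype] = svprofile.compare_profiles(
            chek2_sizes, erpos_sizes, baseline, n_boot=n_boot, seed=fd_seed,
            group_a="CHEK2", group_b="ERpos", svtype=svtype,
        )

    # TP53 x CHEK2* exclusivity
    star = sim.cohort.df.set_index("sample_id")["is_chek2_star"]
    tp53 = truth["tp53_mutant"]
    co_occurrence = int((star & tp53).sum())

    return {
        "wgd_cutpoint": cutpoint,
        "wgd_recovery": recovery,
        "peak_recovery": peaks_found,
        "fd_comparisons": fd_results,
        "chek2star_tp53_cooccurrence": co_occurrence,
        "n_chek2_star": int(star.sum()),
    }


def write_simulation(sim: SimulatedCohort, outdir) -> None:
    """Emit all standard-format files the pipeline consumes."""
    from pathlib import Path

    from .cohort import write_cohort

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(sim.cohort, out / "cohort.tsv")
    sim.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    sim.profiles.to_csv(out / "profiles.tsv", sep="\t")
    sim.catalog.matrix.to_csv(out / "catalog.tsv", sep="\t")
    sim.segments.to_csv(out / "segments.tsv", sep="\t", index=False)
    sv = sim.svs.rename(columns={"size": "size_bp"})
    sv.to_csv(out / "svs.tsv", sep="\t", index=False, na_rep="NA")
    sim.chromothripsis.to_csv(out / "chromothripsis.tsv", sep="\t", index=False)
    sim.truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)
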
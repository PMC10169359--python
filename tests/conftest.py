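import numpy as np
import pandas as pd
import pytest

from chek2profiler import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Reduced-size study for fast tests; structure matches the defaults."""
    cfg = GeneratorConfig()
    cfg.n_per_group = {"CHEK2": 21, "BRCA1": 8, "BRCA2": 8, "HRD": 10,
                       "ERneg": 20, "ERpos": 60}
    return cfg


@pytest.fixture(scope="session")
def small_sim(small_config):
    return generate_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def default_sim():
    """One full-size synthetic study shared across tests."""
    return generate_cohort(seed=7)


def make_sheet(rows: list[dict]) -> pd.DataFrame:
    """Build a sample-sheet frame with required columns defaulted."""
    base = {
        "cohort": "pBC", "germline_gene": "none", "germline_variant": "NA",
        "wildtype_allele": "unknown", "mutant_allele": "retained",
        "er_status": "pos", "hrd_call": "HRP", "tp53_somatic": "unknown",
    }
    out = []
    for i, row in enumerate(rows):
        r = dict(base, sample_id=f"S{i:03d}")
        r.update(row)
        out.append(r)
    return pd.DataFrame(out)


@pytest.fixture()
def sheet_path(tmp_path):
    def _write(rows: list[dict]):
        path = tmp_path / "sheet.tsv"
        make_sheet(rows).to_csv(path, sep="\t", index=False, na_rep="NA")
        return path

    return _write
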
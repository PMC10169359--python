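"""NNLS signature refitting, profound-signature selection and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chek2profiler.cohort import CohortTable, SchemaError, SubgroupLabel, ValidationError, assign_subgroups
from chek2profiler.signatures import (
    SignatureCatalog,
    cluster_subgroups,
    cosine_similarity,
    refit_profiles,
    refit_signatures,
    select_profound,
    subgroup_median_profile,
    toy_catalog,
)

from conftest import make_sheet


@pytest.fixture(scope="module")
def catalog():
    return toy_catalog()


def test_catalog_columns_are_distributions(catalog):
    sums = catalog.matrix.sum(axis=0)
    assert np.allclose(sums, 1.0, atol=1e-6)
    assert (catalog.matrix.to_numpy() >= 0).all()


def test_identity_recovery(catalog):
    """A profile equal to 500x one signature refits to 100 %rc for it."""
    profile = 500.0 * catalog.matrix["TS3"]
    profile.index = catalog.channels
    abs_c, rc = refit_signatures(profile, catalog)
    assert rc["TS3"] == pytest.approx(100.0, abs=1e-8)
    assert abs_c["TS3"] == pytest.approx(500.0, rel=1e-8)
    assert rc.drop("TS3").abs().max() < 1e-8


def grid_nnls_oracle(S, m, step=1e-3):
    """Exhaustive non-negative grid search over two signature weights."""
    best, best_r = None, np.inf
    total = m.sum()
    for w1 in np.arange(0, 1.5 * total, step * total):
        # minimise over w2 analytically: projection of residual, clipped at 0
        r = m - S[:, 0] * w1
        w2 = max(float(S[:, 1] @ r / (S[:, 1] @ S[:, 1])), 0.0)
        resid = np.linalg.norm(r - S[:, 1] * w2)
        if resid < best_r:
            best, best_r = (w1, w2), resid
    return np.array(best)


def test_noiseless_mixture_recovered(catalog):
    S = catalog.matrix.to_numpy()[:, :2]
    m = 0.6 * S[:, 0] + 0.4 * S[:, 1]
    sub = SignatureCatalog("SBS", catalog.matrix.iloc[:, :2])
    abs_c, rc = refit_signatures(m * 1000, sub)
    w = abs_c.to_numpy() / 1000
    np.testing.assert_allclose(w, [0.6, 0.4], rtol=1e-6)
    oracle = grid_nnls_oracle(S, m)
    np.testing.assert_allclose(w, oracle, atol=2e-3)


def test_multisignature_mixture_recovered(catalog):
    weights = np.array([0.5, 0.0, 0.2, 0.0, 0.3, 0.0])
    m = catalog.matrix.to_numpy() @ weights * 2000
    abs_c, _ = refit_signatures(m, catalog)
    np.testing.assert_allclose(abs_c.to_numpy() / 2000, weights, atol=1e-6)


def test_residual_never_increased_by_adding_signature(catalog):
    rng = np.random.default_rng(2)
    m = rng.poisson(50, size=96).astype(float)
    S = catalog.matrix
    for k in range(1, 6):
        small = SignatureCatalog("SBS", S.iloc[:, :k])
        larger = SignatureCatalog("SBS", S.iloc[:, : k + 1])
        r_small = np.linalg.norm(m - S.iloc[:, :k].to_numpy() @ refit_signatures(m, small)[0])
        r_large = np.linalg.norm(m - S.iloc[:, : k + 1].to_numpy() @ refit_signatures(m, larger)[0])
        assert r_large <= r_small + 1e-9


def test_rc_rows_sum_to_100(catalog):
    rng = np.random.default_rng(7)
    profiles = pd.DataFrame(
        rng.poisson(40, size=(96, 5)).astype(float),
        index=catalog.channels, columns=[f"s{i}" for i in range(5)],
    )
    _, rc = refit_profiles(profiles, catalog)
    np.testing.assert_allclose(rc.sum(axis=1), 100.0, atol=1e-9)


def test_empty_profile_and_channel_mismatch_error(catalog):
    with pytest.raises(ValidationError, match="empty"):
        refit_signatures(np.zeros(96), catalog)
    with pytest.raises(SchemaError):
        refit_signatures(np.ones(95), catalog)


def test_select_profound_threshold_semantics():
    rc = pd.DataFrame(
        {"SigX": [6.0, 2.0, 1.0], "SigY": [10.0, 10.0, 0.0], "SigZ": [0.0, 0.0, 0.5]},
        index=["a", "b", "c"],
    )
    # SigX exceeds 5% in only one genome -> not selected at min_samples=2
    assert select_profound(rc, ["a", "b", "c"]) == ["SigY"]
    # removing thresholds keeps everything with any positive contribution
    assert select_profound(rc, ["a", "b", "c"], min_rc=0, min_samples=1) == [
        "SigX", "SigY", "SigZ"]


def _grouped_rc():
    rows = [
        {"sample_id": "c1", "germline_gene": "CHEK2",
         "germline_variant": "c.1100delC", "wildtype_allele": "lost"},
        {"sample_id": "c2", "germline_gene": "CHEK2",
         "germline_variant": "c.1100delC", "wildtype_allele": "lost"},
        {"sample_id": "c3", "germline_gene": "CHEK2",
         "germline_variant": "c.1100delC", "wildtype_allele": "lost"},
        {"sample_id": "e1"}, {"sample_id": "e2"},
    ]
    sheet = make_sheet(rows)
    sheet["sample_id"] = [r["sample_id"] for r in rows]
    cohort = assign_subgroups(CohortTable(sheet))
    rc = pd.DataFrame(
        {"SigA": [10.0, 20.0, 90.0, 50.0, 50.0], "SigB": [90.0, 80.0, 10.0, 50.0, 50.0]},
        index=["c1", "c2", "c3", "e1", "e2"],
    )
    return cohort, rc


def test_subgroup_median_profile_odd_n_median():
    cohort, rc = _grouped_rc()
    med = subgroup_median_profile(rc, cohort, [SubgroupLabel.CHEK2_star, SubgroupLabel.ERpos])
    assert med.loc["CHEK2_star", "SigA"] == 20.0
    assert med.loc["ERpos", "SigA"] == 50.0


def test_subgroup_median_invariant_to_permutation():
    cohort, rc = _grouped_rc()
    a = subgroup_median_profile(rc, cohort, [SubgroupLabel.CHEK2_star])
    b = subgroup_median_profile(rc.iloc[::-1], cohort, [SubgroupLabel.CHEK2_star])
    pd.testing.assert_frame_equal(a, b)


def test_cosine_similarity_values():
    assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
    assert cosine_similarity([1, 1], [1, 0]) == pytest.approx(np.sqrt(2) / 2)


def test_cosine_similarity_symmetric_and_scale_invariant():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b = rng.random(8), rng.random(8)
        s = cosine_similarity(a, b)
        assert cosine_similarity(b, a) == pytest.approx(s)
        assert cosine_similarity(3.7 * a, b) == pytest.approx(s)
    with pytest.raises(ValidationError):
        cosine_similarity([0, 0], [1, 1])


def test_identical_profiles_merge_first_at_height_zero():
    mat = pd.DataFrame(
        [[1.0, 0.0, 1.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]],
        index=["A", "B", "C"],
    )
    res = cluster_subgroups(mat)
    assert res.linkage[0, 2] == pytest.approx(0.0)
    first = {int(res.linkage[0, 0]), int(res.linkage[0, 1])}
    assert first == {0, 1}  # lexicographic order: A, B merge first
    assert res.similarity.loc["A", "B"] == pytest.approx(1.0)
    assert res.similarity.loc["A", "C"] == pytest.approx(0.0)


def test_constructed_proximity_controls_join_order():
    rng = np.random.default_rng(1)
    base = rng.random(10)
    mat = pd.DataFrame(
        {
            "A": base + rng.normal(0, 0.01, 10),
            "B": base + rng.normal(0, 0.01, 10),
            "C": rng.permutation(base) + rng.random(10),
        }
    ).T.abs()
    res = cluster_subgroups(mat)
    first = {int(res.linkage[0, 0]), int(res.linkage[0, 1])}
    assert first == {0, 1}  # A and B are constructed to be most similar
    assert res.leaf_order.index("C") in (0, 2)


def test_synthetic_chek2_clusters_with_erpos(default_sim):
    """CHEK2* median signature profile joins ER+ before HRD-type groups."""
    from chek2profiler.cohort import group_members

    _, rc = refit_profiles(default_sim.profiles, default_sim.catalog)
    star_ids = list(group_members(default_sim.cohort, SubgroupLabel.CHEK2_star)["sample_id"])
    profound = select_profound(rc, star_ids)
    assert len(profound) >= 2
    med = subgroup_median_profile(
        rc, default_sim.cohort,
        [SubgroupLabel.CHEK2_star, SubgroupLabel.ERpos, SubgroupLabel.BRCA1,
         SubgroupLabel.HRD],
        signatures=profound,
    )
    res = cluster_subgroups(med)
    sim = res.similarity
    assert sim.loc["CHEK2_star", "ERpos"] > sim.loc["CHEK2_star", "HRD"]
    assert sim.loc["CHEK2_star", "ERpos"] > sim.loc["CHEK2_star", "BRCA1"]
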
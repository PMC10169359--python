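"""SV size spectra, discrete Fréchet distance and the bootstrap protocol."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gaussian_kde, hypergeom

from chek2profiler.cohort import ValidationError
from chek2profiler.density import silverman_bandwidth
from chek2profiler.svprofile import (
    DensityCurve,
    bootstrap_fd,
    chromothripsis_overlap_test,
    collect_sizes,
    compare_profiles,
    discrete_frechet,
    find_density_peaks,
    flag_in_peak,
    frechet_distance,
    make_grid,
    read_bedpe,
    read_sv_table,
    size_density,
    subsample_control,
)


def brute_force_frechet(a, b):
    """Minimum over *all* monotone couplings of the maximum point distance,
    by explicit recursive path enumeration (independent of the DP)."""
    a, b = np.asarray(a, float), np.asarray(b, float)

    def dist(i, j):
        return float(np.hypot(*(a[i] - b[j])))

    best = [np.inf]

    def walk(i, j, cur):
        cur = max(cur, dist(i, j))
        if cur >= best[0]:
            return
        if i == len(a) - 1 and j == len(b) - 1:
            best[0] = cur
            return
        if i + 1 < len(a):
            walk(i + 1, j, cur)
        if j + 1 < len(b):
            walk(i, j + 1, cur)
        if i + 1 < len(a) and j + 1 < len(b):
            walk(i + 1, j + 1, cur)

    walk(0, 0, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# collection and curves

def _sv_frame():
    return pd.DataFrame({
        "sample_id": ["s1", "s2", "s2", "s1", "s3"],
        "svtype": ["DEL", "DEL", "DEL", "TRA", "TD"],
        "pos1": [10, 5, 1, 0, 7],
        "size": [1000.0, 2000.0, 3000.0, np.nan, 5000.0],
    })


def test_collect_sizes_pools_in_stable_order():
    sizes = collect_sizes(_sv_frame(), "DEL")
    np.testing.assert_array_equal(sizes, [1000.0, 3000.0, 2000.0])


def test_collect_sizes_respects_group_and_floor():
    sizes = collect_sizes(_sv_frame(), "DEL", sample_ids=["s2"], min_size=2500)
    np.testing.assert_array_equal(sizes, [3000.0])
    assert len(collect_sizes(_sv_frame(), "TD", sample_ids=["s1"])) == 0


def test_translocations_have_no_size():
    with pytest.raises(ValidationError, match="translocation"):
        collect_sizes(_sv_frame(), "TRA")


def test_tra_rows_do_not_affect_sized_queries():
    with_tra = _sv_frame()
    without = with_tra[with_tra["svtype"] != "TRA"]
    np.testing.assert_array_equal(
        collect_sizes(with_tra, "DEL"), collect_sizes(without, "DEL"))


def test_density_integrates_to_one():
    rng = np.random.default_rng(0)
    sizes = 10 ** rng.normal(6, 0.5, size=400)
    curve = size_density(sizes)
    assert curve.integral == pytest.approx(1.0, abs=1e-3)


def test_density_matches_scipy_kde_oracle():
    rng = np.random.default_rng(4)
    log_sizes = rng.normal(0.5, 0.3, size=200)
    sizes = 10 ** (log_sizes + 6)
    bw = 0.1
    curve = size_density(sizes, bandwidth=bw)
    oracle = gaussian_kde(log_sizes, bw_method=bw / log_sizes.std(ddof=1))
    np.testing.assert_allclose(curve.density, oracle(curve.grid), rtol=1e-6)


def test_degenerate_sizes_peak_at_their_location():
    curve = size_density(np.full(50, 5_600_000.0))
    peak_pos = curve.grid[np.argmax(curve.density)]
    assert abs(peak_pos - np.log10(5.6)) <= 0.05  # within one grid step


def test_two_separated_components_give_two_maxima():
    rng = np.random.default_rng(1)
    bw = 0.1
    comp1 = 10 ** (rng.normal(-1.0, bw, 500) + 6)
    comp2 = 10 ** (rng.normal(-1.0 + 6 * bw, bw, 500) + 6)  # 3 smoothed sd apart
    curve = size_density(np.concatenate([comp1, comp2]), bandwidth=bw)
    peaks = find_density_peaks(curve, min_prominence=0.05)
    assert len(peaks.peaks) == 2


def test_fewer_than_two_sizes_refused():
    with pytest.raises(ValidationError):
        size_density(np.array([1e6]))


def test_peak_snapping_reports_grid_round_sizes():
    curve = size_density(np.full(100, 28_200_000.0) * np.exp(0))
    peaks = find_density_peaks(curve)
    assert 28.2 in peaks.locations_mb


def test_raising_prominence_never_adds_peaks():
    rng = np.random.default_rng(3)
    sizes = 10 ** (np.concatenate([rng.normal(-1, 0.1, 300),
                                   rng.normal(0.6, 0.1, 200),
                                   rng.normal(1.4, 0.1, 100)]) + 6)
    curve = size_density(sizes, bandwidth=0.1)
    counts = [len(find_density_peaks(curve, min_prominence=p).peaks)
              for p in (0.01, 0.05, 0.2, 0.5)]
    assert counts == sorted(counts, reverse=True)


def test_baseline_equals_concatenation_of_subgroups():
    rng = np.random.default_rng(8)
    a = 10 ** (rng.normal(0, 0.3, 100) + 6)
    b = 10 ** (rng.normal(1, 0.3, 150) + 6)
    pooled = size_density(np.concatenate([a, b]), bandwidth=0.1)
    again = size_density(np.concatenate([b, a]), bandwidth=0.1)
    np.testing.assert_allclose(pooled.density, again.density)


# ---------------------------------------------------------------------------
# discrete Fréchet distance

def test_frechet_identity_is_zero():
    rng = np.random.default_rng(0)
    pts = rng.random((7, 2))
    assert discrete_frechet(pts, pts) == 0.0


@pytest.mark.parametrize("a,b,expected", [
    ([(0, 0), (1, 0)], [(0, 1), (1, 1)], 1.0),
    ([(0, 0), (1, 0), (2, 0)], [(0, 0), (2, 0)], 1.0),
])
def test_frechet_known_couplings(a, b, expected):
    assert discrete_frechet(a, b) == pytest.approx(expected)
    assert discrete_frechet(a, b) == pytest.approx(brute_force_frechet(a, b))


def test_frechet_dp_equals_brute_force_on_random_curves():
    rng = np.random.default_rng(42)
    for _ in range(200):
        a = rng.random((rng.integers(1, 7), 2)) * 4
        b = rng.random((rng.integers(1, 7), 2)) * 4
        assert discrete_frechet(a, b) == pytest.approx(brute_force_frechet(a, b))


def test_frechet_metric_axioms_on_random_curves():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = int(rng.integers(2, 6))
        a, b, c = (rng.random((n, 2)) for _ in range(3))
        dab, dba = discrete_frechet(a, b), discrete_frechet(b, a)
        assert dab == pytest.approx(dba)
        assert dab >= 0
        # bounded below by the endpoint distances
        lower = max(np.hypot(*(a[0] - b[0])), np.hypot(*(a[-1] - b[-1])))
        assert dab >= lower - 1e-12
        # triangle inequality
        assert dab <= discrete_frechet(a, c) + discrete_frechet(c, b) + 1e-12


def test_curve_frechet_requires_matching_grids():
    g1, g2 = make_grid(), make_grid(lo=-3.0)
    c1 = DensityCurve(g1, np.zeros_like(g1), 10, 0.1)
    c2 = DensityCurve(g2, np.zeros_like(g2), 10, 0.1)
    with pytest.raises(ValidationError, match="grid"):
        frechet_distance(c1, c2)


def test_curve_frechet_axis_modes_differ():
    rng = np.random.default_rng(5)
    a = size_density(10 ** (rng.normal(0, 0.3, 100) + 6), bandwidth=0.1)
    b = size_density(10 ** (rng.normal(1, 0.3, 100) + 6), bandwidth=0.1)
    assert frechet_distance(a, b, fd_axes="scaled") != pytest.approx(
        frechet_distance(a, b, fd_axes="raw"))


# ---------------------------------------------------------------------------
# bootstrap protocol

@pytest.fixture(scope="module")
def baseline_and_sizes():
    rng = np.random.default_rng(21)
    group = 10 ** (rng.normal(0.2, 0.4, 300) + 6)
    other = 10 ** (rng.normal(0.9, 0.4, 600) + 6)
    pooled = np.concatenate([group, other])
    baseline = size_density(pooled, bandwidth=silverman_bandwidth(np.log10(pooled / 1e6)))
    return baseline, group, other


def test_bootstrap_is_seed_deterministic(baseline_and_sizes):
    baseline, group, _ = baseline_and_sizes
    d1 = bootstrap_fd(group, baseline, n_boot=5, seed=3, group="g", svtype="DEL")
    d2 = bootstrap_fd(group, baseline, n_boot=5, seed=3, group="g", svtype="DEL")
    np.testing.assert_array_equal(d1, d2)
    d3 = bootstrap_fd(group, baseline, n_boot=5, seed=4, group="g", svtype="DEL")
    assert not np.array_equal(d1, d3)


def test_bootstrap_invariant_to_input_order(baseline_and_sizes):
    baseline, group, _ = baseline_and_sizes
    d1 = bootstrap_fd(group, baseline, n_boot=3, seed=0)
    d2 = bootstrap_fd(group[::-1], baseline, n_boot=3, seed=0)
    np.testing.assert_array_equal(d1, d2)


def test_bootstrap_single_replicate(baseline_and_sizes):
    baseline, group, _ = baseline_and_sizes
    assert len(bootstrap_fd(group, baseline, n_boot=1, seed=0)) == 1


def test_pooled_subgroup_sits_closer_than_shifted_one(baseline_and_sizes):
    baseline, group, other = baseline_and_sizes
    pooled = np.concatenate([group, other])
    shifted = pooled * 10 ** 0.5
    d_pool = bootstrap_fd(pooled, baseline, n_boot=20, seed=1, group="pool")
    d_shift = bootstrap_fd(shifted, baseline, n_boot=20, seed=1, group="shift")
    assert d_pool.mean() < d_shift.mean()


def test_self_comparison_with_same_stream_is_null(baseline_and_sizes):
    baseline, group, _ = baseline_and_sizes
    cmp = compare_profiles(group, group, baseline, n_boot=10, seed=5,
                           group_a="same", group_b="same")
    assert cmp.mean_a == cmp.mean_b
    assert cmp.p_value == pytest.approx(1.0)


def test_distinct_spectra_are_detected(baseline_and_sizes):
    baseline, group, other = baseline_and_sizes
    cmp = compare_profiles(group, other, baseline, n_boot=50, seed=5,
                           group_a="g", group_b="o")
    assert cmp.p_value < 1e-6
    assert len(cmp.distances_a) == len(cmp.distances_b) == 50
    assert cmp.mean_a == pytest.approx(cmp.distances_a.mean())


def test_subsample_full_pool_reproduces_pool_density(baseline_and_sizes):
    baseline, group, other = baseline_and_sizes
    pool = np.concatenate([group, other])
    res = subsample_control(pool, n_target=len(pool), reps=2, seed=0,
                            query_windows=[(-0.2, 0.2)])
    assert len(res) == 2
    # the draw is the whole pool, so the two replicates agree exactly
    assert res["n_peaks"].nunique() == 1


def test_subsample_control_reproducible_and_bounded(baseline_and_sizes):
    _, group, other = baseline_and_sizes
    pool = np.concatenate([group, other])
    r1 = subsample_control(pool, 100, reps=5, seed=9, query_windows=[(0.8, 1.0)])
    r2 = subsample_control(pool, 100, reps=5, seed=9, query_windows=[(0.8, 1.0)])
    pd.testing.assert_frame_equal(r1, r2)
    with pytest.raises(ValidationError):
        subsample_control(pool, len(pool) + 1, reps=1, seed=0, query_windows=[])


# ---------------------------------------------------------------------------
# chromothripsis overlap

def test_in_peak_flags_are_order_invariant():
    curve = size_density(np.full(60, 10 ** 6.65), bandwidth=0.05)
    peaks = find_density_peaks(curve)
    svs = pd.DataFrame({
        "sample_id": ["a", "b", "c"],
        "size": [10 ** 6.65, 10 ** 6.0, 10 ** 6.7],
    })
    f1 = flag_in_peak(svs, peaks)
    f2 = flag_in_peak(svs.iloc[::-1], peaks).sort_index()
    pd.testing.assert_series_equal(f1, f2)
    assert bool(f1[0]) and not bool(f1[1]) and bool(f1[2])


def _overlap_frame(n11, n10, n01, n00):
    """SVs laid out so the in-peak x in-region 2x2 equals the given counts."""
    rows, regions = [], []
    i = 0
    for in_peak, inside, count in [(True, True, n11), (True, False, n10),
                                   (False, True, n01), (False, False, n00)]:
        for _ in range(count):
            sid = f"s{i}"
            pos = 500 if inside else 5_000_000
            rows.append({"sample_id": sid, "svtype": "TD", "chrom1": "chr1",
                         "pos1": pos, "chrom2": "chr1", "pos2": pos + 100,
                         "size": 100.0, "in_peak": in_peak})
            regions.append({"sample_id": sid, "chrom": "chr1", "start": 0, "end": 1000})
            i += 1
    return pd.DataFrame(rows), pd.DataFrame(regions)


def test_overlap_test_matches_hypergeometric_oracle():
    svs, regions = _overlap_frame(10, 2, 3, 15)
    res = chromothripsis_overlap_test(svs, regions, svtype="TD")
    assert res["table"] == [[10, 2], [3, 15]]
    k, n_pk = 10, 12
    total, total_inside = 30, 13
    p_obs = hypergeom.pmf(k, total, total_inside, n_pk)
    oracle = sum(
        hypergeom.pmf(x, total, total_inside, n_pk)
        for x in range(max(0, total_inside - (total - n_pk)), min(n_pk, total_inside) + 1)
        if hypergeom.pmf(x, total, total_inside, n_pk) <= p_obs * (1 + 1e-9)
    )
    assert res["p_value"] == pytest.approx(oracle, rel=1e-9)


def test_all_svs_outside_regions_is_vacuous():
    svs, _ = _overlap_frame(0, 5, 0, 5)
    regions = pd.DataFrame({"sample_id": ["zzz"], "chrom": ["chr9"],
                            "start": [0], "end": [10]})
    res = chromothripsis_overlap_test(svs, regions, svtype="TD")
    assert res["p_value"] == 1.0 and res["warning"]


def test_no_regions_in_cohort_warns():
    svs, _ = _overlap_frame(0, 3, 0, 3)
    res = chromothripsis_overlap_test(svs, pd.DataFrame(columns=["sample_id", "chrom", "start", "end"]))
    assert res["p_value"] == 1.0 and "no chromothripsis" in res["warning"]


# ---------------------------------------------------------------------------
# readers

def test_bedpe_reader_derives_sizes(tmp_path):
    path = tmp_path / "svs.bedpe"
    path.write_text(
        "chr1\t100\t101\tchr1\t5100\t5101\ts1\t.\t+\t-\tDEL\n"
        "chr2\t0\t1\tchr3\t500\t501\ts1\t.\t+\t+\tTRA\n"
    )
    df = read_bedpe(path, sample_id="s1")
    assert df.loc[0, "size"] == 5000
    assert np.isnan(df.loc[1, "size"])


def test_sv_table_reader_validates(tmp_path):
    path = tmp_path / "svs.tsv"
    pd.DataFrame({"sample_id": ["a"], "svtype": ["DEL"], "size_bp": [1500]}).to_csv(
        path, sep="\t", index=False)
    df = read_sv_table(path)
    assert df.loc[0, "size"] == 1500
    bad = tmp_path / "bad.tsv"
    pd.DataFrame({"sample_id": ["a"], "svtype": ["DEL"]}).to_csv(bad, sep="\t", index=False)
    with pytest.raises(ValidationError, match="size_bp"):
        read_sv_table(bad)
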
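"""ED statistic, tricube smoothing, threshold, and region calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poolmap import ed_scan
from poolmap.io_formats import GeneModel, PoolCounts


def fv(**freqs):
    return ed_scan.FrequencyVector(dict(freqs), depth=100, usable=True)


# ---------------------------------------------------------------------------
# allele frequencies


def test_allele_frequencies_published_pool():
    """32 ref + 12 alt reads -> frequencies 0.72727 / 0.27273 at depth 44."""
    f = ed_scan.allele_frequencies(PoolCounts({"C": 32, "T": 12}), min_depth=4)
    assert f.usable and f.depth == 44
    assert f.freq["C"] == pytest.approx(32 / 44, abs=1e-9)
    assert f.freq["T"] == pytest.approx(12 / 44, abs=1e-9)
    assert sum(f.freq.values()) == pytest.approx(1.0, abs=1e-9)


def test_allele_frequencies_symmetric_and_degenerate():
    f = ed_scan.allele_frequencies(PoolCounts({"A": 10, "C": 10, "G": 10, "T": 10}))
    assert all(x == pytest.approx(0.25) for x in f.freq.values())
    low = ed_scan.allele_frequencies(PoolCounts({"C": 0, "T": 0}), min_depth=5)
    assert not low.usable and low.depth == 0
    with pytest.raises(ValueError):
        ed_scan.allele_frequencies(PoolCounts({"C": 1}), min_depth=0)


# ---------------------------------------------------------------------------
# ED statistic


def test_ed_statistic_limits():
    assert ed_scan.ed_statistic(fv(A=0.25, C=0.25, G=0.25, T=0.25),
                                fv(A=0.25, C=0.25, G=0.25, T=0.25)) == 0.0
    full = ed_scan.ed_statistic(fv(A=0, C=0, G=0, T=1), fv(A=0, C=1, G=0, T=0))
    assert full == pytest.approx(math.sqrt(2), abs=1e-12)


def test_ed_statistic_on_published_depth_quartet():
    """Mutant pool 0/37 vs wild pool 32/12 gives ED = sqrt(2)*(32/44) = 1.02852.

    (Rounding the frequencies to 5 decimals first gives 1.02853; the
    exact closed form is asserted here.)
    """
    f_mut = ed_scan.allele_frequencies(PoolCounts({"C": 0, "T": 37}))
    f_wt = ed_scan.allele_frequencies(PoolCounts({"C": 32, "T": 12}))
    ed = ed_scan.ed_statistic(f_mut, f_wt)
    assert ed == pytest.approx(math.sqrt(2) * (32 / 44), abs=1e-12)
    assert ed == pytest.approx(1.02852, abs=2e-5)


def test_ed_statistic_rejects_mismatched_allele_space():
    with pytest.raises(ValueError, match="allele space"):
        ed_scan.ed_statistic(fv(A=1, C=0, G=0, T=0), fv(REF=1, ALT=0))
    with pytest.raises(ValueError, match="usable"):
        ed_scan.ed_statistic(
            fv(A=1, C=0, G=0, T=0),
            ed_scan.FrequencyVector({"A": 0.0}, depth=0, usable=False),
        )


def _simplex4(draw_vals):
    total = sum(draw_vals) or 1.0
    return [v / total for v in draw_vals]


@settings(max_examples=300, deadline=None)
@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=4),
    st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=4),
)
def test_ed_symmetry_and_range_property(v1, v2):
    """ED is symmetric and confined to [0, sqrt(2)] on the frequency simplex."""
    a = fv(**dict(zip("ACGT", _simplex4(v1))))
    b = fv(**dict(zip("ACGT", _simplex4(v2))))
    d_ab = ed_scan.ed_statistic(a, b)
    assert d_ab == ed_scan.ed_statistic(b, a)
    assert -1e-12 <= d_ab <= math.sqrt(2) + 1e-12


# ---------------------------------------------------------------------------
# smoothing


def brute_force_tricube(points, window_bp, k):
    """Independent all-pairs evaluation of the tricube sliding mean."""
    h = window_bp / 2.0
    out = []
    for _, p in points.iterrows():
        num = den = 0.0
        for _, q in points.iterrows():
            if q["chrom"] != p["chrom"]:
                continue
            d = abs(q["pos"] - p["pos"])
            if d >= h:
                continue
            w = (1 - (d / h) ** 3) ** 3
            num += w * q["ed"] ** k
            den += w
        out.append(num / den if den else p["ed"] ** k)
    return out


def toy_points(eds, spacing=1000, chrom="c1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": [spacing * (i + 1) for i in range(len(eds))],
         "ed": eds, "variant_class": "SNP"}
    )


def test_fit_profile_constant_track():
    for k in (1, 2, 5):
        pts = ed_scan.fit_profile(toy_points([0.3] * 7), window_bp=4000, k=k)
        assert np.allclose(pts["ed_fitted"], 0.3 ** k)


def test_fit_profile_spike_bounded_by_max():
    pts = ed_scan.fit_profile(toy_points([0, 0, 1.0, 0, 0]), window_bp=4000)
    assert pts["ed_fitted"][2] <= 1.0
    assert pts["ed_fitted"][2] > pts["ed_fitted"][0]


@pytest.mark.parametrize("k", [1, 2])
def test_fit_profile_matches_brute_force_oracle(k):
    """Vectorised smoother equals all-pairs tricube evaluation."""
    rng = np.random.default_rng(11)
    eds = rng.uniform(0, 1.2, size=25)
    pts = toy_points(list(eds))
    fitted = ed_scan.fit_profile(pts, window_bp=4000, k=k)["ed_fitted"]
    assert np.allclose(fitted, brute_force_tricube(pts, 4000, k), atol=1e-12)


def test_fit_profile_window_limits():
    rng = np.random.default_rng(5)
    pts = toy_points(list(rng.uniform(0, 1, size=12)))
    raw = ed_scan.fit_profile(pts, window_bp=1)["ed_fitted"]
    assert np.allclose(raw, pts["ed"])          # window -> 0: raw track
    wide = ed_scan.fit_profile(pts, window_bp=10**9)["ed_fitted"]
    assert np.allclose(wide, pts["ed"].mean(), atol=1e-6)  # window -> inf


def test_fit_profile_no_chromosome_bleed():
    pts = pd.concat(
        [toy_points([1.0] * 5, chrom="c1"), toy_points([0.0] * 5, chrom="c2")],
        ignore_index=True,
    )
    fitted = ed_scan.fit_profile(pts, window_bp=10**9)["ed_fitted"]
    assert np.allclose(fitted[:5], 1.0) and np.allclose(fitted[5:], 0.0)


# ---------------------------------------------------------------------------
# threshold


def test_threshold_hand_computed_fixture():
    """median 0.1 + 3 x sample SD 0.35777 = 1.17331 on the 5-point fixture."""
    pts = toy_points([0.1, 0.1, 0.1, 0.1, 0.9])
    pts["ed_fitted"] = pts["ed"]
    assert ed_scan.compute_threshold(pts) == pytest.approx(1.17331, abs=1e-5)
    assert ed_scan.compute_threshold(pts, column="ed_fitted") == pytest.approx(1.17331, abs=1e-5)


def test_threshold_constant_track_and_median_monotonicity():
    pts = toy_points([0.4, 0.4, 0.4])
    assert ed_scan.compute_threshold(pts) == pytest.approx(0.4)
    base = toy_points([0.2, 0.3, 0.4, 0.5, 0.6])
    extended = toy_points([0.2, 0.3, 0.4, 0.5, 0.6, 0.1])
    assert np.median(extended["ed"]) <= np.median(base["ed"])
    with pytest.raises(ValueError):
        ed_scan.compute_threshold(toy_points([0.1]))


# ---------------------------------------------------------------------------
# region calling


def fitted_points(values, spacing=15_000, chrom="c1"):
    pts = toy_points(values, spacing=spacing, chrom=chrom)
    pts["ed_fitted"] = pts["ed"]
    return pts


def test_call_regions_empty_when_all_below():
    pts = fitted_points([0.1] * 30)
    assert ed_scan.call_regions(pts, threshold=0.5) == []


def test_call_regions_single_run():
    values = [0.1] * 10 + [0.9] * 12 + [0.1] * 10
    pts = fitted_points(values)
    regions = ed_scan.call_regions(pts, threshold=0.5, min_variants=10, merge_gap_bp=1)
    assert len(regions) == 1
    r = regions[0]
    first, last = 15_000 * 11, 15_000 * 22
    assert r.start <= first and r.end >= last          # outward snapping
    assert r.start % 10_000 == 0 and r.end % 10_000 == 0
    assert r.n_variants == 12
    inside = pts[(pts["ed_fitted"] >= 0.5)]
    assert all(r.contains(p) for p in inside["pos"])   # every hot variant covered


def test_call_regions_merge_gap_behaviour():
    """Two 12-variant runs 50 kb apart merge at 100-kb gap, split at 10 kb."""
    values = [0.9] * 12 + [0.1] * 3 + [0.9] * 12   # gap approx 50 kb at 12.5-kb spacing
    pts = fitted_points(values, spacing=12_500)
    merged = ed_scan.call_regions(pts, 0.5, min_variants=10, merge_gap_bp=100_000)
    assert len(merged) == 1 and merged[0].n_variants == 24
    split = ed_scan.call_regions(pts, 0.5, min_variants=10, merge_gap_bp=10_000)
    assert len(split) == 2
    assert [r.n_variants for r in split] == [12, 12]


def test_call_regions_counts_overlapping_genes():
    pts = fitted_points([0.9] * 12)
    genes = [
        GeneModel("in1", "c1", "+", [(20_000, 21_000), (22_000, 23_000)], 20_000, 23_000),
        GeneModel("out1", "other", "+", [(20_000, 21_000), (22_000, 23_000)], 20_000, 23_000),
        GeneModel("far", "c1", "+", [(900_000, 901_000), (902_000, 903_000)], 900_000, 903_000),
    ]
    (r,) = ed_scan.call_regions(pts, 0.5, min_variants=5, gene_models=genes)
    assert r.n_genes == 1


def brute_force_regions(pts, threshold, min_variants, merge_gap_bp):
    """Exhaustive maximal-run scan used as the oracle for small instances."""
    out = []
    for chrom in sorted(pts["chrom"].unique()):
        sub = pts[pts["chrom"] == chrom].reset_index(drop=True)
        runs, current = [], []
        for _, row in sub.iterrows():
            if row["ed_fitted"] >= threshold:
                current.append(int(row["pos"]))
            elif current:
                runs.append(current)
                current = []
        if current:
            runs.append(current)
        merged = []
        for run in runs:
            if merged and run[0] - merged[-1][-1] < merge_gap_bp:
                merged[-1].extend(run)
            else:
                merged.append(run)
        for run in merged:
            if len(run) >= min_variants:
                out.append((chrom, run[0], run[-1], len(run)))
    return out


@pytest.mark.parametrize("seed", range(6))
def test_call_regions_agrees_with_exhaustive_scan(seed):
    """On <=50-point instances the caller equals a brute-force run scan."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 50))
    pts = fitted_points(list(rng.uniform(0, 1, size=n)), spacing=int(rng.integers(5_000, 40_000)))
    threshold = 0.6
    min_variants = int(rng.integers(1, 5))
    merge_gap = int(rng.integers(1, 120_000))
    regions = ed_scan.call_regions(pts, threshold, min_variants, merge_gap)
    expected = brute_force_regions(pts, threshold, min_variants, merge_gap)
    assert len(regions) == len(expected)
    for r, (chrom, first, last, cnt) in zip(regions, expected):
        assert r.chrom == chrom and r.n_variants == cnt
        assert r.start == (first // 10_000) * 10_000
        assert r.end == math.ceil(last / 10_000) * 10_000


# ---------------------------------------------------------------------------
# region geometry


@pytest.mark.parametrize(
    "start,end,size",
    [
        (11_620_000, 24_230_000, 12.61),
        (16_300_000, 18_240_000, 1.94),
        (100, 100, 0.00),
        (0, 5_000, 0.01),  # half-up rounding at the boundary
    ],
)
def test_region_size_mb(start, end, size):
    r = ed_scan.CandidateRegion("Fvb1", start, end, n_variants=1)
    assert ed_scan.region_size_mb(r) == size
    assert r.size_mb == size
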
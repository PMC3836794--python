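"""Geographic distances, Mantel tests, cross-divide rank correlation."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats

import migradiv as mg
from migradiv.spatial import (
    cross_divide_test,
    geo_distances,
    haversine_km,
    mantel_test,
    split_by_divide,
)


def law_of_cosines_km(lat1, lon1, lat2, lon2):
    """Independent spherical distance: law of cosines on the same sphere."""
    f1, f2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    c = math.sin(f1) * math.sin(f2) + math.cos(f1) * math.cos(f2) * math.cos(dl)
    return 6371.0 * math.acos(min(1.0, max(-1.0, c)))


def test_haversine_reference_points(blackcap):
    metadata, _, _ = blackcap
    md = {m.code: m for m in metadata}
    # identical coordinates (sympatric NW and SW migrants)
    assert haversine_km(48.03, 7.82, 48.03, 7.82) == 0.0
    # one degree of longitude on the equator
    assert haversine_km(0, 0, 0, 1) == pytest.approx(2 * math.pi * 6371 / 360, rel=1e-9)
    # an independent formula agrees on the longest survey pair
    sv, km = md["Sv"], md["Km"]
    assert haversine_km(sv.latitude, sv.longitude, km.latitude, km.longitude) == pytest.approx(
        law_of_cosines_km(sv.latitude, sv.longitude, km.latitude, km.longitude), rel=1e-9
    )


def test_geo_distance_modes(blackcap):
    metadata, _, _ = blackcap
    gc = geo_distances(metadata, mode="great-circle")
    lo = geo_distances(metadata, mode="longitudinal")
    assert gc.get("Fr_NW", "Fr_SW") == 0.0
    # longitudinal mode depends on longitude only
    md = {m.code: m for m in metadata}
    for a, b in [("Sv", "Km"), ("Os", "Kf")]:
        expect = haversine_km(0, md[a].longitude, 0, md[b].longitude)
        assert lo.get(a, b) == pytest.approx(expect)
    # triangle inequality in great-circle mode
    codes = gc.codes
    for a, b, c in itertools.combinations(range(len(codes)), 3):
        assert gc.values[a, c] <= gc.values[a, b] + gc.values[b, c] + 1e-9
    with pytest.raises(ValueError):
        geo_distances(metadata, mode="euclidean")


# ----------------------------------------------------------------------
def _random_matrix(rng, k):
    a = np.abs(rng.normal(size=(k, k)))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    return a


def test_mantel_perfect_association(rng):
    k = 6
    vals = _random_matrix(rng, k)
    codes = [f"p{i}" for i in range(k)]
    m1 = mg.PairwiseMatrix(codes, vals)
    m2 = mg.PairwiseMatrix(codes, vals.copy())
    res = mantel_test(m1, m2, permutations=199, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p < 0.05


def test_mantel_matches_exact_enumeration(rng):
    """With 4 populations the permutation null is fully enumerable (4! = 24
    relabelings); the Monte-Carlo p must converge on the exact value."""
    k = 4
    codes = list("abcd")
    A = _random_matrix(rng, k)
    B = _random_matrix(rng, k)
    iu = np.triu_indices(k, 1)
    obs = stats.pearsonr(A[iu], B[iu])[0]
    hits = sum(
        stats.pearsonr(A[np.ix_(per, per)][iu], B[iu])[0] >= obs - 1e-12
        for per in itertools.permutations(range(k))
    )
    exact = hits / 24
    res = mantel_test(
        mg.PairwiseMatrix(codes, A), mg.PairwiseMatrix(codes, B),
        permutations=4999, seed=1,
    )
    assert res.p == pytest.approx(exact, abs=0.03)


def test_mantel_invariant_to_affine_rescaling(rng):
    k = 6
    codes = [f"p{i}" for i in range(k)]
    A = _random_matrix(rng, k)
    B = _random_matrix(rng, k)
    r1 = mantel_test(mg.PairwiseMatrix(codes, A), mg.PairwiseMatrix(codes, B), 199, seed=2)
    r2 = mantel_test(mg.PairwiseMatrix(codes, A * 3.7), mg.PairwiseMatrix(codes, 0.2 * B + 5), 199, seed=2)
    assert r1.r == pytest.approx(r2.r)
    assert r1.p == r2.p


def test_mantel_agrees_with_skbio(rng):
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import mantel as sk_mantel

    k = 7
    codes = [f"p{i}" for i in range(k)]
    A = _random_matrix(rng, k)
    B = _random_matrix(rng, k)
    mine = mantel_test(mg.PairwiseMatrix(codes, A), mg.PairwiseMatrix(codes, B), 999, seed=3)
    r_sk, _, _ = sk_mantel(DistanceMatrix(A, codes), DistanceMatrix(B, codes),
                           method="pearson", permutations=0)
    assert mine.r == pytest.approx(float(r_sk), abs=1e-12)


def test_mantel_rejects_degenerate_input(rng):
    k = 5
    codes = [f"p{i}" for i in range(k)]
    const = np.ones((k, k)) - np.eye(k)
    with pytest.raises(ValueError, match="constant"):
        mantel_test(mg.PairwiseMatrix(codes, const), mg.PairwiseMatrix(codes, _random_matrix(rng, k)), 199)
    with pytest.raises(ValueError, match="4 populations"):
        mantel_test(
            mg.PairwiseMatrix(codes[:3], _random_matrix(rng, 3)),
            mg.PairwiseMatrix(codes[:3], _random_matrix(rng, 3)), 199,
        )


# ----------------------------------------------------------------------
def test_divide_split(blackcap):
    metadata, _, _ = blackcap
    west, east = split_by_divide(metadata, 13.0)
    assert west == ["Sv", "Ub", "Fr_NW", "Fr_SW", "Wh", "Mn", "Os"]  # Os at 10.86E is west
    assert east == ["Kf", "Vn", "Ry", "Bw", "Km"]


def test_cross_divide_monotone_gives_rho_one():
    md = [
        mg.PopulationMetadata(f"w{i}", 48, lon, "SW", "short") for i, lon in enumerate([0.0, 2.0, 5.0])
    ] + [
        mg.PopulationMetadata(f"e{i}", 48, lon, "SE", "short") for i, lon in enumerate([14.0, 18.0])
    ]
    codes = [m.code for m in md]
    lon = {m.code: m.longitude for m in md}
    vals = np.zeros((5, 5))
    for i, a in enumerate(codes):
        for j, b in enumerate(codes):
            if i != j:
                vals[i, j] = abs(lon[a] - lon[b]) ** 1.7 / 100  # strictly monotone in distance
    m = mg.PairwiseMatrix(codes, vals)
    res = cross_divide_test(m, md, 13.0, resamples=500, seed=0)
    assert res.rho == pytest.approx(1.0)
    assert res.significant


def test_cross_divide_requires_both_sides_and_enough_pairs():
    md = [mg.PopulationMetadata(f"w{i}", 48, float(i), "SW", "short") for i in range(4)]
    vals = np.ones((4, 4)) - np.eye(4)
    with pytest.raises(ValueError, match="each side"):
        cross_divide_test(mg.PairwiseMatrix([m.code for m in md], vals), md, 13.0, resamples=200)
    md2 = md[:2] + [mg.PopulationMetadata("e0", 48, 14.0, "SE", "short")]
    vals2 = np.ones((3, 3)) - np.eye(3)
    with pytest.raises(ValueError, match="3 cross-divide pairs"):
        cross_divide_test(mg.PairwiseMatrix([m.code for m in md2], vals2), md2, 13.0, resamples=200)


def test_cross_divide_null_ci_covers_zero_and_shrinks(rng):
    def run(n_west, n_east, seed):
        md = [mg.PopulationMetadata(f"w{i}", 48, float(i), "SW", "short") for i in range(n_west)]
        md += [mg.PopulationMetadata(f"e{i}", 48, 14.0 + i, "SE", "short") for i in range(n_east)]
        codes = [m.code for m in md]
        k = len(codes)
        vals = np.abs(rng.normal(size=(k, k)))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        return cross_divide_test(mg.PairwiseMatrix(codes, vals), md, 13.0, resamples=2000, seed=seed)

    small = run(3, 3, seed=5)
    big = run(8, 8, seed=5)
    for res in (small, big):
        assert res.ci_lower < 0 < res.ci_upper
    assert (big.ci_upper - big.ci_lower) < (small.ci_upper - small.ci_lower)


def test_cross_divide_spearman_invariant_to_monotone_transform(blackcap):
    from migradiv.differentiation import slatkin_matrix

    metadata, dest, _ = blackcap
    a = cross_divide_test(dest, metadata, resamples=200, seed=9)
    b = cross_divide_test(slatkin_matrix(dest), metadata, resamples=200, seed=9)
    assert a.rho == pytest.approx(b.rho, abs=1e-12)   # d vs d/(1-d): same ranks
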
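"""Geographic distances, Mantel isolation-by-distance tests, and the
cross-divide longitudinal permutation test.

Distances are great-circle (haversine, spherical Earth R = 6371 km).  The
``longitudinal`` mode zeroes every latitude first, giving the equatorial-arc
distance that depends on longitude only — the geometry used to ask whether
genetic distance grows with east-west separation across a migratory divide.

The Mantel test correlates the off-diagonal entries of a genetic and a
geographic distance matrix and assesses significance by jointly permuting the
row/column order of one matrix (one-sided toward positive association by
default, isolation-by-distance being directional).

The cross-divide test takes every west x east population pair across a given
divide longitude, computes the Spearman rank correlation between longitudinal
and genetic distance over those pairs, and compares it with a null
distribution obtained by permuting the geographic distance values across
pairs; the 2.5th/97.5th percentiles of the null form the 95% CI used to judge
significance.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import PairwiseMatrix, PopulationMetadata

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geo_distances(
    metadata: Sequence[PopulationMetadata], mode: str = "great-circle"
) -> PairwiseMatrix:
    """Pairwise distance matrix in km.

    ``mode="great-circle"``: haversine on the given coordinates.
    ``mode="longitudinal"``: haversine after setting every latitude to zero
    (equatorial arc; a strictly increasing function of |delta longitude|).
    """
    if mode not in ("great-circle", "longitudinal"):
        raise ValueError(f"unknown mode {mode!r}")
    codes = [m.code for m in metadata]
    lat = [0.0 if mode == "longitudinal" else m.latitude for m in metadata]
    lon = [m.longitude for m in metadata]
    k = len(codes)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = haversine_km(lat[i], lon[i], lat[j], lon[j])
            vals[i, j] = vals[j, i] = d
    return PairwiseMatrix(codes, vals, label=f"km ({mode})")


# ----------------------------------------------------------------------
@dataclass
class MantelResult:
    r: float
    p: float
    permutations: int
    seed: int | None
    alternative: str


def mantel_test(
    genetic: PairwiseMatrix,
    geographic: PairwiseMatrix,
    permutations: int = 10_000,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel matrix-correlation test.

    Pearson r over the n(n-1)/2 unordered off-diagonal pairs; the null is
    built by jointly permuting rows and columns of the genetic matrix.
    ``alternative`` is ``"greater"`` (default; positive association) or
    ``"two-sided"``.
    """
    if genetic.codes != geographic.codes:
        raise ValueError("matrices carry different population codes or order")
    k = len(genetic.codes)
    if k < 4:
        raise ValueError("need at least 4 populations")
    iu = np.triu_indices(k, 1)
    a = genetic.values[iu]
    b = geographic.values[iu]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant matrix: Mantel r undefined")
    obs = float(stats.pearsonr(a, b)[0])
    rng = np.random.default_rng(seed)
    bz = (b - b.mean()) / b.std()
    hits = 0
    A = genetic.values
    for _ in range(permutations):
        per = rng.permutation(k)
        ap = A[np.ix_(per, per)][iu]
        r = float(np.mean((ap - ap.mean()) / ap.std() * bz))
        if alternative == "greater":
            if r >= obs:
                hits += 1
        else:
            if abs(r) >= abs(obs):
                hits += 1
    return MantelResult(obs, (1 + hits) / (permutations + 1), permutations, seed, alternative)


# ----------------------------------------------------------------------
@dataclass
class CrossDivideResult:
    rho: float
    p: float
    ci_lower: float
    ci_upper: float
    resamples: int
    divide_longitude: float
    pairs: list[tuple[str, str]]
    seed: int | None

    @property
    def significant(self) -> bool:
        """Observed rho falls outside the null 95% CI."""
        return not (self.ci_lower <= self.rho <= self.ci_upper)


def split_by_divide(
    metadata: Sequence[PopulationMetadata], divide_longitude: float = 13.0
) -> tuple[list[str], list[str]]:
    """(west, east) population codes; west = longitude strictly below the divide."""
    west = [m.code for m in metadata if m.longitude < divide_longitude]
    east = [m.code for m in metadata if m.longitude >= divide_longitude]
    return west, east


def cross_divide_test(
    genetic: PairwiseMatrix,
    metadata: Sequence[PopulationMetadata],
    divide_longitude: float = 13.0,
    resamples: int = 10_000,
    seed: int | None = None,
    scheme: str = "permutation",
) -> CrossDivideResult:
    """Spearman correlation of longitudinal vs genetic distance over
    cross-divide pairs, with a resampling null CI.

    The null permutes (default) or bootstraps the vector of geographic
    distances across the pairs, recomputing rho each time; the 95% CI is the
    (2.5th, 97.5th) percentile interval of the null rho distribution.
    """
    md = [m for m in metadata if m.code in genetic.codes]
    west, east = split_by_divide(md, divide_longitude)
    if not west or not east:
        raise ValueError("need at least one population on each side of the divide")
    lon = {m.code: m.longitude for m in md}
    pairs = [(w, e) for w in west for e in east]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 cross-divide pairs")
    geo = np.array(
        [haversine_km(0.0, lon[w], 0.0, lon[e]) for w, e in pairs]
    )
    gen = np.array([genetic.get(w, e) for w, e in pairs])
    rho = float(stats.spearmanr(geo, gen)[0])
    rng = np.random.default_rng(seed)
    null = np.empty(resamples)
    for r in range(resamples):
        if scheme == "permutation":
            g = rng.permutation(geo)
        elif scheme == "bootstrap":
            g = rng.choice(geo, size=len(geo), replace=True)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        null[r] = stats.spearmanr(g, gen)[0]
    lo, hi = np.nanpercentile(null, [2.5, 97.5])
    p = float((1 + np.sum(np.abs(null) >= abs(rho))) / (resamples + 1))
    return CrossDivideResult(
        rho, p, float(lo), float(hi), resamples, divide_longitude, pairs, seed
    )
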
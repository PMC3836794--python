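"""Pairwise genetic differentiation and migratory-group comparisons.

The primary statistic is Jost's D in its unbiased (sample-size corrected)
form.  Per locus, for ``n`` populations with harmonic-mean sample size ``Ñ``::

    H_S_obs = 1 - mean_j sum_a p_ja^2
    H_S_est = (2Ñ / (2Ñ - 1)) * H_S_obs
    H_T_obs = 1 - sum_a (mean_j p_ja)^2
    H_T_est = H_T_obs + H_S_est / (2 Ñ n)
    D_est   = ((H_T_est - H_S_est) / (1 - H_S_est)) * n / (n - 1)

The multilocus value is the arithmetic mean of the per-locus values (clamped
at 0 from below for reporting; raw values are retained for permutation
nulls).  The complementary Weir-Cockerham theta (variance-components F_ST) is
also provided, as is the Slatkin transform d/(1-d) that linearises a
differentiation index into a genetic distance.

Significance of a pairwise D_est is assessed by randomly reassigning
individuals between the two populations (sizes preserved) and recomputing the
raw multilocus D_est; a bootstrap scheme (resampling individuals from the
pooled pair with replacement) is available behind a flag.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import (
    DIRECTIONS,
    MISSING,
    AlleleFrequencySet,
    GenotypeTable,
    PairwiseMatrix,
    PopulationMetadata,
    metadata_by_code,
)


@dataclass
class DifferentiationResult:
    """Per-locus and multilocus differentiation for one population set."""

    populations: list[str]
    loci: list[str]
    hs_est: np.ndarray
    ht_est: np.ndarray
    d_locus_raw: np.ndarray
    d_locus: np.ndarray          # clamped at 0 from below
    n_harmonic: np.ndarray
    n_populations: int
    d_multilocus: float
    d_multilocus_raw: float
    theta: float | None = None


def _dest_per_locus(
    freq: np.ndarray, nsizes: np.ndarray
) -> tuple[float, float, float, float]:
    """(hs_est, ht_est, d_raw, nharm) for one locus.

    ``freq``: (n_pops, n_alleles) frequencies; ``nsizes``: diploid sample
    sizes.  Returns NaN for d when the estimator degenerates (H_S_est >= 1,
    possible only at sample size 1).
    """
    n = freq.shape[0]
    hs_obs = 1.0 - np.mean(np.sum(freq * freq, axis=1))
    nharm = n / np.sum(1.0 / nsizes)
    hs_est = (2.0 * nharm) / (2.0 * nharm - 1.0) * hs_obs
    pbar = freq.mean(axis=0)
    ht_obs = 1.0 - np.sum(pbar * pbar)
    ht_est = ht_obs + hs_est / (2.0 * nharm * n)
    if 1.0 - hs_est <= 0:
        return hs_est, ht_est, np.nan, nharm
    d = (ht_est - hs_est) / (1.0 - hs_est) * n / (n - 1.0)
    return hs_est, ht_est, d, nharm


def jost_d(
    freqs: AlleleFrequencySet,
    populations: Sequence[str],
    aggregation: str = "mean",
) -> DifferentiationResult:
    """Unbiased Jost D over the given populations (>= 2).

    Loci without data in every requested population are dropped.
    ``aggregation`` is ``"mean"`` (arithmetic mean of clamped per-locus
    values, the default) or ``"harmonic"``.
    """
    pops = list(populations)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    pidx = [freqs.populations.index(p) for p in pops]
    hs, ht, draw, nh, loci = [], [], [], [], []
    for l, locus in enumerate(freqs.loci):
        nsizes = freqs.n[pidx, l]
        if (nsizes == 0).any():
            continue
        f = freqs.counts[l][pidx] / (2.0 * nsizes[:, None])
        r = _dest_per_locus(f, nsizes.astype(float))
        hs.append(r[0]); ht.append(r[1]); draw.append(r[2]); nh.append(r[3])
        loci.append(locus)
    if not loci:
        raise ValueError(f"no shared loci among populations {pops}")
    draw = np.asarray(draw)
    clamped = np.clip(draw, 0.0, None)
    valid = ~np.isnan(draw)
    if aggregation == "mean":
        multi = float(np.mean(clamped[valid]))
    elif aggregation == "harmonic":
        c = clamped[valid]
        multi = 0.0 if (c <= 0).any() else float(len(c) / np.sum(1.0 / c))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return DifferentiationResult(
        pops, loci, np.asarray(hs), np.asarray(ht), draw, clamped,
        np.asarray(nh), len(pops), multi, float(np.mean(draw[valid])),
    )


def dest_pairwise(
    freqs: AlleleFrequencySet, pop_a: str, pop_b: str, aggregation: str = "mean"
) -> DifferentiationResult:
    """Unbiased Jost D between two populations."""
    return jost_d(freqs, [pop_a, pop_b], aggregation=aggregation)


def dest_matrix(
    freqs: AlleleFrequencySet, aggregation: str = "mean"
) -> PairwiseMatrix:
    """All pairwise multilocus D_est values (clamped) as a symmetric matrix."""
    codes = freqs.populations
    k = len(codes)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = dest_pairwise(freqs, codes[i], codes[j], aggregation).d_multilocus
            vals[i, j] = vals[j, i] = d
    return PairwiseMatrix(codes, vals, label="D_est")


# ----------------------------------------------------------------------
def _pair_dosage(table: GenotypeTable, pop_a: str, pop_b: str):
    """One-hot allele dosage matrix for the individuals of a pair.

    Returns (X, present, slices, sizes) where X is (n_ind, total_alleles)
    dosages, ``present`` is (n_ind, n_loci) data-presence flags, ``slices``
    maps locus -> column slice, and ``sizes`` = (nA, nB).
    """
    ia = table.individuals_of(pop_a)
    ib = table.individuals_of(pop_b)
    idx = np.concatenate([ia, ib])
    slices = []
    start = 0
    for l in range(table.n_loci):
        k = len(table.allele_names[l])
        slices.append(slice(start, start + k))
        start += k
    X = np.zeros((len(idx), start))
    present = np.zeros((len(idx), table.n_loci))
    for l in range(table.n_loci):
        a = table.codes[idx, l, 0]
        b = table.codes[idx, l, 1]
        ok = a != MISSING
        rows = np.flatnonzero(ok)
        base = slices[l].start
        np.add.at(X, (rows, base + a[ok]), 1.0)
        np.add.at(X, (rows, base + b[ok]), 1.0)
        present[ok, l] = 1.0
    return X, present, slices, (len(ia), len(ib))


def _dest_multilocus_from_counts(
    ca: np.ndarray, cb: np.ndarray, na: np.ndarray, nb: np.ndarray, slices
) -> np.ndarray:
    """Raw multilocus D_est for a batch of replicates.

    ``ca``/``cb``: (R, total_alleles) allele counts; ``na``/``nb``: (R,
    n_loci) diploid sample sizes.  Loci with a zero sample in either member
    of a replicate are dropped from that replicate's mean.
    """
    R = ca.shape[0]
    d = np.full((R, len(slices)), np.nan)
    for l, sl in enumerate(slices):
        nal, nbl = na[:, l], nb[:, l]
        ok = (nal > 0) & (nbl > 0)
        if not ok.any():
            continue
        fa = ca[ok, sl] / (2.0 * nal[ok, None])
        fb = cb[ok, sl] / (2.0 * nbl[ok, None])
        hs_obs = 1.0 - 0.5 * (np.sum(fa * fa, axis=1) + np.sum(fb * fb, axis=1))
        nharm = 2.0 / (1.0 / nal[ok] + 1.0 / nbl[ok])
        hs_est = (2 * nharm) / (2 * nharm - 1) * hs_obs
        pbar = 0.5 * (fa + fb)
        ht_obs = 1.0 - np.sum(pbar * pbar, axis=1)
        ht_est = ht_obs + hs_est / (4.0 * nharm)
        denom = 1.0 - hs_est
        dl = np.where(denom > 0, (ht_est - hs_est) / np.where(denom > 0, denom, 1.0) * 2.0, np.nan)
        d[ok, l] = dl
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(d, axis=1)


def dest_significance(
    table: GenotypeTable,
    pop_a: str,
    pop_b: str,
    reps: int = 999,
    seed: int | None = None,
    scheme: str = "permutation",
) -> float:
    """Permutation p-value for pairwise D_est > 0.

    Under ``scheme="permutation"`` (default) individuals are randomly
    reassigned between the two populations with sizes preserved — the
    exchangeable null.  ``scheme="bootstrap"`` draws both pseudo-populations
    from the pooled pair with replacement.  One-sided:
    ``p = (1 + #{replicate >= observed}) / (reps + 1)`` on the raw
    (unclamped) multilocus D_est.
    """
    if reps < 100:
        raise ValueError("reps < 100 gives an unstable p-value")
    X, present, slices, (na, nb) = _pair_dosage(table, pop_a, pop_b)
    n = na + nb
    if n < 4:
        raise ValueError("combined sample size < 4")
    rng = np.random.default_rng(seed)
    sel = np.zeros((1, n)); sel[0, :na] = 1.0
    obs = _dest_multilocus_from_counts(
        sel @ X, (1 - sel) @ X, sel @ present, (1 - sel) @ present, slices
    )[0]
    A = np.zeros((reps, n))
    if scheme == "permutation":
        for r in range(reps):
            A[r, rng.permutation(n)[:na]] = 1.0
        B = 1.0 - A
        cb_counts, nb_sizes = B @ X, B @ present
    elif scheme == "bootstrap":
        B = np.zeros((reps, n))
        for r in range(reps):
            np.add.at(A[r], rng.integers(0, n, na), 1.0)
            np.add.at(B[r], rng.integers(0, n, nb), 1.0)
        cb_counts, nb_sizes = B @ X, B @ present
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    null = _dest_multilocus_from_counts(A @ X, cb_counts, A @ present, nb_sizes, slices)
    hits = np.sum(np.nan_to_num(null, nan=-np.inf) >= obs)
    return float((1 + hits) / (reps + 1))


def dest_matrix_with_significance(
    table: GenotypeTable,
    reps: int = 999,
    seed: int | None = None,
    aggregation: str = "mean",
) -> PairwiseMatrix:
    """Pairwise D_est matrix with permutation p-values."""
    from .diversity import allele_frequencies

    freqs = allele_frequencies(table)
    mat = dest_matrix(freqs, aggregation=aggregation)
    k = len(mat.codes)
    pv = np.full((k, k), np.nan)
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(k * (k - 1) // 2))
    for i in range(k):
        for j in range(i + 1, k):
            p = dest_significance(table, mat.codes[i], mat.codes[j], reps=reps, seed=int(next(seeds)))
            pv[i, j] = pv[j, i] = p
    return PairwiseMatrix(mat.codes, mat.values, pv, label="D_est")


# ----------------------------------------------------------------------
def wc_fst(
    freqs: AlleleFrequencySet, pop_a: str, pop_b: str
) -> float:
    """Weir-Cockerham theta between two populations (multilocus ratio of sums)."""
    return wc_fst_multi(freqs, [pop_a, pop_b])


def wc_fst_multi(freqs: AlleleFrequencySet, populations: Sequence[str]) -> float:
    """Weir-Cockerham (1984) theta over >= 2 populations.

    Moment estimator from among-population (a), among-individual-within-
    population (b) and within-individual (c) variance components, summed over
    alleles and loci: theta = sum(a) / sum(a + b + c).
    """
    if not freqs.het_by_allele:
        raise ValueError("frequency set lacks per-allele heterozygote counts")
    pidx = [freqs.populations.index(p) for p in populations]
    r = len(pidx)
    if r < 2:
        raise ValueError("need at least two populations")
    num = den = 0.0
    for l in range(len(freqs.loci)):
        nsz = freqs.n[pidx, l].astype(float)
        if (nsz == 0).any():
            continue
        nbar = nsz.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - np.sum(nsz * nsz) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        p = freqs.counts[l][pidx] / (2.0 * nsz[:, None])
        hobs = freqs.het_by_allele[l][pidx] / nsz[:, None]
        pbar = np.sum(nsz[:, None] * p, axis=0) / (r * nbar)
        s2 = np.sum(nsz[:, None] * (p - pbar) ** 2, axis=0) / ((r - 1) * nbar)
        hbar = np.sum(nsz[:, None] * hobs, axis=0) / (r * nbar)
        pq = pbar * (1 - pbar)
        a = (nbar / nc) * (s2 - (pq - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        num += float(np.sum(a))
        den += float(np.sum(a + b + c))
    if den == 0:
        return 0.0
    return num / den


def fst_matrix(freqs: AlleleFrequencySet) -> PairwiseMatrix:
    codes = freqs.populations
    k = len(codes)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vals[i, j] = vals[j, i] = wc_fst(freqs, codes[i], codes[j])
    return PairwiseMatrix(codes, vals, label="theta_WC")


# ----------------------------------------------------------------------
def slatkin_transform(d):
    """Genetic distance d/(1-d); negative d is clamped to 0, d >= 1 rejected."""
    arr = np.asarray(d, dtype=float)
    if (arr >= 1.0).any():
        raise ValueError("differentiation value >= 1 has no finite distance")
    arr = np.clip(arr, 0.0, None)
    out = arr / (1.0 - arr)
    return float(out) if np.isscalar(d) or out.ndim == 0 else out


def slatkin_matrix(dest: PairwiseMatrix) -> PairwiseMatrix:
    vals = slatkin_transform(dest.values.copy())
    np.fill_diagonal(vals, 0.0)
    return PairwiseMatrix(dest.codes, vals, label="D_est/(1-D_est)")


# ----------------------------------------------------------------------
def classify_pair_group(
    metadata: Sequence[PopulationMetadata], pop_a: str, pop_b: str
) -> str:
    """Migratory-orientation group of a pair: within-X or X-vs-Y (unordered)."""
    md = metadata_by_code(metadata)
    try:
        da, db = md[pop_a].direction, md[pop_b].direction
    except KeyError as e:
        raise KeyError(f"population {e.args[0]!r} missing from metadata") from None
    if da == db:
        return f"within-{da}"
    x, y = sorted((da, db), key=DIRECTIONS.index)
    return f"{x}-vs-{y}"


def pair_group_values(
    matrix: PairwiseMatrix, metadata: Sequence[PopulationMetadata]
) -> dict[str, list[float]]:
    """Group every off-diagonal value of the matrix by migratory orientation."""
    out: dict[str, list[float]] = {}
    k = len(matrix.codes)
    for i in range(k):
        for j in range(i + 1, k):
            g = classify_pair_group(metadata, matrix.codes[i], matrix.codes[j])
            out.setdefault(g, []).append(float(matrix.values[i, j]))
    return out


def compare_group_distributions(
    matrix: PairwiseMatrix,
    metadata: Sequence[PopulationMetadata],
    group_x: str,
    group_y: str,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two pair groups.

    Exact enumeration when both groups have <= 25 values and no ties; normal
    approximation with tie and continuity correction otherwise (matching R's
    ``wilcox.test`` defaults).  Returns (U statistic, p).
    """
    groups = pair_group_values(matrix, metadata)
    for g in (group_x, group_y):
        if g not in groups or not groups[g]:
            raise ValueError(f"group {g!r} is empty")
    x, y = groups[group_x], groups[group_y]
    if min(len(x), len(y)) < 2:
        warnings.warn("a group has < 2 values; the test may be uninformative")
    ties = len(set(x) | set(y)) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
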
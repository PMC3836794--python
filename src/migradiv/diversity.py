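"""Per-population diversity statistics and Hardy-Weinberg tests.

Implements the classic microsatellite summary columns: effective number of
alleles A_E = 1/sum(p_i^2), observed heterozygosity H_O, and the unbiased
expected heterozygosity H_E = (2N/(2N-1)) * (1 - sum(p_i^2)).  Population
values are unweighted means over loci with standard errors over loci
(n-1 denominator).

Hardy-Weinberg departures are tested one-sidedly against heterozygote
deficiency with a Monte-Carlo exact test conditional on the observed allele
counts: the allele pool of a population x locus cell is randomly re-paired
into diploids and the observed heterozygote count compared with the null
distribution.  Multiple tests are corrected with Storey q-values.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MISSING, AlleleFrequencySet, GenotypeTable


def allele_frequencies(table: GenotypeTable) -> AlleleFrequencySet:
    """Count alleles per population x locus (locus-wise complete case).

    Every non-missing diploid genotype contributes two allele observations;
    individuals missing at a locus are excluded from that locus only.
    """
    n_pop = len(table.populations)
    counts = []
    het_by_allele = []
    n = np.zeros((n_pop, table.n_loci), dtype=np.int64)
    het = np.zeros((n_pop, table.n_loci), dtype=np.int64)
    for l in range(table.n_loci):
        k = len(table.allele_names[l])
        c = np.zeros((n_pop, max(k, 1)), dtype=np.int64)
        h = np.zeros((n_pop, max(k, 1)), dtype=np.int64)
        a = table.codes[:, l, 0]
        b = table.codes[:, l, 1]
        ok = a != MISSING
        pops = table.pop_index[ok]
        np.add.at(c, (pops, a[ok]), 1)
        np.add.at(c, (pops, b[ok]), 1)
        np.add.at(n[:, l], pops, 1)
        hmask = ok & (a != b)
        np.add.at(het[:, l], table.pop_index[hmask], 1)
        np.add.at(h, (table.pop_index[hmask], a[hmask]), 1)
        np.add.at(h, (table.pop_index[hmask], b[hmask]), 1)
        counts.append(c)
        het_by_allele.append(h)
    return AlleleFrequencySet(
        list(table.populations), list(table.loci), [list(x) for x in table.allele_names],
        counts, n, het, het_by_allele,
    )


def effective_alleles(p: np.ndarray) -> float:
    """A_E = 1 / sum(p^2) for one frequency vector."""
    p = np.asarray(p, dtype=float)
    return float(1.0 / np.sum(p * p))


def unbiased_expected_heterozygosity(p: np.ndarray, n: int) -> float:
    """(2N/(2N-1)) * (1 - sum p^2) for a sample of ``n`` diploids."""
    p = np.asarray(p, dtype=float)
    return float((2 * n) / (2 * n - 1) * (1.0 - np.sum(p * p)))


def diversity_summary(freqs: AlleleFrequencySet) -> pd.DataFrame:
    """Per-population A_E, H_O and unbiased H_E with SEs over loci.

    Population x locus cells with no data are excluded from that population's
    means.  Returns a DataFrame indexed by population code.
    """
    rows = []
    n_loci = len(freqs.loci)
    for pi, pop in enumerate(freqs.populations):
        ae, ho, he = [], [], []
        for l in range(n_loci):
            nl = int(freqs.n[pi, l])
            if nl == 0:
                continue
            p = freqs.counts[l][pi] / (2.0 * nl)
            ae.append(effective_alleles(p))
            ho.append(freqs.het[pi, l] / nl)
            he.append(unbiased_expected_heterozygosity(p, nl))
        rows.append(
            {
                "population": pop,
                "n_loci": len(ae),
                "ae": np.mean(ae),
                "ae_se": _se(ae),
                "ho": np.mean(ho),
                "ho_se": _se(ho),
                "he": np.mean(he),
                "he_se": _se(he),
            }
        )
    return pd.DataFrame(rows).set_index("population")


def _se(x: list[float]) -> float:
    if len(x) < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


# ----------------------------------------------------------------------
def hwe_heterozygote_deficiency_test(
    table: GenotypeTable,
    population: str,
    locus: str,
    reps: int = 10_000,
    seed: int | None = None,
) -> float:
    """One-sided Monte-Carlo exact test against heterozygote deficiency.

    The observed allele pool is re-paired at random ``reps`` times (permutation
    without replacement, i.e. the exact-test null conditional on allele
    counts) and ``p = (1 + #{het <= observed}) / (reps + 1)``.  Monomorphic or
    single-individual cells return 1 by convention.
    """
    if reps < 100:
        raise ValueError("reps < 100 gives an unstable p-value")
    p = table.populations.index(population)
    l = table.loci.index(locus)
    sel = (table.pop_index == p) & (table.codes[:, l, 0] != MISSING)
    g = table.codes[sel, l, :]
    if g.shape[0] < 2:
        return 1.0
    pool = g.ravel()
    if len(np.unique(pool)) < 2:
        return 1.0
    obs = int(np.sum(g[:, 0] != g[:, 1]))
    rng = np.random.default_rng(seed)
    count = 0
    pool = pool.copy()
    for _ in range(reps):
        rng.shuffle(pool)
        pairs = pool.reshape(-1, 2)
        if int(np.sum(pairs[:, 0] != pairs[:, 1])) <= obs:
            count += 1
    return (1 + count) / (reps + 1)


def hwe_test_all(
    table: GenotypeTable, reps: int = 10_000, seed: int | None = None
) -> pd.DataFrame:
    """HWE deficiency p- and q-values for every population x locus cell.

    Returns a long-format DataFrame (population, locus, p, q); q-values are
    computed over all tests jointly, mirroring a study-wide FDR correction.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(table.populations) * table.n_loci)
    rows = []
    k = 0
    for pop in table.populations:
        for loc in table.loci:
            pv = hwe_heterozygote_deficiency_test(table, pop, loc, reps=reps, seed=int(seeds[k]))
            rows.append({"population": pop, "locus": loc, "p": pv})
            k += 1
    df = pd.DataFrame(rows)
    df["q"] = qvalue_correct(df["p"].to_list())
    return df


# ----------------------------------------------------------------------
def qvalue_correct(pvalues: list[float] | np.ndarray, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single fixed lambda.

    ``pi0 = min(1, #{p > lambda} / ((1 - lambda) m))``; q-values are the
    step-up-enforced ``pi0 * m * p_(i) / i``, capped at 1.  Empty input
    returns an empty array.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = min(1.0, np.sum(p > lambda_) / ((1.0 - lambda_) * m))
    order = np.argsort(p, kind="stable")
    q = pi0 * m * p[order] / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
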
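"""Hierarchical F-statistics: nested partition of genetic variance.

Populations are nested inside migratory-distance classes, which are nested
inside migratory directions (direction / distance / population, coarse to
fine); below the population sit the individual and the within-individual
(gamete) levels.  Variance components are estimated by the moment (nested
ANOVA) method applied to allele-indicator variables on gametes: for each
locus the sums of squares between the groups of every level are equated to
their expectations under the nested random-effects model (unbalanced-design
coefficients), the linear system is solved per locus, and components are
pooled by summation over alleles and loci.  F-statistics are ratios of
cumulative components: the F between a level i and an enclosing level j is

    F_{i/j} = (sum of components from just below j down through i)
              / (sum of components from just below j to the bottom)

so that with population as the only grouping level, F_{pop/total} is the
classic variance-components F_ST.  Negative component estimates are retained
(not clamped) in the ratios.

Each level is tested by permuting its units among the cells of the enclosing
level while keeping the structure below intact: whole distance cells are
shuffled among directions, populations among distance cells within a
direction, and individuals among populations within a distance cell.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeTable, PopulationMetadata


@dataclass
class HierarchicalDesign:
    """Nested grouping of populations, coarse to fine, above the population.

    ``groupings`` is an ordered list of ``(level name, {population: label})``
    pairs; nesting is enforced by building composite cells internally, so a
    label reused under two different parent cells denotes two distinct units.
    An empty list gives the population-only design.
    """

    populations: list[str]
    groupings: list[tuple[str, dict[str, str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, mapping in self.groupings:
            absent = [p for p in self.populations if p not in mapping]
            if absent:
                raise ValueError(f"level {name!r}: populations without a label: {absent}")

    @property
    def level_names(self) -> list[str]:
        return [n for n, _ in self.groupings] + ["population", "individual"]

    def cell_keys(self) -> list[list[tuple]]:
        """Per grouping level, the composite (nested) cell key of every population."""
        keys: list[list[tuple]] = []
        prev: list[tuple] = [() for _ in self.populations]
        for _, mapping in self.groupings:
            cur = [prev[i] + (mapping[p],) for i, p in enumerate(self.populations)]
            keys.append(cur)
            prev = cur
        return keys

    @classmethod
    def from_metadata(
        cls,
        metadata: Sequence[PopulationMetadata],
        populations: Sequence[str] | None = None,
        variant: str = "A",
        reclassify: dict[str, str] | None = None,
    ) -> "HierarchicalDesign":
        """Direction / distance / population design from site metadata.

        ``variant="A"`` uses directions as recorded; ``variant="B"``
        reclassifies the Oslo population (code ``Os``) as a SE migrant,
        reflecting the broad-front autumn orientation of south-Norwegian
        breeders.  ``reclassify`` overrides directions for arbitrary codes.
        """
        md = {m.code: m for m in metadata}
        pops = list(populations) if populations is not None else [m.code for m in metadata]
        direction = {p: md[p].direction for p in pops}
        if variant == "B" and "Os" in direction:
            direction["Os"] = "SE"
        elif variant not in ("A", "B"):
            raise ValueError("variant must be 'A' or 'B'")
        if reclassify:
            direction.update(reclassify)
        distance = {p: md[p].distance_class for p in pops}
        return cls(pops, [("direction", direction), ("distance", distance)])


@dataclass
class HierFResult:
    """Variance components (pooled and per locus) and the F-statistic table."""

    levels: list[str]                  # groupings + population, individual, within
    components: pd.Series              # pooled variance components per level
    components_per_locus: pd.DataFrame
    fstats: pd.DataFrame               # F[level i, within level j]; NaN where undefined

    def f(self, level: str, within: str = "total") -> float:
        return float(self.fstats.loc[level, within])


# ----------------------------------------------------------------------
def _assignments(table: GenotypeTable, design: HierarchicalDesign) -> list[np.ndarray]:
    """Per hierarchy level (groupings, population, individual), the dense
    group index of every individual."""
    pop_of = [table.populations[i] for i in table.pop_index]
    pop_pos = {p: i for i, p in enumerate(design.populations)}
    for p in table.populations:
        if p not in pop_pos:
            raise ValueError(f"population {p!r} missing from the design")
    out: list[np.ndarray] = []
    for keys in design.cell_keys():
        uniq: dict[tuple, int] = {}
        per_pop = [uniq.setdefault(keys[pop_pos[p]], len(uniq)) for p in design.populations]
        out.append(np.array([per_pop[pop_pos[p]] for p in pop_of]))
    out.append(np.array([pop_pos[p] for p in pop_of]))
    out.append(np.arange(table.n_individuals))
    return out


def _dosage_matrix(table: GenotypeTable):
    """(X, present, col_locus): one-hot allele dosages, data-presence flags,
    and the locus index of every dosage column."""
    col_locus = []
    starts = []
    start = 0
    for l in range(table.n_loci):
        k = len(table.allele_names[l])
        starts.append(start)
        col_locus.extend([l] * k)
        start += k
    X = np.zeros((table.n_individuals, start))
    present = np.zeros((table.n_individuals, table.n_loci))
    for l in range(table.n_loci):
        a = table.codes[:, l, 0]
        b = table.codes[:, l, 1]
        ok = a != MISSING
        rows = np.flatnonzero(ok)
        np.add.at(X, (rows, starts[l] + a[ok]), 1.0)
        np.add.at(X, (rows, starts[l] + b[ok]), 1.0)
        present[ok, l] = 1.0
    return X, present, np.asarray(col_locus)


def _group_sum(values: np.ndarray, idx: np.ndarray, n_groups: int) -> np.ndarray:
    onehot = np.zeros((n_groups, len(idx)))
    onehot[idx, np.arange(len(idx))] = 1.0
    return onehot @ values


def _components_from_data(
    X: np.ndarray,
    present: np.ndarray,
    col_locus: np.ndarray,
    assignments: list[np.ndarray],
) -> np.ndarray:
    """Moment variance components per level and locus.

    Returns ``(n_levels + 1, n_loci)``: one row per grouping level (coarse to
    fine, including population and individual), last row = within-individual.
    Raises if a level adds no degrees of freedom (single effective unit).
    """
    n_loci = present.shape[1]
    L = len(assignments)
    sums, sizes = [], []
    for a in assignments:
        g = int(a.max()) + 1
        sums.append(_group_sum(X, a, g))
        sizes.append(2.0 * _group_sum(present, a, g))
    M = 2.0 * present.sum(axis=0)                     # gametes per locus
    has_data = M > 0

    def t_of(S: np.ndarray, m: np.ndarray) -> np.ndarray:
        me = m[:, col_locus]
        Z = np.divide(S * S, me, out=np.zeros_like(S), where=me > 0)
        return np.bincount(col_locus, weights=Z.sum(axis=0), minlength=n_loci)

    T = [t_of(X.sum(axis=0, keepdims=True), M[None, :])]
    T += [t_of(S, m) for S, m in zip(sums, sizes)]
    T_obs = np.bincount(col_locus, weights=X.sum(axis=0), minlength=n_loci)
    SS = np.stack([T[j + 1] - T[j] for j in range(L)] + [T_obs - T[L]])

    ngroups = np.stack([(m > 0).sum(axis=0) for m in sizes])   # (L, n_loci)
    # expectation coefficients for T_0, T_1..T_L and T_obs, per locus
    coef = np.zeros((L + 2, L + 1, n_loci))
    for k in range(L):
        q = sizes[k] ** 2                                      # (g_k, n_loci)
        coef[0, k] = np.divide(q.sum(axis=0), M, out=np.zeros(n_loci), where=has_data)
        for j in range(1, L + 1):
            if k < j - 1:
                coef[j, k] = M
            else:
                # sum over groups g at level j of sum_{h at level k in g} m_h^2 / m_g
                fo = np.empty(int(assignments[k].max()) + 1, dtype=int)
                fo[assignments[k]] = assignments[j - 1]
                gj = int(assignments[j - 1].max()) + 1
                agg = np.zeros((gj, n_loci))
                np.add.at(agg, fo, q)
                mj = sizes[j - 1]
                coef[j, k] = np.divide(agg, mj, out=np.zeros_like(agg), where=mj > 0).sum(axis=0)
    coef[0, L] = has_data.astype(float)
    for j in range(1, L + 1):
        coef[j, L] = ngroups[j - 1]
    coef[L + 1, :, :] = M                                      # T_obs row

    A = coef[1:] - coef[:-1]                                   # (L+1, L+1, n_loci) expected-SS rows
    df = np.vstack([ngroups, [M / 2.0]]) - np.vstack([np.ones(n_loci), ngroups])
    if (df[:-1, has_data] <= 0).any():
        bad = int(np.argmax((df[:-1, has_data] <= 0).any(axis=1)))
        raise ValueError(f"hierarchy level index {bad} adds no degrees of freedom (single unit)")

    comps = np.zeros((L + 1, n_loci))
    idx = np.flatnonzero(has_data)
    if idx.size:
        Ab = A[:, :, idx].transpose(2, 0, 1)                   # (loci, L+1, L+1)
        ssb = SS[:, idx].T[:, :, None]
        comps[:, idx] = np.linalg.solve(Ab, ssb)[:, :, 0].T
    return comps


def hier_fstats(table: GenotypeTable, design: HierarchicalDesign) -> HierFResult:
    """Hierarchical variance components and F-statistics for a design."""
    assignments = _assignments(table, design)
    X, present, col_locus = _dosage_matrix(table)
    comps = _components_from_data(X, present, col_locus, assignments)
    levels = design.level_names + ["within"]
    pooled = comps.sum(axis=1)
    per_locus = pd.DataFrame(comps.T, index=table.loci, columns=levels)
    total = pooled.sum()
    fst = pd.DataFrame(np.nan, index=levels[:-1], columns=["total"] + levels[:-2])
    cum = np.cumsum(pooled)
    for i, li in enumerate(levels[:-1]):
        fst.loc[li, "total"] = cum[i] / total if total != 0 else np.nan
        for j in range(i):
            denom = total - cum[j]
            fst.loc[li, levels[j]] = (cum[i] - cum[j]) / denom if denom != 0 else np.nan
    return HierFResult(levels, pd.Series(pooled, index=levels), per_locus, fst)


# ----------------------------------------------------------------------
def _level_statistic(pooled: np.ndarray, level_idx: int) -> float:
    """F of a level within its enclosing level, from pooled components."""
    total = pooled.sum()
    above = pooled[:level_idx].sum()
    denom = total - above
    return float(pooled[level_idx] / denom) if denom != 0 else np.nan


def hier_permutation_test(
    table: GenotypeTable,
    design: HierarchicalDesign,
    level: str,
    permutations: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for the structuring effect of one level.

    The tested level's units are permuted among the cells of the enclosing
    level with everything below kept intact: distance cells among directions,
    populations among distance cells (within direction), individuals among
    populations (within distance cell).  The statistic is the level's F
    within its enclosing level; ``p = (1 + #{>= observed}) / (perms + 1)``.
    """
    if permutations < 100:
        raise ValueError("permutations < 100 gives an unstable p-value")
    level_names = design.level_names[:-1]   # groupings + population
    if level not in level_names:
        raise ValueError(f"unknown level {level!r}; choose from {level_names}")
    li = level_names.index(level)
    base = _assignments(table, design)

    n_grouping = len(base) - 1              # groupings incl. population
    unit_idx = base[li + 1] if li + 1 < n_grouping else np.arange(table.n_individuals)
    parent_idx = base[li - 1] if li > 0 else np.zeros(table.n_individuals, dtype=int)
    tested_idx = base[li]
    n_units = int(unit_idx.max()) + 1
    unit_parent = np.full(n_units, -1, dtype=int)
    unit_label = np.full(n_units, -1, dtype=int)
    unit_parent[unit_idx] = parent_idx
    unit_label[unit_idx] = tested_idx
    parents = np.unique(unit_parent)
    if all(
        len(np.unique(unit_label[unit_parent == pc])) < 2 for pc in parents
    ):
        raise ValueError(
            f"level {level!r} untestable: a single cell within every enclosing unit"
        )
    members_of = [np.flatnonzero(unit_parent == pc) for pc in parents]

    X, present, col_locus = _dosage_matrix(table)
    obs = _level_statistic(
        _components_from_data(X, present, col_locus, base).sum(axis=1), li
    )
    rng = np.random.default_rng(seed)

    hits = 0
    perm_assign = list(base)
    for _ in range(permutations):
        new_label = unit_label.copy()
        for members in members_of:
            new_label[members] = unit_label[members][rng.permutation(len(members))]
        perm_assign[li] = new_label[unit_idx]
        stat = _level_statistic(
            _components_from_data(X, present, col_locus, perm_assign).sum(axis=1), li
        )
        if stat >= obs:
            hits += 1
    return (1 + hits) / (permutations + 1)


def exclude_individuals(table: GenotypeTable, ids: Sequence[str]) -> GenotypeTable:
    """Convenience wrapper to drop specific individuals (e.g. an
    isotope-identified vagrant) before variance partitioning."""
    return table.subset(drop_individuals=ids)
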
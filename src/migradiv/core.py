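"""Core in-memory containers shared across the analysis modules.

The central object is :class:`GenotypeTable`, a compact integer-coded store of
co-dominant diploid multi-locus genotypes (microsatellites) grouped into
populations.  Allele identifiers are opaque string labels: no size or repeat
semantics are attached to them.  Heterozygous genotypes are stored as
unordered pairs (the two allele slots are sorted), since every downstream
statistic is order-invariant.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

DIRECTIONS = ("NW", "SW", "SE")
DISTANCE_CLASSES = ("short", "intermediate", "long")

#: aliases accepted on input for the closed distance-class vocabulary
_DISTANCE_ALIASES = {"intermed": "intermediate", "interm": "intermediate"}


@dataclass(frozen=True)
class PopulationMetadata:
    """Sampling-site record: coordinates plus migratory classification.

    Coordinates are decimal degrees (WGS84 assumed; no projection is ever
    performed).  ``direction`` is the autumn migratory direction and
    ``distance_class`` the migratory distance category, both drawn from closed
    vocabularies.
    """

    code: str
    latitude: float
    longitude: float
    direction: str
    distance_class: str
    name: str = ""
    n: int | None = None
    breeding_season_sample: bool = True

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.code}: latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"{self.code}: longitude {self.longitude} outside [-180, 180]")
        dist = _DISTANCE_ALIASES.get(self.distance_class, self.distance_class)
        object.__setattr__(self, "distance_class", dist)
        if self.direction not in DIRECTIONS:
            raise ValueError(f"{self.code}: unknown migratory direction {self.direction!r}")
        if dist not in DISTANCE_CLASSES:
            raise ValueError(f"{self.code}: unknown distance class {self.distance_class!r}")


def metadata_by_code(metadata: Sequence[PopulationMetadata]) -> dict[str, PopulationMetadata]:
    out: dict[str, PopulationMetadata] = {}
    for m in metadata:
        if m.code in out:
            raise ValueError(f"duplicate population code {m.code!r} in metadata")
        out[m.code] = m
    return out


class GenotypeTable:
    """Diploid multi-locus genotypes for individuals grouped into populations.

    Parameters
    ----------
    populations:
        Ordered population codes.
    loci:
        Ordered locus names (must be unique).
    allele_names:
        Per locus, the ordered allele universe (list of string labels).
    pop_index:
        For each individual, the index of its population.
    codes:
        ``(n_individuals, n_loci, 2)`` integer array of allele indices into
        the per-locus universe; ``-1`` in either slot marks a missing
        genotype.  Pairs are stored sorted (unordered genotypes).
    individual_ids:
        Optional individual labels; generated if omitted.
    """

    def __init__(
        self,
        populations: Sequence[str],
        loci: Sequence[str],
        allele_names: Sequence[Sequence[str]],
        pop_index: np.ndarray,
        codes: np.ndarray,
        individual_ids: Sequence[str] | None = None,
    ) -> None:
        self.populations = list(populations)
        self.loci = list(loci)
        self.allele_names = [list(a) for a in allele_names]
        self.pop_index = np.asarray(pop_index, dtype=np.int64)
        codes = np.asarray(codes, dtype=np.int32)
        # normalise to unordered pairs; propagate missingness to both slots
        codes = np.sort(codes, axis=2)
        miss = (codes[:, :, 0] == MISSING) | (codes[:, :, 1] == MISSING)
        codes[miss] = MISSING
        self.codes = codes
        if individual_ids is None:
            individual_ids = [
                f"{self.populations[p]}_{i}" for i, p in enumerate(self.pop_index)
            ]
        self.individual_ids = list(individual_ids)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def population_sizes(self) -> dict[str, int]:
        counts = np.bincount(self.pop_index, minlength=len(self.populations))
        return dict(zip(self.populations, counts.tolist()))

    def individuals_of(self, population: str) -> np.ndarray:
        return np.flatnonzero(self.pop_index == self.populations.index(population))

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus names")
        if len(self.populations) == 0:
            raise ValueError("table contains zero populations")
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("duplicate population codes")
        if self.codes.shape != (len(self.pop_index), self.n_loci, 2):
            raise ValueError("genotype array shape does not match individuals x loci x 2")
        if len(self.individual_ids) != self.n_individuals:
            raise ValueError("individual id count mismatch")
        sizes = np.bincount(self.pop_index, minlength=len(self.populations))
        if (sizes < 1).any() or self.pop_index.max(initial=-1) >= len(self.populations):
            raise ValueError("every population must contain at least one individual")
        for l, names in enumerate(self.allele_names):
            col = self.codes[:, l, :]
            if col.max(initial=MISSING) >= len(names):
                raise ValueError(f"locus {self.loci[l]}: allele index outside universe")

    # ------------------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: Mapping[str, Sequence[Sequence[tuple[str, str] | None]]],
        loci: Sequence[str],
        individual_ids: Mapping[str, Sequence[str]] | None = None,
    ) -> "GenotypeTable":
        """Build a table from nested python data.

        ``records`` maps population code -> list of individuals, each a list
        (one entry per locus) of ``(allele, allele)`` string pairs or ``None``
        for missing.
        """
        populations = list(records)
        loci = list(loci)
        universe: list[dict[str, int]] = [dict() for _ in loci]
        rows: list[np.ndarray] = []
        pop_index: list[int] = []
        ids: list[str] = []
        for p, code in enumerate(populations):
            indivs = records[code]
            given = list(individual_ids[code]) if individual_ids else None
            for k, geno in enumerate(indivs):
                if len(geno) != len(loci):
                    raise ValueError(f"{code}: individual {k} has {len(geno)} loci, expected {len(loci)}")
                row = np.full((len(loci), 2), MISSING, dtype=np.int32)
                for l, g in enumerate(geno):
                    if g is None:
                        continue
                    a, b = g
                    for s, al in enumerate((str(a), str(b))):
                        row[l, s] = universe[l].setdefault(al, len(universe[l]))
                rows.append(row)
                pop_index.append(p)
                ids.append(given[k] if given else f"{code}_{k + 1}")
        allele_names = [list(u) for u in universe]
        return cls(populations, loci, allele_names, np.array(pop_index), np.array(rows), ids)

    def genotype(self, individual: int, locus: int) -> tuple[str, str] | None:
        a, b = self.codes[individual, locus]
        if a == MISSING:
            return None
        names = self.allele_names[locus]
        return (names[a], names[b])

    # ------------------------------------------------------------------
    def subset(
        self,
        populations: Iterable[str] | None = None,
        loci: Iterable[str] | None = None,
        drop_individuals: Iterable[str] = (),
    ) -> "GenotypeTable":
        """Return a copy restricted to the given populations/loci.

        ``drop_individuals`` removes specific individuals by id (used e.g. to
        exclude a single isotope-identified migrant from differentiation
        analyses).
        """
        pops = list(populations) if populations is not None else list(self.populations)
        for p in pops:
            if p not in self.populations:
                raise KeyError(f"unknown population {p!r}")
        loci_keep = list(loci) if loci is not None else list(self.loci)
        lidx = [self.loci.index(l) for l in loci_keep]
        drop = set(drop_individuals)
        keep_pop = np.isin(self.pop_index, [self.populations.index(p) for p in pops])
        keep_ind = np.array([i not in drop for i in self.individual_ids])
        mask = keep_pop & keep_ind
        old_new = {self.populations.index(p): i for i, p in enumerate(pops)}
        new_pop_index = np.array([old_new[p] for p in self.pop_index[mask]])
        return GenotypeTable(
            pops,
            loci_keep,
            [self.allele_names[l] for l in lidx],
            new_pop_index,
            self.codes[mask][:, lidx, :],
            [i for i, m in zip(self.individual_ids, mask) if m],
        )


@dataclass
class AlleleFrequencySet:
    """Per population x locus allele counts, sample sizes and heterozygotes.

    ``counts[l]`` is an ``(n_populations, n_alleles_l)`` array of allele-copy
    counts; ``n`` holds the number of diploid individuals with a non-missing
    genotype (locus-wise complete case) and ``het`` the observed heterozygote
    count.  Frequencies are ``counts / (2 n)``; a population x locus cell with
    ``n == 0`` has no defined frequency vector and is excluded from per-locus
    means downstream.
    """

    populations: list[str]
    loci: list[str]
    allele_names: list[list[str]]
    counts: list[np.ndarray]
    n: np.ndarray
    het: np.ndarray
    #: per locus, (n_populations, n_alleles) counts of individuals
    #: heterozygous *for* each allele (exactly one copy carried)
    het_by_allele: list[np.ndarray] = field(default_factory=list)

    def frequencies(self, locus: str | int) -> np.ndarray:
        """``(n_populations, n_alleles)`` frequency array; NaN rows where n=0."""
        l = locus if isinstance(locus, int) else self.loci.index(locus)
        tot = 2.0 * self.n[:, l]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts[l] / tot[:, None]
        out[tot == 0] = np.nan
        return out

    def freq(self, population: str, locus: str) -> dict[str, float]:
        p = self.populations.index(population)
        l = self.loci.index(locus)
        f = self.frequencies(l)[p]
        return {a: float(v) for a, v in zip(self.allele_names[l], f) if v > 0}


class PairwiseMatrix:
    """Symmetric population x population statistic with optional p-values."""

    def __init__(
        self,
        codes: Sequence[str],
        values: np.ndarray,
        pvalues: np.ndarray | None = None,
        label: str = "",
    ) -> None:
        values = np.asarray(values, dtype=float)
        k = len(codes)
        if values.shape != (k, k):
            raise ValueError("matrix shape does not match code list")
        off = ~np.eye(k, dtype=bool)
        if not np.allclose(values[off], values.T[off], atol=1e-12, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if pvalues is not None:
            pvalues = np.asarray(pvalues, dtype=float)
            pv = pvalues[off & np.isfinite(pvalues)]
            if ((pv < 0) | (pv > 1)).any():
                raise ValueError("p-values outside [0, 1]")
        self.codes = list(codes)
        self.values = values
        self.pvalues = pvalues
        self.label = label

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.codes.index(a), self.codes.index(b)])

    def off_diagonal(self, codes: Sequence[str] | None = None) -> np.ndarray:
        """Upper-triangle vector over the requested (sub)set of codes."""
        sub = self.submatrix(codes) if codes is not None else self
        iu = np.triu_indices(len(sub.codes), 1)
        return sub.values[iu]

    def submatrix(self, codes: Sequence[str]) -> "PairwiseMatrix":
        idx = [self.codes.index(c) for c in codes]
        pv = self.pvalues[np.ix_(idx, idx)] if self.pvalues is not None else None
        return PairwiseMatrix(codes, self.values[np.ix_(idx, idx)], pv, self.label)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.codes, columns=self.codes)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "PairwiseMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(list(df.index), df.to_numpy(dtype=float), label=label)
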
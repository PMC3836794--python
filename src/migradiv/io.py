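"""Readers and writers for the standard file formats the pipeline touches.

Genotypes travel in the Genepop dialect (title line, locus names one per line
or comma-separated, case-insensitive ``POP`` separators, then lines
``id ,  g1 g2 ...`` with 2- or 3-digit allele coding; an all-zero allele code
marks a missing genotype).  Population metadata is a delimited table with one
row per sampling site; pairwise matrices are CSV with population codes as row
and column labels.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeTable, PairwiseMatrix, PopulationMetadata


class GenepopParseError(ValueError):
    """Raised for malformed Genepop input, naming the offending line."""


def _parse_token(token: str, line_no: int) -> tuple[str, str] | None:
    if len(token) % 2 != 0 or not token.isdigit():
        raise GenepopParseError(
            f"line {line_no}: genotype token {token!r} does not split into two equal-width allele codes"
        )
    d = len(token) // 2
    if d not in (2, 3):
        raise GenepopParseError(
            f"line {line_no}: allele coding must be 2 or 3 digits, got token {token!r}"
        )
    a, b = token[:d], token[d:]
    if int(a) == 0 or int(b) == 0:
        return None
    # normalise zero-padding so 2- and 3-digit dialects agree on labels
    return str(int(a)), str(int(b))


def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a Genepop file into a validated :class:`GenotypeTable`.

    Population codes are taken from the leading ``code_`` prefix of the first
    individual id in each block (the convention this package's writer uses);
    blocks without such a prefix are named ``pop1``, ``pop2``, ...
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty file")
    loci: list[str] = []
    i = 1  # skip title line
    while i < len(lines) and lines[i].strip().upper() != "POP":
        for name in re.split(r"[,\s]+", lines[i].strip()):
            if name:
                loci.append(name)
        i += 1
    if len(set(loci)) != len(loci):
        raise GenepopParseError("duplicate locus names")
    if not loci:
        raise GenepopParseError("no locus names before first POP")

    blocks: list[list[tuple[str, list[tuple[str, str] | None], int]]] = []
    current: list[tuple[str, list[tuple[str, str] | None], int]] | None = None
    for j in range(i, len(lines)):
        raw = lines[j].strip()
        if not raw:
            continue
        if raw.upper() == "POP":
            if current is not None:
                blocks.append(current)
            current = []
            continue
        if current is None:
            raise GenepopParseError(f"line {j + 1}: genotype line before first POP")
        if "," not in raw:
            raise GenepopParseError(f"line {j + 1}: missing ',' separating id from genotypes")
        ind_id, rest = raw.split(",", 1)
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"line {j + 1}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        geno = [_parse_token(t, j + 1) for t in tokens]
        current.append((ind_id.strip(), geno, j + 1))
    if current is not None:
        blocks.append(current)
    blocks = [b for b in blocks if b]
    if not blocks:
        raise GenepopParseError("zero populations in file")

    codes: list[str] = []
    records: dict[str, list] = {}
    ids: dict[str, list[str]] = {}
    for k, block in enumerate(blocks):
        first = block[0][0]
        m = re.match(r"(.+)_\d+$", first)
        code = m.group(1) if m else f"pop{k + 1}"
        if code in records:
            code = f"{code}.{k + 1}"
        codes.append(code)
        records[code] = [g for _, g, _ in block]
        ids[code] = [i for i, _, _ in block]
    return GenotypeTable.from_records(records, loci, individual_ids=ids)


def write_genepop(table: GenotypeTable, path: str | Path, title: str = "migradiv export") -> None:
    """Write a table in 3-digit Genepop coding.

    Numeric allele labels in 1..999 are preserved (zero-padded); any other
    label universe is renumbered 1..k in universe order.
    """
    labels: list[list[int]] = []
    for names in table.allele_names:
        try:
            nums = [int(x) for x in names]
            ok = all(1 <= v <= 999 for v in nums) and len(set(nums)) == len(nums)
        except ValueError:
            ok = False
        labels.append(nums if ok else list(range(1, len(names) + 1)))
    out = [title]
    out.extend(table.loci)
    for p, code in enumerate(table.populations):
        out.append("POP")
        idx = np.flatnonzero(table.pop_index == p)
        for k, i in enumerate(idx):
            toks = []
            for l in range(table.n_loci):
                a, b = table.codes[i, l]
                if a == MISSING:
                    toks.append("000000")
                else:
                    toks.append(f"{labels[l][a]:03d}{labels[l][b]:03d}")
            out.append(f"{code}_{k + 1} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ----------------------------------------------------------------------
def read_metadata(path: str | Path) -> list[PopulationMetadata]:
    """Read population metadata CSV (columns code, name, n, lat, lon,
    direction, distance[, breeding])."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"code", "lat", "lon", "direction", "distance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            PopulationMetadata(
                code=str(row["code"]),
                name=str(row.get("name", "")),
                n=int(row["n"]) if "n" in df.columns and pd.notna(row.get("n")) else None,
                latitude=float(row["lat"]),
                longitude=float(row["lon"]),
                direction=str(row["direction"]).strip(),
                distance_class=str(row["distance"]).strip(),
                breeding_season_sample=bool(row.get("breeding", True)),
            )
        )
    if len({m.code for m in out}) != len(out):
        raise ValueError("duplicate population codes in metadata")
    return out


def write_metadata(metadata: Sequence[PopulationMetadata], path: str | Path) -> None:
    pd.DataFrame(
        {
            "code": [m.code for m in metadata],
            "name": [m.name for m in metadata],
            "n": [m.n for m in metadata],
            "lat": [m.latitude for m in metadata],
            "lon": [m.longitude for m in metadata],
            "direction": [m.direction for m in metadata],
            "distance": [m.distance_class for m in metadata],
            "breeding": [m.breeding_season_sample for m in metadata],
        }
    ).to_csv(path, index=False)


def check_metadata_covers(table: GenotypeTable, metadata: Sequence[PopulationMetadata]) -> None:
    """Raise if any genotyped population lacks a metadata row."""
    known = {m.code for m in metadata}
    absent = [p for p in table.populations if p not in known]
    if absent:
        raise ValueError(f"populations missing from metadata: {absent}")


# ----------------------------------------------------------------------
def write_matrix(matrix: PairwiseMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path)


def read_matrix(path: str | Path, label: str = "") -> PairwiseMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return PairwiseMatrix.from_dataframe(df, label=label)


def read_combined_matrix(path: str | Path) -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """Read a publication-layout matrix: differentiation below the diagonal,
    genetic distance above.  Returns ``(dest, distance)`` symmetric matrices."""
    df = pd.read_csv(path, index_col=0)
    codes = [str(c) for c in df.index]
    vals = df.to_numpy(dtype=float)
    k = len(codes)
    dest = np.zeros((k, k))
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i > j:
                dest[i, j] = dest[j, i] = vals[i, j]
            elif i < j:
                dist[i, j] = dist[j, i] = vals[i, j]
    return (
        PairwiseMatrix(codes, dest, label="D_est"),
        PairwiseMatrix(codes, dist, label="D_est/(1-D_est)"),
    )


def write_combined_matrix(dest: PairwiseMatrix, distance: PairwiseMatrix, path: str | Path) -> None:
    """Write the publication layout (differentiation below, distance above)."""
    if dest.codes != distance.codes:
        raise ValueError("matrices carry different population codes")
    k = len(dest.codes)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            vals[i, j] = dest.values[i, j] if i > j else distance.values[i, j]
    np.fill_diagonal(vals, 0.0)
    pd.DataFrame(vals, index=dest.codes, columns=dest.codes).to_csv(path)
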
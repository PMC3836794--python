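"""Packaged reference data: the published summary tables of a 12-population
European blackcap (Sylvia atricapilla) microsatellite survey.

The survey genotyped 502 birds at 14 microsatellite loci across 12 sampling
sites spanning the SW/SE migratory divide (~13 degrees E) and a sympatric
NW/SW migratory polymorphism in southern Germany.  Raw genotypes were not
deposited; what is available are the per-site summary statistics (sample
size, coordinates, migratory classification, A_E / H_O / H_E) and the full
pairwise differentiation matrix (Jost D_est below the diagonal, the Slatkin
genetic distance d/(1-d) above).  These printed tables are sufficient inputs
for the spatial analyses (Mantel isolation-by-distance, cross-divide rank
correlation) and drive the matrix-only pipeline mode.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import PairwiseMatrix, PopulationMetadata
from .io import read_combined_matrix


def _data_path(name: str):
    return resources.files("migradiv.data").joinpath(name)


def blackcap_summary() -> pd.DataFrame:
    """Per-site summary table (code, name, n, coordinates, migratory
    direction/distance, A_E, H_O, unbiased H_E with SEs)."""
    with resources.as_file(_data_path("blackcap_metadata.csv")) as p:
        return pd.read_csv(p)


def blackcap_metadata() -> list[PopulationMetadata]:
    """Site metadata as :class:`PopulationMetadata` records (survey order,
    sorted by longitude)."""
    df = blackcap_summary()
    return [
        PopulationMetadata(
            code=r.code, name=r.name, n=int(r.n), latitude=float(r.lat),
            longitude=float(r.lon), direction=r.direction, distance_class=r.distance,
            breeding_season_sample=bool(r.breeding),
        )
        for r in df.itertuples()
    ]


def blackcap_differentiation() -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """The published pairwise matrix, split into its two triangles.

    Returns ``(dest, distance)``: symmetric multilocus Jost D_est and the
    corresponding Slatkin genetic distance d/(1-d), both at the printed
    3-decimal precision.
    """
    with resources.as_file(_data_path("blackcap_differentiation.csv")) as p:
        return read_combined_matrix(p)
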
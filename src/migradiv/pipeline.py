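"""One-call orchestration of the full analysis, plus a matrix-only mode.

``run_pipeline`` drives the genotype-based stages (diversity summary, HWE
tests with FDR correction, pairwise D_est / theta with permutation
significance, migratory-group comparisons, Mantel and cross-divide spatial
tests, hierarchical F-statistics under both Oslo classifications, isotope
assignment).  ``run_matrix_mode`` recomputes every statistic that needs only
a published pairwise differentiation matrix plus site metadata — the mode of
interest when raw genotypes are unavailable.

All randomness flows from one integer seed through ``numpy`` seed sequences,
so a rerun with the same config produces byte-identical reports.
"""
from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import differentiation as diff
from . import diversity, hierarchy, isotope, spatial
from .core import GenotypeTable, PairwiseMatrix, PopulationMetadata
from .io import (
    check_metadata_covers,
    read_genepop,
    read_matrix,
    read_metadata,
    write_combined_matrix,
    write_matrix,
)

log = logging.getLogger("migradiv")


@dataclass
class PipelineConfig:
    """Inputs and tuning knobs of one pipeline run (YAML-loadable)."""

    genepop: str | None = None
    metadata: str | None = None
    isotopes: str | None = None          # CSV: id, population, d2h
    dest_matrix: str | None = None       # matrix-only mode input
    outdir: str = "migradiv_out"
    divide_longitude: float = 13.0
    permutations: int = 10_000
    pair_permutations: int = 999         # per-pair D_est significance
    fdr_thresholds: tuple[float, float] = (0.01, 0.05)
    exclude_loci: tuple[str, ...] = ()
    exclude_populations: tuple[str, ...] = ()
    exclude_individuals: tuple[str, ...] = ()
    isotope_threshold: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.permutations < 100 or self.pair_permutations < 100:
            raise ValueError("permutation counts must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fdr_thresholds", "exclude_loci", "exclude_populations", "exclude_individuals"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


# ----------------------------------------------------------------------
def _spatial_report(
    dest: PairwiseMatrix,
    metadata: Sequence[PopulationMetadata],
    divide_longitude: float,
    permutations: int,
    seeds,
) -> dict:
    """Mantel tests on population subsets plus the cross-divide rank test."""
    md = [m for m in metadata if m.code in dest.codes]
    distance = diff.slatkin_matrix(dest)
    west, east = spatial.split_by_divide(md, divide_longitude)
    breeding = [m.code for m in md if m.breeding_season_sample]
    subsets = {
        "all": [m.code for m in md],
        "east": east,
        "west": west,
        "all_breeding": breeding,
        "west_breeding": [c for c in west if c in breeding],
    }
    mantel = {}
    for name, codes in subsets.items():
        if len(codes) < 4:
            continue
        sub_md = [m for m in md if m.code in codes]
        geo = spatial.geo_distances(sub_md, mode="great-circle")
        mantel[name] = spatial.mantel_test(
            distance.submatrix([m.code for m in sub_md]),
            geo,
            permutations=permutations,
            seed=int(next(seeds)),
        )
    cross = spatial.cross_divide_test(
        distance, md, divide_longitude, resamples=permutations, seed=int(next(seeds))
    )
    cross_breeding = None
    md_b = [m for m in md if m.breeding_season_sample]
    w_b, e_b = spatial.split_by_divide(md_b, divide_longitude)
    if len(w_b) * len(e_b) >= 3:
        cross_breeding = spatial.cross_divide_test(
            distance.submatrix([m.code for m in md_b]),
            md_b,
            divide_longitude,
            resamples=permutations,
            seed=int(next(seeds)),
        )
    return {"distance": distance, "mantel": mantel, "cross_divide": cross,
            "cross_divide_breeding": cross_breeding}


def _group_report(
    dest: PairwiseMatrix, metadata: Sequence[PopulationMetadata]
) -> pd.DataFrame:
    values = diff.pair_group_values(dest, metadata)
    rows = []
    for gx, gy in itertools.combinations(sorted(values), 2):
        if not values[gx] or not values[gy]:
            continue
        u, p = diff.compare_group_distributions(dest, metadata, gx, gy)
        rows.append(
            {"group_x": gx, "group_y": gy, "n_x": len(values[gx]),
             "n_y": len(values[gy]), "U": u, "p": p}
        )
    return pd.DataFrame(rows)


def run_matrix_mode(
    dest: PairwiseMatrix,
    metadata: Sequence[PopulationMetadata],
    divide_longitude: float = 13.0,
    permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Spatial and group statistics from a published differentiation matrix."""
    seeds = iter(np.random.SeedSequence(seed).generate_state(64))
    out = _spatial_report(dest, metadata, divide_longitude, permutations, seeds)
    out["groups"] = _group_report(dest, metadata)
    return out


# ----------------------------------------------------------------------
def run_pipeline(config: PipelineConfig) -> dict:
    """Full (or matrix-only) pipeline run; writes reports under
    ``config.outdir`` and returns the in-memory results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("config digest %s seed %d", config.digest(), config.seed)
    results: dict = {}
    try:
        if config.metadata is None:
            raise ValueError("a metadata table is required")
        metadata = read_metadata(config.metadata)
        metadata = [m for m in metadata if m.code not in config.exclude_populations]

        if config.dest_matrix is not None and config.genepop is None:
            dest = read_matrix(config.dest_matrix, label="D_est")
            keep = [c for c in dest.codes if c not in config.exclude_populations]
            dest = dest.submatrix(keep)
        elif config.genepop is not None:
            table = read_genepop(config.genepop)
            check_metadata_covers(table, metadata)
            table = table.subset(
                populations=[p for p in table.populations if p not in config.exclude_populations],
                loci=[l for l in table.loci if l not in config.exclude_loci],
                drop_individuals=config.exclude_individuals,
            )
            results["diversity"] = _stage("diversity", _diversity_stage, table, outdir)
            seeds = iter(np.random.SeedSequence([config.seed, 7]).generate_state(8))
            results["hwe"] = _stage("hwe", _hwe_stage, table, config, int(next(seeds)), outdir)
            dest, theta = _stage(
                "differentiation", _differentiation_stage, table, config, int(next(seeds)), outdir
            )
            results["dest"] = dest
            results["theta"] = theta
            results["hierarchy"] = _stage(
                "hierarchy", _hierarchy_stage, table, metadata, config, int(next(seeds)), outdir
            )
        else:
            raise ValueError("either a Genepop file or a D_est matrix is required")

        spatial_res = _stage(
            "spatial", run_matrix_mode, dest, metadata,
            config.divide_longitude, config.permutations, config.seed,
        )
        results.update(spatial_res)
        results["dest"] = dest
        write_combined_matrix(dest, spatial_res["distance"], outdir / "differentiation_matrix.csv")
        _write_spatial(spatial_res, outdir)
        spatial_res["groups"].to_csv(outdir / "group_comparisons.csv", index=False)

        if config.isotopes is not None:
            results["isotope"] = _stage("isotope", _isotope_stage, config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()
    return results


def _stage(name, fn, *args):
    log.info("stage %s", name)
    try:
        return fn(*args)
    except Exception:
        log.exception("stage %s failed", name)
        raise RuntimeError(f"pipeline stage {name!r} failed") from None


def _diversity_stage(table: GenotypeTable, outdir: Path) -> pd.DataFrame:
    summary = diversity.diversity_summary(diversity.allele_frequencies(table))
    summary.to_csv(outdir / "diversity_summary.csv")
    return summary


def _hwe_stage(table, config, seed, outdir) -> pd.DataFrame:
    hwe = diversity.hwe_test_all(table, reps=config.permutations, seed=seed)
    for thr in config.fdr_thresholds:
        hwe[f"significant_q<{thr}"] = hwe["q"] < thr
    hwe.to_csv(outdir / "hwe_tests.csv", index=False)
    return hwe


def _differentiation_stage(table, config, seed, outdir):
    dest = diff.dest_matrix_with_significance(
        table, reps=config.pair_permutations, seed=seed
    )
    freqs = diversity.allele_frequencies(table)
    theta = diff.fst_matrix(freqs)
    write_matrix(theta, outdir / "theta_matrix.csv")
    if dest.pvalues is not None:
        pd.DataFrame(dest.pvalues, index=dest.codes, columns=dest.codes).to_csv(
            outdir / "dest_pvalues.csv"
        )
    return dest, theta


def _hierarchy_stage(table, metadata, config, seed, outdir) -> pd.DataFrame:
    rows = []
    seeds = iter(np.random.SeedSequence([seed, 11]).generate_state(16))
    for variant in ("A", "B"):
        design = hierarchy.HierarchicalDesign.from_metadata(
            metadata, populations=table.populations, variant=variant
        )
        res = hierarchy.hier_fstats(table, design)
        for level in design.level_names[:-1]:
            enclosing = "total" if level == "direction" else design.level_names[
                design.level_names.index(level) - 1
            ]
            p = hierarchy.hier_permutation_test(
                table, design, level, permutations=config.permutations, seed=int(next(seeds))
            )
            rows.append(
                {"variant": variant, "level": level, "within": enclosing,
                 "F": res.f(level, enclosing if level != "direction" else "total"),
                 "p": p}
            )
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "hierarchical_fstats.csv", index=False)
    return df


def _isotope_stage(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    df = pd.read_csv(config.isotopes)
    assign = isotope.assign_wintering(df["d2h"], threshold=config.isotope_threshold)
    assign.insert(0, "id", df["id"])
    if "population" in df.columns:
        assign.insert(1, "population", df["population"])
        counts = isotope.assignment_counts(assign, df["population"])
        counts.to_csv(outdir / "isotope_counts.csv")
        groups = {
            k: v["d2h"].to_list()
            for k, v in df.groupby("population")
            if len(v) >= 2
        }
        if len(groups) >= 2:
            comp = isotope.compare_isotope_distributions(groups)
            comp["pairwise"].to_csv(outdir / "isotope_comparisons.csv", index=False)
    assign.to_csv(outdir / "isotope_assignments.csv", index=False)
    return assign


def _write_spatial(res: dict, outdir: Path) -> None:
    report = {
        "mantel": {
            k: dataclasses.asdict(v) for k, v in res["mantel"].items()
        },
        "cross_divide": dataclasses.asdict(res["cross_divide"]),
    }
    if res.get("cross_divide_breeding") is not None:
        report["cross_divide_breeding"] = dataclasses.asdict(res["cross_divide_breeding"])
    for block in ("cross_divide", "cross_divide_breeding"):
        if block in report:
            report[block]["pairs"] = [list(p) for p in report[block]["pairs"]]
    (outdir / "spatial_report.json").write_text(json.dumps(report, indent=2))
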
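"""Nested variance components, hierarchical F-statistics, level tests."""
import numpy as np
import pytest

import migradiv as mg
from migradiv.differentiation import wc_fst_multi
from migradiv.hierarchy import (
    HierarchicalDesign,
    hier_fstats,
    hier_permutation_test,
)


def _three_level_config(seed, level_div, sizes=(20,) * 12, n_loci=6):
    # unbalanced cell design mirroring the survey: 1 + 3 + 2 distance cells
    # per direction, so the direction grouping is identifiable under cell
    # permutation (all directions hold different numbers of cells)
    dirs = ("NW",) + ("SW",) * 6 + ("SE",) * 5
    dists = ("intermediate",
             "short", "intermediate", "intermediate", "long", "long", "short",
             "intermediate", "intermediate", "long", "long", "long")
    return mg.SimulationConfig(
        seed=seed, sizes=sizes, n_loci=n_loci, model="hierarchical",
        level_divergence=level_div, directions=dirs, distance_classes=dists,
    )


def _design_for(cfg):
    codes = cfg.codes
    return HierarchicalDesign(
        codes,
        [("direction", dict(zip(codes, cfg.directions))),
         ("distance", dict(zip(codes, cfg.distance_classes)))],
    )


def test_population_only_design_equals_weir_cockerham():
    """With population as the only level, the nested-ANOVA F equals the
    two-level Weir-Cockerham theta (independent algebra) within 0.01."""
    seeds = np.random.SeedSequence(314).generate_state(10)
    for s in seeds:
        cfg = mg.SimulationConfig(seed=int(s) % 2**31, sizes=(25, 30, 35), n_loci=8, divergence=0.08)
        table, _ = mg.sim_genotypes(cfg)
        res = hier_fstats(table, HierarchicalDesign(list(table.populations)))
        theta = wc_fst_multi(mg.allele_frequencies(table), table.populations)
        assert res.f("population") == pytest.approx(theta, abs=0.01)


def test_panmixia_gives_near_zero_f():
    cfg = _three_level_config(99, (0.0, 0.0, 0.0), sizes=(30,) * 12)
    table, _ = mg.sim_genotypes(cfg)
    res = hier_fstats(table, _design_for(cfg))
    for level in ("direction", "distance", "population"):
        assert abs(res.f(level)) < 0.02


def test_components_sum_to_total_and_order_invariance():
    cfg = _three_level_config(7, (0.05, 0.02, 0.01))
    table, _ = mg.sim_genotypes(cfg)
    design = _design_for(cfg)
    res = hier_fstats(table, design)
    assert res.components.sum() == pytest.approx(
        res.components_per_locus.sum().sum(), rel=1e-9
    )
    # permuting population order in the design leaves components unchanged
    rev = HierarchicalDesign(design.populations[::-1], design.groupings)
    res2 = hier_fstats(table, rev)
    np.testing.assert_allclose(
        res.components.to_numpy(), res2.components.to_numpy(), rtol=1e-9, atol=1e-12
    )


def test_direction_structure_dominates_when_injected():
    """Strong direction-level divergence, none below: direction F exceeds
    population F in >= 95/100 replicates, and its permutation test fires."""
    wins = 0
    sig = 0
    seeds = np.random.SeedSequence(271).generate_state(100)
    for s in seeds:
        cfg = _three_level_config(int(s) % 2**31, (0.3, 0.0, 0.0), sizes=(12,) * 12, n_loci=5)
        table, _ = mg.sim_genotypes(cfg)
        design = _design_for(cfg)
        res = hier_fstats(table, design)
        if res.f("direction", "total") > res.f("population", "distance"):
            wins += 1
    assert wins >= 95
    seeds2 = np.random.SeedSequence(272).generate_state(40)
    for s in seeds2:
        cfg = _three_level_config(int(s) % 2**31, (0.3, 0.0, 0.0), sizes=(12,) * 12, n_loci=5)
        table, _ = mg.sim_genotypes(cfg)
        p = hier_permutation_test(table, _design_for(cfg), "direction",
                                  permutations=199, seed=int(s))
        if p < 0.05:
            sig += 1
    assert sig >= 38   # >= 95% power


def test_single_unit_level_raises():
    cfg = mg.SimulationConfig(seed=5, sizes=(10, 10), n_loci=3, divergence=0.05,
                              model="hierarchical", level_divergence=(0.0, 0.0, 0.05),
                              directions=("SW", "SW"), distance_classes=("short", "short"))
    table, _ = mg.sim_genotypes(cfg)
    design = _design_for(cfg)
    with pytest.raises(ValueError, match="degrees of freedom"):
        hier_fstats(table, design)


def test_untestable_level_raises():
    cfg = _three_level_config(11, (0.0, 0.0, 0.02))
    table, _ = mg.sim_genotypes(cfg)
    codes = cfg.codes
    # one distance cell per direction: distance level has nothing to permute
    design = HierarchicalDesign(
        codes,
        [("direction", dict(zip(codes, cfg.directions))),
         ("distance", {c: "only" for c in codes})],
    )
    with pytest.raises(ValueError, match="untestable"):
        hier_permutation_test(table, design, "distance", permutations=100, seed=0)


def test_oslo_variant_reclassification(blackcap):
    metadata, _, _ = blackcap
    a = HierarchicalDesign.from_metadata(metadata, variant="A")
    b = HierarchicalDesign.from_metadata(metadata, variant="B")
    assert dict(a.groupings)["direction"]["Os"] == "SW"
    assert dict(b.groupings)["direction"]["Os"] == "SE"


def test_excluding_an_individual(blackcap):
    cfg = mg.SimulationConfig(seed=8, sizes=(6, 6), n_loci=3, divergence=0.02)
    table, _ = mg.sim_genotypes(cfg)
    smaller = table.subset(drop_individuals=["P1_3"])
    assert smaller.n_individuals == table.n_individuals - 1
    assert "P1_3" not in smaller.individual_ids
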
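# migradiv

Population-genetic analysis of songbird migratory divides: microsatellite
diversity and differentiation statistics, isolation-by-distance tests, a
cross-divide longitudinal permutation test, hierarchical F-statistics over
migratory groupings, and stable-isotope wintering-ground assignment.

## The problem

European blackcaps (*Sylvia atricapilla*) breeding in central Europe split
into south-west and south-east autumn migrants across a migratory divide near
13°E, with a recently evolved north-west route to the British Isles breeding
sympatrically with SW migrants in southern Germany. Whether these divides are
real barriers to gene flow is a quantitative question about *weak* neutral
structure: pairwise differentiation among such populations is of order
0.00–0.07, at the edge of what microsatellite panels resolve. `migradiv`
implements the statistical toolkit this kind of study needs, end to end, for
anyone analysing co-dominant multi-locus genotypes sampled across a
behavioural or geographic divide.

## The statistics

* **Unbiased Jost D** per locus, for populations with harmonic-mean sample
  size N̄ and n populations:

      H_S,est = (2N̄ / (2N̄−1)) · (1 − mean_j Σ_a p²_ja)
      H_T,est = (1 − Σ_a p̄²_a) + H_S,est / (2N̄n)
      D_est   = ((H_T,est − H_S,est) / (1 − H_S,est)) · n/(n−1)

  multilocus D_est is the arithmetic mean over loci (clamped at 0 for
  reporting); significance by permuting individuals between the pair.
* **Weir–Cockerham θ** (variance-components F_ST, multilocus ratio of sums)
  as the complementary fixation index.
* **Slatkin's genetic distance** D/(1−D), linearising differentiation for
  regression against geography.
* **Mantel tests** of genetic vs great-circle distance (joint row/column
  permutation, one-sided toward isolation-by-distance).
* **Cross-divide test**: Spearman rank correlation of longitudinal distance
  vs genetic distance over all west×east pairs across a divide longitude,
  judged against a permutation null 95% CI.
* **Hierarchical F-statistics**: nested moment (ANOVA) variance components on
  allele indicators over gametes — direction / distance class / population /
  individual — with per-level permutation tests.
* **δ²H assignment**: two-reference normal-likelihood posterior with a 75%
  probability criterion (references: −94.3 ± 4.9 ‰ British Isles winterers,
  −51.6 ± 5.8 ‰ southern Iberia).
* **Diversity summaries**: A_E = 1/Σp², H_O, unbiased H_E, Monte-Carlo exact
  heterozygote-deficiency tests, Storey q-value FDR correction.

A calibrated synthetic-data generator (Dirichlet frequency hierarchies with a
closed-form divergence→concentration mapping, HWE genotype sampling,
island / stepping-stone / nested modes) reproduces the survey's design — 12
populations with sample sizes 8–105, 14 loci — with known truth, so every
estimator is tested by parameter recovery. The published per-site summary
table and pairwise-differentiation matrix ship with the package
(`blackcap_metadata()`, `blackcap_differentiation()`).

## Worked example

```python
import migradiv as mg

cfg = mg.SimulationConfig(seed=42, sizes=(50, 50), divergence=0.05)
table, true_freqs = mg.sim_genotypes(cfg)
freqs = mg.allele_frequencies(table)
print(mg.expected_dest(true_freqs))                       # 0.0684
print(mg.dest_pairwise(freqs, "P1", "P2").d_multilocus)   # 0.0698
print(mg.wc_fst(freqs, "P1", "P2"))                       # 0.0256
print(mg.dest_significance(table, "P1", "P2", reps=999, seed=1))  # 0.0010
```

The estimated multilocus D_est (0.0698) sits on the recorded truth (0.0684);
θ is much smaller than D for these high-diversity markers, as expected; the
permutation p-value rejects panmixia. On the published survey matrix:

```python
from migradiv.differentiation import slatkin_matrix
md = mg.blackcap_metadata()
dest, _ = mg.blackcap_differentiation()
res = mg.mantel_test(slatkin_matrix(dest).submatrix([m.code for m in md]),
                     mg.geo_distances(md), permutations=10_000, seed=7)
print(res.r, res.p)        # 0.422 0.0475  — significant IBD over all 12 sites
```

`examples/` contains one short narrative script per capability
(differentiation, IBD, cross-divide, hierarchical F, isotope assignment), and
the `migradiv` CLI exposes the same stages as subcommands
(`simulate`, `diversity`, `differentiate`, `spatial`, `hierarchy`, `isotope`,
`run-all`, `matrix-mode`) driven by a YAML config.

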
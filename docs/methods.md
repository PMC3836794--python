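# Methods

`migradiv` analyses weak neutral genetic structure among songbird populations
sampled across migratory divides. This note documents the statistical models,
the tunable parameters, the synthetic-data generator and its calibration,
numerical choices, and known limitations.

## Differentiation: unbiased Jost D and Weir–Cockerham θ

Jost's D measures allelic differentiation on the effective-diversity scale:
0 when populations share identical allele frequencies, 1 when they share no
alleles. The package implements the sample-size-corrected ("unbiased")
estimator. Per locus, for n populations with allele frequencies p_ja and
harmonic-mean diploid sample size N̄:

    H_S,obs = 1 − mean_j Σ_a p²_ja           (within-population gene diversity)
    H_S,est = (2N̄ / (2N̄ − 1)) · H_S,obs
    H_T,obs = 1 − Σ_a (mean_j p_ja)²          (total gene diversity)
    H_T,est = H_T,obs + H_S,est / (2 N̄ n)
    D_est   = ((H_T,est − H_S,est) / (1 − H_S,est)) · n/(n−1)

Multilocus aggregation is the arithmetic mean of per-locus values (harmonic
mean available via `aggregation="harmonic"`). Negative per-locus values —
pure sampling noise under near-identity — are clamped to 0 for reporting;
raw values are retained internally because permutation nulls must preserve
the estimator's full sampling distribution. Loci with data in only one
member of a pair are dropped from that pair. If H_S,est ≥ 1 (possible only
at sample size 1) the locus is recorded as NaN and excluded from the mean.

Significance of a pairwise D_est is assessed by randomly reassigning
individuals between the two populations with sizes preserved — the
exchangeable null — recomputing the raw multilocus D_est each replicate, with
p = (1 + #{replicate ≥ observed}) / (reps + 1). A bootstrap scheme (both
pseudo-samples drawn from the pooled pair with replacement) is available via
`scheme="bootstrap"`; permutation is the default because exchangeability
under the null is exactly what reassignment enforces.

θ is the classic Weir–Cockerham (1984) moment estimator from
among-population (a), among-individual (b) and within-individual (c)
variance components, summed over alleles and loci: θ = Σa / Σ(a+b+c). It is
algebraically independent of the nested-ANOVA machinery in the hierarchy
module, which is exploited as a cross-check: with population as the only
grouping level the hierarchical F equals θ (the test suite verifies
agreement to within 0.01 on simulated data; in practice they agree to ~4
decimals).

## Spatial analyses

Distances are great-circle (haversine, spherical Earth R = 6371 km). The
"longitudinal" mode zeroes latitudes first, so distance is a strictly
increasing function of |Δ longitude| — appropriate when the question is
east–west position relative to a divide. Because Spearman correlations are
invariant to strictly monotone transforms, the choice of arc vs planar
longitudinal distance cannot affect the cross-divide rho.

The Mantel statistic is the Pearson correlation over the n(n−1)/2 unordered
off-diagonal pairs; the null jointly permutes the row/column order of one
matrix. The test is one-sided toward positive association by default
(isolation-by-distance is a directional hypothesis); two-sided available.

The cross-divide test partitions populations at a divide longitude (default
13.0°E; a site exactly on the divide counts as east), forms all west×east
pairs, computes Spearman's rho of longitudinal vs genetic distance over
those pairs, and builds a null by permuting the geographic-distance vector
freely across pairs (10,000 resamples by default; bootstrap optional). The
95% CI is the (2.5, 97.5) percentile interval of the null; the observed rho
is significant when outside it. Free permutation (rather than
row/column-constrained) is used because the published CI is symmetric about
zero, which is the signature of an unstructured permutation null.

Two sympatric samples at identical coordinates (the NW- and SW-assigned
birds of one site) legitimately have zero geographic distance.

## Hierarchical F-statistics

Variance components for the nested design direction / distance class /
population / individual / gamete are estimated by the moment (nested ANOVA)
method on allele-indicator variables over gametes. For each locus, the
between-group sums of squares of every level are equated to their
expectations under the unbalanced nested random-effects model (coefficients
built from group sizes), the linear system is solved per locus, and
components are pooled by summation over alleles and loci. Negative component
estimates are retained, not clamped. The F between level i and an enclosing
level j is the ratio of cumulative components

    F_{i/j} = Σ_{k=j+1..i} σ²_k / Σ_{k=j+1..bottom} σ²_k ,

so F(population/total) is the variance-components F_ST.

Each level is tested by permuting its units among the cells of the enclosing
level, keeping everything below intact: whole distance cells among
directions; populations among distance cells within their direction;
individuals among populations within their distance cell. The statistic is
the tested level's F within its enclosing level, and
p = (1 + #{≥ observed}) / (perms + 1). The choice of F as the permutation
statistic (rather than a likelihood-ratio G statistic over allele counts) is
a design decision; both respond to the same departures and F is the quantity
the module reports.

A caution on design granularity: the direction-level test permutes whole
cells, and its resolution is limited by the number of distinct
cell-to-direction assignments. With the survey's 6 cells split 1/3/2 across
directions there are 60 distinct assignments and the attainable p-value
floor is ≈ 0.02; designs with equal cell counts per direction are partially
non-identifiable (relabelling directions leaves F unchanged) and lose power.

## Isotope assignment

Claw δ²H in European songbirds tracks wintering latitude. Assignment uses
two normal references — British Isles winterers (−94.3 ‰, SD 4.9) and
southern Iberia (−51.6 ‰, SD 5.8) — with equal priors (configurable):
posterior_k(x) = N(x; μ_k, σ_k) / Σ N(x; μ, σ), computed in log space so far
tails cannot underflow. A bird is called for a ground only when its
posterior reaches the threshold (default 0.75); thresholds > 0.5 guarantee
exactly three contiguous call regions along the δ²H axis, and raising the
threshold can only unassign. δ²H carries no longitudinal information at
these latitudes, so SW and SE winterers share the pooled southern reference
and no SW/SE call is attempted.

## Diversity and multiple testing

A_E = 1/Σp², H_O, and unbiased H_E = (2N/(2N−1))(1 − Σp²) are computed per
population × locus with locus-wise complete-case handling of missing
genotypes (an individual missing at a locus is excluded from that locus
only); per-population values are unweighted means over loci, SE = sd(n−1
denominator)/√L. Hardy–Weinberg departures are tested one-sidedly against
heterozygote deficiency by Monte-Carlo re-pairing of the observed allele
pool (the exact-test null conditional on allele counts); the test is
slightly conservative, as the suite's 500-locus null simulation verifies.
FDR correction is Storey's q-value at a single fixed λ = 0.5:
π₀ = min(1, #{p > 0.5}/(0.5m)), q = step-up-enforced π₀·m·p_(i)/i, capped at
1 — the essence of the q-value method without spline smoothing of π₀.

## Synthetic-data generator

The generator emulates a 12-site, 14-locus microsatellite survey with
unbalanced samples (default sizes 8–105, total 502) and weak structure.
Allele frequencies follow a Dirichlet hierarchy: ancestral per-locus
frequencies ~ symmetric Dirichlet(0.5) over k = 10 alleles (chosen to match
the survey's gene diversity ~0.75 and effective allele counts ~4), and a
descendant is drawn as Dirichlet(θ·parent) with θ solved in closed form from
the target pairwise divergence d:

    E[D] ≈ H / (1 + θ(1 − H))   ⇒   θ = (H − d) / (d (1 − H)),

H the parent's gene diversity. The mapping follows from Dirichlet moments
and is a ratio-of-expectations approximation; it is validated against the
exact parameter `expected_dest` computed on the recorded true frequencies
(parameter-recovery tests hold |mean D̂ − d| ≤ 0.02 at d ∈ {0, 0.05, 0.3}),
never assumed exact. Ancestors too uniform in frequency to host the target
divergence are redrawn; along stepping-stone chains a lineage that has
drifted to low diversity caps its step divergence at 0.9H rather than
aborting (the recorded truth reflects what was realised). Genotypes are two
independent allele draws per individual (HWE within populations), so
generated data pass the deficiency test at nominal rates. Identical seeds
reproduce datasets bit-for-bit.

Three spatial modes: island (exchangeable populations), stepping-stone
(divergence accumulates along a line, producing isolation-by-distance), and
hierarchical (nested draws direction → distance cell → population with
per-level divergences).

Calibration to the published survey: the default pairwise divergence is
0.014, the mean of the 66 published pairwise D_est values. For the
hierarchical "weak structure" scenario the published matrix's class means
(within-cell 0.008; within-direction-across-cell 0.016; across-direction
0.015) decompose — small divergences compound approximately additively down
the hierarchy — into per-level divergences (direction, distance, population)
= (0.0, 0.008, 0.008).

What the generator does not emulate: mutation-model (stepwise) allele-size
structure, null alleles, genotyping error, temporal sampling, and
*idiosyncratic* per-population divergence. The last matters for
interpretation: in the real survey most differentiation is carried by two or
three particular populations while most within-cell pairs are
indistinguishable, a pattern a level-homogeneous generator cannot express.
Consequently, passing parameter-recovery tests demonstrates estimator
correctness under the stated conditions, not that real surveys satisfy those
conditions; and hierarchical permutation tests that correctly detect true
per-level divergence of 0.008 at 502 individuals can be non-significant on
real data whose structure is not organised by level.

## Numerical and reproducibility choices

All permutation p-values use the (1 + hits)/(N + 1) convention, so p > 0 and
the tests are exact-level conservative. Permutation counts below 100 are
rejected as unstable. All randomness flows from integer seeds through numpy
`SeedSequence`, and pipeline reruns with the same config are byte-identical.
Matrix symmetry is enforced at 1e−12; frequency vectors must sum to 1 within
1e−12. Genotype allele pairs are stored unordered; allele identifiers are
opaque labels (no size semantics, since allele binning is out of scope).
Missing genotypes are those with any all-zero allele code; handling is
locus-wise complete-case throughout (the original study does not state its
missing-data rule; this is the standard convention and is flagged for
sensitivity analysis).

Simulation counts in the test suite (200 recovery datasets per divergence,
500 null datasets for type-I error, 100 weak-structure replicates at 199
permutations, 10,000 permutations for the published-table statistics) are
the package's chosen balance of statistical resolution against runtime.

## Known limitations

* The published pairwise matrix is printed at 3 decimals, and its two
  triangles were rounded independently. Rank-based statistics recomputed
  from it differ from the originally reported ones because rounding creates
  large tie blocks at 0.000: the cross-divide rho from the printed table is
  0.590 (35 pairs) / 0.447 (30 pairs) against the published 0.467 / 0.377,
  under every tie-handling convention. The permutation-null CI and all
  Mantel correlations are insensitive to this and reproduce within ±0.02.
* The original study's resampling scheme for pairwise D_est significance and
  its per-level permutation scheme for the hierarchical tests are not
  described; both are reconstructed here (individual reassignment;
  unit-within-enclosing-level permutation) and documented above.
* Whether the original SEs are over loci (assumed here) or individuals is
  not stated.
* Great-circle distance stands in for the original ellipsoidal/"Euclidean"
  routine; at intra-European scales the discrepancy is < 1% and Mantel r is
  affine-invariant.
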
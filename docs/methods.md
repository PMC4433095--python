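# Methods

## The model

All four samplers fit the same whole-genome regression to pre-corrected
phenotypes,

    y_i = sum_j z_ij u_j + e_i,

where `z_ij` is the coded genotype of animal *i* at marker *j*
(AA = 10, AB = 0, BB = −10; imputed fractional dosages map linearly),
`u_j` a random marker effect and `e_i ~ N(0, σ²_e)`.  Marker effects are
drawn from `N(0, σ²)` with probability `1 − π` and are exactly zero with
probability `π`.  All variances carry scaled-inverse-χ² priors; when π is
estimated (BayesCπ) it has a uniform (0,1) prior.  The four family members
differ only in two switches:

| model   | marker variance        | π                              |
|---------|------------------------|--------------------------------|
| BayesA  | one per locus          | fixed at 0                     |
| BayesB  | one per locus          | fixed (Metropolis–Hastings)    |
| BayesC  | common across loci     | fixed (π = 0 is "BayesC0")     |
| BayesCπ | common across loci     | estimated, uniform prior       |

### Full conditionals

With `r_j = z_j'(e + z_j u_j^old δ_j^old)` and `c_j = z_j'z_j + σ²_e/σ²_uj`:

* effect: `u_j | · ~ N(r_j/c_j, σ²_e/c_j)`; monomorphic surviving loci
  (`z_j'z_j = 0`) are forced to zero.
* per-locus variance (A, B): scaled-inv-χ²(ν_a+1, (ν_a S_a + u_j²)/(ν_a+1)).
* common variance (C, Cπ): scaled-inv-χ²(ν_a+m, (ν_a S_a + Σ_{δ=1} u_j²)/(ν_a+m))
  with m the number of included loci.  This draw is not always written out
  in descriptions of BayesC but is required for a coherent chain state and
  is the standard conditional.
* indicator (C, Cπ), u integrated out: with `v0 = z'z σ²_e` and
  `v1 = v0 + (z'z)² σ²_u`,
  `odds(δ=1:0) = [(1−π)/π] √(v0/v1) exp{r_j²(1/v0 − 1/v1)/2}`.
* indicator (B): per locus and sweep, `mh_cycles` (default 2) independence
  proposals drawn from the prior (δ* ~ Bern(1−π), σ²* from the prior
  scaled-inv-χ²); because the proposal is the prior, the acceptance ratio is
  the ratio of marginal likelihoods `N(r_j; 0, v0 + δ (z'z)² σ²)`.
* π (Cπ): Beta(k − m + 1, m + 1).
* residual variance: scaled-inv-χ²(ν_e+n, (e'e + ν_e S_e)/(ν_e+n)).
* fixed effects (when present): one multivariate-normal block draw with a
  flat prior, mean `(X'X)^{-1}X'(e + Xb^old)` and covariance `σ²_e (X'X)^{-1}`.

Update order within a sweep is fixed for reproducibility: fixed effects,
loci in storage order (indicator, then effect, then locus variance), common
variance, π, residual variance.  There is no thinning; posterior means are
running averages over all post-burn-in sweeps, with excluded-locus effects
counted as zero.  That zero-counting is what shrinks each posterior-mean
effect by its inclusion frequency.  The residual vector is maintained
incrementally and satisfies `e = y − Xb − Z(u∘δ)` to machine precision at
all times (asserted in tests).

### Priors from starting variances

Chains are parameterized by starting additive and residual variances
(`Va_start`, `Ve_start`), as practitioners usually have these from REML.
The per-locus prior-mean effect variance partitions `Va_start` over the
expected model content weighted by genotype column variances:
`E[σ²_u] = Va_start / ((1−π) Σ_j var(z_j))`, converted to the χ² scale by
`S = E[σ²_u](ν−2)/ν`.  Prior degrees of freedom default to ν_a = ν_e = 4,
the de-facto convention of genomic-selection MCMC software; both are
configurable.  Production chain defaults are 160 000 iterations with
10 000 burn-in; every desk-scale run in the tests states its own (much
shorter) chain length explicitly.

### Per-iteration genomic variance

`Va` per sweep is computed as the sample variance across training animals
of their current genomic values `Σ_j z_ij u_j δ_j` (recovered cheaply as
`y − Xb − e`), and `h² = Va/(Va + σ²_e)`.  This definition keeps every h²
sample inside [0, 1] and needs no extra pass over the genotypes.  A
consequence worth knowing: because fitted genomic values absorb some noise,
the posterior-mean h² is biased slightly upward when k is large relative to
n (the recovery test sees ≈ 0.43 for a true 0.4 at n = 1000, k = 2000).

## Pre-correction

Contemporary groups are the nonempty cells of herd × breed × sex ×
harvest-date.  Group effects plus the mean are estimated once in a single
all-animals BayesCπ fit that keeps the markers in the model (so genetic
signal is not absorbed into group effects), with an intercept and a
drop-first-level identifiability constraint.  Phenotypes are then adjusted
by subtracting the posterior-mean group value — a pure per-group
translation — so downstream training/validation splits never refit group
effects on subsets.  One pooled fit per trait is used, with breed inside
the group factor.

## Evaluation

"Bootstrap replicates" are repeated random disjoint splits (no resampling
with replacement): training size is round-half-up of `n × fraction`,
sampled uniformly without regard to breed.  Each model sees byte-identical
replicate splits (split seeds derive from the master seed, the fraction and
the replicate index only).  Validation skill is the Pearson correlation r
between DGV (`Σ_j z_ij û_j`) and adjusted phenotype; the realized accuracy
is `r/√h²`, since √h² bounds a phenotype–DGV correlation.  Values above 1
are reported with a warning, never clamped — they signal an understated h².
The best-fit training fraction minimizes the coefficient of variation of r
across replicates among fractions strictly above 0.5 (ties to the larger
fraction).  Cross-model comparison uses classical paired t-tests on the
per-replicate correlations; the shipped Bonferroni family is 36 tests
(6 model pairs × 6 traits), giving the 0.05/36 ≈ 0.0014 threshold.
Per-breed accuracies standardize the within-breed validation correlation
per replicate and then average (the other order is available from the same
report; breeds with fewer than 3 validation animals are skipped with a
notice).

## The simulator

The generator reproduces the statistical structure of a five-sire-breed
commercial carcass population (default progeny counts 651/695/1095/283/516,
i.e. 3240 animals) without attempting to emulate any real genotypes.

* **Breed divergence** follows Balding–Nichols: ancestral frequency
  p0 ~ U(0.05, 0.95) per SNP; breed frequency ~ Beta(p0(1−F)/F,
  (1−p0)(1−F)/F).  F = 0.05 by default (pairwise F_ST ≈ F; a property test
  re-estimates it from the table).  F = 0 short-circuits to p0 exactly.
* **Crossing.** Sires are HWE draws from their breed's frequencies; each
  progeny gets one paternal gamete and one dam gamete drawn from the
  ancestry-weighted mixture of breed frequencies (gamete-level "grading
  up" rather than explicit multi-generation pedigrees; British-breed dams
  default to 75% own-breed / 25% Angus, Continental-breed dams to 50%
  Angus).  These mixtures are configurable, not estimated.
* **Families.** Sizes are drawn from a singleton-inflated truncated
  negative binomial: P(size = 1) equals the singleton-sire target (0.37)
  exactly, and sizes ≥ 2 follow NB(r = 0.4, p) truncated to [2, 200] with p
  solved so that the fraction of animals in families of ≤ 10 hits its
  target (0.45).  A plain zero-truncated NB cannot reach both targets
  jointly (its singleton probability maxes out near 0.33 at the required
  tail weight), which is why the singleton mass is explicit.
* **Architectures.** `n_qtl` loci get Gaussian effects; the "mixture"
  option designates one large-effect QTL whose 2pq-weighted variance share
  is set to `large_effect_fraction_of_vg`.  Effects are rescaled so the
  empirical var(g) equals `target_h2` on a unit-phenotypic-variance scale,
  and the residual variance is then `var(g)(1−h²)/h²` so the realized
  heritability is exact up to noise.  Breed-specific QTL columns are
  rewritten in place: resampled to MAF ≥ 0.05 within the named breed and
  fixed at dosage 0 in all others (assertable by direct count).
* **Phenotypes.** `y = μ + cg + g + e` with contemporary groups formed as
  4 herds × breed × 2 sexes × 2 dates (empty cells pruned) and cg effects
  N(0, cg_effect_sd²).  The output table carries true g and cg per animal
  so recovery tests never re-derive truth.
* **Missingness** is injected as an entry-wise Bernoulli mask (default
  overall rate 0.89%); the dosage store underneath is never altered.

What the generator does **not** emulate: linkage and LD (markers are
unlinked), selection, multi-generation pedigrees, genotyping-error
structure.  Tests that pass on these data show the estimation machinery is
correct under the stated generative model; they do not certify accuracy
levels on real LD-structured genotypes.  One concrete consequence: with
unlinked markers, fixing π = 0.95 (BayesB95) on a trait where every marker
is causal genuinely discards variance, whereas on real data LD lets the
retained markers tag the excluded loci — so the near-equivalence of
BayesB95 and BayesC0 seen on infinitesimal traits in LD-rich cattle data
does not reproduce here (measured gap ≈ −0.07 in validation r), while the
BayesA/BayesC0 near-equivalence and the oligogenic advantage of BayesA/B95
do reproduce.

## Quality control

Animals below 0.95 call rate are removed first, then SNPs below 0.89 call
rate on the surviving animals, then SNPs with MAF below 0.01 recomputed on
the survivors; removal is strict "<" so boundary values survive, and a SNP
with zero called animals is removed whenever a MAF filter is in force.
The filter order is a package choice (the source conventions do not fix
one); it makes the MAF reflect the analyzed animal set and is idempotent.
Missing genotypes are mean-imputed within SNP — haplotype-based imputation
is deliberately out of scope; at ~1% missingness mean imputation preserves
allele frequencies and the column variances the priors depend on.

## Numerical and engineering choices

* The chain kernel is compiled with numba; genotypes are stored transposed
  (SNPs × animals, C-contiguous) so each locus update is a contiguous dot
  product; the residual is updated only when the locus contribution
  changes.
* Determinism: a chain is a pure function of (data, config, seed); reruns
  are bit-identical.  Split seeds and per-model fit seeds derive from the
  master seed with a stable CRC tag (no salted hashing).
* π is clamped to [1e-8, 1 − 1e-8] inside odds computations; π = 1 is
  accepted as a degenerate chain (nothing ever included) with the prior
  scale computed at the boundary and never consulted.
* Ridge/BLUP cross-checks use a dense solve `(Z'Z + λI)^{-1}Z'y`; instances
  are test-sized by construction.

## Desk-scale test sizes

The test and acceptance runs use scaled-down problems chosen to keep the
statistical contrasts they probe comfortably resolvable: oracle checks at
n = 200–1000 and k = 500–2000 with 20 000–30 000 sweeps; comparative runs
(model ordering, breed-specific QTL, best-fit fraction) at n = 800–3000,
k = 300–1200 with 400–6000 sweeps and 10 replicate splits.  Production
analyses would use the 160 000-iteration defaults.

## Known limitations

* No LD, dominance, epistasis, or multi-trait support.
* Mean imputation rather than phasing-based imputation.
* h² per iteration is a derived statistic of fitted genomic values, not a
  sampled model parameter; its small upward bias at k ≫ n is documented
  above.
* BayesCπ's documented tendency to underestimate h² on large-effect traits
  in the source software is not reproduced or investigated here.
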
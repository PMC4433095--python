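# bayesalphabet

Bayesian-alphabet whole-genome regression for genomic prediction in
multi-breed, crossbred livestock populations.

Commercial beef cattle are mostly crossbred, pedigree is often unknown, and
genetic evaluation has historically stopped at the purebred sector.  Direct
genomic values (DGV) — an animal's predicted genetic merit computed as the
sum of estimated SNP effects over its genotype — make selection and
management decisions possible from a DNA sample alone.  This package
implements the full analysis stack used to study that setting: the four
classical whole-genome regression samplers, genotype quality control,
contemporary-group pre-correction, bootstrap training/validation evaluation
with realized accuracies, and a multi-breed population simulator so every
stage is testable without proprietary data.

## The model

All samplers fit

y_i = Σ_j z_ij u_j + e_i,  z_ij ∈ {−10, 0, 10} (AA/AB/BB),

with marker effects u_j ~ N(0, σ²) with probability 1 − π and u_j = 0 with
probability π, scaled-inverse-χ² priors on all variances, and single-site
Gibbs sampling (Metropolis–Hastings inclusion steps for BayesB).  The
family members differ in whether the marker variance is per-locus or
common, and whether π is fixed or estimated:

* **BayesA** — per-locus variances, π = 0 (all markers in);
* **BayesB** — per-locus variances, fixed π (e.g. 0.95);
* **BayesC** — common variance, fixed π (π = 0 is "BayesC0", the
  unknown-variance cousin of GBLUP);
* **BayesCπ** — common variance, π estimated with a uniform prior.

Validation skill is the correlation r between DGV and (pre-corrected)
phenotype; the *realized accuracy* is r/√h², since √h² is the ceiling of
that correlation.  See `docs/methods.md` for the full conditionals, prior
construction, and simulator design.

## Worked example

```python
import numpy as np
from bayesalphabet import (BayesAlphabet, ModelConfig, TraitArchitecture,
                           cross_validate, encode_centered_ten, simulate_dataset)
from bayesalphabet.simulate import BreedSpec

# an oligogenic trait: 20 QTL, one carrying 25% of the genetic variance
arch = TraitArchitecture(n_qtl=20, target_h2=0.4, effect_dist="mixture",
                         large_effect_fraction_of_vg=0.25)
breeds = [BreedSpec("Angus", 400, {"Angus": 1.0}),
          BreedSpec("Hereford", 400, {"Hereford": 0.75, "Angus": 0.25})]
gm, pheno, _ = simulate_dataset(arch, n_snps=900, breeds=breeds, seed=42,
                                missing_rate=0.0)
gm = encode_centered_ten(gm)
y = pheno["y"].to_numpy(); y -= y.mean()

res = BayesAlphabet(y, gm, ModelConfig(model="Cpi", pi=0.5, va_start=0.4,
                    ve_start=0.6, chain_length=6000, burn_in=1000)).fit(seed=1)
print(res.summary())
```

prints

```
Bayesian-alphabet whole-genome regression
=========================================================
model:            BayesCpi
animals:          800
markers:          900
chain:            6000 iterations (1000 burn-in)
seed:             1
---------------------------------------------------------
genomic variance (Va):       0.3984
residual variance (Ve):      0.6031
heritability (h2):           0.3975
pi (posterior mean):         0.9762
markers with inclusion > 0.5: 7
=========================================================
```

The posterior mean π ≈ 0.98 says the data support ~2% of the 900 markers
carrying effects — the simulated architecture (20/900 QTL) recovered from
phenotypes alone — and the h² posterior mean 0.40 matches the simulated 0.4.
Comparing models on identical bootstrap splits:

```python
configs = {"C0": ModelConfig(model="C", pi=0.0, va_start=0.4, ve_start=0.6,
                             chain_length=4000, burn_in=800),
           "A":  ModelConfig(model="A", pi=0.0, va_start=0.4, ve_start=0.6,
                             chain_length=4000, burn_in=800)}
rep = cross_validate(y, gm, configs, fractions=[0.7], n_replicates=10, seed=42)
print(rep.summary()[["model", "fraction", "mean_r", "cv", "realized_accuracy"]])
```

```
  model  fraction    mean_r        cv  realized_accuracy
0     A       0.7  0.549824  0.055391           0.739889
1    C0       0.7  0.395927  0.088807           0.611937
```

BayesA's per-locus variances let the large QTL escape over-shrinkage: +0.15
in validation correlation over the equal-variance BayesC0 on this trait,
the signature advantage of unequal-variance models on oligogenic traits.

A `bayesalphabet` CLI wraps the same pipeline on tab-delimited files
(`simulate`, `qc`, `precorrect`, `train`, `predict`, `evaluate`, `compare`).

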
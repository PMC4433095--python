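"""The whole-genome regression model object.

Statsmodels-style usage::

    model = BayesAlphabet(y_adj, genotypes, config)     # or from_dataframe
    res = model.fit(seed=1)
    res.summary()
    dgv = res.predict(validation_genotypes)

The model is y_i = sum_j z_ij u_j + e_i with z in {-10, 0, 10} (AA = 10,
AB = 0, BB = -10), marker effects u_j ~ N(0, sigma2) with probability
1 - pi or exactly 0 with probability pi, scaled-inverse-chi-square priors
on all variances, and optionally a flat-prior fixed-effect block (e.g.
contemporary groups).  Four samplers share the machinery:

=========  ===========================  ==========================
model      marker variance              pi
=========  ===========================  ==========================
BayesA     one per locus                fixed at 0
BayesB     one per locus                fixed (MH inclusion step)
BayesC     common to all loci           fixed (0 -> "BayesC0")
BayesCpi   common to all loci           estimated, uniform prior
=========  ===========================  ==========================
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import samplers
from ._mcmc import run_chain_kernel
from .config import ModelConfig
from .genotypes import CENTERED_TEN, GenotypeMatrix
from .results import BayesAlphabetResults


class BayesAlphabet:
    """Bayesian-alphabet whole-genome regression.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Phenotypes (typically pre-corrected for contemporary-group effects).
    genotypes : GenotypeMatrix or ndarray
        Centered-ten coded markers.  A :class:`GenotypeMatrix` must carry
        coding state ``centered-ten`` and an empty mask; a plain array is
        taken as already coded.
    config : ModelConfig
    exog : ndarray, optional
        Fixed-effect design matrix (full rank; include the intercept and use
        a drop-one-level constraint for factors).
    """

    def __init__(self, endog, genotypes, config: ModelConfig, exog=None,
                 snp_ids=None):
        self.endog = np.ascontiguousarray(endog, dtype=np.float64)
        if np.isnan(self.endog).any():
            raise ValueError("NaN in phenotypes")
        if isinstance(genotypes, GenotypeMatrix):
            genotypes._require(CENTERED_TEN)
            if genotypes.n_missing:
                raise ValueError("genotypes still carry missing entries")
            Z = genotypes.dosages
            self.snp_ids = np.asarray(genotypes.snp_ids)
        else:
            Z = np.asarray(genotypes, dtype=np.float64)
            self.snp_ids = (
                np.asarray(snp_ids)
                if snp_ids is not None
                else np.array([f"SNP{j:06d}" for j in range(Z.shape[1])])
            )
        if Z.shape[0] != self.endog.shape[0]:
            raise ValueError("phenotype length must equal animal count")
        # SNPs x animals, contiguous rows for the single-site sweeps
        self.Zt = np.ascontiguousarray(Z.T, dtype=np.float64)
        self.exog = (
            np.ascontiguousarray(exog, dtype=np.float64)
            if exog is not None
            else np.zeros((self.endog.shape[0], 0))
        )
        self.config = config
        self.nobs = self.endog.shape[0]
        self.n_snps = self.Zt.shape[0]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str,
                       genotypes: GenotypeMatrix, config: ModelConfig,
                       exog=None) -> "BayesAlphabet":
        """Build from a phenotype table with an ``animal_id`` column,
        aligning rows to the genotype matrix (inner order of the matrix)."""
        data = data.set_index("animal_id").loc[list(genotypes.animal_ids)]
        return cls(data[trait].to_numpy(), genotypes, config, exog=exog)

    def fit(self, seed: int | None = None) -> BayesAlphabetResults:
        """Run the MCMC chain and return posterior summaries.

        Identical (data, config, seed) triples give bit-identical results.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        col_vars = self.Zt.var(axis=1)
        # pi = 1 is a legal degenerate chain (no locus ever included); the
        # prior-scale partition then has no loci to spread Va over, so the
        # scale is computed at the boundary and never consulted.
        pi_scale = min(cfg.pi, 1.0 - 1e-9)
        s_a, s_e = samplers.prior_scales(
            cfg.va_start, cfg.ve_start, pi_scale, col_vars, cfg.nu_a, cfg.nu_e
        )
        p = self.exog.shape[1]
        if p > 0:
            XtX = self.exog.T @ self.exog
            if np.linalg.matrix_rank(XtX) < p:
                # reuse the error path with column naming
                samplers.sample_fixed_effects(
                    self.exog, np.zeros(self.nobs), 1.0, np.random.default_rng(0)
                )
            XtX_inv = np.linalg.inv(XtX)
            L_cov = np.linalg.cholesky(XtX_inv)
        else:
            XtX_inv = np.zeros((0, 0))
            L_cov = np.zeros((0, 0))

        k = self.n_snps
        s2u0 = cfg.va_start / max((1.0 - pi_scale) * col_vars.sum(), 1e-300)

        (u_mean, incl, b_mean, va_tr, ve_tr, h2_tr, pi_tr, acc, e, u, delta,
         b) = run_chain_kernel(
            self.endog,
            self.Zt,
            self.exog,
            XtX_inv,
            L_cov,
            cfg.model_code,
            float(cfg.pi),
            float(s2u0),
            float(cfg.ve_start),
            float(s_a),
            float(s_e),
            float(cfg.nu_a),
            float(cfg.nu_e),
            int(cfg.chain_length),
            int(cfg.burn_in),
            int(cfg.mh_cycles),
            bool(cfg.fix_variances),
            int(seed) % (2**32 - 1),
        )
        return BayesAlphabetResults(
            model=self,
            config=cfg,
            seed=seed,
            params=pd.Series(u_mean, index=self.snp_ids, name="effect"),
            inclusion_freq=pd.Series(incl, index=self.snp_ids, name="inclusion"),
            fixed_effects=np.asarray(b_mean),
            va_samples=va_tr,
            ve_samples=ve_tr,
            h2_samples=h2_tr,
            pi_samples=pi_tr,
            mh_acceptance=float(acc),
            prior_scales=(float(s_a), float(s_e)),
            _final_state={"e": e, "u": u, "delta": delta, "b": b},
        )
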
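"""Posterior summaries of a fitted whole-genome regression chain."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BayesAlphabetResults:
    """Posterior summary of one MCMC analysis.

    ``params`` holds posterior-mean marker effects averaged over all
    post-burn-in samples with excluded-locus draws counted as zero — so a
    marker included 10% of the time has its effect shrunk by that factor
    relative to its conditional mean when included.  ``inclusion_freq`` is
    the per-SNP posterior inclusion probability.  Variance-component traces
    cover the full chain; posterior means (``va``, ``ve``, ``h2``, ``pi``)
    average the post-burn-in part.
    """

    model: object
    config: object
    seed: int
    params: pd.Series
    inclusion_freq: pd.Series
    fixed_effects: np.ndarray
    va_samples: np.ndarray
    ve_samples: np.ndarray
    h2_samples: np.ndarray
    pi_samples: np.ndarray
    mh_acceptance: float
    prior_scales: tuple
    _final_state: dict = field(default_factory=dict, repr=False)

    def _post(self, x):
        return x[self.config.burn_in:]

    @property
    def va(self) -> float:
        return float(self._post(self.va_samples).mean())

    @property
    def ve(self) -> float:
        return float(self._post(self.ve_samples).mean())

    @property
    def h2(self) -> float:
        return float(self._post(self.h2_samples).mean())

    @property
    def pi(self) -> float:
        return float(self._post(self.pi_samples).mean())

    def predict(self, genotypes) -> np.ndarray:
        """Direct genomic values for new animals: DGV_i = sum_j z_ij u_hat_j.

        Accepts a centered-ten :class:`GenotypeMatrix` (SNP ids must match
        the training panel) or a plain coded array.
        """
        from .evaluation import predict_dgv

        return predict_dgv(genotypes, self.params)

    def residual_identity_gap(self) -> float:
        """Max absolute violation of e = y - Xb - Z(u * delta) at the final
        chain state; machine-precision small when bookkeeping is intact."""
        m = self.model
        st = self._final_state
        fitted = m.Zt.T @ (st["u"] * st["delta"])
        if m.exog.shape[1]:
            fitted = fitted + m.exog @ st["b"]
        return float(np.max(np.abs(st["e"] - (m.endog - fitted))))

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"effect": self.params, "inclusion": self.inclusion_freq}
        ).rename_axis("snp_id")

    def chain_log(self) -> pd.DataFrame:
        """Per-iteration variance components (full chain, burn-in included)."""
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.va_samples)),
                "va": self.va_samples,
                "ve": self.ve_samples,
                "h2": self.h2_samples,
                "pi": self.pi_samples,
            }
        )

    def summary(self) -> str:
        cfg = self.config
        k = len(self.params)
        lines = [
            "Bayesian-alphabet whole-genome regression",
            "=" * 57,
            f"model:            Bayes{cfg.model}"
            + ("0" if cfg.model == "C" and cfg.pi == 0 else ""),
            f"animals:          {self.model.nobs}",
            f"markers:          {k}",
            f"chain:            {cfg.chain_length} iterations "
            f"({cfg.burn_in} burn-in)",
            f"seed:             {self.seed}",
            "-" * 57,
            f"genomic variance (Va):   {self.va:10.4f}",
            f"residual variance (Ve):  {self.ve:10.4f}",
            f"heritability (h2):       {self.h2:10.4f}",
        ]
        if cfg.model == "Cpi":
            lines.append(f"pi (posterior mean):     {self.pi:10.4f}")
        else:
            lines.append(f"pi (fixed):              {cfg.pi:10.4f}")
        if not np.isnan(self.mh_acceptance):
            lines.append(f"MH acceptance rate:      {self.mh_acceptance:10.4f}")
        n_in = int((self.inclusion_freq > 0.5).sum())
        lines += [
            f"markers with inclusion > 0.5: {n_in}",
            "=" * 57,
        ]
        return "\n".join(lines)
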
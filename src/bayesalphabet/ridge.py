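"""Closed-form fixed-variance ridge / BLUP solver.

BayesC with pi = 0 and known variances is exactly ridge regression of the
phenotype on the coded markers with lambda = sigma2_e / sigma2_u, which is
in turn the mixed-model BLUP of marker effects.  The dense solve here is
the independent oracle the MCMC samplers are verified against; instances
are test-sized by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RidgeProblem:
    y: np.ndarray
    Z: np.ndarray  # coded genotypes, animals x SNPs
    lam: float  # sigma2_e / sigma2_u

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if self.Z.shape[0] != np.asarray(self.y).shape[0]:
            raise ValueError("dimensions not conformable")


def solve_ridge(problem: RidgeProblem) -> np.ndarray:
    """u_hat = (Z'Z + lambda I)^{-1} Z'y via a dense solve."""
    Z = np.asarray(problem.Z, dtype=float)
    y = np.asarray(problem.y, dtype=float)
    k = Z.shape[1]
    return np.linalg.solve(Z.T @ Z + problem.lam * np.eye(k), Z.T @ y)


def blup_genomic_values(problem: RidgeProblem) -> np.ndarray:
    """Z u_hat: the BLUP of genomic values for the given variance ratio."""
    return np.asarray(problem.Z, dtype=float) @ solve_ridge(problem)
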
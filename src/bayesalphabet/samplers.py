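"""Full-conditional building blocks of the Bayesian-alphabet samplers.

These are the scalar/vector forms of the draws performed inside the
compiled chain kernel (:mod:`bayesalphabet._mcmc`), exposed so each
conditional can be exercised and verified on its own.  ``rng`` arguments
take a :class:`numpy.random.Generator`.

Notation: for locus j, ``r`` is z_j'(e + z_j u_j_old delta_j_old) — the
locus's share of the data given every other effect at its current value —
and ``zz`` is z_j'z_j.
"""

from __future__ import annotations

import numpy as np


def scaled_inv_chi2(df: float, scale: float, rng, size=None):
    """Draw from the scaled inverse chi-square: df * scale / chi2(df).

    Mean (for df > 2) is df * scale / (df - 2).
    """
    return df * scale / rng.chisquare(df, size=size)


def prior_scales(
    va_start: float,
    ve_start: float,
    pi: float,
    col_vars: np.ndarray,
    nu_a: float = 4.0,
    nu_e: float = 4.0,
) -> tuple[float, float]:
    """Scaled-inverse-chi-square prior scales from starting variances.

    The additive variance is partitioned over the (1 - pi) fraction of loci
    expected in the model, weighted by genotype column variances: the prior
    mean per-locus effect variance is ``va_start / ((1 - pi) * sum(col_vars))``.
    A scaled-inv-chi2(nu, S) has mean S * nu / (nu - 2), so S = mean * (nu - 2) / nu
    for nu > 2 (for nu <= 2 the prior mean does not exist and S is taken as
    the target value itself).  The residual scale comes from ``ve_start``
    the same way.
    """
    if va_start <= 0 or ve_start <= 0:
        raise ValueError("starting variances must be > 0")
    if pi >= 1.0:
        raise ValueError("pi = 1 leaves no loci in the model")
    total = float(np.sum(col_vars))
    if total <= 0:
        raise ValueError("sum of genotype column variances must be > 0")
    mean_a = va_start / ((1.0 - pi) * total)
    s_a = mean_a * (nu_a - 2.0) / nu_a if nu_a > 2 else mean_a
    s_e = ve_start * (nu_e - 2.0) / nu_e if nu_e > 2 else ve_start
    return s_a, s_e


def effect_conditional_moments(r, zz, s2e, s2u):
    """Mean and variance of u_j | rest: N(r / c, s2e / c) with
    c = zz + s2e / s2u.  As s2u -> inf this tends to the OLS solution
    r / zz; as s2e/s2u grows the mean shrinks toward 0."""
    c = zz + s2e / s2u
    return r / c, s2e / c


def sample_marker_effect(r, zz, s2e, s2u, rng):
    """Gibbs draw of an included marker effect.  ``zz == 0`` (monomorphic
    survivor) forces the effect to zero."""
    if zz == 0:
        return 0.0
    m, v = effect_conditional_moments(r, zz, s2e, s2u)
    return m + np.sqrt(v) * rng.standard_normal()


def sample_locus_variance(u_j, nu_a, s_a, rng):
    """BayesA/B per-locus variance draw:
    scaled-inv-chi2(nu_a + 1, (nu_a S_a + u_j^2) / (nu_a + 1))."""
    return scaled_inv_chi2(nu_a + 1.0, (nu_a * s_a + u_j**2) / (nu_a + 1.0), rng)


def indicator_log_odds(r, zz, s2e, s2u, pi):
    """Log odds of delta_j = 1 vs 0 with u_j integrated out (BayesC/Cpi).

    Under delta = 0, r ~ N(0, v0) with v0 = zz * s2e; under delta = 1,
    r ~ N(0, v1) with v1 = v0 + zz^2 * s2u.  The odds are
    ((1 - pi)/pi) * sqrt(v0/v1) * exp(r^2 (1/v0 - 1/v1) / 2).
    """
    pi = min(max(pi, 1e-8), 1.0 - 1e-8)
    v0 = zz * s2e
    v1 = v0 + zz * zz * s2u
    return (
        np.log((1.0 - pi) / pi)
        + 0.5 * np.log(v0 / v1)
        + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
    )


def sample_indicator_gibbs(r, zz, s2e, s2u, pi, rng):
    """Bernoulli draw of the inclusion indicator (BayesC/Cpi).  pi = 0 is
    the BayesC0 path: always included, no randomness consumed."""
    if pi <= 0.0:
        return 1
    p1 = 1.0 / (1.0 + np.exp(-indicator_log_odds(r, zz, s2e, s2u, pi)))
    return int(rng.random() < p1)


def sample_indicator_mh(r, zz, s2e, pi, nu_a, s_a, delta, s2_cur, rng, cycles=2):
    """BayesB indicator/variance update: ``cycles`` Metropolis-Hastings
    proposals drawn from the prior (delta* ~ Bern(1 - pi), sigma2* ~
    scaled-inv-chi2(nu_a, S_a)); acceptance ratio is the ratio of marginal
    likelihoods N(r; 0, v0 + delta zz^2 sigma2).  Returns
    (delta, sigma2, n_accepted)."""
    v0 = zz * s2e

    def log_ml(d, s2):
        v = v0 + d * zz * zz * s2
        return -0.5 * np.log(v) - 0.5 * r * r / v

    lm = log_ml(delta, s2_cur)
    acc = 0
    for _ in range(cycles):
        d_prop = int(rng.random() < (1.0 - pi))
        s2_prop = scaled_inv_chi2(nu_a, s_a, rng)
        lm_prop = log_ml(d_prop, s2_prop)
        if np.log(rng.random()) < lm_prop - lm:
            delta, s2_cur, lm = d_prop, s2_prop, lm_prop
            acc += 1
    return delta, s2_cur, acc


def sample_pi(k: int, m: int, rng):
    """BayesCpi: pi | m included of k loci ~ Beta(k - m + 1, m + 1)
    (uniform prior on pi)."""
    return rng.beta(k - m + 1.0, m + 1.0)


def sample_residual_variance(e, nu_e, s_e, rng):
    """Residual variance draw:
    scaled-inv-chi2(nu_e + n, (e'e + nu_e S_e) / (nu_e + n))."""
    e = np.asarray(e, dtype=float)
    n = e.shape[0]
    return scaled_inv_chi2(nu_e + n, (e @ e + nu_e * s_e) / (nu_e + n), rng)


def sample_fixed_effects(X, w, s2e, rng):
    """Block draw of fixed-effect coefficients with a flat prior:
    b ~ N((X'X)^{-1} X'w, s2e (X'X)^{-1}) where w = e + X b_old.

    Raises on rank deficiency, naming the confounded columns.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        return np.zeros(0)
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < X.shape[1]:
        # identify columns involved in the deficiency via QR pivoting
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True)
        bad = sorted(piv[rank:])
        raise np.linalg.LinAlgError(
            f"fixed-effect design rank deficient; confounded columns {bad}"
        )
    XtX_inv = np.linalg.inv(XtX)
    mean = XtX_inv @ (X.T @ w)
    L = np.linalg.cholesky(XtX_inv)
    return mean + np.sqrt(s2e) * (L @ rng.standard_normal(X.shape[1]))


def genomic_variance(g: np.ndarray, s2e: float) -> tuple[float, float]:
    """(Va, h2) from current genomic values: Va is the sample variance of g
    across animals, h2 = Va / (Va + s2e)."""
    g = np.asarray(g, dtype=float)
    if g.shape[0] < 2:
        raise ValueError("genomic variance undefined for fewer than 2 animals")
    va = float(g.var(ddof=1))
    return va, va / (va + s2e) if (va + s2e) > 0 else 0.0


def weighted_start(va: np.ndarray, ve: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Sample-size-weighted means of within-group additive and residual
    variance estimates, used as chain starting values."""
    va, ve, n = (np.asarray(x, dtype=float) for x in (va, ve, n))
    if va.size == 0 or va.size != ve.size or va.size != n.size:
        raise ValueError("need equal-length nonempty variance and weight lists")
    if np.any(n <= 0):
        raise ValueError("weights must be positive")
    return float(np.average(va, weights=n)), float(np.average(ve, weights=n))
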
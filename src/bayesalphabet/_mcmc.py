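"""Numba single-site Gibbs / Metropolis-Hastings kernels.

One compiled function runs a whole chain for any of the four models
(BayesA, BayesB, BayesC, BayesCpi).  The genotype matrix is passed
transposed (SNPs x animals, C-contiguous) so each locus row is a
contiguous dot product.  The residual vector e = y - Xb - Z(u*delta) is
maintained incrementally; the conditional draws follow the standard
Bayesian-alphabet full conditionals:

* marker effect  u_j | rest ~ N(r_j / c_j, sigma2_e / c_j)
  with c_j = z_j'z_j + sigma2_e / sigma2_uj and
  r_j = z_j'(e + z_j u_j_old * delta_j_old)
* locus variance (A, B)   ~ scaled-inv-chi2(nu_a + 1, (nu_a S_a + u_j^2)/(nu_a + 1))
* common variance (C, Cpi)~ scaled-inv-chi2(nu_a + m, (nu_a S_a + sum u^2)/(nu_a + m))
* indicator (C, Cpi): u_j integrated out; odds(delta=1 : 0) =
  ((1-pi)/pi) sqrt(v0/v1) exp(r_j^2 (1/v0 - 1/v1)/2),
  v0 = z'z sigma2_e, v1 = v0 + (z'z)^2 sigma2_u
* indicator (B): mh_cycles Metropolis-Hastings proposals from the prior
  (delta* ~ Bern(1-pi), sigma2* ~ scaled-inv-chi2(nu_a, S_a)); acceptance is
  the ratio of N(r_j; 0, v) marginal likelihoods
* pi (Cpi) ~ Beta(k - m + 1, m + 1)
* residual variance ~ scaled-inv-chi2(nu_e + n, (e'e + nu_e S_e)/(nu_e + n))

The per-iteration genomic variance Va is the variance across animals of
their current genomic values Z(u*delta), recovered cheaply as
y - Xb - e, and h2 = Va / (Va + sigma2_e).
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODEL_A, MODEL_B, MODEL_C, MODEL_CPI = 0, 1, 2, 3


@njit(cache=True)
def _scaled_inv_chi2(df, scale):
    return df * scale / np.random.chisquare(df)


@njit(cache=True)
def _dot(a, b):
    s = 0.0
    for i in range(a.shape[0]):
        s += a[i] * b[i]
    return s


@njit(cache=True)
def _axpy(alpha, x, y):
    for i in range(x.shape[0]):
        y[i] += alpha * x[i]


@njit(cache=True)
def _log_marginal(r, v):
    return -0.5 * np.log(v) - 0.5 * r * r / v


@njit(cache=True)
def run_chain_kernel(
    y,
    Zt,  # (k, n) C-contiguous centered-ten genotypes
    X,  # (n, p) fixed-effect design; p may be 0
    XtX_inv,  # (p, p)
    L_cov,  # (p, p) lower Cholesky of XtX_inv
    model,  # 0=A 1=B 2=C 3=Cpi
    pi0,
    s2u0,
    s2e0,
    Sa,
    Se,
    nu_a,
    nu_e,
    chain_length,
    burn_in,
    mh_cycles,
    fix_variances,
    seed,
):
    np.random.seed(seed)
    k, n = Zt.shape
    p = X.shape[1]

    zz = np.empty(k)
    for j in range(k):
        zz[j] = _dot(Zt[j], Zt[j])

    u = np.zeros(k)
    delta = np.zeros(k, dtype=np.int64)
    s2u_loc = np.full(k, s2u0)  # per-locus (A, B)
    s2u = s2u0  # common (C, Cpi)
    s2e = s2e0
    pi = pi0
    b = np.zeros(p)
    xb = np.zeros(n)
    e = y.copy()

    if model == MODEL_A:
        for j in range(k):
            delta[j] = 1

    u_mean = np.zeros(k)
    incl = np.zeros(k)
    b_mean = np.zeros(p)
    va_tr = np.zeros(chain_length)
    ve_tr = np.zeros(chain_length)
    h2_tr = np.zeros(chain_length)
    pi_tr = np.zeros(chain_length)
    mh_prop = 0
    mh_acc = 0
    n_kept = 0

    for it in range(chain_length):
        # ---- fixed effects: block draw, flat prior --------------------
        if p > 0:
            w = np.empty(p)
            for c in range(p):
                s = 0.0
                for i in range(n):
                    s += X[i, c] * (e[i] + xb[i])
                w[c] = s
            mean = XtX_inv @ w
            znorm = np.empty(p)
            for c in range(p):
                znorm[c] = np.random.normal()
            b_new = mean + np.sqrt(s2e) * (L_cov @ znorm)
            for i in range(n):
                old = xb[i]
                s = 0.0
                for c in range(p):
                    s += X[i, c] * b_new[c]
                xb[i] = s
                e[i] += old - s
            b = b_new

        # ---- loci ------------------------------------------------------
        for j in range(k):
            if zz[j] == 0.0:
                u[j] = 0.0
                delta[j] = 0
                continue
            old_contrib = u[j] * delta[j]
            r = _dot(Zt[j], e) + zz[j] * old_contrib

            if model == MODEL_A:
                c_j = zz[j] + s2e / s2u_loc[j]
                u_new = r / c_j + np.sqrt(s2e / c_j) * np.random.normal()
                delta[j] = 1
                if not fix_variances:
                    s2u_loc[j] = _scaled_inv_chi2(
                        nu_a + 1.0, (nu_a * Sa + u_new * u_new) / (nu_a + 1.0)
                    )
            elif model == MODEL_B:
                d_cur = delta[j]
                s2_cur = s2u_loc[j]
                v0 = zz[j] * s2e
                lm_cur = _log_marginal(r, v0 + d_cur * zz[j] * zz[j] * s2_cur)
                for _ in range(mh_cycles):
                    d_prop = 1 if np.random.random() < (1.0 - pi) else 0
                    s2_prop = _scaled_inv_chi2(nu_a, Sa)
                    lm_prop = _log_marginal(
                        r, v0 + d_prop * zz[j] * zz[j] * s2_prop
                    )
                    mh_prop += 1
                    if np.log(np.random.random()) < lm_prop - lm_cur:
                        d_cur = d_prop
                        s2_cur = s2_prop
                        lm_cur = lm_prop
                        mh_acc += 1
                delta[j] = d_cur
                s2u_loc[j] = s2_cur
                if d_cur == 1:
                    c_j = zz[j] + s2e / s2u_loc[j]
                    u_new = r / c_j + np.sqrt(s2e / c_j) * np.random.normal()
                    if not fix_variances:
                        s2u_loc[j] = _scaled_inv_chi2(
                            nu_a + 1.0, (nu_a * Sa + u_new * u_new) / (nu_a + 1.0)
                        )
                else:
                    u_new = 0.0
            else:  # BayesC / BayesCpi
                if pi <= 0.0:
                    delta[j] = 1
                else:
                    pi_c = min(max(pi, 1e-8), 1.0 - 1e-8)
                    v0 = zz[j] * s2e
                    v1 = v0 + zz[j] * zz[j] * s2u
                    log_odds = (
                        np.log((1.0 - pi_c) / pi_c)
                        + 0.5 * np.log(v0 / v1)
                        + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
                    )
                    p1 = 1.0 / (1.0 + np.exp(-log_odds))
                    delta[j] = 1 if np.random.random() < p1 else 0
                if delta[j] == 1:
                    c_j = zz[j] + s2e / s2u
                    u_new = r / c_j + np.sqrt(s2e / c_j) * np.random.normal()
                else:
                    u_new = 0.0

            u[j] = u_new
            new_contrib = u_new * delta[j]
            if new_contrib != old_contrib:
                _axpy(old_contrib - new_contrib, Zt[j], e)

        # ---- common marker variance (C, Cpi) ---------------------------
        m = 0
        for j in range(k):
            m += delta[j]
        if (model == MODEL_C or model == MODEL_CPI) and not fix_variances:
            ssq = 0.0
            for j in range(k):
                if delta[j] == 1:
                    ssq += u[j] * u[j]
            s2u = _scaled_inv_chi2(nu_a + m, (nu_a * Sa + ssq) / (nu_a + m))

        # ---- pi (Cpi) --------------------------------------------------
        if model == MODEL_CPI:
            pi = np.random.beta(k - m + 1.0, m + 1.0)
            if pi < 1e-8:
                pi = 1e-8
            elif pi > 1.0 - 1e-8:
                pi = 1.0 - 1e-8

        # ---- residual variance ----------------------------------------
        if not fix_variances:
            sse = _dot(e, e)
            s2e = _scaled_inv_chi2(nu_e + n, (sse + nu_e * Se) / (nu_e + n))

        # ---- genomic variance / h2 ------------------------------------
        gm_ = 0.0
        for i in range(n):
            gm_ += y[i] - xb[i] - e[i]
        gm_ /= n
        va = 0.0
        for i in range(n):
            d = (y[i] - xb[i] - e[i]) - gm_
            va += d * d
        va /= max(n - 1, 1)
        va_tr[it] = va
        ve_tr[it] = s2e
        h2_tr[it] = va / (va + s2e) if (va + s2e) > 0 else 0.0
        pi_tr[it] = pi

        if it >= burn_in:
            n_kept += 1
            for j in range(k):
                u_mean[j] += u[j] * delta[j]
                incl[j] += delta[j]
            for c in range(p):
                b_mean[c] += b[c]

    if n_kept > 0:
        u_mean /= n_kept
        incl /= n_kept
        if p > 0:
            b_mean /= n_kept
    acc_rate = mh_acc / mh_prop if mh_prop > 0 else np.nan
    return u_mean, incl, b_mean, va_tr, ve_tr, h2_tr, pi_tr, acc_rate, e, u, delta, b
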
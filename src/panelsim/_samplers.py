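"""Single-site Gibbs kernels for the Bayes-B / Bayes-C mixture regressions.

Compiled with numba; genotypes are passed transposed (loci x individuals,
C-contiguous) so each locus update streams over a contiguous row.  Both
kernels maintain the residual vector e = y - mu - X b and, per locus,
sample an inclusion indicator from the marginal odds with the effect
integrated out, then the effect from its normal full conditional.

Variance priors are scaled-inverse-chi-square: sigma^2 = df*S / chi2(df).
Bayes-C uses one common effect variance; Bayes-B gives every included
locus its own variance (point-mass-at-zero + scaled-t mixture).  All
randomness flows through numpy's legacy RNG seeded once per call, so a
fixed seed reproduces the chain bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _dot(a, b):
    s = 0.0
    for i in range(a.size):
        s += a[i] * b[i]
    return s


@njit(cache=True)
def bayes_mixture_gibbs(
    Xt,                # (p, n) centered genotypes, C-contiguous
    y,                 # (n,) phenotypes
    n_iter,
    burn_in,
    thin,
    seed,
    pi_zero,           # prior P(effect == 0); ignored if update_pi
    df_b, scale_b,     # effect-variance prior
    df_e, scale_e,     # residual-variance prior
    per_locus_var,     # True -> Bayes-B, False -> Bayes-C
    update_var_b,
    update_var_e,
    update_pi,
    update_scale_b,    # Bayes-B only: sample the common variance scale
):
    p, n = Xt.shape
    np.random.seed(seed)

    xx = np.empty(p)
    for j in range(p):
        xx[j] = _dot(Xt[j], Xt[j])
    p_poly = 0
    for j in range(p):
        if xx[j] > 0.0:
            p_poly += 1

    scale_b0 = scale_b  # heuristic prior mean of the sampled scale
    scale_shape = 1.1

    b = np.zeros(p)
    var_j = np.full(p, scale_b)      # per-locus variances (Bayes-B)
    var_b = scale_b                  # common variance (Bayes-C)
    var_e = scale_e
    pi = pi_zero
    mu = y.mean()
    e = y - mu

    b_sum = np.zeros(p)
    b_sumsq = np.zeros(p)
    incl_sum = np.zeros(p)
    mu_sum = 0.0
    var_b_sum = 0.0
    var_e_sum = 0.0
    pi_sum = 0.0
    n_samples = 0

    for it in range(n_iter):
        # intercept
        mu_new = np.random.normal(mu + e.mean(), np.sqrt(var_e / n))
        delta_mu = mu_new - mu
        for i in range(n):
            e[i] -= delta_mu
        mu = mu_new

        n_incl = 0
        ssq_b = 0.0
        for j in range(p):
            if xx[j] <= 0.0:
                continue
            row = Xt[j]
            rhs = _dot(row, e) + xx[j] * b[j]
            if per_locus_var:
                if update_var_b and b[j] == 0.0:
                    # refresh the locus variance from its prior
                    var_j[j] = df_b * scale_b / np.random.chisquare(df_b)
                vb = var_j[j]
            else:
                vb = var_b
            if pi >= 1.0:
                include = False
            elif pi <= 0.0:
                include = True
            else:
                v0 = xx[j] * var_e
                v1 = xx[j] * xx[j] * vb + v0
                log0 = np.log(pi) - 0.5 * (np.log(v0) + rhs * rhs / v0)
                log1 = np.log(1.0 - pi) - 0.5 * (np.log(v1) + rhs * rhs / v1)
                prob1 = 1.0 / (1.0 + np.exp(log0 - log1))
                include = np.random.random() < prob1
            if include:
                c = xx[j] + var_e / vb
                mean_j = rhs / c
                b_new = mean_j + np.random.normal(0.0, 1.0) * np.sqrt(var_e / c)
                diff = b[j] - b_new
                if diff != 0.0:
                    for i in range(n):
                        e[i] += row[i] * diff
                b[j] = b_new
                n_incl += 1
                if per_locus_var:
                    if update_var_b:
                        var_j[j] = (
                            b_new * b_new + df_b * scale_b
                        ) / np.random.chisquare(df_b + 1.0)
                    ssq_b += b_new * b_new / var_j[j]
                else:
                    ssq_b += b_new * b_new
            else:
                if b[j] != 0.0:
                    for i in range(n):
                        e[i] += row[i] * b[j]
                    b[j] = 0.0

        if (not per_locus_var) and update_var_b:
            var_b = (ssq_b + df_b * scale_b) / np.random.chisquare(df_b + n_incl)
        if per_locus_var and update_var_b and update_scale_b:
            # conjugate gamma update of the common scale of the locus
            # variances; every locus carries a variance, refreshed from the
            # prior while its effect is excluded
            sum_inv = 0.0
            for j in range(p):
                if xx[j] > 0.0:
                    sum_inv += 1.0 / var_j[j]
            shape = scale_shape + 0.5 * df_b * p_poly
            rate = scale_shape / scale_b0 + 0.5 * df_b * sum_inv
            scale_b = np.random.gamma(shape, 1.0 / rate)
        if update_var_e:
            var_e = (_dot(e, e) + df_e * scale_e) / np.random.chisquare(df_e + n)
        if update_pi:
            # Beta(1,1) prior on P(zero)
            n_zero = p - n_incl
            a = np.random.gamma(n_zero + 1.0, 1.0)
            bgam = np.random.gamma(n_incl + 1.0, 1.0)
            pi = a / (a + bgam)

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_samples += 1
            mu_sum += mu
            var_e_sum += var_e
            var_b_sum += var_b if not per_locus_var else var_j.mean()
            pi_sum += pi
            for j in range(p):
                b_sum[j] += b[j]
                b_sumsq[j] += b[j] * b[j]
                if b[j] != 0.0:
                    incl_sum[j] += 1.0

    inv = 1.0 / n_samples
    b_mean = b_sum * inv
    b_var = b_sumsq * inv - b_mean * b_mean
    return (
        mu_sum * inv,
        b_mean,
        np.sqrt(np.maximum(b_var, 0.0)),
        incl_sum * inv,
        var_b_sum * inv,
        var_e_sum * inv,
        pi_sum * inv,
        n_samples,
    )
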
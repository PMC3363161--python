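"""Numba kernels for the single-site Gibbs samplers.

All kernels maintain the residual vector e = y - mu - X_c a (- W_c d) and
update it incrementally per SNP.  Randomness comes from numba's internal
np.random state, seeded once inside each kernel, so a chain is reproducible
from (seed, config) alone.  Effects of excluded SNPs are exactly zero in
every stored sample, so posterior inclusion probabilities can be recovered
as the fraction of nonzero retained effects.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _chi2(df):
    return 2.0 * np.random.gamma(0.5 * df, 1.0)


@njit(cache=True)
def _logistic(x):
    if x > 35.0:
        return 1.0
    if x < -35.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def bayescpi_chain(y, Xt, xtx, active, n_iter, burn_in, thin,
                   pi0, sample_pi, nu_a, s2_prior_a, nu_e, s2_prior_e,
                   fix_s2a, s2a_fix, fix_s2e, s2e_fix, fix_mu, mu_fix, seed):
    """BayesCpi: normal mixture with a common effect variance.

    Returns (a_samples, mu_s, s2a_s, s2e_s, pi_s, genvar_s).
    """
    np.random.seed(seed)
    k, n = Xt.shape
    k_active = 0
    for j in range(k):
        if active[j]:
            k_active += 1
    a = np.zeros(k)
    mu = mu_fix if fix_mu else y.mean()
    e = y - mu
    s2a = s2a_fix if fix_s2a else max(s2_prior_a, 1e-8)
    s2e = s2e_fix if fix_s2e else max(s2_prior_e, 1e-8)
    pi = pi0

    n_keep = (n_iter - burn_in + thin - 1) // thin
    a_samp = np.zeros((n_keep, k))
    mu_s = np.zeros(n_keep)
    s2a_s = np.zeros(n_keep)
    s2e_s = np.zeros(n_keep)
    pi_s = np.zeros(n_keep)
    genvar_s = np.zeros(n_keep)
    kept = 0

    for it in range(n_iter):
        lam = s2e / s2a
        m = 0
        for j in range(k):
            if not active[j]:
                continue
            aj = a[j]
            r = xtx[j] * aj
            for i in range(n):
                r += Xt[j, i] * e[i]
            v0 = xtx[j] * s2e
            v1 = xtx[j] * xtx[j] * s2a + v0
            logbf = 0.5 * (np.log(v0 / v1) + r * r * (1.0 / v0 - 1.0 / v1))
            if pi <= 0.0:
                inc = True
            elif pi >= 1.0:
                inc = False
            else:
                p1 = _logistic(np.log((1.0 - pi) / pi) + logbf)
                inc = np.random.random() < p1
            new = 0.0
            if inc:
                c = xtx[j] + lam
                new = r / c + np.random.normal() * np.sqrt(s2e / c)
                m += 1
            if new != aj:
                d = aj - new
                for i in range(n):
                    e[i] += Xt[j, i] * d
                a[j] = new
        if not fix_mu:
            me = 0.0
            for i in range(n):
                me += e[i]
            me /= n
            dm = me + np.random.normal() * np.sqrt(s2e / n)
            mu += dm
            for i in range(n):
                e[i] -= dm
        if not fix_s2a:
            ssa = 0.0
            for j in range(k):
                ssa += a[j] * a[j]
            s2a = (nu_a * s2_prior_a + ssa) / _chi2(nu_a + m)
        if not fix_s2e:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            s2e = (nu_e * s2_prior_e + sse) / _chi2(nu_e + n)
        if sample_pi:
            pi = np.random.beta(k_active - m + 1.0, m + 1.0)
        if it >= burn_in and (it - burn_in) % thin == 0:
            a_samp[kept] = a
            mu_s[kept] = mu
            s2a_s[kept] = s2a
            s2e_s[kept] = s2e
            pi_s[kept] = pi
            gm = 0.0
            gss = 0.0
            for i in range(n):
                g = y[i] - mu - e[i]
                gm += g
                gss += g * g
            gm /= n
            genvar_s[kept] = gss / n - gm * gm
            kept += 1
    return a_samp, mu_s, s2a_s, s2e_s, pi_s, genvar_s


@njit(cache=True)
def bayesb_chain(y, Xt, xtx, active, n_iter, burn_in, thin,
                 pi, nu_a, s2_prior_a, nu_e, s2_prior_e,
                 fix_s2e, s2e_fix, fix_mu, mu_fix, seed):
    """BayesB: per-locus effect variances, pi fixed.

    The (indicator, locus variance) pair is proposed from the prior and
    accepted on the ratio of marginal likelihoods with the effect integrated
    out; the effect is then drawn from its normal full conditional.
    Returns (a_samples, mu_s, s2e_s, genvar_s).
    """
    np.random.seed(seed)
    k, n = Xt.shape
    a = np.zeros(k)
    delta = np.zeros(k, dtype=np.uint8)
    s2loc = np.empty(k)
    for j in range(k):
        s2loc[j] = nu_a * s2_prior_a / _chi2(nu_a)
    mu = mu_fix if fix_mu else y.mean()
    e = y - mu
    s2e = s2e_fix if fix_s2e else max(s2_prior_e, 1e-8)

    n_keep = (n_iter - burn_in + thin - 1) // thin
    a_samp = np.zeros((n_keep, k))
    mu_s = np.zeros(n_keep)
    s2e_s = np.zeros(n_keep)
    genvar_s = np.zeros(n_keep)
    kept = 0

    for it in range(n_iter):
        for j in range(k):
            if not active[j]:
                continue
            aj = a[j]
            r = xtx[j] * aj
            for i in range(n):
                r += Xt[j, i] * e[i]
            v0 = xtx[j] * s2e
            # marginal log-likelihood of current state
            if delta[j]:
                vc = xtx[j] * xtx[j] * s2loc[j] + v0
            else:
                vc = v0
            ll_cur = -0.5 * (np.log(vc) + r * r / vc)
            # propose from the prior
            prop_inc = np.random.random() < (1.0 - pi)
            s2p = nu_a * s2_prior_a / _chi2(nu_a) if prop_inc else s2loc[j]
            if prop_inc:
                vp = xtx[j] * xtx[j] * s2p + v0
            else:
                vp = v0
            ll_prop = -0.5 * (np.log(vp) + r * r / vp)
            if np.log(np.random.random()) < ll_prop - ll_cur:
                delta[j] = 1 if prop_inc else 0
                if prop_inc:
                    s2loc[j] = s2p
            new = 0.0
            if delta[j]:
                c = xtx[j] + s2e / s2loc[j]
                new = r / c + np.random.normal() * np.sqrt(s2e / c)
            if new != aj:
                d = aj - new
                for i in range(n):
                    e[i] += Xt[j, i] * d
                a[j] = new
        if not fix_mu:
            me = 0.0
            for i in range(n):
                me += e[i]
            me /= n
            dm = me + np.random.normal() * np.sqrt(s2e / n)
            mu += dm
            for i in range(n):
                e[i] -= dm
        if not fix_s2e:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            s2e = (nu_e * s2_prior_e + sse) / _chi2(nu_e + n)
        if it >= burn_in and (it - burn_in) % thin == 0:
            a_samp[kept] = a
            mu_s[kept] = mu
            s2e_s[kept] = s2e
            gm = 0.0
            gss = 0.0
            for i in range(n):
                g = y[i] - mu - e[i]
                gm += g
                gss += g * g
            gm /= n
            genvar_s[kept] = gss / n - gm * gm
            kept += 1
    return a_samp, mu_s, s2e_s, genvar_s


@njit(cache=True)
def bayescpi_dominance_chain(y, Xt, Wt, xtx, wtw, active_a, active_d,
                             n_iter, burn_in, thin, pi_a0, pi_d0,
                             nu_a, s2_prior_a, nu_d, s2_prior_d,
                             nu_e, s2_prior_e, seed):
    """Joint additive + dominance BayesCpi.

    Interleaved single-site updates per SNP (additive given dominance, then
    dominance given additive), each effect class with its own indicator set,
    common variance and sampled pi.  Returns
    (a_samp, d_samp, mu_s, s2a_s, s2d_s, s2e_s, pia_s, pid_s,
    genvar_a_s, genvar_d_s).
    """
    np.random.seed(seed)
    k, n = Xt.shape
    ka = 0
    kd = 0
    for j in range(k):
        if active_a[j]:
            ka += 1
        if active_d[j]:
            kd += 1
    a = np.zeros(k)
    d = np.zeros(k)
    ga = np.zeros(n)  # running X_c a, W_c d for per-sample genetic variances
    gd = np.zeros(n)
    mu = y.mean()
    e = y - mu
    s2a = max(s2_prior_a, 1e-8)
    s2d = max(s2_prior_d, 1e-8)
    s2e = max(s2_prior_e, 1e-8)
    pia = pi_a0
    pid = pi_d0

    n_keep = (n_iter - burn_in + thin - 1) // thin
    a_samp = np.zeros((n_keep, k))
    d_samp = np.zeros((n_keep, k))
    mu_s = np.zeros(n_keep)
    s2a_s = np.zeros(n_keep)
    s2d_s = np.zeros(n_keep)
    s2e_s = np.zeros(n_keep)
    pia_s = np.zeros(n_keep)
    pid_s = np.zeros(n_keep)
    gva_s = np.zeros(n_keep)
    gvd_s = np.zeros(n_keep)
    kept = 0

    for it in range(n_iter):
        lam_a = s2e / s2a
        lam_d = s2e / s2d
        ma = 0
        md = 0
        for j in range(k):
            if active_a[j]:
                aj = a[j]
                r = xtx[j] * aj
                for i in range(n):
                    r += Xt[j, i] * e[i]
                v0 = xtx[j] * s2e
                v1 = xtx[j] * xtx[j] * s2a + v0
                logbf = 0.5 * (np.log(v0 / v1) + r * r * (1.0 / v0 - 1.0 / v1))
                p1 = _logistic(np.log((1.0 - pia) / pia) + logbf)
                new = 0.0
                if np.random.random() < p1:
                    c = xtx[j] + lam_a
                    new = r / c + np.random.normal() * np.sqrt(s2e / c)
                    ma += 1
                if new != aj:
                    dd = aj - new
                    for i in range(n):
                        e[i] += Xt[j, i] * dd
                        ga[i] -= Xt[j, i] * dd
                    a[j] = new
            if active_d[j]:
                dj = d[j]
                r = wtw[j] * dj
                for i in range(n):
                    r += Wt[j, i] * e[i]
                v0 = wtw[j] * s2e
                v1 = wtw[j] * wtw[j] * s2d + v0
                logbf = 0.5 * (np.log(v0 / v1) + r * r * (1.0 / v0 - 1.0 / v1))
                p1 = _logistic(np.log((1.0 - pid) / pid) + logbf)
                new = 0.0
                if np.random.random() < p1:
                    c = wtw[j] + lam_d
                    new = r / c + np.random.normal() * np.sqrt(s2e / c)
                    md += 1
                if new != dj:
                    dd = dj - new
                    for i in range(n):
                        e[i] += Wt[j, i] * dd
                        gd[i] -= Wt[j, i] * dd
                    d[j] = new
        me = 0.0
        for i in range(n):
            me += e[i]
        me /= n
        dm = me + np.random.normal() * np.sqrt(s2e / n)
        mu += dm
        sse = 0.0
        for i in range(n):
            e[i] -= dm
            sse += e[i] * e[i]
        ssa = 0.0
        ssd = 0.0
        for j in range(k):
            ssa += a[j] * a[j]
            ssd += d[j] * d[j]
        s2a = (nu_a * s2_prior_a + ssa) / _chi2(nu_a + ma)
        if kd > 0:
            s2d = (nu_d * s2_prior_d + ssd) / _chi2(nu_d + md)
        s2e = (nu_e * s2_prior_e + sse) / _chi2(nu_e + n)
        pia = np.random.beta(ka - ma + 1.0, ma + 1.0)
        if kd > 0:
            pid = np.random.beta(kd - md + 1.0, md + 1.0)
        if it >= burn_in and (it - burn_in) % thin == 0:
            a_samp[kept] = a
            d_samp[kept] = d
            mu_s[kept] = mu
            s2a_s[kept] = s2a
            s2d_s[kept] = s2d
            s2e_s[kept] = s2e
            pia_s[kept] = pia
            pid_s[kept] = pid
            # genetic values of each class for this sample
            gam = 0.0
            gas = 0.0
            gdm = 0.0
            gds = 0.0
            for i in range(n):
                gam += ga[i]
                gas += ga[i] * ga[i]
                gdm += gd[i]
                gds += gd[i] * gd[i]
            gam /= n
            gdm /= n
            gva_s[kept] = gas / n - gam * gam
            gvd_s[kept] = gds / n - gdm * gdm
            kept += 1
    return (a_samp, d_samp, mu_s, s2a_s, s2d_s, s2e_s, pia_s, pid_s,
            gva_s, gvd_s)
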
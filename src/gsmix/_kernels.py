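"""Numba kernels for the Gibbs sampler.

The whole chain runs inside one jitted function using residual updating:
``e`` always equals the data minus every currently-fitted term, each update
removes its own term, draws from the full conditional and subtracts the new
value back.  Randomness uses numba's internal RNG seeded once per chain,
which makes runs bit-reproducible for a given seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)
LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@njit(cache=True)
def _ndtri(p):
    """Inverse standard-normal CDF (Acklam's rational approximation,
    relative error below 1.2e-9 over the open unit interval)."""
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    a = (-3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02,
         1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00)
    b = (-5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02,
         6.680131188771972e+01, -1.328068155288572e+01)
    c = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00,
         -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00)
    d = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00,
         3.754408661907416e+00)
    plow = 0.02425
    if p < plow:
        q = math.sqrt(-2.0 * math.log(p))
        return (((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
               ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)
    if p > 1.0 - plow:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        return -(((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
                ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)
    q = p - 0.5
    r = q * q
    return (((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r + a[5]) * q / \
           (((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r + b[4]) * r + 1.0)


@njit(cache=True)
def _ndtr(x):
    return 0.5 * math.erfc(-x / SQRT2)


@njit(cache=True)
def _log_ndtr(x):
    if x > -8.0:
        return math.log(0.5 * math.erfc(-x / SQRT2))
    # asymptotic tail: log phi(x) - log(-x)
    return -0.5 * x * x - LOG_SQRT_2PI - math.log(-x)


@njit(cache=True)
def _truncnorm_positive(m, sd):
    """Draw from N(m, sd^2) truncated to (0, inf)."""
    alpha = -m / sd  # lower bound in standard units
    if alpha < 5.0:
        lo = _ndtr(alpha)
        u = lo + (1.0 - lo) * np.random.random()
        if u >= 1.0:
            u = 1.0 - 1e-16
        z = _ndtri(u)
        return m + sd * z
    # far truncation: Robert's exponential rejection
    lam = 0.5 * (alpha + math.sqrt(alpha * alpha + 4.0))
    while True:
        z = alpha + np.random.exponential() / lam
        rho = math.exp(-0.5 * (z - lam) ** 2)
        if np.random.random() <= rho:
            return m + sd * z


@njit(cache=True)
def _scaled_invchi2(ss, df, floor):
    """Draw sigma^2 = ss / chi2(df) (flat-prior form), bounded below."""
    v = ss / np.random.chisquare(df)
    return v if v > floor else floor


@njit(cache=True)
def run_chain(
    y,
    Xf, xtx_f,
    cage_ptr, cage_rows,
    anim_ptr, anim_rows,
    ai_indptr, ai_indices, ai_data,
    QT, qss, marker_start,
    use_genomic, use_poly, use_cage, use_likelihood,
    pi1, sigma2_g0,
    ve0, vc0, vu0, vg10,
    sample_ve, sample_vc, sample_vu, sample_vg1,
    freeze_delta, s_frozen, have_s_frozen,
    niter, burn, thin, seed,
):
    np.random.seed(seed)
    n = y.shape[0]
    pf = Xf.shape[1]
    ncage = cage_ptr.shape[0] - 1
    nanim = anim_ptr.shape[0] - 1
    M = marker_start.shape[0] - 1
    pcols = QT.shape[0]

    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu = mu / n if n > 0 else 0.0
    bfix = np.zeros(pf)
    cc = np.zeros(ncage)
    u = np.zeros(nanim)
    # start all effects at zero so the initial residual y - mu is exact
    a = np.zeros(pcols)
    s = np.zeros(M)
    delta = np.zeros(M, dtype=np.uint8)
    for j in range(M):
        if freeze_delta or pi1 >= 1.0:
            delta[j] = 1
        else:
            delta[j] = 1 if np.random.random() < pi1 else 0
    if have_s_frozen:
        for j in range(M):
            s[j] = s_frozen

    ve, vc, vu, vg1 = ve0, vc0, vu0, vg10
    floor = 1e-10

    e = y.copy()
    for i in range(n):
        e[i] -= mu

    S = (niter - burn) // thin
    mu_s = np.empty(S)
    bfix_s = np.empty((S, pf))
    c_s = np.empty((S, ncage))
    u_s = np.empty((S, nanim))
    avec_s = np.empty((S, pcols))
    s_s = np.empty((S, M))
    delta_s = np.empty((S, M), dtype=np.uint8)
    ve_s = np.empty(S)
    vc_s = np.empty(S)
    vu_s = np.empty(S)
    vg1_s = np.empty(S)
    n_empty = 0  # post-burn-in iterations with no marker in component 1

    log_pi_odds = 0.0
    if use_genomic and not freeze_delta and pi1 < 1.0:
        log_pi_odds = math.log(pi1) - math.log(1.0 - pi1)

    stored = 0
    for it in range(niter):
        if use_likelihood:
            # --- general mean
            tot = 0.0
            for i in range(n):
                tot += e[i] + mu
            mean = tot / n
            mu_new = mean + np.random.standard_normal() * math.sqrt(ve / n)
            for i in range(n):
                e[i] += mu - mu_new
            mu = mu_new

            # --- fixed effects / covariates, flat priors, single site
            for k in range(pf):
                xte = 0.0
                for i in range(n):
                    xte += Xf[i, k] * (e[i] + Xf[i, k] * bfix[k])
                prec = xtx_f[k] / ve
                mean = xte / xtx_f[k]
                bnew = mean + np.random.standard_normal() / math.sqrt(prec)
                dlt = bfix[k] - bnew
                for i in range(n):
                    e[i] += Xf[i, k] * dlt
                bfix[k] = bnew

            # --- cage effects
            if use_cage:
                for g in range(ncage):
                    lo, hi = cage_ptr[g], cage_ptr[g + 1]
                    ng = hi - lo
                    tot = 0.0
                    for r in range(lo, hi):
                        tot += e[cage_rows[r]] + cc[g]
                    prec = ng / ve + 1.0 / vc
                    mean = (tot / ve) / prec
                    cnew = mean + np.random.standard_normal() / math.sqrt(prec)
                    dlt = cc[g] - cnew
                    for r in range(lo, hi):
                        e[cage_rows[r]] += dlt
                    cc[g] = cnew

            # --- polygenic values, single site with sparse A-inverse
            if use_poly:
                for i in range(nanim):
                    lo, hi = anim_ptr[i], anim_ptr[i + 1]
                    ng = hi - lo
                    tot = 0.0
                    for r in range(lo, hi):
                        tot += e[anim_rows[r]] + u[i]
                    aii = 0.0
                    cross = 0.0
                    for t in range(ai_indptr[i], ai_indptr[i + 1]):
                        jdx = ai_indices[t]
                        if jdx == i:
                            aii = ai_data[t]
                        else:
                            cross += ai_data[t] * u[jdx]
                    prec = ng / ve + aii / vu
                    mean = (tot / ve - cross / vu) / prec
                    unew = mean + np.random.standard_normal() / math.sqrt(prec)
                    dlt = u[i] - unew
                    for r in range(lo, hi):
                        e[anim_rows[r]] += dlt
                    u[i] = unew

        # --- markers: joint (delta, s) with s integrated, then a
        if use_genomic:
            for j in range(M):
                c0, c1 = marker_start[j], marker_start[j + 1]
                # remove this marker's contribution from the residual
                if use_likelihood:
                    for k in range(c0, c1):
                        coef = a[k] * s[j]
                        if coef != 0.0:
                            for i in range(n):
                                e[i] += QT[k, i] * coef

                # likelihood terms for s given a:  e = w*s + eps, w = Q_j a_j
                lam = 0.0
                ls = 0.0
                if use_likelihood:
                    wss = 0.0
                    wte = 0.0
                    if c1 - c0 == 1:
                        ak = a[c0]
                        for i in range(n):
                            wte += QT[c0, i] * e[i]
                        wss = ak * ak * qss[c0]
                        wte *= ak
                    else:
                        for i in range(n):
                            wi = 0.0
                            for k in range(c0, c1):
                                wi += a[k] * QT[k, i]
                            wss += wi * wi
                            wte += wi * e[i]
                    lam = wss / ve
                    ls = wte / ve

                # component posteriors for s
                v1 = 1.0 / (lam + 1.0 / vg1)
                m1 = v1 * ls
                if freeze_delta or pi1 >= 1.0:
                    dj = 1
                else:
                    v0 = 1.0 / (lam + 1.0 / sigma2_g0)
                    m0 = v0 * ls
                    log_l0 = 0.5 * math.log(v0 / sigma2_g0) + 0.5 * m0 * m0 / v0
                    log_l1 = (
                        math.log(2.0)
                        + 0.5 * math.log(v1 / vg1)
                        + 0.5 * m1 * m1 / v1
                        + _log_ndtr(m1 / math.sqrt(v1))
                    )
                    logit = log_pi_odds + log_l1 - log_l0
                    if logit > 35.0:
                        p1 = 1.0
                    elif logit < -35.0:
                        p1 = 0.0
                    else:
                        p1 = 1.0 / (1.0 + math.exp(-logit))
                    dj = 1 if np.random.random() < p1 else 0
                delta[j] = dj

                if not have_s_frozen:
                    if dj == 1:
                        s[j] = _truncnorm_positive(m1, math.sqrt(v1))
                    else:
                        v0 = 1.0 / (lam + 1.0 / sigma2_g0)
                        m0 = v0 * ls
                        s[j] = m0 + np.random.standard_normal() * math.sqrt(v0)

                # base effects a, prior N(0, 1), single site
                sj = s[j]
                for k in range(c0, c1):
                    if use_likelihood:
                        xte = 0.0
                        for i in range(n):
                            xte += QT[k, i] * e[i]
                        prec = sj * sj * qss[k] / ve + 1.0
                        mean = (sj * xte / ve) / prec
                        a[k] = mean + np.random.standard_normal() / math.sqrt(prec)
                        coef = a[k] * sj
                        if coef != 0.0:
                            for i in range(n):
                                e[i] -= QT[k, i] * coef
                    else:
                        a[k] = np.random.standard_normal()

        # --- variance components, scaled-inverse-chi-square (flat nu = -2)
        if use_likelihood and sample_ve and n > 3:
            ss = 0.0
            for i in range(n):
                ss += e[i] * e[i]
            ve = _scaled_invchi2(ss, n - 2, floor)
        if use_likelihood and use_cage and sample_vc and ncage > 3:
            ss = 0.0
            for g in range(ncage):
                ss += cc[g] * cc[g]
            vc = _scaled_invchi2(ss, ncage - 2, floor)
        if use_likelihood and use_poly and sample_vu and nanim > 3:
            ss = 0.0
            for i in range(nanim):
                row = 0.0
                for t in range(ai_indptr[i], ai_indptr[i + 1]):
                    row += ai_data[t] * u[ai_indices[t]]
                ss += u[i] * row
            vu = _scaled_invchi2(ss, nanim - 2, floor)
        if use_genomic and sample_vg1:
            ss = 0.0
            m1count = 0
            for j in range(M):
                if delta[j] == 1:
                    ss += s[j] * s[j]
                    m1count += 1
            if m1count > 3:
                vg1 = _scaled_invchi2(ss, m1count - 2, floor)

        # --- bookkeeping and storage
        if it >= burn:
            m1count = 0
            for j in range(M):
                m1count += delta[j]
            if use_genomic and m1count == 0:
                n_empty += 1
            if (it - burn) % thin == 0 and stored < S:
                mu_s[stored] = mu
                for k in range(pf):
                    bfix_s[stored, k] = bfix[k]
                for g in range(ncage):
                    c_s[stored, g] = cc[g]
                for i in range(nanim):
                    u_s[stored, i] = u[i]
                for k in range(pcols):
                    avec_s[stored, k] = a[k] * s[marker_start_col(marker_start, k)]
                for j in range(M):
                    s_s[stored, j] = s[j]
                    delta_s[stored, j] = delta[j]
                ve_s[stored] = ve
                vc_s[stored] = vc
                vu_s[stored] = vu
                vg1_s[stored] = vg1
                stored += 1

    return (mu_s, bfix_s, c_s, u_s, avec_s, s_s, delta_s,
            ve_s, vc_s, vu_s, vg1_s, n_empty)


@njit(cache=True)
def marker_start_col(marker_start, k):
    """Marker index owning column k (markers hold contiguous column runs)."""
    lo = 0
    hi = marker_start.shape[0] - 1
    while lo < hi - 1:
        mid = (lo + hi) // 2
        if marker_start[mid] <= k:
            lo = mid
        else:
            hi = mid
    return lo
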
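"""Numba kernels: tempered samplers for the benchmark model families.

These implement the same power-posterior scheme as the generic pure-Python
sampler in :mod:`steppingstone.tempering` — single-site Metropolis–Hastings
sweeps with the observed-data likelihood tempered by phi, untempered latent
process and prior, and adjacent-chain replica exchange — but specialized per
model family with incremental likelihood bookkeeping so that paper-scale runs
(tens of chains, 1e4-1e6 updates) complete in minutes.  Cross-checks against
the generic sampler on small instances live in the test suite.

Conventions shared by all kernels:
- chain k (0-based) targets P(y|theta,x)^phis[k] pi(x|theta) pi(theta);
- proposal scales adapt toward ~0.44 acceptance during burn-in only, so the
  post-burn-in kernels satisfy detailed balance;
- a swap sweep over adjacent pairs runs every ``swap_interval`` updates,
  alternating odd/even pairings;
- variance-like parameters use log-scale random walks whose Jacobian enters
  the acceptance ratio as +log(v'/v).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG2PI = np.log(2.0 * np.pi)


@njit(cache=True)
def _adapt(scale, acc, att, lo, hi):
    if att > 0:
        rate = acc / att
        scale *= np.exp(rate - 0.44)
        if scale < lo:
            scale = lo
        elif scale > hi:
            scale = hi
    return scale


# ---------------------------------------------------------------------------
# linear regression
# ---------------------------------------------------------------------------


@njit(cache=True)
def lm_ss_kernel(
    y, X, phis, n_burnin, n_samples, swap_interval, seed,
    b_lo, b_hi, e_lo, e_hi,
):
    """Tempered chains for the nested linear regression model.

    Returns (log_obs[K, N], beta_mean[J], eta2_mean, eta2_prior_trace[N])
    where means are over the posterior (phi=1) chain and the prior trace is
    eta^2 sampled on the phi=0 chain.
    """
    K = phis.size
    R = y.size
    J = X.shape[1]
    np.random.seed(seed)

    beta = np.empty((K, J))
    eta2 = np.empty(K)
    resid = np.empty((K, R))
    ssr = np.empty(K)
    for k in range(K):
        for j in range(J):
            beta[k, j] = np.random.uniform(b_lo, b_hi)
        eta2[k] = np.random.uniform(e_lo, e_hi)
        for r in range(R):
            m = 0.0
            for j in range(J):
                m += X[r, j] * beta[k, j]
            resid[k, r] = y[r] - m
        ssr[k] = np.dot(resid[k], resid[k])

    sc_b = np.full((K, J), 0.3)
    sc_e = np.full(K, 0.3)
    acc_b = np.zeros((K, J))
    att_b = np.zeros((K, J))
    acc_e = np.zeros(K)
    att_e = np.zeros(K)

    log_obs = np.empty((K, n_samples))
    eta2_prior = np.empty(n_samples)
    beta_sum = np.zeros(J)
    eta2_sum = 0.0
    parity = 0
    total = n_burnin + n_samples

    for it in range(total):
        for k in range(K):
            phi = phis[k]
            for j in range(J):
                att_b[k, j] += 1.0
                db = sc_b[k, j] * np.random.normal()
                bp = beta[k, j] + db
                if bp < b_lo or bp > b_hi:
                    continue
                dssr = 0.0
                for r in range(R):
                    rr = resid[k, r]
                    rn = rr - X[r, j] * db
                    dssr += rn * rn - rr * rr
                la = -phi * dssr / (2.0 * eta2[k])
                if la >= 0.0 or np.random.random() < np.exp(la):
                    beta[k, j] = bp
                    for r in range(R):
                        resid[k, r] -= X[r, j] * db
                    ssr[k] += dssr
                    acc_b[k, j] += 1.0
            att_e[k] += 1.0
            fac = np.exp(sc_e[k] * np.random.normal())
            ep = eta2[k] * fac
            if e_lo < ep < e_hi:
                dlo = (
                    -0.5 * R * (np.log(ep) - np.log(eta2[k]))
                    - 0.5 * ssr[k] * (1.0 / ep - 1.0 / eta2[k])
                )
                la = phi * dlo + np.log(fac)
                if la >= 0.0 or np.random.random() < np.exp(la):
                    eta2[k] = ep
                    acc_e[k] += 1.0

        if it < n_burnin and (it + 1) % 100 == 0:
            for k in range(K):
                for j in range(J):
                    sc_b[k, j] = _adapt(sc_b[k, j], acc_b[k, j], att_b[k, j], 1e-3, 4.0)
                    acc_b[k, j] = 0.0
                    att_b[k, j] = 0.0
                sc_e[k] = _adapt(sc_e[k], acc_e[k], att_e[k], 1e-3, 3.0)
                acc_e[k] = 0.0
                att_e[k] = 0.0

        if (it + 1) % 100 == 0:
            # refresh resid/ssr from scratch to cancel incremental FP drift
            for k in range(K):
                ssr_k = 0.0
                for r in range(R):
                    m0 = 0.0
                    for j in range(J):
                        m0 += X[r, j] * beta[k, j]
                    resid[k, r] = y[r] - m0
                    ssr_k += resid[k, r] * resid[k, r]
                ssr[k] = ssr_k

        if swap_interval > 0 and (it + 1) % swap_interval == 0:
            for k in range(parity, K - 1, 2):
                lo_k = -0.5 * R * np.log(2.0 * np.pi * eta2[k]) - ssr[k] / (2.0 * eta2[k])
                lo_k1 = -0.5 * R * np.log(2.0 * np.pi * eta2[k + 1]) - ssr[k + 1] / (
                    2.0 * eta2[k + 1]
                )
                la = (phis[k] - phis[k + 1]) * (lo_k1 - lo_k)
                if la >= 0.0 or np.random.random() < np.exp(la):
                    for j in range(J):
                        beta[k, j], beta[k + 1, j] = beta[k + 1, j], beta[k, j]
                    eta2[k], eta2[k + 1] = eta2[k + 1], eta2[k]
                    ssr[k], ssr[k + 1] = ssr[k + 1], ssr[k]
                    for r in range(R):
                        resid[k, r], resid[k + 1, r] = resid[k + 1, r], resid[k, r]
            parity = 1 - parity

        if it >= n_burnin:
            i = it - n_burnin
            for k in range(K):
                log_obs[k, i] = -0.5 * R * np.log(2.0 * np.pi * eta2[k]) - ssr[k] / (
                    2.0 * eta2[k]
                )
            for j in range(J):
                beta_sum[j] += beta[0, j]
            eta2_sum += eta2[0]
            eta2_prior[i] = eta2[K - 1]

    return log_obs, beta_sum / n_samples, eta2_sum / n_samples, eta2_prior


# ---------------------------------------------------------------------------
# pedigree mixed model
# ---------------------------------------------------------------------------


@njit(cache=True)
def mixed_ss_kernel(
    y, X, Ainv, logdetA, phis, n_burnin, n_samples, swap_interval, seed,
    b_lo, b_hi, e_lo, e_hi, w_lo, w_hi,
):
    """Tempered chains for the pedigree mixed model with latent random effects.

    Latent updates: a single-site Gaussian walk on every u_q per update, plus
    one joint multiplicative rescale of u.  Bookkeeping keeps the residual
    vector, its sum of squares, v = A^-1 u and q = u^T A^-1 u incremental.

    Returns (log_obs[K, N], lat0[N], h2_0[N], beta0[N, J], eta2_0[N],
    omega2_0[N], ssr0[N], q0[N], g0[N, J]) where chain-0 quantities feed DIC
    and plug-in evaluation: g0 = X^T resid for re-evaluating the observed-data
    likelihood at the posterior-mean parameters.
    """
    K = phis.size
    R = y.size
    J = X.shape[1]
    np.random.seed(seed)

    beta = np.empty((K, J))
    eta2 = np.empty(K)
    omega2 = np.empty(K)
    u = np.zeros((K, R))
    v = np.zeros((K, R))  # A^-1 u
    quad = np.zeros(K)  # u^T A^-1 u
    resid = np.empty((K, R))
    ssr = np.empty(K)
    for k in range(K):
        for j in range(J):
            beta[k, j] = np.random.uniform(b_lo, b_hi)
        eta2[k] = np.random.uniform(e_lo, e_hi)
        omega2[k] = np.random.uniform(w_lo, w_hi)
        for r in range(R):
            m = 0.0
            for j in range(J):
                m += X[r, j] * beta[k, j]
            resid[k, r] = y[r] - m  # u starts at zero
        ssr[k] = np.dot(resid[k], resid[k])

    lat_const = -0.5 * R * _LOG2PI - 0.5 * logdetA

    sc_b = np.full((K, J), 0.3)
    sc_e = np.full(K, 0.3)
    sc_w = np.full(K, 0.3)
    sc_u = np.full(K, 0.5)
    sc_s = np.full(K, 0.1)
    acc = np.zeros((K, 5))
    att = np.zeros((K, 5))

    log_obs = np.empty((K, n_samples))
    lat0 = np.empty(n_samples)
    h2_0 = np.empty(n_samples)
    beta0 = np.empty((n_samples, J))
    eta2_0 = np.empty(n_samples)
    omega2_0 = np.empty(n_samples)
    ssr0 = np.empty(n_samples)
    q0 = np.empty(n_samples)
    g0 = np.empty((n_samples, J))

    parity = 0
    total = n_burnin + n_samples
    for it in range(total):
        for k in range(K):
            phi = phis[k]
            # fixed effects
            for j in range(J):
                att[k, 0] += 1.0
                db = sc_b[k, j] * np.random.normal()
                bp = beta[k, j] + db
                if bp < b_lo or bp > b_hi:
                    continue
                dssr = 0.0
                for r in range(R):
                    rr = resid[k, r]
                    rn = rr - X[r, j] * db
                    dssr += rn * rn - rr * rr
                la = -phi * dssr / (2.0 * eta2[k])
                if la >= 0.0 or np.random.random() < np.exp(la):
                    beta[k, j] = bp
                    for r in range(R):
                        resid[k, r] -= X[r, j] * db
                    ssr[k] += dssr
                    acc[k, 0] += 1.0
            # eta2
            att[k, 1] += 1.0
            fac = np.exp(sc_e[k] * np.random.normal())
            ep = eta2[k] * fac
            if e_lo < ep < e_hi:
                dlo = (
                    -0.5 * R * (np.log(ep) - np.log(eta2[k]))
                    - 0.5 * ssr[k] * (1.0 / ep - 1.0 / eta2[k])
                )
                la = phi * dlo + np.log(fac)
                if la >= 0.0 or np.random.random() < np.exp(la):
                    eta2[k] = ep
                    acc[k, 1] += 1.0
            # omega2 (latent density is untempered)
            att[k, 2] += 1.0
            fac = np.exp(sc_w[k] * np.random.normal())
            wp = omega2[k] * fac
            if w_lo < wp < w_hi:
                dll = (
                    -0.5 * R * (np.log(wp) - np.log(omega2[k]))
                    - 0.5 * quad[k] * (1.0 / wp - 1.0 / omega2[k])
                )
                la = dll + np.log(fac)
                if la >= 0.0 or np.random.random() < np.exp(la):
                    omega2[k] = wp
                    acc[k, 2] += 1.0
            # random effects, single site
            for r0 in range(R):
                att[k, 3] += 1.0
                du = sc_u[k] * np.random.normal()
                rr = resid[k, r0]
                rn = rr - du
                dssr = rn * rn - rr * rr
                dq = 2.0 * du * v[k, r0] + du * du * Ainv[r0, r0]
                la = -phi * dssr / (2.0 * eta2[k]) - dq / (2.0 * omega2[k])
                if la >= 0.0 or np.random.random() < np.exp(la):
                    u[k, r0] += du
                    resid[k, r0] = rn
                    ssr[k] += dssr
                    quad[k] += dq
                    for r in range(R):
                        v[k, r] += du * Ainv[r, r0]
                    acc[k, 3] += 1.0
            # joint rescale u -> s u
            att[k, 4] += 1.0
            s = np.exp(sc_s[k] * np.random.normal())
            ssr_new = 0.0
            for r in range(R):
                rn = resid[k, r] - (s - 1.0) * u[k, r]
                ssr_new += rn * rn
            dq = (s * s - 1.0) * quad[k]
            la = (
                -phi * (ssr_new - ssr[k]) / (2.0 * eta2[k])
                - dq / (2.0 * omega2[k])
                + R * np.log(s)
            )
            if la >= 0.0 or np.random.random() < np.exp(la):
                for r in range(R):
                    resid[k, r] -= (s - 1.0) * u[k, r]
                    u[k, r] *= s
                    v[k, r] *= s
                ssr[k] = ssr_new
                quad[k] *= s * s
                acc[k, 4] += 1.0

        if it < n_burnin and (it + 1) % 100 == 0:
            for k in range(K):
                for j in range(J):
                    sc_b[k, j] = _adapt(sc_b[k, j], acc[k, 0] / J, att[k, 0] / J, 1e-3, 4.0)
                sc_e[k] = _adapt(sc_e[k], acc[k, 1], att[k, 1], 1e-3, 3.0)
                sc_w[k] = _adapt(sc_w[k], acc[k, 2], att[k, 2], 1e-3, 3.0)
                sc_u[k] = _adapt(sc_u[k], acc[k, 3], att[k, 3], 1e-3, 5.0)
                sc_s[k] = _adapt(sc_s[k], acc[k, 4], att[k, 4], 1e-3, 1.0)
                for m in range(5):
                    acc[k, m] = 0.0
                    att[k, m] = 0.0

        if (it + 1) % 100 == 0:
            # refresh incremental caches from scratch: single-site updates of
            # resid/ssr/v/q accumulate floating-point drift, and a corrupted
            # q = u^T A^-1 u destabilizes the prior-end chains
            for k in range(K):
                ssr_k = 0.0
                for r in range(R):
                    m0 = 0.0
                    for j in range(J):
                        m0 += X[r, j] * beta[k, j]
                    resid[k, r] = y[r] - m0 - u[k, r]
                    ssr_k += resid[k, r] * resid[k, r]
                ssr[k] = ssr_k
                q_k = 0.0
                for r in range(R):
                    vr = 0.0
                    for r2 in range(R):
                        vr += Ainv[r, r2] * u[k, r2]
                    v[k, r] = vr
                    q_k += u[k, r] * vr
                quad[k] = q_k

        if swap_interval > 0 and (it + 1) % swap_interval == 0:
            for k in range(parity, K - 1, 2):
                lo_k = -0.5 * R * np.log(2.0 * np.pi * eta2[k]) - ssr[k] / (2.0 * eta2[k])
                lo_k1 = -0.5 * R * np.log(2.0 * np.pi * eta2[k + 1]) - ssr[k + 1] / (
                    2.0 * eta2[k + 1]
                )
                la = (phis[k] - phis[k + 1]) * (lo_k1 - lo_k)
                if la >= 0.0 or np.random.random() < np.exp(la):
                    for j in range(J):
                        beta[k, j], beta[k + 1, j] = beta[k + 1, j], beta[k, j]
                    eta2[k], eta2[k + 1] = eta2[k + 1], eta2[k]
                    omega2[k], omega2[k + 1] = omega2[k + 1], omega2[k]
                    ssr[k], ssr[k + 1] = ssr[k + 1], ssr[k]
                    quad[k], quad[k + 1] = quad[k + 1], quad[k]
                    for r in range(R):
                        resid[k, r], resid[k + 1, r] = resid[k + 1, r], resid[k, r]
                        u[k, r], u[k + 1, r] = u[k + 1, r], u[k, r]
                        v[k, r], v[k + 1, r] = v[k + 1, r], v[k, r]
            parity = 1 - parity

        if it >= n_burnin:
            i = it - n_burnin
            for k in range(K):
                log_obs[k, i] = -0.5 * R * np.log(2.0 * np.pi * eta2[k]) - ssr[k] / (
                    2.0 * eta2[k]
                )
            lat0[i] = (
                lat_const
                - 0.5 * R * np.log(omega2[0])
                - quad[0] / (2.0 * omega2[0])
            )
            h2_0[i] = omega2[0] / (omega2[0] + eta2[0])
            for j in range(J):
                beta0[i, j] = beta[0, j]
                g = 0.0
                for r in range(R):
                    g += X[r, j] * resid[0, r]
                g0[i, j] = g
            eta2_0[i] = eta2[0]
            omega2_0[i] = omega2[0]
            ssr0[i] = ssr[0]
            q0[i] = quad[0]

    return log_obs, lat0, h2_0, beta0, eta2_0, omega2_0, ssr0, q0, g0


# ---------------------------------------------------------------------------
# compartmental epidemic models
# ---------------------------------------------------------------------------


@njit(cache=True)
def _epi_obs_ll(tEj, tRj, res_j, times, lSe, lSe1, lSp, lSp1):
    """Observed-data log likelihood contribution of one individual.

    Infected for testing purposes means in E or I: from the time of leaving S
    (tE) until recovery (tR, +inf if none)."""
    ll = 0.0
    for m in range(times.size):
        s = times[m]
        if tEj <= s and s < tRj:
            ll += lSe if res_j[m] == 1 else lSe1
        else:
            ll += lSp1 if res_j[m] == 1 else lSp
    return ll


@njit(cache=True)
def _epi_stats(ev_t, ev_ty, ne, p, T, has_E, out):
    """Sufficient statistics of an event sequence for the latent likelihood.

    Fills out[:7] = (n_exp, sum_log_I, n_inf, n_rec, int_SI, int_E, int_I);
    an exposure occurring while no individual is infectious marks the
    sequence invalid through sum_log_I = -inf.  The index case is infectious
    from t = 0.
    """
    S = p - 1
    E = 0
    I = 1
    n_exp = 0.0
    n_inf = 0.0
    n_rec = 0.0
    slogI = 0.0
    iSI = 0.0
    iE = 0.0
    iI = 0.0
    tprev = 0.0
    for e in range(ne):
        t = ev_t[e]
        dt = t - tprev
        iSI += S * I * dt
        iE += E * dt
        iI += I * dt
        ty = ev_ty[e]
        if ty == 0:  # leave S
            if I <= 0:
                slogI = -np.inf
            else:
                slogI += np.log(I)
            n_exp += 1.0
            S -= 1
            if has_E:
                E += 1
            else:
                I += 1
        elif ty == 1:  # E -> I
            n_inf += 1.0
            E -= 1
            I += 1
        else:  # I -> R
            n_rec += 1.0
            I -= 1
        tprev = t
    dt = T - tprev
    iSI += S * I * dt
    iE += E * dt
    iI += I * dt
    out[0] = n_exp
    out[1] = slogI
    out[2] = n_inf
    out[3] = n_rec
    out[4] = iSI
    out[5] = iE
    out[6] = iI


@njit(cache=True)
def _epi_lat_ll(st, bet, nu, gam, has_E, has_R):
    """log pi(x|theta) from sufficient statistics."""
    if st[1] == -np.inf:
        return -np.inf
    ll = st[0] * np.log(bet) + st[1] - bet * st[4]
    if has_E:
        ll += st[2] * np.log(nu) - nu * st[5]
    if has_R:
        ll += st[3] * np.log(gam) - gam * st[6]
    return ll


@njit(cache=True)
def _win_levels(times, res_j, lSe, lSe1, lSp, lSp1, a, T, mode, tE_fix, bounds, levels):
    """Piecewise-constant individual log obs-likelihood over panel intervals.

    mode 0: proposing an infection-window start t (individual infected on
    [t, T]); mode 1: proposing a recovery time t for a window [tE_fix, t).
    The likelihood of individual j's test results is constant for t within an
    interval between consecutive panel times, so add/remove proposals can be
    drawn exactly from the tempered conditional.  Fills ``bounds`` (interval
    edges, starting at a and ending at T) and ``levels`` (log likelihood per
    interval); returns the number of intervals.
    """
    m = times.size
    nb = 1
    bounds[0] = a
    for k in range(m):
        if a < times[k] < T:
            bounds[nb] = times[k]
            nb += 1
    bounds[nb] = T
    n_int = nb
    for i in range(n_int):
        hi = bounds[i + 1]
        l = 0.0
        for k in range(m):
            s = times[k]
            inf_k = lSe if res_j[k] == 1 else lSe1
            uninf_k = lSp1 if res_j[k] == 1 else lSp
            if mode == 0:
                l += inf_k if s >= hi else uninf_k
            elif mode == 1:
                infected = (s >= tE_fix) and (s <= bounds[i])
                l += inf_k if infected else uninf_k
            else:
                # mode 2: window-start draw with the end still unknown —
                # tests before t must be uninfected, later tests are scored
                # at their best case
                if s <= bounds[i]:
                    l += uninf_k
                else:
                    l += inf_k if inf_k > uninf_k else uninf_k
        levels[i] = l
    return n_int


@njit(cache=True)
def _win_sample(bounds, levels, n_int, phi):
    """Draw t from the density proportional to exp(phi * level) per interval.

    Returns (t, log_density); at phi = 0 this is uniform on (bounds[0], T).
    """
    c = -np.inf
    for i in range(n_int):
        v = phi * levels[i]
        if v > c:
            c = v
    Z = 0.0
    for i in range(n_int):
        Z += (bounds[i + 1] - bounds[i]) * np.exp(phi * levels[i] - c)
    u = np.random.random() * Z
    acc = 0.0
    i_sel = n_int - 1
    for i in range(n_int):
        acc += (bounds[i + 1] - bounds[i]) * np.exp(phi * levels[i] - c)
        if u < acc:
            i_sel = i
            break
    t = np.random.uniform(bounds[i_sel], bounds[i_sel + 1])
    logdens = phi * levels[i_sel] - c - np.log(Z)
    return t, logdens


@njit(cache=True)
def _win_logpdf(bounds, levels, n_int, phi, t):
    """Log density of `_win_sample` at the point t."""
    c = -np.inf
    for i in range(n_int):
        v = phi * levels[i]
        if v > c:
            c = v
    Z = 0.0
    for i in range(n_int):
        Z += (bounds[i + 1] - bounds[i]) * np.exp(phi * levels[i] - c)
    i_sel = n_int - 1
    for i in range(n_int):
        if bounds[i] < t <= bounds[i + 1]:
            i_sel = i
            break
    return phi * levels[i_sel] - c - np.log(Z)


@njit(cache=True)
def _epi_rebuild(ev_t, ev_ty, ev_id, ne, j, tEj, tIj, tRj,
                 b_t, b_ty, b_id, T, has_E, has_R):
    """Event list with individual j's events replaced by (tEj, tIj, tRj).

    The index case (j = 0) contributes no exposure/onset events (fixed at
    t = 0); finite times within (0, T) become events, already ordered since
    tE < tI < tR.  Returns the new event count; buffers receive the merged,
    time-sorted sequence.
    """
    c_t = np.empty(3)
    c_ty = np.empty(3, dtype=np.int8)
    nc = 0
    if j != 0 and tEj < T:
        c_t[nc] = tEj
        c_ty[nc] = 0
        nc += 1
    if has_E and j != 0 and tIj < T:
        c_t[nc] = tIj
        c_ty[nc] = 1
        nc += 1
    if has_R and tRj < T:
        c_t[nc] = tRj
        c_ty[nc] = 2
        nc += 1
    m = 0  # write head
    ci = 0
    for e in range(ne):
        if ev_id[e] == j:
            continue
        t = ev_t[e]
        while ci < nc and c_t[ci] < t:
            b_t[m] = c_t[ci]
            b_ty[m] = c_ty[ci]
            b_id[m] = j
            m += 1
            ci += 1
        b_t[m] = t
        b_ty[m] = ev_ty[e]
        b_id[m] = ev_id[e]
        m += 1
    while ci < nc:
        b_t[m] = c_t[ci]
        b_ty[m] = c_ty[ci]
        b_id[m] = j
        m += 1
        ci += 1
    return m


@njit(cache=True)
def epi_ss_kernel(
    has_E, has_R, p, T, times, results, Se, Sp,
    phis, n_burnin, n_samples, swap_interval, seed,
    bt_lo, bt_hi, nu_lo, nu_hi, gm_lo, gm_hi, latent_reps,
):
    """Tempered data-augmentation chains for an SI/SEI/SIR/SEIR model.

    The latent state is the per-individual triple (tE, tI, tR): time of
    leaving S, of becoming infectious (equal to tE in models without E) and
    of recovery, +inf when the event has not happened by the horizon T.  The
    index case is individual 0, infectious from t = 0.  Latent moves per
    individual: a Gaussian shift of one of its event times, or a reversible
    add/remove toggle of its exposure, onset or recovery with uniform
    proposal densities (exact Hastings ratios).

    Returns (log_obs[K, N], lat0[N], st0[N, 7], rates0[N, 3],
    rates_prior[N, 3], accept_rates[4]).
    """
    K = phis.size
    nt = times.size
    INF = np.inf
    lSe = np.log(Se) if Se > 0.0 else -INF
    lSe1 = np.log(1.0 - Se) if Se < 1.0 else -INF
    lSp = np.log(Sp) if Sp > 0.0 else -INF
    lSp1 = np.log(1.0 - Sp) if Sp < 1.0 else -INF
    np.random.seed(seed)

    maxE = 3 * p + 3
    bet = np.empty(K)
    nu = np.empty(K)
    gam = np.empty(K)
    tE = np.full((K, p), INF)
    tI = np.full((K, p), INF)
    tR = np.full((K, p), INF)
    ev_t = np.empty((K, maxE))
    ev_ty = np.empty((K, maxE), dtype=np.int8)
    ev_id = np.empty((K, maxE), dtype=np.int16)
    ne = np.zeros(K, dtype=np.int64)
    st = np.zeros((K, 7))
    li = np.zeros((K, p))
    lo = np.zeros(K)

    for k in range(K):
        bet[k] = np.random.uniform(bt_lo, bt_hi)
        nu[k] = np.random.uniform(nu_lo, nu_hi)
        gam[k] = np.random.uniform(gm_lo, gm_hi)
        tE[k, 0] = 0.0
        tI[k, 0] = 0.0
        _epi_stats(ev_t[k], ev_ty[k], 0, p, T, has_E, st[k])
        tot = 0.0
        for j in range(p):
            li[k, j] = _epi_obs_ll(tE[k, j], tR[k, j], results[j], times, lSe, lSe1, lSp, lSp1)
            tot += li[k, j]
        lo[k] = tot

    b_t = np.empty(maxE)
    b_ty = np.empty(maxE, dtype=np.int8)
    b_id = np.empty(maxE, dtype=np.int16)
    st_buf = np.empty(7)
    wb = np.empty(nt + 2)  # window-proposal interval bounds
    wl = np.empty(nt + 1)  # window-proposal log levels

    # proposal scales: rates (log walks) and event-time shifts
    sc_r = np.full((K, 3), 0.4)
    sc_t = np.full(K, 0.1 * T)
    acc = np.zeros((K, 5))
    att = np.zeros((K, 5))

    # latent move menu: 0 shift, 1 toggle exposure, 2 toggle onset,
    # 3 toggle recovery, 4 toggle whole infection path (R-models)
    menu = np.empty(5, dtype=np.int8)
    n_menu = 0
    menu[n_menu] = 0
    n_menu += 1
    menu[n_menu] = 1
    n_menu += 1
    if has_E:
        menu[n_menu] = 2
        n_menu += 1
    if has_R:
        menu[n_menu] = 3
        n_menu += 1
        menu[n_menu] = 4
        n_menu += 1

    log_obs = np.empty((K, n_samples))
    lat0 = np.empty(n_samples)
    st0 = np.empty((n_samples, 7))
    rates0 = np.empty((n_samples, 3))
    rates_prior = np.empty((n_samples, 3))

    parity = 0
    total = n_burnin + n_samples
    for it in range(total):
        for k in range(K):
            phi = phis[k]
            lat_cur = _epi_lat_ll(st[k], bet[k], nu[k], gam[k], has_E, has_R)
            # --- rate updates (latent likelihood only; O(1) via statistics)
            for pr in range(3):
                if pr == 1 and not has_E:
                    continue
                if pr == 2 and not has_R:
                    continue
                att[k, 0] += 1.0
                fac = np.exp(sc_r[k, pr] * np.random.normal())
                if pr == 0:
                    val = bet[k] * fac
                    ok = bt_lo < val < bt_hi
                    dll = st[k, 0] * np.log(fac) - (val - bet[k]) * st[k, 4]
                elif pr == 1:
                    val = nu[k] * fac
                    ok = nu_lo < val < nu_hi
                    dll = st[k, 2] * np.log(fac) - (val - nu[k]) * st[k, 5]
                else:
                    val = gam[k] * fac
                    ok = gm_lo < val < gm_hi
                    dll = st[k, 3] * np.log(fac) - (val - gam[k]) * st[k, 6]
                if not ok:
                    continue
                la = dll + np.log(fac)
                if la >= 0.0 or np.random.random() < np.exp(la):
                    if pr == 0:
                        bet[k] = val
                    elif pr == 1:
                        nu[k] = val
                    else:
                        gam[k] = val
                    lat_cur += dll
                    acc[k, 0] += 1.0

            # --- latent moves
            for rep in range(latent_reps):
                for j in range(p):
                    ej = tE[k, j]
                    ij = tI[k, j]
                    rj = tR[k, j]
                    new_e = ej
                    new_i = ij
                    new_r = rj
                    logq = 0.0
                    move = -1
                    if j == 0:
                        if not has_R:
                            continue
                        move = 0 if np.random.random() < 0.5 else 3
                    else:
                        mm = int(np.random.random() * n_menu)
                        if mm >= n_menu:
                            mm = n_menu - 1
                        move = menu[mm]
                    if move == 0:
                        acc_idx = 1
                    elif move == 1:
                        acc_idx = 2
                    elif move == 4:
                        acc_idx = 4
                    else:
                        acc_idx = 3

                    if move == 0:
                        # shift one finite event time of j
                        nfin = 0
                        if j != 0 and ej < INF:
                            nfin += 1
                        if j != 0 and has_E and ij < INF:
                            nfin += 1
                        if has_R and rj < INF:
                            nfin += 1
                        if nfin == 0:
                            continue
                        pick = int(np.random.random() * nfin)
                        if pick >= nfin:
                            pick = nfin - 1
                        which = 0
                        cnt = -1
                        if j != 0 and ej < INF:
                            cnt += 1
                            if cnt == pick:
                                which = 0
                        if j != 0 and has_E and ij < INF:
                            cnt += 1
                            if cnt == pick:
                                which = 1
                        if has_R and rj < INF:
                            cnt += 1
                            if cnt == pick:
                                which = 2
                        dt = sc_t[k] * np.random.normal()
                        if which == 0:
                            tnew = ej + dt
                            upper = T
                            if has_E:
                                if ij < upper:
                                    upper = ij
                            else:
                                if rj < upper:
                                    upper = rj
                            if tnew <= 0.0 or tnew >= upper:
                                att[k, acc_idx] += 1.0
                                continue
                            new_e = tnew
                            if not has_E:
                                new_i = tnew
                        elif which == 1:
                            tnew = ij + dt
                            upper = T if rj >= T else rj
                            if tnew <= ej or tnew >= upper:
                                att[k, acc_idx] += 1.0
                                continue
                            new_i = tnew
                        else:
                            tnew = rj + dt
                            tstart = 0.0 if j == 0 else (ij if has_E else ej)
                            if tnew <= tstart or tnew >= T:
                                att[k, acc_idx] += 1.0
                                continue
                            new_r = tnew
                    elif move == 1:
                        # toggle exposure (j >= 1); window-start proposal drawn
                        # from the tempered per-individual test likelihood
                        if ej == INF:
                            n_int = _win_levels(
                                times, results[j], lSe, lSe1, lSp, lSp1,
                                0.0, T, 0, 0.0, wb, wl,
                            )
                            t_new, ld = _win_sample(wb, wl, n_int, phi)
                            new_e = t_new
                            new_i = INF if has_E else t_new
                            new_r = INF
                            logq = -ld
                        else:
                            removable = (ij == INF) if has_E else (rj == INF)
                            if not removable:
                                continue
                            n_int = _win_levels(
                                times, results[j], lSe, lSe1, lSp, lSp1,
                                0.0, T, 0, 0.0, wb, wl,
                            )
                            new_e = INF
                            new_i = INF
                            new_r = INF
                            logq = _win_logpdf(wb, wl, n_int, phi, ej)
                    elif move == 2:
                        # toggle onset (models with E, j >= 1)
                        if ej < INF and ij == INF:
                            new_i = np.random.uniform(ej, T)
                            logq = np.log(T - ej)
                        elif ij < INF and rj == INF and ej < INF:
                            new_i = INF
                            logq = -np.log(T - ej)
                        else:
                            continue
                    elif move == 3:
                        # toggle recovery; proposal drawn from the tempered
                        # per-individual test likelihood given window start ej
                        tstart = 0.0 if j == 0 else (ij if has_E else ej)
                        if tstart < INF and rj == INF:
                            if tstart >= T:
                                continue
                            n_int = _win_levels(
                                times, results[j], lSe, lSe1, lSp, lSp1,
                                tstart, T, 1, ej, wb, wl,
                            )
                            t_new, ld = _win_sample(wb, wl, n_int, phi)
                            new_r = t_new
                            logq = -ld
                        elif rj < INF:
                            n_int = _win_levels(
                                times, results[j], lSe, lSe1, lSp, lSp1,
                                tstart, T, 1, ej, wb, wl,
                            )
                            new_r = INF
                            logq = _win_logpdf(wb, wl, n_int, phi, rj)
                        else:
                            continue
                    else:
                        # toggle whole infection path (R-models, j >= 1):
                        # add or remove (exposure [, onset], recovery) jointly,
                        # avoiding the poor "infected forever" intermediate
                        if ej == INF:
                            n_int = _win_levels(
                                times, results[j], lSe, lSe1, lSp, lSp1,
                                0.0, T, 2, 0.0, wb, wl,
                            )
                            t_e, ld1 = _win_sample(wb, wl, n_int, phi)
                            n_int = _win_levels(
                                times, results[j], lSe, lSe1, lSp, lSp1,
                                t_e, T, 1, t_e, wb, wl,
                            )
                            t_r, ld2 = _win_sample(wb, wl, n_int, phi)
                            new_e = t_e
                            new_r = t_r
                            logq = -(ld1 + ld2)
                            if has_E:
                                new_i = np.random.uniform(t_e, t_r)
                                logq += np.log(t_r - t_e)
                        elif rj < INF and (not has_E or ij < INF):
                            n_int = _win_levels(
                                times, results[j], lSe, lSe1, lSp, lSp1,
                                0.0, T, 2, 0.0, wb, wl,
                            )
                            ld1 = _win_logpdf(wb, wl, n_int, phi, ej)
                            n_int = _win_levels(
                                times, results[j], lSe, lSe1, lSp, lSp1,
                                ej, T, 1, ej, wb, wl,
                            )
                            ld2 = _win_logpdf(wb, wl, n_int, phi, rj)
                            logq = ld1 + ld2
                            if has_E:
                                logq -= np.log(rj - ej)
                            new_e = INF
                            new_i = INF
                            new_r = INF
                        else:
                            continue

                    att[k, acc_idx] += 1.0
                    nnew = _epi_rebuild(
                        ev_t[k], ev_ty[k], ev_id[k], ne[k], j,
                        new_e, new_i, new_r, b_t, b_ty, b_id, T, has_E, has_R,
                    )
                    _epi_stats(b_t, b_ty, nnew, p, T, has_E, st_buf)
                    lat_new = _epi_lat_ll(st_buf, bet[k], nu[k], gam[k], has_E, has_R)
                    if lat_new == -np.inf:
                        continue
                    li_new = _epi_obs_ll(new_e, new_r, results[j], times, lSe, lSe1, lSp, lSp1)
                    dobs = li_new - li[k, j]
                    la = (phi * dobs if phi != 0.0 else 0.0) + (lat_new - lat_cur) + logq
                    if la >= 0.0 or np.random.random() < np.exp(la):
                        for e in range(nnew):
                            ev_t[k, e] = b_t[e]
                            ev_ty[k, e] = b_ty[e]
                            ev_id[k, e] = b_id[e]
                        ne[k] = nnew
                        for m in range(7):
                            st[k, m] = st_buf[m]
                        tE[k, j] = new_e
                        tI[k, j] = new_i
                        tR[k, j] = new_r
                        lo[k] += li_new - li[k, j]
                        li[k, j] = li_new
                        lat_cur = lat_new
                        acc[k, acc_idx] += 1.0

        if it < n_burnin and (it + 1) % 100 == 0:
            for k in range(K):
                for pr in range(3):
                    sc_r[k, pr] = _adapt(sc_r[k, pr], acc[k, 0] / 3.0, att[k, 0] / 3.0, 1e-3, 3.0)
                sc_t[k] = _adapt(sc_t[k], acc[k, 1], att[k, 1], 1e-4 * T, T)
                for m in range(5):
                    acc[k, m] = 0.0
                    att[k, m] = 0.0

        if (it + 1) % 100 == 0:
            # refresh the total observed-data log likelihood (sum of cached
            # per-individual contributions) to cancel incremental FP drift
            for k in range(K):
                tot = 0.0
                for j in range(p):
                    tot += li[k, j]
                lo[k] = tot

        if swap_interval > 0 and (it + 1) % swap_interval == 0:
            for k in range(parity, K - 1, 2):
                la = (phis[k] - phis[k + 1]) * (lo[k + 1] - lo[k])
                if la >= 0.0 or np.random.random() < np.exp(la):
                    bet[k], bet[k + 1] = bet[k + 1], bet[k]
                    nu[k], nu[k + 1] = nu[k + 1], nu[k]
                    gam[k], gam[k + 1] = gam[k + 1], gam[k]
                    lo[k], lo[k + 1] = lo[k + 1], lo[k]
                    ne[k], ne[k + 1] = ne[k + 1], ne[k]
                    for j in range(p):
                        tE[k, j], tE[k + 1, j] = tE[k + 1, j], tE[k, j]
                        tI[k, j], tI[k + 1, j] = tI[k + 1, j], tI[k, j]
                        tR[k, j], tR[k + 1, j] = tR[k + 1, j], tR[k, j]
                        li[k, j], li[k + 1, j] = li[k + 1, j], li[k, j]
                    for m in range(7):
                        st[k, m], st[k + 1, m] = st[k + 1, m], st[k, m]
                    nmax = ne[k] if ne[k] > ne[k + 1] else ne[k + 1]
                    for e in range(nmax):
                        ev_t[k, e], ev_t[k + 1, e] = ev_t[k + 1, e], ev_t[k, e]
                        ev_ty[k, e], ev_ty[k + 1, e] = ev_ty[k + 1, e], ev_ty[k, e]
                        ev_id[k, e], ev_id[k + 1, e] = ev_id[k + 1, e], ev_id[k, e]
            parity = 1 - parity

        if it >= n_burnin:
            i = it - n_burnin
            for k in range(K):
                log_obs[k, i] = lo[k]
            lat0[i] = _epi_lat_ll(st[0], bet[0], nu[0], gam[0], has_E, has_R)
            for m in range(7):
                st0[i, m] = st[0, m]
            rates0[i, 0] = bet[0]
            rates0[i, 1] = nu[0]
            rates0[i, 2] = gam[0]
            rates_prior[i, 0] = bet[K - 1]
            rates_prior[i, 1] = nu[K - 1]
            rates_prior[i, 2] = gam[K - 1]

    acc_rates = np.zeros((K, 5))
    for k in range(K):
        for m in range(5):
            acc_rates[k, m] = acc[k, m] / att[k, m] if att[k, m] > 0 else 0.0
    return log_obs, lat0, st0, rates0, rates_prior, acc_rates
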
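"""Compiled Metropolis-within-Gibbs kernels.

The integrated-model kernel works on per-site sufficient statistics of the
citizen-science layer (sum and number of observed replicate counts), which
is exact for a Poisson observation model whose rate is constant within a
site.  Sites without expert data have their occupancy indicator marginalized
analytically (a two-component mixture in the likelihood); indicator draws
for reporting are taken from the exact full conditional at record time.

These kernels are private plumbing: the public surface, and the reference
log-densities the tests check against, live in :mod:`intabund.model` and
:mod:`intabund.mcmc`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_BIG_NEG = -1.0e300


@njit(cache=True)
def _csll(S, R, mu):
    """Poisson log-likelihood of R replicate counts summing to S, rate mu."""
    if mu <= 0.0:
        return 0.0 if S == 0.0 else _BIG_NEG
    return S * math.log(mu) - R * mu


@njit(cache=True)
def _expert_ll(w, lam, variant, k, vfloor):
    """Expert log-density at an occupied site (z = 1), constants dropped."""
    if variant == 0:  # Poisson
        if lam <= 0.0:
            return 0.0 if w == 0.0 else _BIG_NEG
        return w * math.log(lam) - lam
    var = k * lam
    if var < vfloor:
        var = vfloor
    d = w - lam
    return -0.5 * math.log(var) - 0.5 * d * d / var


@njit(cache=True)
def _logaddexp(a, b):
    if a < b:
        a, b = b, a
    if b <= _BIG_NEG:
        return a
    return a + math.log1p(math.exp(b - a))


@njit(cache=True)
def _site_ll(i, p, om, m, lam_i, S, R, w, has_exp, z_exp, variant, k, vfloor):
    """Likelihood+occupancy contribution of site i, given its lambda."""
    log_om = math.log(om) if om > 0.0 else _BIG_NEG
    log_1mom = math.log1p(-om) if om < 1.0 else _BIG_NEG
    if has_exp[i]:
        if z_exp[i] == 1:
            return (
                _csll(S[i], R[i], lam_i * p + m)
                + _expert_ll(w[i], lam_i, variant, k, vfloor)
                + log_om
            )
        return _csll(S[i], R[i], m) + log_1mom
    occ = log_om + _csll(S[i], R[i], lam_i * p + m)
    emp = log_1mom + _csll(S[i], R[i], m)
    return _logaddexp(occ, emp)


@njit(cache=True)
def _iam_target(p, om, m, lam, S, R, w, has_exp, z_exp, variant, k, vfloor,
                lam_shape, lam_rate):
    """Full log target (likelihood x priors, constants dropped)."""
    total = 0.0
    n = S.shape[0]
    for i in range(n):
        total += _site_ll(i, p, om, m, lam[i], S, R, w, has_exp, z_exp,
                          variant, k, vfloor)
        total += (lam_shape - 1.0) * math.log(lam[i]) - lam_rate * lam[i]
    return total


@njit(cache=True)
def iam_chain(S, R, w, has_exp, z_exp, variant, k, vfloor,
              m_max, lam_shape, lam_rate,
              n_iter, burn_in, thin, seed,
              p0, om0, m0, lam0,
              up_p, up_om, up_m, up_lam,
              out_p, out_om, out_m, out_lam, out_z):
    """Run one MCMC chain; fills the out_* arrays with retained draws."""
    np.random.seed(seed)
    n = S.shape[0]
    p = p0
    om = om0
    m = m0
    lam = lam0.copy()

    # adaptive random-walk scales, frozen after burn-in
    s_p = 0.3
    s_om = 0.5
    s_m = 1.0
    s_joint = 0.1
    s_lam = np.full(n, 0.15)
    acc_p = 0.0
    acc_om = 0.0
    acc_m = 0.0
    acc_joint = 0.0
    acc_lam = np.zeros(n)
    window = 50

    cur = _iam_target(p, om, m, lam, S, R, w, has_exp, z_exp, variant, k,
                      vfloor, lam_shape, lam_rate)
    idx = 0
    for it in range(n_iter):
        # --- lambda updates: site-local, so only the site term changes
        if up_lam:
            for i in range(n):
                dead = has_exp[i] and z_exp[i] == 0
                if dead:
                    # likelihood-free: full conditional is the Gamma prior
                    lam_new = np.random.gamma(lam_shape, 1.0 / lam_rate)
                    cur += (lam_shape - 1.0) * (math.log(lam_new) - math.log(lam[i]))
                    cur += -lam_rate * (lam_new - lam[i])
                    lam[i] = lam_new
                    continue
                old_site = _site_ll(i, p, om, m, lam[i], S, R, w, has_exp,
                                    z_exp, variant, k, vfloor)
                old_pr = (lam_shape - 1.0) * math.log(lam[i]) - lam_rate * lam[i]
                if (not has_exp[i]) and np.random.random() < 0.5:
                    # independence proposal from the prior (helps jump
                    # between the occupied and empty mixture branches)
                    lam_new = np.random.gamma(lam_shape, 1.0 / lam_rate)
                    new_site = _site_ll(i, p, om, m, lam_new, S, R, w,
                                        has_exp, z_exp, variant, k, vfloor)
                    if math.log(np.random.random()) < new_site - old_site:
                        new_pr = ((lam_shape - 1.0) * math.log(lam_new)
                                  - lam_rate * lam_new)
                        cur += new_site + new_pr - old_site - old_pr
                        lam[i] = lam_new
                    continue
                lam_new = lam[i] * math.exp(s_lam[i] * np.random.normal())
                new_site = _site_ll(i, p, om, m, lam_new, S, R, w, has_exp,
                                    z_exp, variant, k, vfloor)
                new_pr = (lam_shape - 1.0) * math.log(lam_new) - lam_rate * lam_new
                # log-scale walk: Jacobian contributes log(lam_new/lam_old)
                ratio = (new_site + new_pr) - (old_site + old_pr) \
                    + math.log(lam_new) - math.log(lam[i])
                if math.log(np.random.random()) < ratio:
                    cur += new_site + new_pr - old_site - old_pr
                    lam[i] = lam_new
                    acc_lam[i] += 1.0

        # --- p: logit-scale random walk
        if up_p:
            lp = math.log(p / (1.0 - p)) + s_p * np.random.normal()
            p_new = 1.0 / (1.0 + math.exp(-lp))
            if 0.0 < p_new < 1.0:
                new = _iam_target(p_new, om, m, lam, S, R, w, has_exp, z_exp,
                                  variant, k, vfloor, lam_shape, lam_rate)
                jac = (math.log(p_new) + math.log1p(-p_new)
                       - math.log(p) - math.log1p(-p))
                if math.log(np.random.random()) < new - cur + jac:
                    p = p_new
                    cur = new
                    acc_p += 1.0

        # --- joint ridge move: shift p on the logit scale while scaling
        # every lambda_i by p/p' so the citizen-science means lambda*p stay
        # put; the expert layer arbitrates.  In (logit p, log lambda)
        # coordinates this is a unit-Jacobian shear with symmetric noise, so
        # the acceptance ratio only needs the log-scale measure terms.
        if up_p and up_lam:
            lp = math.log(p / (1.0 - p)) + s_joint * np.random.normal()
            p_new = 1.0 / (1.0 + math.exp(-lp))
            if 0.0 < p_new < 1.0:
                c = p / p_new
                lam_prop = lam * c
                new = _iam_target(p_new, om, m, lam_prop, S, R, w, has_exp,
                                  z_exp, variant, k, vfloor, lam_shape,
                                  lam_rate)
                jac = (math.log(p_new) + math.log1p(-p_new)
                       - math.log(p) - math.log1p(-p)
                       + n * math.log(c))
                if math.log(np.random.random()) < new - cur + jac:
                    p = p_new
                    for i in range(n):
                        lam[i] = lam_prop[i]
                    cur = new
                    acc_joint += 1.0

        # --- omega: logit-scale random walk
        if up_om:
            lo = math.log(om / (1.0 - om)) + s_om * np.random.normal()
            om_new = 1.0 / (1.0 + math.exp(-lo))
            if 0.0 < om_new < 1.0:
                new = _iam_target(p, om_new, m, lam, S, R, w, has_exp, z_exp,
                                  variant, k, vfloor, lam_shape, lam_rate)
                jac = (math.log(om_new) + math.log1p(-om_new)
                       - math.log(om) - math.log1p(-om))
                if math.log(np.random.random()) < new - cur + jac:
                    om = om_new
                    cur = new
                    acc_om += 1.0

        # --- m: random walk reflected into [0, m_max]
        if up_m:
            m_new = m + s_m * np.random.normal()
            for _ in range(8):
                if m_new < 0.0:
                    m_new = -m_new
                elif m_new > m_max:
                    m_new = 2.0 * m_max - m_new
                else:
                    break
            if 0.0 <= m_new <= m_max:
                new = _iam_target(p, om, m_new, lam, S, R, w, has_exp, z_exp,
                                  variant, k, vfloor, lam_shape, lam_rate)
                if math.log(np.random.random()) < new - cur:
                    m = m_new
                    cur = new
                    acc_m += 1.0

        # --- adapt proposal scales during burn-in only
        if it < burn_in and (it + 1) % window == 0:
            s_p *= math.exp((acc_p / window - 0.44) * 0.5)
            s_om *= math.exp((acc_om / window - 0.44) * 0.5)
            s_m *= math.exp((acc_m / window - 0.44) * 0.5)
            s_joint *= math.exp((acc_joint / window - 0.44) * 0.5)
            acc_joint = 0.0
            for i in range(n):
                s_lam[i] *= math.exp((acc_lam[i] / window - 0.44) * 0.5)
                acc_lam[i] = 0.0
            acc_p = 0.0
            acc_om = 0.0
            acc_m = 0.0

        # --- record
        if it >= burn_in and (it - burn_in) % thin == 0:
            out_p[idx] = p
            out_om[idx] = om
            out_m[idx] = m
            log_om = math.log(om) if om > 0.0 else _BIG_NEG
            log_1mom = math.log1p(-om) if om < 1.0 else _BIG_NEG
            for i in range(n):
                out_lam[idx, i] = lam[i]
                if has_exp[i]:
                    out_z[idx, i] = z_exp[i]
                else:
                    a = log_om + _csll(S[i], R[i], lam[i] * p + m)
                    b = log_1mom + _csll(S[i], R[i], m)
                    pz = 1.0 / (1.0 + math.exp(min(b - a, 700.0))) \
                        if a - b > -700.0 else 0.0
                    out_z[idx, i] = 1 if np.random.random() < pz else 0
            idx += 1
    return idx


@njit(cache=True)
def nmix_chain(y, obs, lam_shape, lam_rate,
               n_iter, burn_in, thin, seed,
               p0, lamE0, N0,
               out_p, out_lamE, out_N):
    """One chain of the binomial-Poisson N-mixture sampler — exact Gibbs.

    p and lambda_E have conjugate full conditionals (Beta and Gamma); each
    integer latent abundance is drawn exactly from its full conditional by
    enumerating the support upward from max_j y[i, j] with a multiplicative
    term recurrence until the Poisson tail is negligible.
    """
    np.random.seed(seed)
    n, reps = y.shape
    N = N0.copy()
    lamE = lamE0
    p = p0

    ymax = np.zeros(n, dtype=np.int64)
    ysum = np.zeros(n)
    robs = np.zeros(n)
    for i in range(n):
        for j in range(reps):
            if obs[i, j]:
                robs[i] += 1.0
                ysum[i] += y[i, j]
                if y[i, j] > ymax[i]:
                    ymax[i] = y[i, j]
        if N[i] < ymax[i]:
            N[i] = ymax[i]

    cap = 4096
    wbuf = np.empty(cap)
    idx = 0
    for it in range(n_iter):
        # p | N, y  ~  Beta(1 + sum y, 1 + sum_i R_i N_i - sum y)
        a = 1.0
        b = 1.0
        for i in range(n):
            a += ysum[i]
            b += robs[i] * N[i] - ysum[i]
        p = np.random.beta(a, b)

        # lambda_E | N  ~  Gamma(shape + sum N, rate + n)
        totN = 0.0
        for i in range(n):
            totN += N[i]
        lamE = np.random.gamma(lam_shape + totN, 1.0 / (lam_rate + n))

        # N_i | rest: enumerate from ymax_i; successive-term ratio is
        # lamE/(N+1) * (1-p)^R_i * prod_j (N+1)/(N+1-y_ij)
        q = 1.0 - p
        for i in range(n):
            t = 1.0
            wbuf[0] = 1.0
            total = 1.0
            peak = 1.0
            steps = 1
            Ncur = ymax[i]
            while steps < cap:
                ratio = lamE / (Ncur + 1.0) * q ** robs[i]
                for j in range(reps):
                    if obs[i, j]:
                        ratio *= (Ncur + 1.0) / (Ncur + 1.0 - y[i, j])
                t *= ratio
                if t > 1.0e280:  # rescale to dodge overflow near the mode
                    for s in range(steps):
                        wbuf[s] /= 1.0e280
                    t /= 1.0e280
                    total /= 1.0e280
                    peak /= 1.0e280
                wbuf[steps] = t
                total += t
                if t > peak:
                    peak = t
                elif t < peak * 1.0e-14 and steps > 10:
                    steps += 1
                    break
                steps += 1
                Ncur += 1
            u = np.random.random() * total
            acc = 0.0
            pick = steps - 1
            for s in range(steps):
                acc += wbuf[s]
                if u <= acc:
                    pick = s
                    break
            N[i] = ymax[i] + pick

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_p[idx] = p
            out_lamE[idx] = lamE
            for i in range(n):
                out_N[idx, i] = N[i]
            idx += 1
    return idx
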
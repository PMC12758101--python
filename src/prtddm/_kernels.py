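"""Numba kernels: WFPT density, diffusion sampling, trial likelihood, MCMC.

All heavy numerics live here as nopython-compiled scalar/loop code.  The
public modules (:mod:`prtddm.core`, :mod:`prtddm.simulate`,
:mod:`prtddm.inference`) wrap these kernels with typed, documented APIs.

Conventions
-----------
- The diffusion runs between 0 (lower boundary = "lean" response) and ``a``
  (upper boundary = "rich" response); ``z`` is the relative starting point
  in (0, 1) measured from the lower boundary; ``v`` is the signed drift
  toward the upper boundary; diffusion coefficient fixed at 1.
- Stimuli and responses are coded +1 (rich) / -1 (lean) / 0 (no response).
- Parameter vectors are ordered (alpha, B_v, B_z, v_intercept, a, t) on an
  unconstrained "link" scale: logit for alpha, log for a, identity
  elsewhere.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: series truncation error for the normalized first-passage density; the
#: resulting absolute density error is far below the 1e-6 contract
_WFPT_ERR = 1e-12

# link-scale parameter ordering
IDX_ALPHA, IDX_BV, IDX_BZ, IDX_V0, IDX_A, IDX_T = 0, 1, 2, 3, 4, 5
N_PARAMS = 6


@njit(cache=True)
def _logistic(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _fpt_norm(w, z):
    """Normalized first-passage density at the lower boundary.

    Zero drift, unit threshold, relative start ``z``, rescaled time
    ``w = (rt - t) / a**2``.  Automatically switches between the
    small-time and large-time series expansions, using whichever needs
    fewer terms for truncation error below ``_WFPT_ERR``.
    """
    if w <= 0.0:
        return 0.0
    err = _WFPT_ERR
    # number of terms required by the small-time expansion
    if 2.0 * np.sqrt(2.0 * np.pi * w) * err < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * w * np.log(2.0 * err * np.sqrt(2.0 * np.pi * w)))
        if ks < np.sqrt(w) + 1.0:
            ks = np.sqrt(w) + 1.0
    else:
        ks = 2.0
    # number of terms required by the large-time expansion
    if np.pi * w * err < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * w * err) / (np.pi * np.pi * w))
        if kl < 1.0 / (np.pi * np.sqrt(w)):
            kl = 1.0 / (np.pi * np.sqrt(w))
    else:
        kl = 1.0 / (np.pi * np.sqrt(w))

    if ks < kl:
        K = int(np.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) - ((K - 1) // 2)
        f = 0.0
        for k in range(lo, hi + 1):
            y = z + 2.0 * k
            f += y * np.exp(-y * y / (2.0 * w))
        f /= np.sqrt(2.0 * np.pi * w * w * w)
    else:
        K = int(np.ceil(kl))
        f = 0.0
        for k in range(1, K + 1):
            f += k * np.exp(-k * k * np.pi * np.pi * w / 2.0) * np.sin(k * np.pi * z)
        f *= np.pi
    return f


@njit(cache=True)
def wfpt_logpdf_lower(u, v, a, z):
    """Log density of absorption at the lower boundary at decision time u."""
    if u <= 0.0 or a <= 0.0 or z <= 0.0 or z >= 1.0:
        return -np.inf
    f = _fpt_norm(u / (a * a), z)
    if f <= 0.0:
        return -np.inf
    return np.log(f) - v * a * z - v * v * u / 2.0 - 2.0 * np.log(a)


@njit(cache=True)
def wfpt_logpdf_signed(u, v, a, z, upper):
    """Log WFPT density at the named boundary (upper=True for rich)."""
    if upper:
        return wfpt_logpdf_lower(u, -v, a, 1.0 - z)
    return wfpt_logpdf_lower(u, v, a, z)


@njit(cache=True)
def _trial_drift_start(qr, ql, s, alpha, bv, bz, v0, literal_sign):
    """Starting point and signed drift for one trial.

    ``s`` is the stimulus sign.  Default convention: the stimulus signs the
    intercept only (v = s*v0 + bv*dq), so growing dq speeds correct rich
    responses and slows correct lean responses.  ``literal_sign`` signs the
    whole sum instead: v = s*(v0 + bv*dq).
    """
    dq = qr - ql
    z = _logistic(bz * dq)
    if literal_sign:
        v = s * (v0 + bv * dq)
    else:
        v = s * v0 + bv * dq
    return dq, z, v


@njit(cache=True)
def trial_loglik_fill(
    stim, resp, rt, reward, valid,
    alpha, bv, bz, v0, a, t, literal_sign,
    out_ll, out_qr, out_ql, out_v, out_z,
):
    """Sequential trial likelihood with latent trajectory.

    Fills per-trial log densities (0 for invalid / no-response trials) and
    the pre-choice latents, and returns the total log-likelihood.  Q values
    start at 0 for both responses and are updated by the delta rule for the
    chosen response whenever a response occurred (feedback was shown even on
    QC-invalid trials).
    """
    n = stim.shape[0]
    if a <= 0.0 or t < 0.0 or alpha < 0.0 or alpha > 1.0:
        for i in range(n):
            out_ll[i] = np.nan
        return -np.inf
    qr = 0.0
    ql = 0.0
    total = 0.0
    for i in range(n):
        dq, z, v = _trial_drift_start(qr, ql, stim[i], alpha, bv, bz, v0, literal_sign)
        out_qr[i] = qr
        out_ql[i] = ql
        out_v[i] = v
        out_z[i] = z
        li = 0.0
        if valid[i] and resp[i] != 0:
            li = wfpt_logpdf_signed(rt[i] - t, v, a, z, resp[i] > 0)
        out_ll[i] = li
        total += li
        if resp[i] > 0:
            qr += alpha * (reward[i] - qr)
        elif resp[i] < 0:
            ql += alpha * (reward[i] - ql)
    return total


@njit(cache=True)
def _subject_ll(stim, resp, rt, reward, valid, n, th, literal_sign):
    """Total log-likelihood for one subject from link-scale parameters."""
    alpha = _logistic(th[IDX_ALPHA])
    bv = th[IDX_BV]
    bz = th[IDX_BZ]
    v0 = th[IDX_V0]
    a = np.exp(th[IDX_A])
    t = th[IDX_T]
    if t <= 0.0:
        return -np.inf
    qr = 0.0
    ql = 0.0
    total = 0.0
    for i in range(n):
        dq = qr - ql
        z = _logistic(bz * dq)
        if literal_sign:
            v = stim[i] * (v0 + bv * dq)
        else:
            v = stim[i] * v0 + bv * dq
        if valid[i] and resp[i] != 0:
            total += wfpt_logpdf_signed(rt[i] - t, v, a, z, resp[i] > 0)
            if total == -np.inf:
                return -np.inf
        if resp[i] > 0:
            qr += alpha * (reward[i] - qr)
        elif resp[i] < 0:
            ql += alpha * (reward[i] - ql)
    return total


@njit(cache=True)
def sample_fp(n, v, a, z, dt, use_bridge, tmax, seed):
    """Sample first-passage (boundary, decision time) pairs.

    Euler–Maruyama with step ``dt``; with ``use_bridge`` a Brownian-bridge
    crossing test is applied within each step, removing most of the
    O(sqrt(dt)) boundary-overshoot bias.  Boundary code: +1 upper, -1
    lower, 0 censored at ``tmax``.
    """
    np.random.seed(seed)
    bounds = np.empty(n, dtype=np.int8)
    times = np.empty(n, dtype=np.float64)
    sdt = np.sqrt(dt)
    # bridge crossing prob exp(-2*d/dt) is < 2e-8 beyond this product cutoff
    cut = 9.0 * dt
    for i in range(n):
        x = z * a
        tt = 0.0
        b = 0
        while tt < tmax:
            xn = x + v * dt + sdt * np.random.randn()
            tt += dt
            if xn >= a:
                b = 1
                break
            if xn <= 0.0:
                b = -1
                break
            if use_bridge:
                du = (a - x) * (a - xn)
                if du < cut and np.random.rand() < np.exp(-2.0 * du / dt):
                    b = 1
                    break
                dl = x * xn
                if dl < cut and np.random.rand() < np.exp(-2.0 * dl / dt):
                    b = -1
                    break
            x = xn
        bounds[i] = b
        times[i] = tt
    return bounds, times


@njit(cache=True)
def simulate_trials(
    stim, scheduled, queued,
    alpha, bv, bz, v0, a, t, literal_sign,
    dt, use_bridge, deadline, seed,
    resp_out, rt_out, rew_out, z_out, v_out,
):
    """Forward-simulate one PRT session.

    First-passage times exceeding ``deadline - t`` become non-responses
    (no feedback, no learning).  Under the queued delivery rule, scheduled
    rewards missed by an incorrect/absent response are re-queued for the
    next correct response to the same stimulus type.
    """
    np.random.seed(seed)
    n = stim.shape[0]
    qr = 0.0
    ql = 0.0
    pend_rich = 0
    pend_lean = 0
    sdt = np.sqrt(dt)
    tmax = deadline - t
    cut = 9.0 * dt
    for i in range(n):
        dq, z, v = _trial_drift_start(qr, ql, stim[i], alpha, bv, bz, v0, literal_sign)
        z_out[i] = z
        v_out[i] = v
        # one first-passage draw
        x = z * a
        tt = 0.0
        b = 0
        while tt < tmax:
            xn = x + v * dt + sdt * np.random.randn()
            tt += dt
            if xn >= a:
                b = 1
                break
            if xn <= 0.0:
                b = -1
                break
            if use_bridge:
                du = (a - x) * (a - xn)
                if du < cut and np.random.rand() < np.exp(-2.0 * du / dt):
                    b = 1
                    break
                dl = x * xn
                if dl < cut and np.random.rand() < np.exp(-2.0 * dl / dt):
                    b = -1
                    break
            x = xn
        if queued and scheduled[i]:
            if stim[i] > 0:
                pend_rich += 1
            else:
                pend_lean += 1
        if b == 0:
            resp_out[i] = 0
            rt_out[i] = np.nan
            rew_out[i] = 0
            continue
        resp_out[i] = b
        rt_out[i] = t + tt
        correct = b == stim[i]
        r = 0
        if correct:
            if queued:
                if stim[i] > 0 and pend_rich > 0:
                    r = 1
                    pend_rich -= 1
                elif stim[i] < 0 and pend_lean > 0:
                    r = 1
                    pend_lean -= 1
            elif scheduled[i]:
                r = 1
        rew_out[i] = r
        if b > 0:
            qr += alpha * (r - qr)
        else:
            ql += alpha * (r - ql)


@njit(cache=True)
def run_chain(
    stim, resp, rt, reward, valid, ntr,
    free, tied, literal_sign,
    m0, s0, sig_scale,
    n_iter, n_burn, thin, seed,
    mu0, sig0, theta0,
):
    """One MCMC chain of the hierarchical model (Metropolis-within-Gibbs).

    Data arrays are (n_subjects, max_trials) padded; ``ntr[i]`` gives the
    usable length for subject ``i``.  Subject parameters use random-walk
    Metropolis with Robbins–Monro step adaptation during burn-in (target
    acceptance 0.44); group means are conjugate-normal updates; group SDs
    use log-scale Metropolis with half-normal priors.  Fixed parameters
    (``free[j] == False``) keep their initial values everywhere; with
    ``tied`` the B_z column mirrors B_v (one shared value-weight).
    """
    np.random.seed(seed)
    nsub = stim.shape[0]
    mu = mu0.copy()
    sig = sig0.copy()
    theta = theta0.copy()
    ll = np.empty(nsub)
    for i in range(nsub):
        ll[i] = _subject_ll(stim[i], resp[i], rt[i], reward[i], valid[i], ntr[i], theta[i], literal_sign)

    step = np.full((nsub, N_PARAMS), 0.15)
    step[:, IDX_T] = 0.02
    step_s = np.full(N_PARAMS, 0.25)
    step_r = np.full(N_PARAMS, 0.15)
    acc = np.zeros((nsub, N_PARAMS))
    acc_s = np.zeros(N_PARAMS)
    acc_r = np.zeros(N_PARAMS)
    prop_ll = np.empty(nsub)

    n_kept = (n_iter - n_burn + thin - 1) // thin
    draws_mu = np.empty((n_kept, N_PARAMS))
    draws_sig = np.empty((n_kept, N_PARAMS))
    draws_theta = np.empty((n_kept, nsub, N_PARAMS))
    kept = 0
    batch = 0

    for it in range(n_iter):
        # subject-level random-walk Metropolis, one parameter at a time
        for i in range(nsub):
            for j in range(N_PARAMS):
                if not free[j]:
                    continue
                if tied and j == IDX_BZ:
                    continue
                old = theta[i, j]
                prop = old + step[i, j] * np.random.randn()
                theta[i, j] = prop
                if tied and j == IDX_BV:
                    theta[i, IDX_BZ] = prop
                llp = _subject_ll(
                    stim[i], resp[i], rt[i], reward[i], valid[i], ntr[i], theta[i], literal_sign
                )
                d_prior = ((old - mu[j]) ** 2 - (prop - mu[j]) ** 2) / (2.0 * sig[j] ** 2)
                logr = llp - ll[i] + d_prior
                if np.log(np.random.rand()) < logr:
                    ll[i] = llp
                    acc[i, j] += 1.0
                else:
                    theta[i, j] = old
                    if tied and j == IDX_BV:
                        theta[i, IDX_BZ] = old
        # group means: conjugate normal given subject values and group SD
        for j in range(N_PARAMS):
            if not free[j] or (tied and j == IDX_BZ):
                continue
            prec = 1.0 / (s0[j] * s0[j]) + nsub / (sig[j] * sig[j])
            s_th = 0.0
            for i in range(nsub):
                s_th += theta[i, j]
            mean = (m0[j] / (s0[j] * s0[j]) + s_th / (sig[j] * sig[j])) / prec
            mu[j] = mean + np.random.randn() / np.sqrt(prec)
        # group SDs: Metropolis on log(sigma), half-normal prior
        for j in range(N_PARAMS):
            if not free[j] or (tied and j == IDX_BZ):
                continue
            ssq = 0.0
            for i in range(nsub):
                d = theta[i, j] - mu[j]
                ssq += d * d
            s_old = sig[j]
            s_new = np.exp(np.log(s_old) + step_s[j] * np.random.randn())
            lt_old = (
                -nsub * np.log(s_old) - ssq / (2.0 * s_old * s_old)
                - s_old * s_old / (2.0 * sig_scale[j] ** 2) + np.log(s_old)
            )
            lt_new = (
                -nsub * np.log(s_new) - ssq / (2.0 * s_new * s_new)
                - s_new * s_new / (2.0 * sig_scale[j] ** 2) + np.log(s_new)
            )
            if np.log(np.random.rand()) < lt_new - lt_old:
                sig[j] = s_new
                acc_s[j] += 1.0
        # interweaved ancillary rescale move: sigma -> c*sigma with subject
        # deviations scaled along (theta -> mu + c*(theta - mu)).  Breaks
        # the funnel coupling between group SD and weakly-identified
        # subject parameters that the centered sweep mixes slowly.
        for j in range(N_PARAMS):
            if not free[j] or (tied and j == IDX_BZ):
                continue
            u = step_r[j] * np.random.randn()
            c = np.exp(u)
            s_new = sig[j] * c
            dll = 0.0
            for i in range(nsub):
                old_ij = theta[i, j]
                theta[i, j] = mu[j] + c * (old_ij - mu[j])
                if tied and j == IDX_BV:
                    theta[i, IDX_BZ] = theta[i, j]
                llp = _subject_ll(
                    stim[i], resp[i], rt[i], reward[i], valid[i], ntr[i],
                    theta[i], literal_sign,
                )
                prop_ll[i] = llp
                dll += llp - ll[i]
                theta[i, j] = old_ij
                if tied and j == IDX_BV:
                    theta[i, IDX_BZ] = old_ij
            # prior x Jacobian terms reduce to log(c) + half-normal change
            logr = dll + u - (s_new * s_new - sig[j] * sig[j]) / (
                2.0 * sig_scale[j] ** 2
            )
            if np.log(np.random.rand()) < logr:
                for i in range(nsub):
                    theta[i, j] = mu[j] + c * (theta[i, j] - mu[j])
                    if tied and j == IDX_BV:
                        theta[i, IDX_BZ] = theta[i, j]
                    ll[i] = prop_ll[i]
                sig[j] = s_new
                acc_r[j] += 1.0
        # step-size adaptation during burn-in
        if it < n_burn and (it + 1) % 50 == 0:
            batch += 1
            delta = 1.0 / np.sqrt(batch)
            if delta > 0.25:
                delta = 0.25
            for i in range(nsub):
                for j in range(N_PARAMS):
                    if acc[i, j] / 50.0 > 0.44:
                        step[i, j] *= np.exp(delta)
                    else:
                        step[i, j] *= np.exp(-delta)
                    acc[i, j] = 0.0
            for j in range(N_PARAMS):
                if acc_s[j] / 50.0 > 0.44:
                    step_s[j] *= np.exp(delta)
                else:
                    step_s[j] *= np.exp(-delta)
                acc_s[j] = 0.0
                if acc_r[j] / 50.0 > 0.44:
                    step_r[j] *= np.exp(delta)
                else:
                    step_r[j] *= np.exp(-delta)
                acc_r[j] = 0.0
        if it >= n_burn and (it - n_burn) % thin == 0:
            draws_mu[kept] = mu
            draws_sig[kept] = sig
            draws_theta[kept] = theta
            kept += 1
    return draws_mu, draws_sig, draws_theta


@njit(cache=True)
def run_subject_chain(
    stim, resp, rt, reward, valid, n,
    free, tied, literal_sign,
    prior_m, prior_s,
    n_iter, n_burn, thin, seed, theta_init,
):
    """Single-subject (non-hierarchical) random-walk Metropolis chain.

    ``prior_m``/``prior_s`` define fixed, weakly-informative normal priors
    on the link scale.
    """
    np.random.seed(seed)
    theta = theta_init.copy()
    ll = _subject_ll(stim, resp, rt, reward, valid, n, theta, literal_sign)
    step = np.full(N_PARAMS, 0.15)
    step[IDX_T] = 0.02
    acc = np.zeros(N_PARAMS)
    n_kept = (n_iter - n_burn + thin - 1) // thin
    draws = np.empty((n_kept, N_PARAMS))
    kept = 0
    batch = 0
    for it in range(n_iter):
        for j in range(N_PARAMS):
            if not free[j]:
                continue
            if tied and j == IDX_BZ:
                continue
            old = theta[j]
            prop = old + step[j] * np.random.randn()
            theta[j] = prop
            if tied and j == IDX_BV:
                theta[IDX_BZ] = prop
            llp = _subject_ll(stim, resp, rt, reward, valid, n, theta, literal_sign)
            d_prior = ((old - prior_m[j]) ** 2 - (prop - prior_m[j]) ** 2) / (
                2.0 * prior_s[j] ** 2
            )
            if np.log(np.random.rand()) < llp - ll + d_prior:
                ll = llp
                acc[j] += 1.0
            else:
                theta[j] = old
                if tied and j == IDX_BV:
                    theta[IDX_BZ] = old
        if it < n_burn and (it + 1) % 50 == 0:
            batch += 1
            delta = 1.0 / np.sqrt(batch)
            if delta > 0.25:
                delta = 0.25
            for j in range(N_PARAMS):
                if acc[j] / 50.0 > 0.44:
                    step[j] *= np.exp(delta)
                else:
                    step[j] *= np.exp(-delta)
                acc[j] = 0.0
        if it >= n_burn and (it - n_burn) % thin == 0:
            draws[kept] = theta
            kept += 1
    return draws


@njit(cache=True)
def pointwise_loglik(stim, resp, rt, reward, valid, ntr, theta_draws, literal_sign):
    """Per-trial log-likelihood matrix over posterior draws.

    Returns an (n_draws, n_valid_trials_total) matrix; trials are laid out
    subject-major in chronological order, only QC-valid responded trials.
    """
    ndraw = theta_draws.shape[0]
    nsub = stim.shape[0]
    # count likelihood-bearing trials
    ntot = 0
    for i in range(nsub):
        for k in range(ntr[i]):
            if valid[i, k] and resp[i, k] != 0:
                ntot += 1
    out = np.empty((ndraw, ntot))
    for d in range(ndraw):
        col = 0
        for i in range(nsub):
            th = theta_draws[d, i]
            alpha = _logistic(th[IDX_ALPHA])
            bv = th[IDX_BV]
            bz = th[IDX_BZ]
            v0 = th[IDX_V0]
            a = np.exp(th[IDX_A])
            t = th[IDX_T]
            qr = 0.0
            ql = 0.0
            for k in range(ntr[i]):
                dq = qr - ql
                z = _logistic(bz * dq)
                if literal_sign:
                    v = stim[i, k] * (v0 + bv * dq)
                else:
                    v = stim[i, k] * v0 + bv * dq
                if valid[i, k] and resp[i, k] != 0:
                    out[d, col] = wfpt_logpdf_signed(rt[i, k] - t, v, a, z, resp[i, k] > 0)
                    col += 1
                if resp[i, k] > 0:
                    qr += alpha * (reward[i, k] - qr)
                elif resp[i, k] < 0:
                    ql += alpha * (reward[i, k] - ql)
    return out
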
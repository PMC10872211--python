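"""Numba kernel for the multivariate animal-model Gibbs sampler.

Single-site Gibbs over location effects (fixed effects as one matrix-normal
block; breeding values, permanent-environment, year, and observer effects
as per-entity multivariate draws) alternating with inverse-Wishart draws of
the covariance components.  The additive-genetic prior enters through the
sparse A-inverse, so one sweep costs O(nonzeros + records).

All draws use numpy's legacy RandomState inside numba, seeded once per fit:
the chain is bit-reproducible for a given (data, settings, seed).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------- low level


@njit(cache=True)
def _forward(L, b):
    """Solve L x = b for lower-triangular L."""
    n = L.shape[0]
    x = np.empty(n)
    for i in range(n):
        s = b[i]
        for j in range(i):
            s -= L[i, j] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _backward_t(L, b):
    """Solve L' x = b for lower-triangular L."""
    n = L.shape[0]
    x = np.empty(n)
    for i in range(n - 1, -1, -1):
        s = b[i]
        for j in range(i + 1, n):
            s -= L[j, i] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _inv_lower(L):
    """Inverse of a lower-triangular matrix (lower-triangular result)."""
    n = L.shape[0]
    Li = np.zeros((n, n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = 1.0
        col = _forward(L, e)
        for i in range(n):
            Li[i, k] = col[i]
    return Li


@njit(cache=True)
def _spd_inverse(S):
    L = np.linalg.cholesky(S)
    Li = _inv_lower(L)
    return Li.T @ Li


@njit(cache=True)
def _mvn_from_precision(Q, rhs):
    """Draw x ~ N(Q^-1 rhs, Q^-1)."""
    L = np.linalg.cholesky(Q)
    m = _backward_t(L, _forward(L, rhs))
    z = np.empty(L.shape[0])
    for i in range(L.shape[0]):
        z[i] = np.random.standard_normal()
    return m + _backward_t(L, z)


@njit(cache=True, inline="always")
def _chol_small(Q, L):
    """In-place Cholesky of small SPD Q into preallocated L."""
    n = Q.shape[0]
    for i in range(n):
        for j in range(i + 1):
            s = Q[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
        for j in range(i + 1, n):
            L[i, j] = 0.0


@njit(cache=True, inline="always")
def _draw_mvn_buf(L, rhs, tmp, out):
    """out = Q^-1 rhs + L^-T z with Q = L L', using scratch tmp."""
    n = L.shape[0]
    for i in range(n):
        s = rhs[i]
        for j in range(i):
            s -= L[i, j] * tmp[j]
        tmp[i] = s / L[i, i]
    for i in range(n - 1, -1, -1):
        s = tmp[i]
        for j in range(i + 1, n):
            s -= L[j, i] * out[j]
        out[i] = s / L[i, i]
    # mean now in out; add noise term L^-T z
    for i in range(n):
        tmp[i] = np.random.standard_normal()
    for i in range(n - 1, -1, -1):
        s = tmp[i]
        for j in range(i + 1, n):
            s -= L[j, i] * tmp[j]
        tmp[i] = s / L[i, i]
    for i in range(n):
        out[i] += tmp[i]


@njit(cache=True)
def _invwishart(S, df):
    """Draw G ~ IW(scale=S, df) with E[G] = S / (df - T - 1)."""
    T = S.shape[0]
    Ls = np.linalg.cholesky(S)
    C = _inv_lower(Ls).T  # upper, C C' = S^-1
    B = np.zeros((T, T))
    for i in range(T):
        # chi2(df - i) = gamma(k/2, 2)
        B[i, i] = np.sqrt(np.random.gamma(0.5 * (df - i), 2.0))
        for j in range(i):
            B[i, j] = np.random.standard_normal()
    M = C @ B
    W = M @ M.T
    Lw = np.linalg.cholesky(W)
    Lwi = _inv_lower(Lw)
    return Lwi.T @ Lwi


# ---------------------------------------------------------------- kernel


@njit(cache=True)
def gibbs_kernel(
    seed,
    n_burn,
    n_iter,
    thin,
    Y,
    miss,
    X,
    L_X,
    rec_ind,
    rec_year,
    rec_obs,
    ind_rptr,
    ind_rix,
    year_rptr,
    year_rix,
    obs_rptr,
    obs_rix,
    ai_indptr,
    ai_indices,
    ai_data,
    V0G,
    V0PE,
    V0Y,
    V0R,
    s0_obs,
    nu0,
    use_pe,
    use_y,
    use_obs,
):
    np.random.seed(seed)
    nrec, T = Y.shape
    P = X.shape[1]
    n_ind = ind_rptr.shape[0] - 1
    n_year = year_rptr.shape[0] - 1
    n_obs = obs_rptr.shape[0] - 1
    nkeep = n_iter // thin

    # state
    G = V0G.copy()
    PE = V0PE.copy()
    Yc = V0Y.copy()
    R = V0R.copy()
    obs_var = s0_obs.copy()
    a = np.zeros((n_ind, T))
    pe = np.zeros((n_ind, T))
    yr = np.zeros((n_year, T))
    ob = np.zeros((n_obs, T))
    B = np.zeros((P, T))
    fixed = np.zeros((nrec, T))
    Yw = Y.copy()  # working response with imputed missing values

    # record counts per entity
    n_rec_ind = np.zeros(n_ind, dtype=np.int64)
    for i in range(n_ind):
        n_rec_ind[i] = ind_rptr[i + 1] - ind_rptr[i]
    n_pe = 0
    for i in range(n_ind):
        if n_rec_ind[i] > 0:
            n_pe += 1
    aii = np.zeros(n_ind)
    for i in range(n_ind):
        for p in range(ai_indptr[i], ai_indptr[i + 1]):
            if ai_indices[p] == i:
                aii[i] = ai_data[p]

    out_G = np.zeros((nkeep, T, T))
    out_PE = np.zeros((nkeep, T, T))
    out_Y = np.zeros((nkeep, T, T))
    out_R = np.zeros((nkeep, T, T))
    out_obs = np.zeros((nkeep, T))
    out_B = np.zeros((nkeep, P, T))

    kept = 0
    total = n_burn + n_iter
    for it in range(total):
        Ginv = _spd_inverse(G)
        Rinv = _spd_inverse(R)
        if use_pe:
            PEinv = _spd_inverse(PE)
        else:
            PEinv = np.zeros((T, T))
        if use_y:
            Yinv = _spd_inverse(Yc)
        else:
            Yinv = np.zeros((T, T))

        # ---- impute missing trait values (conditional normal within record)
        for r in range(nrec):
            nmis = 0
            for t in range(T):
                if miss[r, t]:
                    nmis += 1
            if nmis == 0:
                continue
            mu = np.empty(T)
            for t in range(T):
                mu[t] = fixed[r, t] + a[rec_ind[r], t] + pe[rec_ind[r], t]
                if use_y:
                    mu[t] += yr[rec_year[r], t]
                if use_obs and rec_obs[r] >= 0:
                    mu[t] += ob[rec_obs[r], t]
            nobs_t = T - nmis
            if nobs_t == 0:
                # fully missing record: draw from N(mu, R)
                Lr = np.linalg.cholesky(R)
                z = np.empty(T)
                for t in range(T):
                    z[t] = np.random.standard_normal()
                d = Lr @ z
                for t in range(T):
                    Yw[r, t] = mu[t] + d[t]
                continue
            oix = np.empty(nobs_t, dtype=np.int64)
            mix = np.empty(nmis, dtype=np.int64)
            ko = 0
            km = 0
            for t in range(T):
                if miss[r, t]:
                    mix[km] = t
                    km += 1
                else:
                    oix[ko] = t
                    ko += 1
            Roo = np.empty((nobs_t, nobs_t))
            Rom = np.empty((nobs_t, nmis))
            Rmm = np.empty((nmis, nmis))
            for i2 in range(nobs_t):
                for j2 in range(nobs_t):
                    Roo[i2, j2] = R[oix[i2], oix[j2]]
                for j2 in range(nmis):
                    Rom[i2, j2] = R[oix[i2], mix[j2]]
            for i2 in range(nmis):
                for j2 in range(nmis):
                    Rmm[i2, j2] = R[mix[i2], mix[j2]]
            dev_o = np.empty(nobs_t)
            for i2 in range(nobs_t):
                dev_o[i2] = Yw[r, oix[i2]] - mu[oix[i2]]
            K = np.linalg.solve(Roo, Rom)  # (o, m)
            cmean = np.empty(nmis)
            for j2 in range(nmis):
                s = mu[mix[j2]]
                for i2 in range(nobs_t):
                    s += K[i2, j2] * dev_o[i2]
                cmean[j2] = s
            ccov = Rmm - Rom.T @ K
            # guard tiny asymmetry
            for i2 in range(nmis):
                for j2 in range(i2):
                    v = 0.5 * (ccov[i2, j2] + ccov[j2, i2])
                    ccov[i2, j2] = v
                    ccov[j2, i2] = v
                ccov[i2, i2] = max(ccov[i2, i2], 1e-12)
            Lc = np.linalg.cholesky(ccov)
            z = np.empty(nmis)
            for j2 in range(nmis):
                z[j2] = np.random.standard_normal()
            d = Lc @ z
            for j2 in range(nmis):
                Yw[r, mix[j2]] = cmean[j2] + d[j2]

        # ---- fixed effects (matrix-normal block draw)
        RHS = np.zeros((P, T))
        for r in range(nrec):
            i = rec_ind[r]
            for t in range(T):
                res = Yw[r, t] - a[i, t] - pe[i, t]
                if use_y:
                    res -= yr[rec_year[r], t]
                if use_obs and rec_obs[r] >= 0:
                    res -= ob[rec_obs[r], t]
                for p in range(P):
                    RHS[p, t] += X[r, p] * res
        L_R = np.linalg.cholesky(R)
        for t in range(T):
            B[:, t] = _backward_t(L_X, _forward(L_X, RHS[:, t]))
        Z = np.empty((P, T))
        for p in range(P):
            for t in range(T):
                Z[p, t] = np.random.standard_normal()
        U = np.empty((P, T))
        for t in range(T):
            U[:, t] = _backward_t(L_X, Z[:, t])
        B += U @ L_R.T
        for r in range(nrec):
            for t in range(T):
                s = 0.0
                for p in range(P):
                    s += X[r, p] * B[p, t]
                fixed[r, t] = s

        # ---- breeding values (single site over individuals)
        sa = np.empty(T)
        sres = np.empty(T)
        rhs = np.empty(T)
        Qb = np.empty((T, T))
        Lb = np.empty((T, T))
        tmpb = np.empty(T)
        outb = np.empty(T)
        for i in range(n_ind):
            for t in range(T):
                sa[t] = 0.0
            for p in range(ai_indptr[i], ai_indptr[i + 1]):
                j = ai_indices[p]
                if j != i:
                    w = ai_data[p]
                    for t in range(T):
                        sa[t] += w * a[j, t]
            for t1 in range(T):
                s = 0.0
                for t2 in range(T):
                    s += Ginv[t1, t2] * sa[t2]
                rhs[t1] = -s
            nri = n_rec_ind[i]
            for t1 in range(T):
                for t2 in range(T):
                    Qb[t1, t2] = aii[i] * Ginv[t1, t2] + nri * Rinv[t1, t2]
            if nri > 0:
                for t in range(T):
                    sres[t] = 0.0
                for q in range(ind_rptr[i], ind_rptr[i + 1]):
                    r = ind_rix[q]
                    for t in range(T):
                        res = Yw[r, t] - fixed[r, t] - pe[i, t]
                        if use_y:
                            res -= yr[rec_year[r], t]
                        if use_obs and rec_obs[r] >= 0:
                            res -= ob[rec_obs[r], t]
                        sres[t] += res
                for t1 in range(T):
                    s = 0.0
                    for t2 in range(T):
                        s += Rinv[t1, t2] * sres[t2]
                    rhs[t1] += s
            _chol_small(Qb, Lb)
            _draw_mvn_buf(Lb, rhs, tmpb, outb)
            for t in range(T):
                a[i, t] = outb[t]

        # ---- permanent environment
        if use_pe:
            for i in range(n_ind):
                nri = n_rec_ind[i]
                if nri == 0:
                    continue
                for t1 in range(T):
                    for t2 in range(T):
                        Qb[t1, t2] = PEinv[t1, t2] + nri * Rinv[t1, t2]
                for t in range(T):
                    sres[t] = 0.0
                for q in range(ind_rptr[i], ind_rptr[i + 1]):
                    r = ind_rix[q]
                    for t in range(T):
                        res = Yw[r, t] - fixed[r, t] - a[i, t]
                        if use_y:
                            res -= yr[rec_year[r], t]
                        if use_obs and rec_obs[r] >= 0:
                            res -= ob[rec_obs[r], t]
                        sres[t] += res
                for t1 in range(T):
                    s = 0.0
                    for t2 in range(T):
                        s += Rinv[t1, t2] * sres[t2]
                    rhs[t1] = s
                _chol_small(Qb, Lb)
                _draw_mvn_buf(Lb, rhs, tmpb, outb)
                for t in range(T):
                    pe[i, t] = outb[t]

        # ---- year effects
        if use_y:
            for k in range(n_year):
                nk = year_rptr[k + 1] - year_rptr[k]
                if nk == 0:
                    continue
                for t1 in range(T):
                    for t2 in range(T):
                        Qb[t1, t2] = Yinv[t1, t2] + nk * Rinv[t1, t2]
                for t in range(T):
                    sres[t] = 0.0
                for q in range(year_rptr[k], year_rptr[k + 1]):
                    r = year_rix[q]
                    i = rec_ind[r]
                    for t in range(T):
                        res = Yw[r, t] - fixed[r, t] - a[i, t] - pe[i, t]
                        if use_obs and rec_obs[r] >= 0:
                            res -= ob[rec_obs[r], t]
                        sres[t] += res
                for t1 in range(T):
                    s = 0.0
                    for t2 in range(T):
                        s += Rinv[t1, t2] * sres[t2]
                    rhs[t1] = s
                _chol_small(Qb, Lb)
                _draw_mvn_buf(Lb, rhs, tmpb, outb)
                for t in range(T):
                    yr[k, t] = outb[t]

        # ---- observer effects (diagonal prior)
        if use_obs:
            for o in range(n_obs):
                no = obs_rptr[o + 1] - obs_rptr[o]
                if no == 0:
                    continue
                for t1 in range(T):
                    for t2 in range(T):
                        Qb[t1, t2] = no * Rinv[t1, t2]
                    Qb[t1, t1] += 1.0 / obs_var[t1]
                for t in range(T):
                    sres[t] = 0.0
                for q in range(obs_rptr[o], obs_rptr[o + 1]):
                    r = obs_rix[q]
                    i = rec_ind[r]
                    for t in range(T):
                        res = Yw[r, t] - fixed[r, t] - a[i, t] - pe[i, t]
                        if use_y:
                            res -= yr[rec_year[r], t]
                        sres[t] += res
                for t1 in range(T):
                    s = 0.0
                    for t2 in range(T):
                        s += Rinv[t1, t2] * sres[t2]
                    rhs[t1] = s
                _chol_small(Qb, Lb)
                _draw_mvn_buf(Lb, rhs, tmpb, outb)
                for t in range(T):
                    ob[o, t] = outb[t]

        # ---- covariance components
        Sa = np.zeros((T, T))
        for i in range(n_ind):
            for p in range(ai_indptr[i], ai_indptr[i + 1]):
                j = ai_indices[p]
                w = ai_data[p]
                for t1 in range(T):
                    for t2 in range(T):
                        Sa[t1, t2] += w * a[i, t1] * a[j, t2]
        for t1 in range(T):
            for t2 in range(t1):
                v = 0.5 * (Sa[t1, t2] + Sa[t2, t1])
                Sa[t1, t2] = v
                Sa[t2, t1] = v
        G = _invwishart(nu0 * V0G + Sa, nu0 + n_ind)

        if use_pe:
            Sp = np.zeros((T, T))
            for i in range(n_ind):
                if n_rec_ind[i] > 0:
                    for t1 in range(T):
                        for t2 in range(T):
                            Sp[t1, t2] += pe[i, t1] * pe[i, t2]
            PE = _invwishart(nu0 * V0PE + Sp, nu0 + n_pe)

        if use_y:
            Sy = np.zeros((T, T))
            for k in range(n_year):
                for t1 in range(T):
                    for t2 in range(T):
                        Sy[t1, t2] += yr[k, t1] * yr[k, t2]
            Yc = _invwishart(nu0 * V0Y + Sy, nu0 + n_year)

        if use_obs:
            for t in range(T):
                ssq = 0.0
                for o in range(n_obs):
                    ssq += ob[o, t] * ob[o, t]
                df = nu0 + n_obs
                chi = np.random.gamma(0.5 * df, 2.0)
                obs_var[t] = (nu0 * s0_obs[t] + ssq) / chi

        Se = np.zeros((T, T))
        for r in range(nrec):
            i = rec_ind[r]
            e = np.empty(T)
            for t in range(T):
                res = Yw[r, t] - fixed[r, t] - a[i, t] - pe[i, t]
                if use_y:
                    res -= yr[rec_year[r], t]
                if use_obs and rec_obs[r] >= 0:
                    res -= ob[rec_obs[r], t]
                e[t] = res
            for t1 in range(T):
                for t2 in range(T):
                    Se[t1, t2] += e[t1] * e[t2]
        R = _invwishart(nu0 * V0R + Se, nu0 + nrec)

        # ---- store
        if it >= n_burn and (it - n_burn) % thin == thin - 1:
            out_G[kept] = G
            out_PE[kept] = PE
            out_Y[kept] = Yc
            out_R[kept] = R
            out_obs[kept] = obs_var
            out_B[kept] = B
            kept += 1

    return out_G, out_PE, out_Y, out_R, out_obs, out_B
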
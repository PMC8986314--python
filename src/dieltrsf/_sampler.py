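"""Numba MCMC kernel for the hierarchical multinomial selection model.

Adaptive Metropolis-within-Gibbs:

* the selection coefficients of each non-reference category are updated as
  a random-walk block (one proposal per category per sweep), with the step
  size adapted toward a target acceptance rate during burn-in;
* city random intercepts are scalar random-walk updates;
* mu_k and tau_k have conjugate Normal / Gamma full conditionals and are
  drawn exactly (Gibbs);
* the Laplace rate pi has a bounded-domain slice update (its full
  conditional is a truncated Gamma).

The categorical likelihood is maintained incrementally: for each event row
we cache exp(lambda_ik) and its row sum, so a proposal touching one
category column costs one exp and one log per affected row. Caches are
refreshed periodically to wash out floating-point drift. lambda values in
this model are bounded (log availability plus a few units of effect), so
linear-space sums cannot overflow; proposals pushing |lambda| past 60 are
rejected outright.
"""

import numpy as np
from numba import njit

BETA_TARGET_ACCEPT = 0.28
INT_TARGET_ACCEPT = 0.44
REFRESH_EVERY = 200
LAM_BOUND = 60.0


@njit(cache=True, fastmath=True)
def run_chain(X, y, la, city, C, n_iter, burn, thin, n_keep, seed, pi_lo, pi_hi):
    I, J = X.shape
    K = la.shape[1]
    Km = K - 1
    np.random.seed(seed)

    # initial state: small random jitter so chains start dispersed
    beta = np.empty((J, Km))
    for j in range(J):
        for k in range(Km):
            beta[j, k] = 0.25 * np.random.randn()
    b = np.empty((C, Km))
    for c in range(C):
        for k in range(Km):
            b[c, k] = 0.25 * np.random.randn()
    mu = np.zeros(Km)
    tau = np.ones(Km)
    pi = pi_lo + np.random.rand() * min(2.0, pi_hi - pi_lo)

    # linear predictor and its exp caches
    lam = np.empty((I, K))
    for i in range(I):
        lam[i, 0] = la[i, 0]
        for k in range(Km):
            acc = 0.0
            for j in range(J):
                acc += X[i, j] * beta[j, k]
            lam[i, k + 1] = acc + b[city[i], k] + la[i, k + 1]
    E = np.exp(lam)
    T = np.empty(I)
    LT = np.empty(I)
    for i in range(I):
        s = 0.0
        for k in range(K):
            s += E[i, k]
        T[i] = s
        LT[i] = np.log(s)

    # sufficient statistics
    Sxy = np.zeros((J, Km))
    Ncy = np.zeros((C, Km))
    for i in range(I):
        if y[i] > 0:
            k = y[i] - 1
            for j in range(J):
                Sxy[j, k] += X[i, j]
            Ncy[city[i], k] += 1.0

    # rows grouped by city
    counts = np.zeros(C + 1, dtype=np.int64)
    for i in range(I):
        counts[city[i] + 1] += 1
    for c in range(C):
        counts[c + 1] += counts[c]
    order = np.empty(I, dtype=np.int64)
    fill = counts[:-1].copy()
    for i in range(I):
        order[fill[city[i]]] = i
        fill[city[i]] += 1

    ls_beta = np.full(Km, np.log(0.1))  # log step per category block
    ls_b = np.full((C, Km), np.log(0.2))

    d_j = np.empty(J)
    Enew = np.empty(I)
    Tnew = np.empty(I)
    LTnew = np.empty(I)
    delta = np.empty(I)

    n_beta = J * Km
    P = n_beta + C * Km + Km + Km + 1
    out = np.empty((n_keep, P))
    kept = 0

    for it in range(n_iter):
        gamma = 0.0
        if it < burn:
            gamma = min(0.25, 2.0 / np.sqrt(it + 10.0))

        # --- beta block updates, one per non-reference category
        for k in range(Km):
            kk = k + 1
            step = np.exp(ls_beta[k])
            dlp = 0.0
            for j in range(J):
                d_j[j] = step * np.random.randn()
                newv = beta[j, k] + d_j[j]
                dlp += pi * (abs(beta[j, k]) - abs(newv)) + d_j[j] * Sxy[j, k]
            ok = True
            for i in range(I):
                dl = 0.0
                for j in range(J):
                    dl += X[i, j] * d_j[j]
                delta[i] = dl
                ln = lam[i, kk] + dl
                if ln > LAM_BOUND or ln < -LAM_BOUND:
                    ok = False
                    break
                e = E[i, kk] * np.exp(dl)
                t = T[i] + e - E[i, kk]
                lt = np.log(t)
                Enew[i] = e
                Tnew[i] = t
                LTnew[i] = lt
                dlp -= lt - LT[i]
            if ok:
                a = 1.0 if dlp >= 0.0 else np.exp(dlp)
            else:
                a = 0.0
            if np.random.rand() < a:
                for j in range(J):
                    beta[j, k] += d_j[j]
                for i in range(I):
                    lam[i, kk] += delta[i]
                    E[i, kk] = Enew[i]
                    T[i] = Tnew[i]
                    LT[i] = LTnew[i]
            if gamma > 0.0:
                ls_beta[k] += gamma * (a - BETA_TARGET_ACCEPT)

        # --- city random intercepts, scalar updates
        for k in range(Km):
            kk = k + 1
            for c in range(C):
                step = np.exp(ls_b[c, k])
                d = step * np.random.randn()
                newv = b[c, k] + d
                dlp = -0.5 * tau[k] * ((newv - mu[k]) ** 2 - (b[c, k] - mu[k]) ** 2)
                dlp += d * Ncy[c, k]
                expd = np.exp(d)
                ok = True
                for p in range(counts[c], counts[c + 1]):
                    i = order[p]
                    ln = lam[i, kk] + d
                    if ln > LAM_BOUND or ln < -LAM_BOUND:
                        ok = False
                        break
                    e = E[i, kk] * expd
                    t = T[i] + e - E[i, kk]
                    lt = np.log(t)
                    Enew[p] = e
                    Tnew[p] = t
                    LTnew[p] = lt
                    dlp -= lt - LT[i]
                if ok:
                    a = 1.0 if dlp >= 0.0 else np.exp(dlp)
                else:
                    a = 0.0
                if np.random.rand() < a:
                    b[c, k] = newv
                    for p in range(counts[c], counts[c + 1]):
                        i = order[p]
                        lam[i, kk] += d
                        E[i, kk] = Enew[p]
                        T[i] = Tnew[p]
                        LT[i] = LTnew[p]
                if gamma > 0.0:
                    ls_b[c, k] += gamma * (a - INT_TARGET_ACCEPT)

        # --- mu_k, tau_k: conjugate Gibbs (Normal(0, var 10) and Gamma(1,1) priors)
        for k in range(Km):
            sb = 0.0
            for c in range(C):
                sb += b[c, k]
            prec = 0.1 + C * tau[k]
            mu[k] = (tau[k] * sb) / prec + np.random.randn() / np.sqrt(prec)
            ss = 0.0
            for c in range(C):
                ss += (b[c, k] - mu[k]) ** 2
            tau[k] = np.random.gamma(1.0 + 0.5 * C, 1.0 / (1.0 + 0.5 * ss))

        # --- pi: slice sampler on the bounded support [pi_lo, pi_hi]
        sab = 0.0
        for j in range(J):
            for k in range(Km):
                sab += abs(beta[j, k])
        logf = n_beta * np.log(pi) - pi * sab
        logy = logf - np.random.exponential(1.0)
        lo = pi_lo
        hi = pi_hi
        for _ in range(200):
            cand = lo + np.random.rand() * (hi - lo)
            if n_beta * np.log(cand) - cand * sab >= logy:
                pi = cand
                break
            if cand < pi:
                lo = cand
            else:
                hi = cand

        # --- periodic cache refresh against floating-point drift
        if (it + 1) % REFRESH_EVERY == 0:
            for i in range(I):
                s = 0.0
                for k in range(K):
                    E[i, k] = np.exp(lam[i, k])
                    s += E[i, k]
                T[i] = s
                LT[i] = np.log(s)

        # --- store
        if it >= burn and (it - burn) % thin == 0 and kept < n_keep:
            p = 0
            for j in range(J):
                for k in range(Km):
                    out[kept, p] = beta[j, k]
                    p += 1
            for c in range(C):
                for k in range(Km):
                    out[kept, p] = b[c, k]
                    p += 1
            for k in range(Km):
                out[kept, p] = mu[k]
                p += 1
            for k in range(Km):
                out[kept, p] = tau[k]
                p += 1
            out[kept, p] = pi
            kept += 1

    return out
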
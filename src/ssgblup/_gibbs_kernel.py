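"""Numba kernel for the multi-trait animal-model Gibbs sampler.

Single-site (animal-blocked) systematic-scan Gibbs on the model
y = Xb + Zu + e with u ~ N(0, G0 (x) A), e rows ~ N(0, R0), flat priors
on b and inverse-Wishart priors on G0 and R0. Missing trait records are
handled by data augmentation: the missing residual components are
resampled each cycle from their conditional normal given the observed
components, which keeps the G0/R0 conditionals exact inverse-Wisharts.

Everything runs on a contiguous pedigree ordering; A^-1 is passed as
CSR arrays. Trait count t is small (<= 5), so the per-animal t x t
solves use hand-rolled Cholesky loops; the per-iteration t x t algebra
uses np.linalg.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1


@njit(cache=True)
def _chol_small(A, L):
    """Cholesky of a small SPD matrix into L (lower). Returns False on failure."""
    t = A.shape[0]
    for i in range(t):
        for j in range(t):
            L[i, j] = 0.0
    for i in range(t):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=True)
def _sample_mvn_prec(L, rhs, z, out):
    """Draw N(P^-1 rhs, P^-1) given L = chol(P); z is a scratch buffer."""
    t = L.shape[0]
    # forward: L y = rhs  (store y in z)
    for i in range(t):
        s = rhs[i]
        for k in range(i):
            s -= L[i, k] * z[k]
        z[i] = s / L[i, i]
    # back: L^T m = y (store mean in out)
    for i in range(t - 1, -1, -1):
        s = z[i]
        for k in range(i + 1, t):
            s -= L[k, i] * out[k]
        out[i] = s / L[i, i]
    # noise: solve L^T w = eps, add to out
    for i in range(t):
        z[i] = np.random.standard_normal()
    for i in range(t - 1, -1, -1):
        s = z[i]
        for k in range(i + 1, t):
            s -= L[k, i] * z[k]
        z[i] = s / L[i, i]
        out[i] += z[i]


@njit(cache=True)
def _inv_wishart(df, S):
    """Draw from IW(df, S) by Bartlett decomposition."""
    t = S.shape[0]
    Linv = np.linalg.cholesky(np.linalg.inv(S))
    A = np.zeros((t, t))
    for i in range(t):
        A[i, i] = np.sqrt(np.random.chisquare(df - i))
        for j in range(i):
            A[i, j] = np.random.standard_normal()
    CW = Linv @ A
    W = CW @ CW.T
    return np.linalg.inv(W)


@njit(cache=True)
def run_chain(
    Y, obs, pattern_id, patterns, rec_animal, animal_rec,
    coef_trait, coef_ptr, coef_rec, coef_val, coef_xtx,
    ainv_indptr, ainv_indices, ainv_data,
    nu_g, Sg, nu_r, Sr,
    n_iter, burn_in, thin, seed,
):
    """Run the Gibbs chain; returns (G0 samples, R0 samples, U mean,
    b mean, status, status_iteration)."""
    np.random.seed(seed)
    n_rec, t = Y.shape
    n_ped = ainv_indptr.shape[0] - 1
    n_pat = patterns.shape[0]
    nc = coef_trait.shape[0]
    n_keep = (n_iter - burn_in) // thin

    # pattern index tables
    n_obs = np.zeros(n_pat, dtype=np.int64)
    n_mis = np.zeros(n_pat, dtype=np.int64)
    obs_idx = np.zeros((n_pat, t), dtype=np.int64)
    mis_idx = np.zeros((n_pat, t), dtype=np.int64)
    for p in range(n_pat):
        for k in range(t):
            if patterns[p, k] == 1:
                obs_idx[p, n_obs[p]] = k
                n_obs[p] += 1
            else:
                mis_idx[p, n_mis[p]] = k
                n_mis[p] += 1

    # state
    b = np.zeros(nc)
    U = np.zeros((n_ped, t))
    E = np.zeros((n_rec, t))
    for r in range(n_rec):
        for k in range(t):
            E[r, k] = Y[r, k] if obs[r, k] == 1 else 0.0
    G0 = Sg.copy()
    R0 = Sr.copy()

    G0_out = np.zeros((n_keep, t, t))
    R0_out = np.zeros((n_keep, t, t))
    U_sum = np.zeros((n_ped, t))
    b_sum = np.zeros(nc)
    E_sum = np.zeros((n_rec, t))

    # scratch
    P = np.zeros((t, t))
    L = np.zeros((t, t))
    rhs = np.zeros(t)
    zbuf = np.zeros(t)
    unew = np.zeros(t)
    svec = np.zeros(t)
    Bmats = np.zeros((n_pat, t, t))
    Lmats = np.zeros((n_pat, t, t))

    kept = 0
    for it in range(1, n_iter + 1):
        G0inv = np.linalg.inv(G0)
        R0inv = np.linalg.inv(R0)

        # -- per-pattern conditional matrices for augmentation
        for p in range(n_pat):
            nm = n_mis[p]
            if nm == 0:
                continue
            no = n_obs[p]
            Rmm = np.zeros((nm, nm))
            for a in range(nm):
                for c in range(nm):
                    Rmm[a, c] = R0[mis_idx[p, a], mis_idx[p, c]]
            if no > 0:
                Roo = np.zeros((no, no))
                Rmo = np.zeros((nm, no))
                for a in range(no):
                    for c in range(no):
                        Roo[a, c] = R0[obs_idx[p, a], obs_idx[p, c]]
                for a in range(nm):
                    for c in range(no):
                        Rmo[a, c] = R0[mis_idx[p, a], obs_idx[p, c]]
                B = Rmo @ np.linalg.inv(Roo)
                S = Rmm - B @ Rmo.T
            else:
                B = np.zeros((nm, 1))
                S = Rmm
            S = 0.5 * (S + S.T)
            Lm = np.linalg.cholesky(S)
            for a in range(nm):
                if no > 0:
                    for c in range(no):
                        Bmats[p, a, c] = B[a, c]
                for c in range(nm):
                    Lmats[p, a, c] = Lm[a, c]

        # -- 1. augment missing residuals
        for r in range(n_rec):
            p = pattern_id[r]
            nm = n_mis[p]
            if nm == 0:
                continue
            no = n_obs[p]
            for a in range(nm):
                s = 0.0
                for c in range(no):
                    s += Bmats[p, a, c] * E[r, obs_idx[p, c]]
                E[r, mis_idx[p, a]] = s
            # add chol noise
            for a in range(nm):
                svec[a] = np.random.standard_normal()
            for a in range(nm):
                s = 0.0
                for c in range(a + 1):
                    s += Lmats[p, a, c] * svec[c]
                E[r, mis_idx[p, a]] += s

        # -- 2. fixed effects, scalar Gauss-Seidel sampling (flat prior)
        for c in range(nc):
            k = coef_trait[c]
            lam = R0inv[k, k] * coef_xtx[c]
            grad = 0.0
            for q in range(coef_ptr[c], coef_ptr[c + 1]):
                r = coef_rec[q]
                x = coef_val[q]
                s = 0.0
                for kk in range(t):
                    s += R0inv[k, kk] * E[r, kk]
                grad += x * s
            delta = grad / lam + np.random.standard_normal() / np.sqrt(lam)
            b[c] += delta
            for q in range(coef_ptr[c], coef_ptr[c + 1]):
                E[coef_rec[q], k] -= coef_val[q] * delta

        # -- 3. breeding values, one animal block at a time
        for i in range(n_ped):
            aii = 0.0
            for k in range(t):
                svec[k] = 0.0
            for q in range(ainv_indptr[i], ainv_indptr[i + 1]):
                j = ainv_indices[q]
                v = ainv_data[q]
                if j == i:
                    aii += v
                else:
                    for k in range(t):
                        svec[k] += v * U[j, k]
            for a in range(t):
                for cc in range(t):
                    P[a, cc] = aii * G0inv[a, cc]
                s = 0.0
                for cc in range(t):
                    s += G0inv[a, cc] * svec[cc]
                rhs[a] = -s
            r = animal_rec[i]
            if r >= 0:
                for a in range(t):
                    for cc in range(t):
                        P[a, cc] += R0inv[a, cc]
                    s = 0.0
                    for cc in range(t):
                        s += R0inv[a, cc] * (E[r, cc] + U[i, cc])
                    rhs[a] += s
            if not _chol_small(P, L):
                return G0_out, R0_out, U_sum, b_sum, E_sum, STATUS_NONFINITE, it
            _sample_mvn_prec(L, rhs, zbuf, unew)
            if r >= 0:
                for k in range(t):
                    E[r, k] -= unew[k] - U[i, k]
            for k in range(t):
                U[i, k] = unew[k]

        # -- 4. genetic covariance G0 | u
        Su = Sg.copy()
        for i in range(n_ped):
            for q in range(ainv_indptr[i], ainv_indptr[i + 1]):
                j = ainv_indices[q]
                v = ainv_data[q]
                for a in range(t):
                    for cc in range(t):
                        Su[a, cc] += v * U[i, a] * U[j, cc]
        Su = 0.5 * (Su + Su.T)
        G0 = _inv_wishart(nu_g + n_ped, Su)

        # -- 5. residual covariance R0 | e (augmented residuals)
        Se = Sr + E.T @ E
        Se = 0.5 * (Se + Se.T)
        R0 = _inv_wishart(nu_r + n_rec, Se)

        ok = True
        for a in range(t):
            for cc in range(t):
                if not (np.isfinite(G0[a, cc]) and np.isfinite(R0[a, cc])):
                    ok = False
        if not ok:
            return G0_out, R0_out, U_sum, b_sum, E_sum, STATUS_NONFINITE, it

        if it > burn_in and (it - burn_in) % thin == 0:
            G0_out[kept] = G0
            R0_out[kept] = R0
            U_sum += U
            b_sum += b
            E_sum += E
            kept += 1

    if kept > 0:
        U_sum /= kept
        b_sum /= kept
        E_sum /= kept
    return G0_out, R0_out, U_sum, b_sum, E_sum, STATUS_OK, n_iter
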
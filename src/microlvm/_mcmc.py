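"""Numba MCMC kernel for the negative-binomial latent variable model.

Model: y_ij ~ NB(mean m_ij, dispersion phi_j), Var = m + m^2/phi,
log m_ij = alpha_i + beta0_j + x_i' beta_j + z_i' lambda_j.

Sampler: adaptive scalar random-walk Metropolis within Gibbs, augmented with
eta-invariant "ridge" moves (translation alpha<->beta0, per-factor rescaling
z*c / lambda/c, per-factor mean shifts into intercepts, and z<->covariate
shears compensated through beta) that traverse the weakly identified
directions a scalar sampler crawls along.

For location updates the NB log-likelihood delta needs no lgamma:
  ll = const(y, phi) + phi log phi - (y+phi) log(phi+m) + y eta,
so caching L = log(phi + m) and M = exp(eta) makes one scalar proposal cost
one exp and one log per affected matrix entry. Dispersion updates pay the
lgamma terms once per taxon per sweep.

Loading constraint codes (``lmask``): 0 = structurally zero (upper triangle),
1 = free with normal prior, 2 = positive diagonal, proposed on the log scale
under a half-normal prior (with Jacobian).
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def run_chain(Y, X, d, n_warmup, n_draws, thin, seed, prior_sd, loading_sd,
              phi_inv_rate, alpha0, b00, beta0_, lam0, z0, u0, lmask):
    """Run one chain; returns post-warmup draws of every parameter block."""
    np.random.seed(seed)
    s, t = Y.shape
    k = X.shape[1]

    alpha = alpha0.copy()
    b0 = b00.copy()
    beta = beta0_.copy()
    lam = lam0.copy()
    z = z0.copy()
    u = u0.copy()  # log phi
    phi = np.exp(u)

    eta = np.empty((s, t))
    L = np.empty((s, t))   # log(phi_j + exp(eta_ij))
    for i in range(s):
        for j in range(t):
            v = alpha[i] + b0[j]
            for kk in range(k):
                v += X[i, kk] * beta[j, kk]
            for l in range(d):
                v += z[i, l] * lam[j, l]
            eta[i, j] = v
            L[i, j] = math.log(phi[j] + math.exp(v))

    pv = 1.0 / (2.0 * prior_sd * prior_sd)
    pl = 1.0 / (2.0 * loading_sd * loading_sd)

    st_alpha = np.full(s, 0.2)
    st_b0 = np.full(t, 0.2)
    st_beta = np.full((t, k), 0.2)
    st_lam = np.full((t, d), 0.2)
    st_z = np.full((s, d), 0.3)
    st_u = np.full(t, 0.3)
    st_ridge = np.full(4, 0.3)
    st_shear = np.full((max(d, 1), k), 0.3)
    ac_alpha = np.zeros(s)
    ac_b0 = np.zeros(t)
    ac_beta = np.zeros((t, k))
    ac_lam = np.zeros((t, d))
    ac_z = np.zeros((s, d))
    ac_u = np.zeros(t)
    ac_ridge = np.zeros(4)
    ac_shear = np.zeros((max(d, 1), k))

    newL_row = np.empty(t)
    newL_col = np.empty(s)

    out_alpha = np.empty((n_draws, s))
    out_b0 = np.empty((n_draws, t))
    out_beta = np.empty((n_draws, t, k))
    out_lam = np.empty((n_draws, t, d))
    out_z = np.empty((n_draws, s, d))
    out_phi = np.empty((n_draws, t))

    total = n_warmup + n_draws * thin
    batch = 25
    rec = 0
    for it in range(total):
        # --- per-site effects alpha_i (affect row i) ---
        for i in range(s):
            delta = st_alpha[i] * np.random.normal()
            prop = alpha[i] + delta
            dl = (alpha[i] * alpha[i] - prop * prop) * pv
            for j in range(t):
                nl = math.log(phi[j] + math.exp(eta[i, j] + delta))
                newL_row[j] = nl
                dl += -(Y[i, j] + phi[j]) * (nl - L[i, j]) + Y[i, j] * delta
            if math.log(np.random.random()) < dl:
                alpha[i] = prop
                for j in range(t):
                    eta[i, j] += delta
                    L[i, j] = newL_row[j]
                ac_alpha[i] += 1.0

        # --- intercepts beta0_j (affect column j) ---
        for j in range(t):
            delta = st_b0[j] * np.random.normal()
            prop = b0[j] + delta
            dl = (b0[j] * b0[j] - prop * prop) * pv
            for i in range(s):
                nl = math.log(phi[j] + math.exp(eta[i, j] + delta))
                newL_col[i] = nl
                dl += -(Y[i, j] + phi[j]) * (nl - L[i, j]) + Y[i, j] * delta
            if math.log(np.random.random()) < dl:
                b0[j] = prop
                for i in range(s):
                    eta[i, j] += delta
                    L[i, j] = newL_col[i]
                ac_b0[j] += 1.0

        # --- covariate coefficients beta_jk ---
        for j in range(t):
            for kk in range(k):
                step = st_beta[j, kk] * np.random.normal()
                prop = beta[j, kk] + step
                dl = (beta[j, kk] * beta[j, kk] - prop * prop) * pv
                for i in range(s):
                    de = step * X[i, kk]
                    nl = math.log(phi[j] + math.exp(eta[i, j] + de))
                    newL_col[i] = nl
                    dl += -(Y[i, j] + phi[j]) * (nl - L[i, j]) + Y[i, j] * de
                if math.log(np.random.random()) < dl:
                    beta[j, kk] = prop
                    for i in range(s):
                        eta[i, j] += step * X[i, kk]
                        L[i, j] = newL_col[i]
                    ac_beta[j, kk] += 1.0

        # --- loadings lambda_jl under the identifiability mask ---
        for j in range(t):
            for l in range(d):
                code = lmask[j, l]
                if code == 0:
                    continue
                cur = lam[j, l]
                if code == 2:
                    tcur = math.log(cur)
                    tprop = tcur + st_lam[j, l] * np.random.normal()
                    prop = math.exp(tprop)
                    # half-normal prior + log-scale Jacobian
                    dl = (cur * cur - prop * prop) * pl + (tprop - tcur)
                else:
                    prop = cur + st_lam[j, l] * np.random.normal()
                    dl = (cur * cur - prop * prop) * pl
                step = prop - cur
                for i in range(s):
                    de = step * z[i, l]
                    nl = math.log(phi[j] + math.exp(eta[i, j] + de))
                    newL_col[i] = nl
                    dl += -(Y[i, j] + phi[j]) * (nl - L[i, j]) + Y[i, j] * de
                if math.log(np.random.random()) < dl:
                    lam[j, l] = prop
                    for i in range(s):
                        eta[i, j] += step * z[i, l]
                        L[i, j] = newL_col[i]
                    ac_lam[j, l] += 1.0

        # --- latent scores z_il ~ N(0,1) prior ---
        for i in range(s):
            for l in range(d):
                cur = z[i, l]
                prop = cur + st_z[i, l] * np.random.normal()
                dl = 0.5 * (cur * cur - prop * prop)
                step = prop - cur
                for j in range(t):
                    de = step * lam[j, l]
                    nl = math.log(phi[j] + math.exp(eta[i, j] + de))
                    newL_row[j] = nl
                    dl += -(Y[i, j] + phi[j]) * (nl - L[i, j]) + Y[i, j] * de
                if math.log(np.random.random()) < dl:
                    z[i, l] = prop
                    for j in range(t):
                        eta[i, j] += step * lam[j, l]
                        L[i, j] = newL_row[j]
                    ac_z[i, l] += 1.0

        # --- dispersions via u_j = log phi_j; prior 1/phi ~ Exp(rate) ---
        for j in range(t):
            ucur = u[j]
            uprop = ucur + st_u[j] * np.random.normal()
            pcur = phi[j]
            pprop = math.exp(uprop)
            dl = (-phi_inv_rate * math.exp(-uprop) - uprop) - \
                 (-phi_inv_rate * math.exp(-ucur) - ucur)
            dl += s * (pprop * uprop - pcur * ucur)          # s * phi log phi
            dl -= s * (math.lgamma(pprop) - math.lgamma(pcur))
            for i in range(s):
                nl = math.log(pprop + math.exp(eta[i, j]))
                newL_col[i] = nl
                dl += math.lgamma(Y[i, j] + pprop) - math.lgamma(Y[i, j] + pcur)
                dl += -(Y[i, j] + pprop) * nl + (Y[i, j] + pcur) * L[i, j]
            if math.log(np.random.random()) < dl:
                u[j] = uprop
                phi[j] = pprop
                for i in range(s):
                    L[i, j] = newL_col[i]
                ac_u[j] += 1.0

        # --- eta-invariant ridge moves. These directions are flat in the
        # likelihood (exactly, except for structurally-zero loading rows), so
        # the conditional posterior of each offset is Gaussian from the priors
        # and can be Gibbs-sampled exactly; random-walk exploration of these
        # ridges is what leaves naive scalar samplers chain-dependent.

        # translate: alpha += delta, b0 -= delta (exact Gibbs)
        sa = 0.0
        for i in range(s):
            sa += alpha[i]
        sb = 0.0
        for j in range(t):
            sb += b0[j]
        prec = 2.0 * pv * (s + t)
        delta = (sb - sa) * 2.0 * pv / prec + np.random.normal() / math.sqrt(prec)
        for i in range(s):
            alpha[i] += delta
        for j in range(t):
            b0[j] -= delta

        # per-covariate coefficient level: beta_.k += c, alpha -= c*x_.k
        # (exact Gibbs; compositional counts identify only taxon contrasts)
        for kk in range(k):
            sax = 0.0
            sxx = 0.0
            for i in range(s):
                sax += alpha[i] * X[i, kk]
                sxx += X[i, kk] * X[i, kk]
            sbk = 0.0
            for j in range(t):
                sbk += beta[j, kk]
            prec = 2.0 * pv * (t + sxx)
            c = 2.0 * pv * (sax - sbk) / prec + np.random.normal() / math.sqrt(prec)
            for j in range(t):
                beta[j, kk] += c
            for i in range(s):
                alpha[i] -= c * X[i, kk]

        for l in range(d):
            # scale factor l: z *= c, lam /= c (random walk; nonlinear)
            eps = st_ridge[1] * np.random.normal()
            c = math.exp(eps)
            nfree = 0
            dl = 0.0
            for i in range(s):
                dl += 0.5 * (z[i, l] * z[i, l]) * (1.0 - c * c)
            for j in range(t):
                if lmask[j, l] != 0:
                    nfree += 1
                    lj = lam[j, l]
                    dl += (lj * lj - (lj / c) * (lj / c)) * pl
            dl += (s - nfree) * eps
            if math.log(np.random.random()) < dl:
                for i in range(s):
                    z[i, l] *= c
                for j in range(t):
                    lam[j, l] /= c
                ac_ridge[1] += 1.0 / d

            # mean-shift factor l into intercepts: z += delta, b0 -= delta*lam
            # (exact Gibbs)
            sz = 0.0
            for i in range(s):
                sz += z[i, l]
            slb = 0.0
            sll = 0.0
            for j in range(t):
                slb += lam[j, l] * b0[j]
                sll += lam[j, l] * lam[j, l]
            prec = s + 2.0 * pv * sll
            delta = (2.0 * pv * slb - sz) / prec + np.random.normal() / math.sqrt(prec)
            for i in range(s):
                z[i, l] += delta
            for j in range(t):
                b0[j] -= delta * lam[j, l]

            # loading translation: lam_.l += c (free rows), alpha -= c*z_.l.
            # Gibbs proposal from the Gaussian prior conditional; Metropolis
            # correction only for structurally-zero rows (which feel the alpha
            # shift) and the positive-diagonal support.
            sl = 0.0
            nfree = 0
            for j in range(t):
                if lmask[j, l] != 0:
                    sl += lam[j, l]
                    nfree += 1
            sza = 0.0
            szz = 0.0
            for i in range(s):
                sza += z[i, l] * alpha[i]
                szz += z[i, l] * z[i, l]
            prec = 2.0 * pl * nfree + 2.0 * pv * szz
            c = (2.0 * pv * sza - 2.0 * pl * sl) / prec + \
                np.random.normal() / math.sqrt(prec)
            ok = True
            for j in range(t):
                if lmask[j, l] == 2 and lam[j, l] + c <= 0.0:
                    ok = False
            if ok:
                dl = 0.0
                for j in range(t):
                    if lmask[j, l] == 0:
                        for i in range(s):
                            de = -c * z[i, l]
                            nl = math.log(phi[j] + math.exp(eta[i, j] + de))
                            dl += -(Y[i, j] + phi[j]) * (nl - L[i, j]) + Y[i, j] * de
                if math.log(np.random.random()) < dl:
                    for j in range(t):
                        if lmask[j, l] != 0:
                            lam[j, l] += c
                        else:
                            for i in range(s):
                                eta[i, j] += -c * z[i, l]
                                L[i, j] = math.log(phi[j] + math.exp(eta[i, j]))
                    for i in range(s):
                        alpha[i] -= c * z[i, l]
                    ac_ridge[3] += 1.0 / d

            # shear with each covariate: z += delta*x_k, beta_k -= delta*lam_l
            # (exact Gibbs)
            for kk in range(k):
                szx = 0.0
                sxx = 0.0
                for i in range(s):
                    szx += z[i, l] * X[i, kk]
                    sxx += X[i, kk] * X[i, kk]
                slb = 0.0
                sll = 0.0
                for j in range(t):
                    slb += lam[j, l] * beta[j, kk]
                    sll += lam[j, l] * lam[j, l]
                prec = sxx + 2.0 * pv * sll
                delta = (2.0 * pv * slb - szx) / prec + \
                    np.random.normal() / math.sqrt(prec)
                for i in range(s):
                    z[i, l] += delta * X[i, kk]
                for j in range(t):
                    beta[j, kk] -= delta * lam[j, l]

        # --- warmup adaptation toward ~0.44 acceptance ---
        if it < n_warmup and (it + 1) % batch == 0:
            st_ridge[1] *= 1.2 if ac_ridge[1] / batch > 0.44 else 0.85
            ac_ridge[1] = 0.0
            for l in range(d):
                for kk in range(k):
                    st_shear[l, kk] *= 1.2 if ac_shear[l, kk] / batch > 0.44 else 0.85
                    ac_shear[l, kk] = 0.0
            for i in range(s):
                st_alpha[i] *= 1.2 if ac_alpha[i] / batch > 0.44 else 0.85
                ac_alpha[i] = 0.0
                for l in range(d):
                    st_z[i, l] *= 1.2 if ac_z[i, l] / batch > 0.44 else 0.85
                    ac_z[i, l] = 0.0
            for j in range(t):
                st_b0[j] *= 1.2 if ac_b0[j] / batch > 0.44 else 0.85
                ac_b0[j] = 0.0
                st_u[j] *= 1.2 if ac_u[j] / batch > 0.44 else 0.85
                ac_u[j] = 0.0
                for kk in range(k):
                    st_beta[j, kk] *= 1.2 if ac_beta[j, kk] / batch > 0.44 else 0.85
                    ac_beta[j, kk] = 0.0
                for l in range(d):
                    st_lam[j, l] *= 1.2 if ac_lam[j, l] / batch > 0.44 else 0.85
                    ac_lam[j, l] = 0.0

        if it >= n_warmup and (it - n_warmup) % thin == 0:
            out_alpha[rec] = alpha
            out_b0[rec] = b0
            out_beta[rec] = beta
            out_lam[rec] = lam
            out_z[rec] = z
            out_phi[rec] = phi
            rec += 1

    return out_alpha, out_b0, out_beta, out_lam, out_z, out_phi
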
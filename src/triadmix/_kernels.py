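"""Numba kernels for characteristic-function density inversion.

The density of the observed z-scores of one tag variant is

    p(z) = (2*pi)^-d * integral phi(t) * cos(t.z) dt,

with phi(t) = exp(-t' S0 t / 2) * prod_k [pi_0' + sum_S pi_S' *
exp(-w_k * t' D Sigma_S D t / 2)], D = diag(sqrt(N_i)).  Every quadratic
form splits into per-axis terms (alpha_i * t_i**2) and cross terms
(2*gamma_ij * t_i * t_j), so each component's factor is a product of 1-D and
2-D lookup tables; the hot loop over grid nodes then involves only multiplies
and adds.  Additional savings: phi and cos(t.z) are even under t -> -t, so
only the t1 >= 0 half-space is summed (doubled); nodes where the residual
envelope is negligible are skipped; neighbors with near-equal weights may be
merged into bins with integer multiplicities.

Cross tables exp(-w*gamma*t_i*t_j) are built by geometric recurrence along
the second axis (one exp per row); rows whose exponents could leave the
float64 range fall back to a log-space fill clamped at exp(640), which can
only matter where the matching axis factors have underflowed and the true
combined component factor is itself negligible.

All kernels return per-variant densities; the caller takes logs.
"""

import numpy as np
from numba import njit

NB_OPTS = dict(cache=True, fastmath=True)

_ENV_CUTOFF = 1e-14


@njit(**NB_OPTS)
def dens_1d(t, dt, env, z, alpha, w_data, w_counts, indptr, pi_null, pi_c):
    """Univariate inversion.

    t : (G,) symmetric grid; env : (G,) residual factor exp(-s0^2 t^2/2);
    z : (nvar,); alpha : (nvar,) = sigma^2 * N_j; w_data/w_counts/indptr :
    CSR neighborhood weight bins and multiplicities.
    """
    nvar = z.shape[0]
    G = t.shape[0]
    mid = G // 2
    out = np.empty(nvar)
    norm = dt / (2.0 * np.pi)
    for j in range(nvar):
        lo, hi = indptr[j], indptr[j + 1]
        acc = 0.0
        aj = alpha[j]
        zj = z[j]
        for i in range(mid, G):
            ti = t[i]
            e = env[i]
            if e < _ENV_CUTOFF:
                continue
            f = 1.0
            e_base = -0.5 * aj * ti * ti
            for p in range(lo, hi):
                fac = pi_null + pi_c * np.exp(w_data[p] * e_base)
                for _ in range(w_counts[p]):
                    f *= fac
            wsym = 1.0 if i == mid else 2.0
            acc += wsym * e * f * np.cos(ti * zj)
        out[j] = acc * norm
    return out


@njit(**NB_OPTS)
def dens_2d(t1, t2, dt1, dt2, env, z, alpha, gamma, w_data, w_counts, indptr, pis):
    """Bivariate inversion.

    env : (G1,G2) residual factor; z : (nvar,2); alpha : (nvar,2);
    gamma : (nvar,) cross coefficient rho*sigma_a*sigma_b*sqrt(Na*Nb);
    pis : (4,) proportions [null, a-only, b-only, both].
    """
    nvar = z.shape[0]
    G1, G2 = t1.shape[0], t2.shape[0]
    mid = G1 // 2
    out = np.empty(nvar)
    norm = dt1 * dt2 / (2.0 * np.pi) ** 2
    p0, pa, pb, pab = pis[0], pis[1], pis[2], pis[3]
    mmax = 0
    for j in range(nvar):
        if indptr[j + 1] - indptr[j] > mmax:
            mmax = indptr[j + 1] - indptr[j]
    A1 = np.empty((mmax, G1))
    A2 = np.empty((mmax, G2))
    C = np.empty((mmax, G1, G2))
    c1 = np.empty(G1); s1 = np.empty(G1)
    c2 = np.empty(G2); s2 = np.empty(G2)
    for j in range(nvar):
        lo, hi = indptr[j], indptr[j + 1]
        M = hi - lo
        a1, a2, g = alpha[j, 0], alpha[j, 1], gamma[j]
        for m in range(M):
            w = w_data[lo + m]
            for i in range(mid, G1):  # A1 even in t1: only t1 >= 0 used
                A1[m, i] = np.exp(-0.5 * w * a1 * t1[i] * t1[i])
            for i in range(G2):
                A2[m, i] = np.exp(-0.5 * w * a2 * t2[i] * t2[i])
            for i in range(mid, G1):
                lv = -w * g * t1[i] * t2[0]
                lr = -w * g * t1[i] * dt2
                if abs(lv) + G2 * abs(lr) < 640.0:
                    v = np.exp(lv)
                    ratio = np.exp(lr)
                    for k in range(G2):
                        C[m, i, k] = v
                        v *= ratio
                else:  # extreme exponents: clamp in log space, no transient inf
                    for k in range(G2):
                        C[m, i, k] = np.exp(min(lv, 640.0))
                        lv += lr
        for i in range(G1):
            c1[i] = np.cos(t1[i] * z[j, 0]); s1[i] = np.sin(t1[i] * z[j, 0])
        for k in range(G2):
            c2[k] = np.cos(t2[k] * z[j, 1]); s2[k] = np.sin(t2[k] * z[j, 1])
        acc = 0.0
        for i in range(mid, G1):
            wsym = 1.0 if i == mid else 2.0
            for k in range(G2):
                e = env[i, k]
                if e < _ENV_CUTOFF:
                    continue
                f = 1.0
                for m in range(M):
                    va = A1[m, i]
                    vb = A2[m, k]
                    fac = p0 + pa * va + pb * vb + pab * va * vb * C[m, i, k]
                    for _ in range(w_counts[lo + m]):
                        f *= fac
                cosv = c1[i] * c2[k] - s1[i] * s2[k]
                acc += wsym * e * f * cosv
        out[j] = acc * norm
    return out


@njit(**NB_OPTS)
def dens_3d(t1, t2, t3, dt1, dt2, dt3, env, z, alpha, gamma, w_data, w_counts,
            indptr, pis):
    """Trivariate inversion.

    env : (G1,G2,G3) residual factor; z : (nvar,3); alpha : (nvar,3);
    gamma : (nvar,3) cross coefficients for pairs (12,13,23);
    pis : (8,) proportions [null,1,2,3,12,13,23,123].
    """
    nvar = z.shape[0]
    G1, G2, G3 = t1.shape[0], t2.shape[0], t3.shape[0]
    mid = G1 // 2
    out = np.empty(nvar)
    norm = dt1 * dt2 * dt3 / (2.0 * np.pi) ** 3
    p0, p1, p2, p3 = pis[0], pis[1], pis[2], pis[3]
    p12, p13, p23, p123 = pis[4], pis[5], pis[6], pis[7]
    mmax = 0
    for j in range(nvar):
        if indptr[j + 1] - indptr[j] > mmax:
            mmax = indptr[j + 1] - indptr[j]
    A1 = np.empty((mmax, G1)); A2 = np.empty((mmax, G2)); A3 = np.empty((mmax, G3))
    C12 = np.empty((mmax, G1, G2))
    C13 = np.empty((mmax, G1, G3))
    C23 = np.empty((mmax, G2, G3))
    c1 = np.empty(G1); s1 = np.empty(G1)
    c2 = np.empty(G2); s2 = np.empty(G2)
    c3 = np.empty(G3); s3 = np.empty(G3)
    u0 = np.empty(mmax); q13 = np.empty(mmax); q23 = np.empty(mmax)
    q123 = np.empty(mmax)
    for j in range(nvar):
        lo, hi = indptr[j], indptr[j + 1]
        M = hi - lo
        a1, a2, a3 = alpha[j, 0], alpha[j, 1], alpha[j, 2]
        g12, g13, g23 = gamma[j, 0], gamma[j, 1], gamma[j, 2]
        for m in range(M):
            w = w_data[lo + m]
            for i in range(mid, G1):
                A1[m, i] = np.exp(-0.5 * w * a1 * t1[i] * t1[i])
            for i in range(G2):
                A2[m, i] = np.exp(-0.5 * w * a2 * t2[i] * t2[i])
            for i in range(G3):
                A3[m, i] = np.exp(-0.5 * w * a3 * t3[i] * t3[i])
            for i in range(mid, G1):  # rows with t1 < 0 never read
                lv = -w * g12 * t1[i] * t2[0]
                lr = -w * g12 * t1[i] * dt2
                if abs(lv) + G2 * abs(lr) < 640.0:
                    v = np.exp(lv)
                    ratio = np.exp(lr)
                    for k in range(G2):
                        C12[m, i, k] = v
                        v *= ratio
                else:
                    for k in range(G2):
                        C12[m, i, k] = np.exp(min(lv, 640.0))
                        lv += lr
                lv = -w * g13 * t1[i] * t3[0]
                lr = -w * g13 * t1[i] * dt3
                if abs(lv) + G3 * abs(lr) < 640.0:
                    v = np.exp(lv)
                    ratio = np.exp(lr)
                    for k in range(G3):
                        C13[m, i, k] = v
                        v *= ratio
                else:
                    for k in range(G3):
                        C13[m, i, k] = np.exp(min(lv, 640.0))
                        lv += lr
            for i in range(G2):
                lv = -w * g23 * t2[i] * t3[0]
                lr = -w * g23 * t2[i] * dt3
                if abs(lv) + G3 * abs(lr) < 640.0:
                    v = np.exp(lv)
                    ratio = np.exp(lr)
                    for k in range(G3):
                        C23[m, i, k] = v
                        v *= ratio
                else:
                    for k in range(G3):
                        C23[m, i, k] = np.exp(min(lv, 640.0))
                        lv += lr
        for i in range(G1):
            c1[i] = np.cos(t1[i] * z[j, 0]); s1[i] = np.sin(t1[i] * z[j, 0])
        for k in range(G2):
            c2[k] = np.cos(t2[k] * z[j, 1]); s2[k] = np.sin(t2[k] * z[j, 1])
        for l in range(G3):
            c3[l] = np.cos(t3[l] * z[j, 2]); s3[l] = np.sin(t3[l] * z[j, 2])
        acc = 0.0
        for i in range(mid, G1):
            wsym = 1.0 if i == mid else 2.0
            for k in range(G2):
                for m in range(M):
                    va = A1[m, i]
                    vb = A2[m, k]
                    vab = va * vb * C12[m, i, k]
                    u0[m] = p0 + p1 * va + p2 * vb + p12 * vab
                    q13[m] = p13 * va
                    q23[m] = p23 * vb
                    q123[m] = p123 * vab
                cr = c1[i] * c2[k] - s1[i] * s2[k]
                ci = c1[i] * s2[k] + s1[i] * c2[k]
                for l in range(G3):
                    e = env[i, k, l]
                    if e < _ENV_CUTOFF:
                        continue
                    f = 1.0
                    for m in range(M):
                        v13 = C13[m, i, l]
                        v23 = C23[m, k, l]
                        fac = u0[m] + A3[m, l] * (
                            p3 + q13[m] * v13 + q23[m] * v23
                            + q123[m] * v13 * v23)
                        for _ in range(w_counts[lo + m]):
                            f *= fac
                    cosv = cr * c3[l] - ci * s3[l]
                    acc += wsym * e * f * cosv
        out[j] = acc * norm
    return out
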
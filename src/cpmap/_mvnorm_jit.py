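"""Compiled (numba) evaluation of trivariate rectangle probabilities and
their derivatives.

Numerically identical in formulation to :mod:`cpmap._mvnorm` (same
conditioning quadrature, same sine-transformed bivariate integral, same
Plackett derivatives) but fused into scalar loops so the estimation inner
loop does not pay numpy temporary-allocation overhead.  Used by the
frequency-model fit; the pure-numpy routines remain the reference and are
cross-checked against this path in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 0.3989422804014327
_TWO_PI = 2.0 * math.pi
_CLIP = 8.3
_TCLIP = 6.8


@njit(cache=False, inline="always")
def _ncdf(x):
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=False, inline="always")
def _npdf(x):
    return math.exp(-0.5 * x * x) * _INV_SQRT_2PI


@njit(cache=False, inline="always")
def _bvn_cdf_sc(h, k, rho, asr, sins, i2c2, wi):
    if h < -_CLIP:
        h = -_CLIP
    elif h > _CLIP:
        h = _CLIP
    if k < -_CLIP:
        k = -_CLIP
    elif k > _CLIP:
        k = _CLIP
    base = _ncdf(h) * _ncdf(k)
    if rho == 0.0:
        return base
    hk2 = h * h + k * k
    hk = 2.0 * h * k
    s = 0.0
    for g in range(wi.shape[0]):
        s += wi[g] * math.exp(-(hk2 - hk * sins[g]) * i2c2[g])
    v = base + asr / _TWO_PI * s
    if v < 0.0:
        return 0.0
    if v > 1.0:
        return 1.0
    return v


@njit(cache=False, inline="always")
def _bvn_rect_sc(l1, u1, l2, u2, rho, asr, sins, i2c2, wi):
    v = (
        _bvn_cdf_sc(u1, u2, rho, asr, sins, i2c2, wi)
        - _bvn_cdf_sc(l1, u2, rho, asr, sins, i2c2, wi)
        - _bvn_cdf_sc(u1, l2, rho, asr, sins, i2c2, wi)
        + _bvn_cdf_sc(l1, l2, rho, asr, sins, i2c2, wi)
    )
    if v < 0.0:
        return 0.0
    if v > 1.0:
        return 1.0
    return v


@njit(cache=False)
def _tri_rect_grad_kernel(
    lower,
    upper,
    jdim,
    cond_k,
    cond_l,
    r_jk,
    r_jl,
    s_k,
    s_l,
    rho_c,
    asr,
    sins,
    i2c2,
    wi,
    xo,
    wo,
    pair_j,
    pair_k,
    pair_b1,
    pair_b2,
    pair_sd,
    pair_r,
    want_grad,
):
    n = lower.shape[0]
    p = np.empty(n)
    dl = np.zeros((n, 3))
    du = np.zeros((n, 3))
    dr = np.zeros((n, 3))
    for i in range(n):
        j = jdim
        kd = cond_k[j]
        ld = cond_l[j]
        a = lower[i, j]
        b = upper[i, j]
        if a < -_TCLIP:
            a = -_TCLIP
        if b > _TCLIP:
            b = _TCLIP
        width = b - a
        acc = 0.0
        if width > 0.0:
            for g in range(xo.shape[0]):
                t = a + width * xo[g]
                rect = _bvn_rect_sc(
                    (lower[i, kd] - r_jk[j] * t) / s_k[j],
                    (upper[i, kd] - r_jk[j] * t) / s_k[j],
                    (lower[i, ld] - r_jl[j] * t) / s_l[j],
                    (upper[i, ld] - r_jl[j] * t) / s_l[j],
                    rho_c[j],
                    asr[j],
                    sins[j],
                    i2c2[j],
                    wi,
                )
                acc += wo[g] * _npdf(t) * rect
            acc *= width
        if acc < 0.0:
            acc = 0.0
        elif acc > 1.0:
            acc = 1.0
        p[i] = acc

        if want_grad:
            # limit derivatives: +-phi(limit) * conditional bivariate rect
            for jj in range(3):
                kk = cond_k[jj]
                ll = cond_l[jj]
                for end in range(2):
                    c = lower[i, jj] if end == 0 else upper[i, jj]
                    if math.isfinite(c):
                        cc = c
                        if cc < -_CLIP:
                            cc = -_CLIP
                        elif cc > _CLIP:
                            cc = _CLIP
                        q = _bvn_rect_sc(
                            (lower[i, kk] - r_jk[jj] * cc) / s_k[jj],
                            (upper[i, kk] - r_jk[jj] * cc) / s_k[jj],
                            (lower[i, ll] - r_jl[jj] * cc) / s_l[jj],
                            (upper[i, ll] - r_jl[jj] * cc) / s_l[jj],
                            rho_c[jj],
                            asr[jj],
                            sins[jj],
                            i2c2[jj],
                            wi,
                        )
                        val = _npdf(cc) * q
                        if end == 0:
                            dl[i, jj] = -val
                        else:
                            du[i, jj] = val
            # Plackett correlation derivatives
            for pidx in range(3):
                pj = pair_j[pidx]
                pk = pair_k[pidx]
                pl = 3 - pj - pk
                r = pair_r[pidx]
                det = 1.0 - r * r
                accr = 0.0
                for e1 in range(2):
                    cj = upper[i, pj] if e1 == 0 else lower[i, pj]
                    s1 = 1.0 if e1 == 0 else -1.0
                    if not math.isfinite(cj):
                        continue
                    for e2 in range(2):
                        ck = upper[i, pk] if e2 == 0 else lower[i, pk]
                        s2 = 1.0 if e2 == 0 else -1.0
                        if not math.isfinite(ck):
                            continue
                        m = pair_b1[pidx] * cj + pair_b2[pidx] * ck
                        hi = upper[i, pl]
                        lo = lower[i, pl]
                        if hi > _CLIP:
                            hi = _CLIP
                        if lo < -_CLIP:
                            lo = -_CLIP
                        interval = _ncdf((hi - m) / pair_sd[pidx]) - _ncdf(
                            (lo - m) / pair_sd[pidx]
                        )
                        z = (cj * cj - 2.0 * r * cj * ck + ck * ck) / det
                        dens = math.exp(-0.5 * z) / (_TWO_PI * math.sqrt(det))
                        accr += s1 * s2 * dens * interval
                dr[i, pidx] = accr
    return p, dl, du, dr


def _context(R: np.ndarray, n_inner: int):
    """Precomputed conditioning constants and bivariate nodes per dimension."""
    from ._mvnorm import _best_conditioning_dim, _conditional_pair, _gl_nodes

    cond_k = np.empty(3, np.int64)
    cond_l = np.empty(3, np.int64)
    r_jk = np.empty(3)
    r_jl = np.empty(3)
    s_k = np.empty(3)
    s_l = np.empty(3)
    rho_c = np.empty(3)
    asr = np.empty(3)
    sins = np.empty((3, n_inner))
    i2c2 = np.empty((3, n_inner))
    xi, wi = _gl_nodes(n_inner)
    for j in range(3):
        k, l, rjk, rjl, sk, sl, rc = _conditional_pair(R, j)
        cond_k[j], cond_l[j] = k, l
        r_jk[j], r_jl[j], s_k[j], s_l[j], rho_c[j] = rjk, rjl, sk, sl, rc
        asr[j] = np.arcsin(rc)
        theta = asr[j] * xi
        sins[j] = np.sin(theta)
        i2c2[j] = 0.5 / np.cos(theta) ** 2
    jdim = _best_conditioning_dim(R)

    pair_j = np.array([0, 0, 1], np.int64)
    pair_k = np.array([1, 2, 2], np.int64)
    pair_b1 = np.empty(3)
    pair_b2 = np.empty(3)
    pair_sd = np.empty(3)
    pair_r = np.empty(3)
    for idx in range(3):
        j, k = pair_j[idx], pair_k[idx]
        l = 3 - j - k
        r = R[j, k]
        det = 1.0 - r * r
        pair_r[idx] = r
        pair_b1[idx] = (R[l, j] - r * R[l, k]) / det
        pair_b2[idx] = (R[l, k] - r * R[l, j]) / det
        var_l = 1.0 - (R[l, j] ** 2 + R[l, k] ** 2 - 2.0 * r * R[l, j] * R[l, k]) / det
        pair_sd[idx] = math.sqrt(max(var_l, 1e-12))
    return (
        jdim, cond_k, cond_l, r_jk, r_jl, s_k, s_l, rho_c,
        asr, sins, i2c2, np.ascontiguousarray(wi),
        pair_j, pair_k, pair_b1, pair_b2, pair_sd, pair_r,
    )


def trivariate_rect_grad_fast(
    lower: np.ndarray,
    upper: np.ndarray,
    R: np.ndarray,
    n_outer: int = 24,
    n_inner: int = 12,
    want_grad: bool = True,
):
    """Compiled analogue of :func:`cpmap._mvnorm.trivariate_rect_grad`."""
    from ._mvnorm import _gl_nodes

    lower = np.ascontiguousarray(np.asarray(lower, dtype=float).reshape(-1, 3))
    upper = np.ascontiguousarray(np.asarray(upper, dtype=float).reshape(-1, 3))
    xo, wo = _gl_nodes(n_outer)
    ctx = _context(R, n_inner)
    return _tri_rect_grad_kernel(
        lower, upper, ctx[0], ctx[1], ctx[2], ctx[3], ctx[4], ctx[5], ctx[6],
        ctx[7], ctx[8], ctx[9], ctx[10], ctx[11],
        np.ascontiguousarray(xo), np.ascontiguousarray(wo),
        ctx[12], ctx[13], ctx[14], ctx[15], ctx[16], ctx[17],
        want_grad,
    )
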
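"""Deterministic multivariate-normal rectangle probabilities and the GHK
simulator.

The multivariate ordered probit needs P(a <= Z <= b) for trivariate standard
normals with correlation matrix R, plus derivatives with respect to the
limits and the correlations.  Everything here is fixed-node Gauss-Legendre
quadrature — fully deterministic and vectorized over observations:

* bivariate CDF: the sine-transformed correlation integral
  ``Phi2(h, k; r) = Phi(h) Phi(k) + (1/2pi) int_0^{asin r}
  exp(-(h^2 + k^2 - 2 h k sin t) / (2 cos^2 t)) dt``
  (the substitution removes the 1/sqrt(1-r^2) endpoint singularity of the
  raw Plackett integral);
* trivariate rectangles: condition on the dimension that minimizes the
  remaining conditional correlation and integrate phi(t) times the
  conditional bivariate rectangle over the (clipped) conditioning interval —
  the integrand is entire, so convergence in the node count is geometric;
* derivatives: limit derivatives reduce to conditional bivariate rectangles,
  correlation derivatives follow Plackett's identity (bivariate density at a
  corner times a conditional univariate interval).

A diagonal R short-circuits to the exact product of univariate interval
probabilities, so independence factorizes to machine precision.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

# Phi(-8.3) ~ 5e-17: below double resolution of the probabilities we sum.
_CLIP = 8.3
# Conditioning-variable integration range: Phi(-6.8) ~ 5e-12 bounds the
# truncation error of a trivariate rectangle.
_TCLIP = 6.8

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on [0, 1], cached."""
    if n not in _GL_CACHE:
        x, w = np.polynomial.legendre.leggauss(n)
        _GL_CACHE[n] = ((x + 1.0) / 2.0, w / 2.0)
    return _GL_CACHE[n]


def _phi(x):
    return np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


def _bvn_inner_nodes(rho: float) -> int:
    a = abs(rho)
    return 8 if a < 0.6 else (12 if a < 0.9 else (20 if a < 0.97 else 32))


def bvn_cdf(h, k, rho: float, n_nodes: int | None = None) -> np.ndarray:
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    ``h`` and ``k`` broadcast; ``rho`` is a scalar.  Infinite limits are
    handled by clipping (error below double-precision resolution).
    """
    h = np.clip(np.asarray(h, dtype=float), -_CLIP, _CLIP)
    k = np.clip(np.asarray(k, dtype=float), -_CLIP, _CLIP)
    base = ndtr(h) * ndtr(k)
    if rho == 0.0:
        return base
    rho = float(np.clip(rho, -0.999999, 0.999999))
    if n_nodes is None:
        n_nodes = _bvn_inner_nodes(rho)
    x01, w01 = _gl_nodes(n_nodes)
    upper = np.arcsin(rho)
    theta = upper * x01
    sin_t = np.sin(theta)
    inv_2cos2 = 0.5 / np.cos(theta) ** 2
    hh = h[..., None]
    kk = k[..., None]
    integrand = np.exp(-(hh * hh + kk * kk - 2.0 * hh * kk * sin_t) * inv_2cos2)
    corr = (upper / (2.0 * np.pi)) * (integrand * w01).sum(axis=-1)
    return np.clip(base + corr, 0.0, 1.0)


def bvn_rect(l1, u1, l2, u2, rho: float) -> np.ndarray:
    """P(l1 <= Z1 <= u1, l2 <= Z2 <= u2), vectorized over the limits.

    The four corner CDFs are evaluated in a single stacked call.
    """
    l1, u1, l2, u2 = np.broadcast_arrays(l1, u1, l2, u2)
    hs = np.stack([u1, l1, u1, l1])
    ks = np.stack([u2, u2, l2, l2])
    c = bvn_cdf(hs, ks, rho)
    return np.clip(c[0] - c[1] - c[2] + c[3], 0.0, 1.0)


def bvn_pdf(x, y, rho: float) -> np.ndarray:
    s2 = 1.0 - rho * rho
    z = (x * x - 2.0 * rho * x * y + y * y) / s2
    return np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(s2))


def _conditional_pair(R: np.ndarray, j: int):
    """Conditioning data for integrating out dimension ``j`` of a 3-D normal."""
    k, l = [d for d in range(3) if d != j]
    r_jk, r_jl, r_kl = R[j, k], R[j, l], R[k, l]
    s_k = np.sqrt(1.0 - r_jk * r_jk)
    s_l = np.sqrt(1.0 - r_jl * r_jl)
    rho_c = (r_kl - r_jk * r_jl) / (s_k * s_l)
    return k, l, r_jk, r_jl, s_k, s_l, float(np.clip(rho_c, -0.999999, 0.999999))


def _best_conditioning_dim(R: np.ndarray) -> int:
    rhos = [abs(_conditional_pair(R, j)[-1]) for j in range(3)]
    return int(np.argmin(rhos))


def _is_diagonal(R: np.ndarray) -> bool:
    return bool(np.all(R[~np.eye(3, dtype=bool)] == 0.0))


def _interval_prob(lower, upper):
    return ndtr(np.clip(upper, -_CLIP, _CLIP)) - ndtr(np.clip(lower, -_CLIP, _CLIP))


def trivariate_rect(
    lower: np.ndarray, upper: np.ndarray, R: np.ndarray, n_nodes: int = 32
) -> np.ndarray:
    """P(lower <= Z <= upper) for Z ~ N(0, R), R a 3x3 correlation matrix.

    ``lower``/``upper`` have shape (n, 3) and may contain +-inf.  A diagonal
    R returns the exact product of univariate interval probabilities.
    """
    lower = np.asarray(lower, dtype=float).reshape(-1, 3)
    upper = np.asarray(upper, dtype=float).reshape(-1, 3)
    if _is_diagonal(R):
        return np.prod(_interval_prob(lower, upper), axis=1)
    j = _best_conditioning_dim(R)
    k, l, r_jk, r_jl, s_k, s_l, rho_c = _conditional_pair(R, j)
    x01, w01 = _gl_nodes(n_nodes)

    a = np.clip(lower[:, j], -_TCLIP, _TCLIP)
    b = np.clip(upper[:, j], -_TCLIP, _TCLIP)
    width = (b - a)[:, None]
    t = a[:, None] + width * x01  # (n, G)
    phi_t = _phi(t)
    inner = bvn_rect(
        (lower[:, k, None] - r_jk * t) / s_k,
        (upper[:, k, None] - r_jk * t) / s_k,
        (lower[:, l, None] - r_jl * t) / s_l,
        (upper[:, l, None] - r_jl * t) / s_l,
        rho_c,
    )
    return np.clip((phi_t * inner * w01).sum(axis=1) * width[:, 0], 0.0, 1.0)


def trivariate_rect_grad(
    lower: np.ndarray, upper: np.ndarray, R: np.ndarray, n_nodes: int = 32
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rectangle probabilities plus derivatives.

    Returns ``(p, d_lower, d_upper, d_rho)`` with shapes (n,), (n,3), (n,3),
    (n,3); the correlation order is [(0,1), (0,2), (1,2)].  Derivatives at
    infinite limits are zero.
    """
    lower = np.asarray(lower, dtype=float).reshape(-1, 3)
    upper = np.asarray(upper, dtype=float).reshape(-1, 3)
    n = lower.shape[0]
    p = trivariate_rect(lower, upper, R, n_nodes=n_nodes)

    d_lower = np.zeros((n, 3))
    d_upper = np.zeros((n, 3))
    # d p / d limit_j = +-phi(limit) * conditional bivariate rectangle.
    for j in range(3):
        k, l, r_jk, r_jl, s_k, s_l, rho_c = _conditional_pair(R, j)
        for sign, arr, out in ((-1.0, lower, d_lower), (1.0, upper, d_upper)):
            c = arr[:, j]
            finite = np.isfinite(c)
            if not finite.any():
                continue
            cf = np.clip(c[finite], -_CLIP, _CLIP)
            q = bvn_rect(
                (lower[finite, k] - r_jk * cf) / s_k,
                (upper[finite, k] - r_jk * cf) / s_k,
                (lower[finite, l] - r_jl * cf) / s_l,
                (upper[finite, l] - r_jl * cf) / s_l,
                rho_c,
            )
            out[finite, j] = sign * _phi(cf) * q

    # Plackett: d p / d rho_jk = sum over the four (j,k) corners of
    # +- phi2(corner; rho_jk) * P(l_rest <= Z_rest <= u_rest | corner).
    d_rho = np.zeros((n, 3))
    for idx, (j, k) in enumerate(((0, 1), (0, 2), (1, 2))):
        l = 3 - j - k
        r = R[j, k]
        det = 1.0 - r * r
        b_j = (R[l, j] - r * R[l, k]) / det
        b_k = (R[l, k] - r * R[l, j]) / det
        var_l = 1.0 - (R[l, j] ** 2 + R[l, k] ** 2 - 2.0 * r * R[l, j] * R[l, k]) / det
        sd_l = np.sqrt(max(var_l, 1e-12))
        acc = np.zeros(n)
        for cj, sj in ((upper[:, j], 1.0), (lower[:, j], -1.0)):
            for ck, sk in ((upper[:, k], 1.0), (lower[:, k], -1.0)):
                finite = np.isfinite(cj) & np.isfinite(ck)
                if not finite.any():
                    continue
                cjf, ckf = cj[finite], ck[finite]
                m = b_j * cjf + b_k * ckf
                interval = ndtr(
                    (np.clip(upper[finite, l], -np.inf, _CLIP) - m) / sd_l
                ) - ndtr((np.clip(lower[finite, l], -_CLIP, np.inf) - m) / sd_l)
                acc[finite] += sj * sk * bvn_pdf(cjf, ckf, r) * interval
        d_rho[:, idx] = acc
    return p, d_lower, d_upper, d_rho


def ghk_rect(
    lower: np.ndarray,
    upper: np.ndarray,
    R: np.ndarray,
    n_draws: int = 500,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """GHK (Geweke-Hajivassiliou-Keane) simulator for MVN rectangles.

    Returns ``(p_hat, mc_se)``: the simulated probabilities and their
    Monte-Carlo standard errors.  The recursive importance sampler works for
    any dimension, not just J = 3.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    lower = np.asarray(lower, dtype=float).reshape(-1, R.shape[0])
    upper = np.asarray(upper, dtype=float).reshape(-1, R.shape[0])
    n, d = lower.shape
    L = np.linalg.cholesky(R)
    z = np.zeros((n_draws, n, d))
    w = np.ones((n_draws, n))
    for j in range(d):
        drift = np.einsum("k,rnk->rn", L[j, :j], z[:, :, :j]) if j else 0.0
        lo = ndtr((lower[None, :, j] - drift) / L[j, j])
        hi = ndtr((upper[None, :, j] - drift) / L[j, j])
        pj = np.clip(hi - lo, 1e-300, 1.0)
        u = rng.random((n_draws, n))
        z[:, :, j] = ndtri(np.clip(lo + u * pj, 1e-300, 1.0 - 1e-16))
        w *= pj
    p_hat = w.mean(axis=0)
    mc_se = w.std(axis=0, ddof=1) / np.sqrt(n_draws)
    return p_hat, mc_se
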
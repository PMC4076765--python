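"""Multivariate (trivariate) ordered probit for per-mode trip frequency.

Each person has a latent propensity per mode, ``t*_j = beta_j' x + eps_j``,
with ``eps = (eps_walk, eps_car, eps_transit)`` multivariate normal with
zero mean and correlation matrix R.  Observed trip counts fall into the
ordered classes {0, 1, 2, 3+} cut by three strictly increasing thresholds
per mode; the probit normalization fixes the latent error variance at one
and omits a separate intercept (the thresholds absorb it).

The likelihood of a person is the MVN probability of the box formed by the
per-mode threshold intervals shifted by ``beta_j' x``.  Two evaluation
methods are provided:

* ``exact`` — deterministic fixed-node quadrature for trivariate normal
  rectangles (see :mod:`cpmap._mvnorm`); the default, and the method used
  for estimation;
* ``ghk`` — the seeded GHK recursive importance sampler, kept as a
  cross-check and for extension beyond three modes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from ._design import covariate_matrix, design_names
from ._mvnorm import ghk_rect, trivariate_rect, trivariate_rect_grad
from .data_model import MODES, CovariateSchema, PersonRecord
from .errors import EstimationError, ParameterDomainError
from .fitting import FitResult, check_full_rank, hessian_std_errors
from .trend_surface import CoordinateScaler, TrendTerms, fit_scaler

#: Ordered count classes; the open top class pools three or more trips.
N_CLASSES = 4

_PAIRS = ((0, 1), (0, 2), (1, 2))


@dataclass
class OrderedProbitParams:
    """Parameters of the trivariate ordered probit.

    ``coefs`` maps each mode to a coefficient vector over the design
    (encoded covariates + trend terms — no intercept); ``thresholds`` maps
    each mode to three strictly increasing cut points; ``corr`` is the 3x3
    latent error correlation matrix in mode order (walk, car, transit).
    """

    coefs: dict[str, np.ndarray]
    thresholds: dict[str, np.ndarray]
    corr: np.ndarray
    schema: CovariateSchema
    scaler: CoordinateScaler

    def __post_init__(self):
        for m in MODES:
            self.coefs[m] = np.asarray(self.coefs[m], dtype=float)
            mu = np.asarray(self.thresholds[m], dtype=float)
            if mu.shape != (3,) or not np.all(np.diff(mu) > 0):
                raise ParameterDomainError(
                    f"thresholds[{m}] must be three strictly increasing values"
                )
            self.thresholds[m] = mu
        R = np.asarray(self.corr, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ParameterDomainError("corr must be a symmetric 3x3 correlation matrix")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ParameterDomainError("corr must be positive definite")
        self.corr = R

    def to_dict(self) -> dict:
        return {
            "model": "mvoprobit",
            "schema": self.schema.to_dict(),
            "coordinate_scaler": self.scaler.to_dict(),
            "coefs": {m: list(self.coefs[m]) for m in MODES},
            "thresholds": {m: list(self.thresholds[m]) for m in MODES},
            "corr": self.corr.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: Mapping) -> "OrderedProbitParams":
        return cls(
            coefs={m: np.asarray(d["coefs"][m], float) for m in MODES},
            thresholds={m: np.asarray(d["thresholds"][m], float) for m in MODES},
            corr=np.asarray(d["corr"], float),
            schema=CovariateSchema.from_dict(d["schema"]),
            scaler=CoordinateScaler.from_dict(d["coordinate_scaler"]),
        )

    @classmethod
    def load(cls, path) -> "OrderedProbitParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def marginal_class_probs(
    design: np.ndarray, trend: TrendTerms, params: OrderedProbitParams, mode: str
) -> np.ndarray:
    """Univariate class probabilities over {0, 1, 2, 3+} for one mode.

    ``P(class o) = Phi(mu_{o+1} - eta) - Phi(mu_o - eta)`` with
    ``mu_0 = -inf`` and ``mu_4 = +inf``; the vector sums to one by
    construction (telescoping).
    """
    x = np.concatenate([np.asarray(design, float), trend.as_array()])
    eta = float(params.coefs[mode] @ x)
    cuts = ndtr(params.thresholds[mode] - eta)
    edges = np.concatenate([[0.0], cuts, [1.0]])
    return np.diff(edges)


# ---------------------------------------------------------------------------
# Likelihood internals
# ---------------------------------------------------------------------------


@dataclass
class _FreqData:
    X: np.ndarray  # (n, p)
    classes: np.ndarray  # (n, 3) ints in {0..3}
    names: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def observed_class(count: int) -> int:
    """Map a trip count to its ordered class (3 pools all counts >= 3)."""
    return min(int(count), 3)


def _assemble(persons: Sequence[PersonRecord], schema, scaler) -> _FreqData:
    X = covariate_matrix(persons, schema, scaler)
    classes = np.array(
        [[observed_class(p.counts.get(m, 0)) for m in MODES] for p in persons]
    )
    return _FreqData(X, classes, design_names(schema))


def _box_limits(data: _FreqData, coefs: np.ndarray, thresholds: np.ndarray):
    """Lower/upper latent-error limits per person/mode, (n, 3) each.

    ``coefs`` is (p, 3), ``thresholds`` (3 modes, 3 cuts)."""
    eta = data.X @ coefs  # (n, 3)
    padded = np.hstack(
        [np.full((3, 1), -np.inf), thresholds, np.full((3, 1), np.inf)]
    )  # (3, 5)
    o = data.classes
    lower = padded[np.arange(3)[None, :], o] - eta
    upper = padded[np.arange(3)[None, :], o + 1] - eta
    return lower, upper


def _params_matrices(params: OrderedProbitParams):
    coefs = np.column_stack([params.coefs[m] for m in MODES])
    thr = np.vstack([params.thresholds[m] for m in MODES])
    return coefs, thr, params.corr


def trivariate_loglik(
    persons: Sequence[PersonRecord],
    params: OrderedProbitParams,
    method: str = "exact",
    n_draws: int = 500,
    seed: int = 0,
    n_nodes: int = 32,
) -> float:
    """Log likelihood of the person sample under the trivariate model.

    ``exact`` is deterministic (and exactly permutation invariant: the
    per-person terms are accumulated with compensated summation); ``ghk``
    simulates each box probability with ``n_draws`` seeded draws.
    """
    data = _assemble(persons, params.schema, params.scaler)
    coefs, thr, R = _params_matrices(params)
    lower, upper = _box_limits(data, coefs, thr)
    if method == "exact":
        p = trivariate_rect(lower, upper, R, n_nodes=n_nodes)
    elif method == "ghk":
        p, _ = ghk_rect(lower, upper, R, n_draws=n_draws, rng=np.random.default_rng(seed))
    else:
        raise ValueError(f"unknown method {method!r}")
    return math.fsum(np.log(np.clip(p, 1e-300, None)))


def ghk_loglik_se(
    persons: Sequence[PersonRecord],
    params: OrderedProbitParams,
    n_draws: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """GHK log likelihood and its Monte-Carlo standard error (delta method)."""
    data = _assemble(persons, params.schema, params.scaler)
    coefs, thr, R = _params_matrices(params)
    lower, upper = _box_limits(data, coefs, thr)
    p, se = ghk_rect(lower, upper, R, n_draws=n_draws, rng=np.random.default_rng(seed))
    ll = math.fsum(np.log(np.clip(p, 1e-300, None)))
    return ll, float(np.sqrt(np.sum((se / np.clip(p, 1e-300, None)) ** 2)))


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


def _corr_from_z(z: np.ndarray) -> np.ndarray:
    """Partial-correlation (C-vine) map from R^3 to the PD correlation
    matrices: r12 = tanh z1, r13 = tanh z2, r23 = r12 r13 + tanh(z3) s12 s13."""
    r12, r13, t3 = np.tanh(z)
    s12, s13 = np.sqrt(1 - r12**2), np.sqrt(1 - r13**2)
    r23 = r12 * r13 + t3 * s12 * s13
    return np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])


def _corr_jacobian(z: np.ndarray) -> np.ndarray:
    """J[a, b] = d rho_a / d z_b with rho ordered (r12, r13, r23)."""
    r12, r13, t3 = np.tanh(z)
    d12, d13, d3 = 1 - r12**2, 1 - r13**2, 1 - t3**2
    s12, s13 = np.sqrt(d12), np.sqrt(d13)
    J = np.zeros((3, 3))
    J[0, 0] = d12
    J[1, 1] = d13
    J[2, 0] = (r13 - t3 * r12 * s13 / s12) * d12
    J[2, 1] = (r12 - t3 * r13 * s12 / s13) * d13
    J[2, 2] = d3 * s12 * s13
    return J


def _z_from_corr(R: np.ndarray) -> np.ndarray:
    r12, r13, r23 = R[0, 1], R[0, 2], R[1, 2]
    t3 = (r23 - r12 * r13) / np.sqrt((1 - r12**2) * (1 - r13**2))
    return np.arctanh(np.clip([r12, r13, t3], -0.999, 0.999))


class _FreqPacking:
    """Flat vector layout: beta blocks (p per mode), threshold blocks
    (3 per mode: first cut, then log increments), correlation z (3)."""

    def __init__(self, p: int, names: tuple[str, ...]):
        self.p = p
        self.names = names
        self.n_params = 3 * p + 9 + 3

    def param_names(self) -> tuple[str, ...]:
        out = []
        for m in MODES:
            out.extend(f"freq:{m}:{n}" for n in self.names)
        for m in MODES:
            out.extend(f"thr:{m}:{c}" for c in (1, 2, 3))
        out.extend(["corr:walk,car", "corr:walk,transit", "corr:car,transit"])
        return tuple(out)

    def unpack(self, theta: np.ndarray, natural: bool = False):
        p = self.p
        coefs = theta[: 3 * p].reshape(3, p).T  # (p, 3)
        traw = theta[3 * p : 3 * p + 9].reshape(3, 3)
        if natural:
            thr = traw.copy()
            R = np.array(
                [
                    [1.0, theta[-3], theta[-2]],
                    [theta[-3], 1.0, theta[-1]],
                    [theta[-2], theta[-1], 1.0],
                ]
            )
        else:
            thr = np.cumsum(
                np.column_stack([traw[:, 0], np.exp(traw[:, 1]), np.exp(traw[:, 2])]),
                axis=1,
            )
            R = _corr_from_z(theta[-3:])
        return coefs, thr, R

    def pack(self, params: OrderedProbitParams, natural: bool = False) -> np.ndarray:
        coefs, thr, R = _params_matrices(params)
        rho = np.array([R[0, 1], R[0, 2], R[1, 2]])
        if natural:
            tblock = thr
            tail = rho
        else:
            tblock = np.column_stack(
                [thr[:, 0], np.log(thr[:, 1] - thr[:, 0]), np.log(thr[:, 2] - thr[:, 1])]
            )
            tail = _z_from_corr(R)
        return np.concatenate([coefs.T.ravel(), tblock.ravel(), tail])

    def to_params(self, theta, schema, scaler, natural=False) -> OrderedProbitParams:
        coefs, thr, R = self.unpack(theta, natural=natural)
        return OrderedProbitParams(
            coefs={m: coefs[:, i].copy() for i, m in enumerate(MODES)},
            thresholds={m: thr[i].copy() for i, m in enumerate(MODES)},
            corr=R,
            schema=schema,
            scaler=scaler,
        )


def _freq_value_and_grad(
    theta: np.ndarray, data: _FreqData, pk: _FreqPacking,
    natural: bool = False, n_nodes: int = 32, n_inner: int = 12,
):
    """Trivariate ordered-probit log likelihood and analytic gradient.

    Uses the compiled rectangle kernel (numerically identical to the numpy
    reference path; see :mod:`cpmap._mvnorm_jit`)."""
    from ._mvnorm_jit import trivariate_rect_grad_fast

    coefs, thr, R = pk.unpack(theta, natural=natural)
    lower, upper = _box_limits(data, coefs, thr)
    p, d_lower, d_upper, d_rho = trivariate_rect_grad_fast(
        lower, upper, R, n_outer=n_nodes, n_inner=n_inner
    )
    p = np.clip(p, 1e-300, None)
    inv_p = 1.0 / p
    ll = np.log(p).sum()

    # beta: a and b both shift by -eta_j.
    g_eta = -(d_lower + d_upper) * inv_p[:, None]  # (n, 3)
    g_coefs = (data.X.T @ g_eta).T.ravel()  # mode-major (3*p,)

    # thresholds mu_{j,c}: upper limit of class c, lower limit of class c+1.
    g_thr = np.zeros((3, 3))
    for j in range(3):
        o = data.classes[:, j]
        for c in range(3):
            g_thr[j, c] = (
                d_upper[o == c, j] * inv_p[o == c]
            ).sum() + (d_lower[o == c + 1, j] * inv_p[o == c + 1]).sum()

    g_rho = d_rho.T @ inv_p  # (3,) for (r12, r13, r23)

    if natural:
        grad = np.concatenate([g_coefs, g_thr.ravel(), g_rho])
    else:
        # chain rule through the cumulative-threshold and vine transforms
        traw = theta[3 * pk.p : 3 * pk.p + 9].reshape(3, 3)
        g_traw = np.zeros((3, 3))
        g_traw[:, 0] = g_thr.sum(axis=1)
        g_traw[:, 1] = (g_thr[:, 1] + g_thr[:, 2]) * np.exp(traw[:, 1])
        g_traw[:, 2] = g_thr[:, 2] * np.exp(traw[:, 2])
        g_z = _corr_jacobian(theta[-3:]).T @ g_rho
        grad = np.concatenate([g_coefs, g_traw.ravel(), g_z])
    return float(ll), grad


def _fit_univariate(X: np.ndarray, o: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Univariate ordered probit (starting values): returns (beta, thresholds)."""
    n, p = X.shape
    freq = np.bincount(o, minlength=4) / n
    cuts0 = ndtri(np.clip(np.cumsum(freq)[:3], 1e-6, 1 - 1e-6))
    t0 = np.concatenate(
        [np.zeros(p), [cuts0[0]], np.log(np.maximum(np.diff(cuts0), 1e-3))]
    )

    edges = np.array([-np.inf, 0, 0, 0, np.inf])

    def neg(theta):
        beta = theta[:p]
        mu = np.cumsum([theta[p], np.exp(theta[p + 1]), np.exp(theta[p + 2])])
        eta = X @ beta
        e = edges.copy()
        e[1:4] = mu
        a = e[o] - eta
        b = e[o + 1] - eta
        Fa, Fb = ndtr(a), ndtr(b)
        pr = np.clip(Fb - Fa, 1e-300, None)
        phi_a = np.where(np.isfinite(a), np.exp(-0.5 * np.minimum(a, 38) ** 2), 0.0) / np.sqrt(2 * np.pi)
        phi_b = np.where(np.isfinite(b), np.exp(-0.5 * np.minimum(b, 38) ** 2), 0.0) / np.sqrt(2 * np.pi)
        inv = 1.0 / pr
        g_eta = (phi_a - phi_b) * inv
        g_beta = X.T @ g_eta
        g_mu = np.zeros(3)
        for c in range(3):
            g_mu[c] = (phi_b[o == c] * inv[o == c]).sum() - (
                phi_a[o == c + 1] * inv[o == c + 1]
            ).sum()
        g_t = np.array(
            [
                g_mu.sum(),
                (g_mu[1] + g_mu[2]) * np.exp(theta[p + 1]),
                g_mu[2] * np.exp(theta[p + 2]),
            ]
        )
        return -np.log(pr).sum(), -np.concatenate([g_beta, g_t])

    res = minimize(neg, t0, jac=True, method="L-BFGS-B", options={"maxiter": 300})
    beta = res.x[:p]
    mu = np.cumsum([res.x[p], np.exp(res.x[p + 1]), np.exp(res.x[p + 2])])
    return beta, mu


def fit_frequency(
    persons: Sequence[PersonRecord],
    schema: CovariateSchema,
    scaler: CoordinateScaler | None = None,
    compute_se: bool = True,
    compute_null: bool = True,
    maxiter: int = 1000,
    gtol: float = 1e-7,
    n_nodes: int = 32,
) -> FitResult:
    """Maximum-likelihood fit of the trivariate ordered probit.

    Starting values are three independent univariate ordered probits with
    R = I; thresholds are optimized as (first cut, log increments) and R
    through a partial-correlation (vine) transform, so monotonicity and
    positive definiteness never bind.  The quasi-Newton search runs on the
    per-observation average log likelihood (``gtol`` applies on that
    scale).  Standard errors come from the numerically differentiated
    analytic score on the natural scale.
    """
    data_probe = np.array(
        [[observed_class(p.counts.get(m, 0)) for m in MODES] for p in persons]
    )
    for j, m in enumerate(MODES):
        seen = set(data_probe[:, j])
        missing = [c for c in range(N_CLASSES) if c not in seen]
        if missing:
            raise EstimationError(
                f"mode {m!r}: class(es) {missing} never observed; "
                "all four frequency classes must appear"
            )
    if scaler is None:
        scaler = fit_scaler([p.home_xy for p in persons])
    data = _assemble(persons, schema, scaler)
    if data.p:
        check_full_rank(data.X, data.names, "frequency model")
    pk = _FreqPacking(data.p, data.names)

    beta0, thr0 = [], []
    for j in range(3):
        b, mu = _fit_univariate(data.X, data.classes[:, j])
        beta0.append(b)
        thr0.append([mu[0], np.log(mu[1] - mu[0]), np.log(mu[2] - mu[1])])
    theta0 = np.concatenate([np.concatenate(beta0), np.ravel(thr0), np.zeros(3)])

    # Per-observation scaling keeps the quasi-Newton line search and the
    # gradient tolerance meaningful regardless of sample size.
    inv_n = 1.0 / data.n

    def neg(theta):
        f, g = _freq_value_and_grad(theta, data, pk, n_nodes=n_nodes)
        return -f * inv_n, -g * inv_n

    res = minimize(neg, theta0, jac=True, method="BFGS",
                   options={"maxiter": maxiter, "gtol": gtol})
    loglik = -res.fun * data.n
    params = pk.to_params(res.x, schema, scaler)

    # Thresholds-only benchmark (beta = 0), same correlation structure.
    data0 = _FreqData(np.zeros((data.n, 0)), data.classes, ())
    pk0 = _FreqPacking(0, ())
    if compute_null:
        def neg0(t):
            f, g = _freq_value_and_grad(t, data0, pk0, n_nodes=n_nodes)
            return -f * inv_n, -g * inv_n

        res0 = minimize(neg0, np.concatenate([np.ravel(thr0), np.zeros(3)]),
                        jac=True, method="BFGS", options={"maxiter": 500, "gtol": gtol})
        loglik_null = -res0.fun * data.n
    else:
        loglik_null = np.nan

    theta_nat = pk.pack(params, natural=True)
    if compute_se:
        se = hessian_std_errors(
            lambda t: _freq_value_and_grad(t, data, pk, natural=True, n_nodes=n_nodes)[1],
            theta_nat,
        )
    else:
        se = np.full(theta_nat.shape, np.nan)

    k = len(theta_nat)
    return FitResult(
        params=params,
        loglik=loglik,
        loglik_null=loglik_null,
        mcfadden_adj_rho2=1.0 - (loglik - k) / loglik_null,
        n_obs=data.n,
        converged=bool(res.success),
        coef_vector=theta_nat,
        std_errors=se,
        param_names=pk.param_names(),
        n_iter=int(res.nit),
    )


def params_to_vector(params: OrderedProbitParams) -> np.ndarray:
    """Natural-scale flat vector aligned with ``FitResult.coef_vector``."""
    p = len(params.coefs[MODES[0]])
    pk = _FreqPacking(p, ("",) * p)
    return pk.pack(params, natural=True)
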
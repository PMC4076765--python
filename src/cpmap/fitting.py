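"""Shared estimation plumbing: fit results, rank checks, Hessian-based
standard errors."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import qr
from statsmodels.tools.numdiff import approx_fprime

from .errors import EstimationError


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``coef_vector``/``std_errors``/``param_names`` are aligned: entry ``i``
    of each refers to the same (natural-scale) parameter.  ``params`` is the
    fitted parameter object of the specific model.
    """

    params: object
    loglik: float
    loglik_null: float
    mcfadden_adj_rho2: float
    n_obs: int
    converged: bool
    coef_vector: np.ndarray
    std_errors: np.ndarray
    param_names: tuple[str, ...]
    n_iter: int = 0

    def summary(self) -> str:
        lines = [
            f"n_obs = {self.n_obs}   loglik = {self.loglik:.2f}   "
            f"loglik_null = {self.loglik_null:.2f}   "
            f"adj-rho2 = {self.mcfadden_adj_rho2:.4f}   converged = {self.converged}",
            f"{'parameter':<34} {'estimate':>10} {'std err':>10}",
        ]
        for name, est, se in zip(self.param_names, self.coef_vector, self.std_errors):
            lines.append(f"{name:<34} {est:>10.4f} {se:>10.4f}")
        return "\n".join(lines)


def check_full_rank(X: np.ndarray, names: Sequence[str], context: str) -> None:
    """Raise :class:`EstimationError` naming (near-)collinear columns."""
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 100
    bad = diag < tol
    if bad.any():
        cols = [names[piv[i]] for i in np.nonzero(bad)[0]]
        raise EstimationError(
            f"{context}: design matrix is rank deficient; "
            f"collinear column(s): {', '.join(cols)}"
        )


def hessian_std_errors(
    score: Callable[[np.ndarray], np.ndarray], theta: np.ndarray
) -> np.ndarray:
    """Standard errors from the numerically differentiated analytic score.

    The observed information is minus the Jacobian of the score at the
    optimum (symmetrized); its inverse diagonal gives the variances.  Entries
    are NaN when the information matrix is not invertible.
    """
    H = approx_fprime(theta, score, centered=True)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.full(theta.shape, np.nan)
    var = np.diag(cov).copy()
    var[var < 0] = np.nan
    return np.sqrt(var)
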
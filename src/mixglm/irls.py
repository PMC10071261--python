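"""Weighted single-GLM fitting by iteratively reweighted least squares.

Each observation contributes to the log-likelihood with a fixed nonnegative
weight (the EM posterior in the mixture context).  Canonical links only, so
the IRLS update is exactly Fisher scoring / Newton on the weighted kernel

    sum_i w_i [ y_i * theta_i - b(theta_i) ].

Convergence is declared when the relative change in the weighted deviance
falls below ``tol`` (default 1e-10); a step is halved whenever it would
increase the weighted deviance; the iteration cap (default 100) triggers a
ConvergenceWarning, returning the last iterate.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import ConvergenceWarning, SeparationWarning, SingularDesignError
from .families import Family, Gaussian

__all__ = ["fit_weighted_glm"]

#: |eta| beyond which a binomial fit is considered separating.
_SEPARATION_ETA = 30.0
_MAX_HALVINGS = 10


def _design(X: np.ndarray, n: int, intercept_only: bool) -> np.ndarray:
    if intercept_only or X is None or X.shape[1] == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), X])


def _weighted_lstsq(Xd, z, sw):
    """Solve min ||diag(sw)(z - Xd b)||^2, guarding against rank deficiency."""
    A = Xd * sw[:, None]
    beta, _, rank, _ = np.linalg.lstsq(A, z * sw, rcond=None)
    if rank < Xd.shape[1]:
        raise SingularDesignError(
            f"weighted design has rank {rank} < {Xd.shape[1]} columns"
        )
    return beta


def fit_weighted_glm(
    y,
    X,
    w,
    family: Family,
    offset=None,
    intercept_only: bool = False,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    """Maximise the weighted GLM log-likelihood over beta.

    Parameters
    ----------
    y : (n,) response on the family's support (counts for binomial).
    X : (n, d) covariates, without an intercept column (added here), or None.
    w : (n,) nonnegative observation weights.
    family : Family
    offset : optional (n,) additive term on the linear-predictor scale.
    intercept_only : fit only beta_0.

    Returns
    -------
    beta : (p,) coefficients, intercept first.
    mu : (n,) fitted means.
    converged : bool
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n = y.shape[0]
    X = None if X is None else np.asarray(X, dtype=float)
    Xd = _design(X, n, intercept_only)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")

    if isinstance(family, Gaussian) and offset is None:
        # identity link, unit variance: one weighted least-squares solve is exact
        sw = np.sqrt(w)
        beta = _weighted_lstsq(Xd, y, sw)
        return beta, Xd @ beta, True

    mu = family.initial_mu(y, w)
    eta = family.theta(mu) - off
    beta = None
    dev = _weighted_deviance(y, mu, w, family)
    converged = False

    for _ in range(max_iter):
        V = family.variance(mu)
        V = np.maximum(V, 1e-12)
        z = eta + (y - mu) / V
        sw = np.sqrt(w * V)
        beta_new = _weighted_lstsq(Xd, z, sw)

        if beta is None:
            beta = beta_new
            dev_new = _deviance_at(beta, Xd, off, y, w, family)
        else:
            step = 1.0
            direction = beta_new - beta
            dev_new = _deviance_at(beta + direction, Xd, off, y, w, family)
            halvings = 0
            while dev_new > dev * (1 + 1e-12) + 1e-12 and halvings < _MAX_HALVINGS:
                step /= 2.0
                halvings += 1
                dev_new = _deviance_at(beta + step * direction, Xd, off, y, w, family)
            beta = beta + step * direction

        eta = Xd @ beta
        with np.errstate(over="ignore"):
            mu = family.inverse_link(eta + off)
        if np.abs(dev - dev_new) <= tol * (np.abs(dev) + tol):
            dev = dev_new
            converged = True
            break
        dev = dev_new

    if not converged:
        warnings.warn(
            "weighted GLM did not converge within the iteration cap; "
            "returning the last iterate",
            ConvergenceWarning,
            stacklevel=2,
        )
    if family.name == "binomial" and np.any(np.abs(eta + off) > _SEPARATION_ETA):
        warnings.warn(
            "binomial fit approaching complete separation "
            "(|linear predictor| > 30)",
            SeparationWarning,
            stacklevel=2,
        )
    return beta, mu, converged


def _weighted_deviance(y, mu, w, family):
    # 0-weight rows contribute exactly 0 even where the unit deviance is inf
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ud = family.unit_deviance(y, mu)
    return float(np.sum(np.where(w != 0.0, w * ud, 0.0)))


def _deviance_at(beta, Xd, off, y, w, family):
    with np.errstate(over="ignore"):
        mu = family.inverse_link(Xd @ beta + off)
    return _weighted_deviance(y, mu, w, family)
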
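"""Exponential-family members used as component distributions.

Each family is written in the canonical-link GLM parameterisation

    f(y; theta, phi) = exp{ [y*theta - b(theta)] / a(phi) + c(y; phi) },

with ``theta = g(mu)`` the canonical parameter of mean ``mu``.  Three members
are shipped: Gaussian (identity link, a(phi) = sigma^2), Poisson (log link,
a(phi) = 1) and binomial (logit link).  The binomial response is stored and
computed on the COUNT scale y in {0, ..., m}; the proportion-scale dispersion
constant a(phi) = 1/m is absorbed into the count-scale kernel, which is what
the count-scale deviance formulas assume.

The module also provides the weighted log-likelihood, the weighted IRLS-ready
building blocks (variance function, unit deviance) and the dispersion MLE.
All saturated-model evaluations use the convention 0*log(0) = 0, which
``scipy.special.xlogy`` implements exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln, xlogy

from .exceptions import ConfigurationError, DataValidationError, DomainError

__all__ = [
    "Family",
    "Gaussian",
    "Poisson",
    "Binomial",
    "get_family",
    "theta_from_mu",
    "weighted_loglik",
    "dispersion_mle",
    "GAUSSIAN_VARIANCE_FLOOR",
]

#: Lower bound for the Gaussian component variance MLE; a component floored
#: here is flagged as (near-)degenerate by the EM driver.
GAUSSIAN_VARIANCE_FLOOR = 1e-10


class Family:
    """Abstract exponential-family member (canonical link only)."""

    name: str = ""
    #: True when a(phi) is a known constant (Poisson, binomial).
    dispersion_known: bool = True

    # -- canonical-link machinery -------------------------------------------
    def theta(self, mu):
        """Canonical parameter theta = g(mu); raises DomainError off-domain."""
        raise NotImplementedError

    def inverse_link(self, eta):
        """Mean mu = g^{-1}(eta)."""
        raise NotImplementedError

    def b(self, theta):
        """Cumulant function b(theta); b'(theta(mu)) = mu."""
        raise NotImplementedError

    def a_of_phi(self, phi):
        """Dispersion scale a(phi)."""
        raise NotImplementedError

    def variance(self, mu):
        """Variance function b''(theta(mu)) on the response scale."""
        raise NotImplementedError

    # -- densities and deviances --------------------------------------------
    def loglik(self, y, mu, phi):
        """Elementwise exact log density, including the c(y; phi) term."""
        raise NotImplementedError

    def unit_deviance(self, y, mu):
        """Per-observation deviance contribution 2*[ll(sat) - ll(mu)]*a(phi),
        i.e. on the scale that omits the dispersion divisor."""
        raise NotImplementedError

    # -- support ------------------------------------------------------------
    def check_mu(self, mu):
        """Raise DomainError unless every mu lies in the open mean domain."""
        raise NotImplementedError

    def validate_response(self, y):
        """Raise DataValidationError unless y lies in the family's support."""
        raise NotImplementedError

    def initial_mu(self, y, w):
        """Interior starting means for IRLS."""
        raise NotImplementedError

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"{type(self).__name__}()"


class Gaussian(Family):
    """Normal response; identity link, unknown dispersion phi = sigma^2."""

    name = "gaussian"
    dispersion_known = False

    def theta(self, mu):
        mu = np.asarray(mu, dtype=float)
        if not np.all(np.isfinite(mu)):
            raise DomainError("gaussian mean must be finite")
        return mu

    def inverse_link(self, eta):
        return np.asarray(eta, dtype=float)

    def b(self, theta):
        theta = np.asarray(theta, dtype=float)
        return theta**2 / 2.0

    def a_of_phi(self, phi):
        return float(phi)

    def variance(self, mu):
        return np.ones_like(np.asarray(mu, dtype=float))

    def loglik(self, y, mu, phi):
        y = np.asarray(y, dtype=float)
        mu = np.asarray(mu, dtype=float)
        return -0.5 * ((y - mu) ** 2 / phi + np.log(2.0 * np.pi * phi))

    def unit_deviance(self, y, mu):
        y = np.asarray(y, dtype=float)
        return (y - np.asarray(mu, dtype=float)) ** 2

    def check_mu(self, mu):
        if not np.all(np.isfinite(mu)):
            raise DomainError("gaussian mean must be finite")

    def validate_response(self, y):
        if not np.all(np.isfinite(y)):
            raise DataValidationError("gaussian response must be finite")

    def initial_mu(self, y, w):
        return np.asarray(y, dtype=float)


class Poisson(Family):
    """Poisson counts; log link, a(phi) = 1."""

    name = "poisson"
    dispersion_known = True

    def theta(self, mu):
        mu = np.asarray(mu, dtype=float)
        if np.any(mu <= 0):
            raise DomainError("poisson mean must be > 0")
        return np.log(mu)

    def inverse_link(self, eta):
        return np.exp(np.asarray(eta, dtype=float))

    def b(self, theta):
        return np.exp(np.asarray(theta, dtype=float))

    def a_of_phi(self, phi):
        return 1.0

    def variance(self, mu):
        return np.asarray(mu, dtype=float)

    def loglik(self, y, mu, phi=None):
        y = np.asarray(y, dtype=float)
        mu = np.asarray(mu, dtype=float)
        # xlogy(0, 0) = 0 covers the saturated model at y = 0 exactly
        return xlogy(y, mu) - mu - gammaln(y + 1.0)

    def unit_deviance(self, y, mu):
        y = np.asarray(y, dtype=float)
        mu = np.asarray(mu, dtype=float)
        return 2.0 * (xlogy(y, y) - xlogy(y, mu) - y + mu)

    def check_mu(self, mu):
        if np.any(np.asarray(mu) <= 0) or not np.all(np.isfinite(mu)):
            raise DomainError("poisson mean must be positive and finite")

    def validate_response(self, y):
        y = np.asarray(y)
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise DataValidationError(
                "poisson response must be a nonnegative integer count"
            )

    def initial_mu(self, y, w):
        y = np.asarray(y, dtype=float)
        ybar = float(np.sum(w * y) / np.sum(w))
        return (y + max(ybar, 0.1)) / 2.0


class Binomial(Family):
    """Binomial counts y in {0, ..., m}; logit link on the proportion y/m.

    Means live on the count scale in (0, m); the count-scale kernel is
    ``y*theta - m*ln(1 + e^theta)`` with theta = logit(mu/m), which equals the
    proportion-scale kernel divided by a(phi) = 1/m.
    """

    name = "binomial"
    dispersion_known = True

    def __init__(self, trials: int):
        trials = int(trials)
        if trials < 1:
            raise ConfigurationError(
                f"binomial trials must be a positive integer, got {trials}"
            )
        self.trials = trials

    @property
    def m(self) -> int:
        return self.trials

    def theta(self, mu):
        mu = np.asarray(mu, dtype=float)
        if np.any(mu <= 0) or np.any(mu >= self.m):
            raise DomainError(f"binomial mean must lie in (0, {self.m})")
        return np.log(mu / (self.m - mu))

    def inverse_link(self, eta):
        return self.m * expit(np.asarray(eta, dtype=float))

    def b(self, theta):
        # m * ln(1 + e^theta), computed stably
        theta = np.asarray(theta, dtype=float)
        return self.m * np.logaddexp(0.0, theta)

    def a_of_phi(self, phi=None):
        # proportion-scale constant carried explicitly; the count-scale
        # kernel used throughout already absorbs it
        return 1.0 / self.m

    def variance(self, mu):
        mu = np.asarray(mu, dtype=float)
        return mu * (1.0 - mu / self.m)

    def loglik(self, y, mu, phi=None):
        y = np.asarray(y, dtype=float)
        p = np.asarray(mu, dtype=float) / self.m
        binom = gammaln(self.m + 1.0) - gammaln(y + 1.0) - gammaln(self.m - y + 1.0)
        return binom + xlogy(y, p) + xlogy(self.m - y, 1.0 - p)

    def unit_deviance(self, y, mu):
        y = np.asarray(y, dtype=float)
        mu = np.asarray(mu, dtype=float)
        return 2.0 * (
            xlogy(y, y) - xlogy(y, mu)
            + xlogy(self.m - y, self.m - y) - xlogy(self.m - y, self.m - mu)
        )

    def check_mu(self, mu):
        mu = np.asarray(mu)
        if np.any(mu <= 0) or np.any(mu >= self.m) or not np.all(np.isfinite(mu)):
            raise DomainError(f"binomial mean must lie in (0, {self.m})")

    def validate_response(self, y):
        y = np.asarray(y)
        if np.any(y < 0) or np.any(y > self.m) or np.any(y != np.floor(y)):
            raise DataValidationError(
                f"binomial response must be an integer count in [0, {self.m}]"
            )

    def initial_mu(self, y, w):
        y = np.asarray(y, dtype=float)
        return (y + self.m / 2.0) / 2.0

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"Binomial(trials={self.m})"


def get_family(name: str, trials: int | None = None) -> Family:
    """Construct a family by name ('gaussian', 'poisson', 'binomial')."""
    name = name.lower()
    if name == "gaussian":
        return Gaussian()
    if name == "poisson":
        return Poisson()
    if name == "binomial":
        if trials is None:
            raise ConfigurationError("binomial family requires the number of trials m")
        return Binomial(trials)
    raise ConfigurationError(f"unknown family {name!r}")


def theta_from_mu(mu, family: Family):
    """Canonical parameter of a mean value (Table-style link g)."""
    return family.theta(mu)


def weighted_loglik(y, mu, phi, w, family: Family) -> float:
    """Weighted log-likelihood  sum_i w_i * ln f(y_i; mu_i, phi).

    Weights equal to zero contribute exactly zero even where the log density
    is -inf (0 * (-inf) := 0), so the function is safe at saturated boundary
    points with zero weight.  A zero-length input returns 0.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if y.size == 0:
        return 0.0
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    w = np.broadcast_to(np.asarray(w, dtype=float), y.shape)
    ll = family.loglik(y, mu, phi)
    out = np.where(w != 0.0, w * ll, 0.0)
    return float(np.sum(out))


def dispersion_mle(y, mu, w, family: Family) -> float:
    """Weighted dispersion MLE.

    Gaussian: sum w (y - mu)^2 / sum w, floored at GAUSSIAN_VARIANCE_FLOOR.
    Poisson / binomial: the dispersion is a known constant 1 (the binomial
    proportion-scale constant 1/m is carried by the family itself).
    """
    if family.dispersion_known:
        return 1.0
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    w = np.asarray(w, dtype=float)
    wsum = float(np.sum(w))
    if wsum <= 0:
        raise DomainError("dispersion MLE requires positive total weight")
    phi = float(np.sum(w * (y - mu) ** 2) / wsum)
    return max(phi, GAUSSIAN_VARIANCE_FLOOR)
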
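"""Finite mixtures of generalized linear models, fitted by weighted EM.

The model assumes each observation (x_i, y_i) arises from one of k latent
classes; within class j the response follows an exponential-family GLM with
canonical link, coefficients beta_j and (Gaussian only) dispersion phi_j, and
the class itself has prior probability pi_j:

    f(y_i) = sum_j pi_j f(y_i; mu_ij, phi_j),   g(mu_ij) = beta_j' x_i* + off_i.

Estimation alternates an E-step (posterior class memberships z_ij) with a
weighted M-step (pi_j = mean posterior; beta_j, phi_j from a z_.j-weighted
GLM fit) until the observed-data log-likelihood stabilises.  The results
object carries everything downstream layers need: posteriors, fitted
component means, soft sizes and soft response means, MAP labels, information
criteria, and the deviance decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data import RegressionData
from .exceptions import (
    ConfigurationError,
    DataValidationError,
    DegenerateComponentError,
    NumericalUnderflowError,
)
from .families import Family, dispersion_mle, get_family
from .irls import fit_weighted_glm

__all__ = ["MixtureGLM", "MixtureGLMParams", "MixtureGLMResults", "map_classify"]


@dataclass
class MixtureGLMParams:
    """Parameter set psi = (pi_j, beta_j, phi_j) of a k-component mixture."""

    pi: np.ndarray        # (k,) mixing weights, positive, summing to one
    beta: np.ndarray      # (k, d+1) coefficients, intercept first
    phi: np.ndarray       # (k,) dispersions (all ones when known)
    family: Family

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float).ravel()
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.phi = np.asarray(self.phi, dtype=float).ravel()
        if np.any(self.pi <= 0) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ConfigurationError("mixing weights must be positive and sum to 1")
        if np.any(self.phi <= 0):
            raise ConfigurationError("dispersions must be positive")

    @property
    def k(self) -> int:
        return self.pi.shape[0]


def map_classify(posteriors: np.ndarray) -> np.ndarray:
    """MAP labels (1-based) from a posterior matrix; ties go to the lowest
    component index (np.argmax's first-maximum rule)."""
    z = np.asarray(posteriors, dtype=float)
    return np.argmax(z, axis=1) + 1


class MixtureGLM:
    """Mixture-of-GLMs model bound to a data set.

    Parameters
    ----------
    endog : (n,) response vector (counts for Poisson/binomial).
    exog : (n, d) covariates WITHOUT an intercept column (added internally),
        or None for an intercept-only mixture.
    k : number of components.
    family : a Family instance, or a name ('gaussian', 'poisson',
        'binomial'); binomial requires ``trials``.
    offset : optional (n,) additive linear-predictor term (Poisson only).
    """

    def __init__(self, endog, exog=None, k: int = 1, family=None,
                 offset=None, trials: int | None = None):
        if family is None:
            family = "gaussian"
        if isinstance(family, str):
            family = get_family(family, trials=trials)
        self.family = family
        y = np.asarray(endog, dtype=float).ravel()
        X = np.empty((y.shape[0], 0)) if exog is None else np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.data = RegressionData(y=y, X=X, offset=offset)
        self.data.validate_for(family)
        if k < 1:
            raise ConfigurationError("k must be >= 1")
        self.k = int(k)
        self.endog = self.data.y
        self.exog = self.data.X
        self.offset = self.data.offset
        self.n = self.data.n
        self.d = self.data.d

    # ------------------------------------------------------------------
    @classmethod
    def from_data(cls, data: RegressionData, k: int, family, trials=None):
        model = cls(data.y, data.X, k=k, family=family,
                    offset=data.offset, trials=trials)
        model.data.true_labels = data.true_labels
        return model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str, covariates,
                       k: int = 1, family="gaussian", offset_col=None,
                       trials=None):
        cols = list(covariates)
        missing = [c for c in [response, *cols] if c not in df.columns]
        if missing:
            raise DataValidationError(f"missing columns: {missing}")
        offset = None
        if offset_col is not None:
            if offset_col not in df.columns:
                raise DataValidationError(f"missing offset column {offset_col!r}")
            offset = df[offset_col].to_numpy(dtype=float)
        return cls(df[response].to_numpy(dtype=float),
                   df[cols].to_numpy(dtype=float) if cols else None,
                   k=k, family=family, offset=offset, trials=trials)

    # ------------------------------------------------------------------
    def component_means(self, params: MixtureGLMParams) -> np.ndarray:
        """Fitted means mu_ij, shape (n, k)."""
        Xd = np.column_stack([np.ones(self.n), self.exog])
        eta = Xd @ params.beta.T
        if self.offset is not None:
            eta = eta + self.offset[:, None]
        return self.family.inverse_link(eta)

    def _component_logdens(self, params: MixtureGLMParams) -> np.ndarray:
        mu = self.component_means(params)
        out = np.empty((self.n, params.k))
        for j in range(params.k):
            out[:, j] = self.family.loglik(self.endog, mu[:, j], params.phi[j])
        return out

    def loglike(self, params: MixtureGLMParams) -> float:
        """Observed-data log-likelihood."""
        logd = self._component_logdens(params) + np.log(params.pi)
        return float(np.sum(logsumexp(logd, axis=1)))

    def e_step(self, params: MixtureGLMParams) -> np.ndarray:
        """Posterior membership probabilities z_ij (rows sum to one).

        Computed in log space with per-row max subtraction for stability.
        """
        logd = self._component_logdens(params) + np.log(params.pi)
        rowmax = np.max(logd, axis=1)
        bad = ~np.isfinite(rowmax)
        if np.any(bad):
            raise NumericalUnderflowError(int(np.flatnonzero(bad)[0]))
        z = np.exp(logd - rowmax[:, None])
        z /= z.sum(axis=1, keepdims=True)
        return z

    def m_step(self, posteriors: np.ndarray) -> MixtureGLMParams:
        """Weighted maximisation: pi_j = nhat_j / n; (beta_j, phi_j) from a
        posterior-weighted GLM fit and dispersion MLE.

        Raises DegenerateComponentError when a component's soft size falls
        below d + 2 (not enough effective observations to fit it).
        """
        z = np.asarray(posteriors, dtype=float)
        nhat = z.sum(axis=0)
        minimum = self.d + 2
        for j, nj in enumerate(nhat):
            if nj < minimum:
                raise DegenerateComponentError(j + 1, float(nj), minimum)
        k = z.shape[1]
        pi = nhat / self.n
        beta = np.empty((k, self.d + 1))
        phi = np.empty(k)
        for j in range(k):
            bj, muj, _ = fit_weighted_glm(
                self.endog, self.exog, z[:, j], self.family, offset=self.offset
            )
            beta[j] = bj
            phi[j] = dispersion_mle(self.endog, muj, z[:, j], self.family)
        return MixtureGLMParams(pi=pi, beta=beta, phi=phi, family=self.family)

    # ------------------------------------------------------------------
    def fit(self, init=None, tol: float = 1e-8, max_iter: int = 500,
            seed: int | None = None, **init_kwargs) -> "MixtureGLMResults":
        """Run the EM algorithm and return a results object.

        ``init`` may be: a 1-based hard label vector of length n; an (n, k)
        posterior/membership matrix; the name of an initialization strategy
        (see :mod:`mixglm.initialization`, requires ``seed``); or None for
        k = 1.  ``tol`` is the relative observed-data log-likelihood change
        below which EM stops.
        """
        z = self._initial_posteriors(init, seed, init_kwargs)
        # every iteration ends on an M-step, so the returned coefficients are
        # the exact weighted-GLM optimum under the returned posteriors (the
        # Gaussian deviance identity D_j = ED_j + RD_j needs this exactness)
        params = self.m_step(z)
        prev = self.loglike(params)
        trace: list[float] = [prev]
        converged = False
        for _ in range(max_iter):
            z = self.e_step(params)
            params = self.m_step(z)
            ll = self.loglike(params)
            trace.append(ll)
            if abs(ll - prev) <= tol * (abs(prev) + tol):
                converged = True
                break
            prev = ll
        return MixtureGLMResults(self, params, z, np.asarray(trace), converged)

    def _initial_posteriors(self, init, seed, init_kwargs) -> np.ndarray:
        if init is None:
            if self.k == 1:
                return np.ones((self.n, 1))
            raise ConfigurationError("k > 1 requires an initialization")
        if isinstance(init, str):
            from .initialization import initial_partition

            labels = initial_partition(self.data, self.k, init, seed=seed,
                                       family=self.family, **init_kwargs)
            return self._labels_to_posteriors(labels)
        init = np.asarray(init)
        if init.ndim == 1:
            return self._labels_to_posteriors(init.astype(int))
        if init.shape != (self.n, self.k):
            raise ConfigurationError(
                f"posterior init must have shape {(self.n, self.k)}"
            )
        z = np.asarray(init, dtype=float)
        if np.any(z < 0) or np.any(np.abs(z.sum(axis=1) - 1.0) > 1e-8):
            raise ConfigurationError("posterior rows must be nonnegative, summing to 1")
        return z

    def _labels_to_posteriors(self, labels: np.ndarray) -> np.ndarray:
        if labels.shape[0] != self.n:
            raise ConfigurationError("label init length does not match n")
        if labels.min() < 1 or labels.max() > self.k:
            raise ConfigurationError(f"labels must lie in 1..{self.k}")
        z = np.zeros((self.n, self.k))
        z[np.arange(self.n), labels - 1] = 1.0
        return z


class MixtureGLMResults:
    """Fitted mixture of GLMs.

    Attributes
    ----------
    params : MixtureGLMParams
    posteriors : (n, k) membership probabilities at convergence.
    fitted_means : (n, k) component means mu_ij.
    soft_sizes : (k,) nhat_j = sum_i z_ij.
    soft_means : (k,) ybar_j = sum_i z_ij y_i / nhat_j.
    grand_mean : unweighted sample mean of y.
    loglik_trace : per-iteration observed-data log-likelihood (nondecreasing).
    map_labels : (n,) 1-based MAP classification.
    """

    def __init__(self, model: MixtureGLM, params: MixtureGLMParams,
                 posteriors: np.ndarray, loglik_trace: np.ndarray,
                 converged: bool):
        self.model = model
        self.params = params
        self.posteriors = posteriors
        self.loglik_trace = loglik_trace
        self.converged = converged
        self.fitted_means = model.component_means(params)
        self.soft_sizes = posteriors.sum(axis=0)
        self.soft_means = posteriors.T @ model.endog / self.soft_sizes
        self.grand_mean = float(np.mean(model.endog))
        if params.k == 1:
            # identical by definition; keep them bitwise equal so the k=1
            # between deviance is exactly zero
            self.soft_means = np.array([self.grand_mean])
        self.map_labels = map_classify(posteriors)
        self._decomposition = {}

    # -- basic accessors ----------------------------------------------------
    @property
    def k(self) -> int:
        return self.params.k

    @property
    def nobs(self) -> int:
        return self.model.n

    @property
    def llf(self) -> float:
        """Final observed-data log-likelihood."""
        return float(self.loglik_trace[-1])

    @property
    def n_params(self) -> int:
        """(k-1) mixing weights + k(d+1) coefficients + k dispersions if free."""
        k, d = self.k, self.model.d
        free_phi = 0 if self.model.family.dispersion_known else k
        return (k - 1) + k * (d + 1) + free_phi

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.n_params * np.log(self.nobs)

    @property
    def entropy(self) -> float:
        """Posterior classification entropy -sum z ln z (0 ln 0 := 0)."""
        z = self.posteriors
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(z > 0, z * np.log(z), 0.0)
        return float(-np.sum(t))

    @property
    def icl(self) -> float:
        """BIC plus twice the posterior entropy (entropy-penalised BIC)."""
        return self.bic + 2.0 * self.entropy

    # -- downstream measures -------------------------------------------------
    def deviance(self, offset_aware_null: bool = False):
        """Deviance decomposition and R-squared measures (cached)."""
        from .deviance import decompose

        key = bool(offset_aware_null)
        if key not in self._decomposition:
            self._decomposition[key] = decompose(
                self, offset_aware_null=offset_aware_null
            )
        return self._decomposition[key]

    def bse(self) -> np.ndarray:
        """Approximate (k, d+1) standard errors of the coefficients from the
        posterior-weighted Fisher information at convergence.

        These treat the soft partition as fixed, the classical weighted-GLM
        approximation; full-mixture standard errors would be larger.
        """
        model = self.model
        Xd = np.column_stack([np.ones(model.n), model.exog])
        out = np.empty_like(self.params.beta)
        for j in range(self.k):
            V = model.family.variance(self.fitted_means[:, j])
            a = model.family.a_of_phi(self.params.phi[j])
            if model.family.name == "binomial":
                a = 1.0  # count-scale kernel already absorbs 1/m
            W = self.posteriors[:, j] * V / a
            info = Xd.T @ (Xd * W[:, None])
            out[j] = np.sqrt(np.diag(np.linalg.inv(info)))
        return out

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fit and its deviance measures."""
        dec = self.deviance()
        fam = self.model.family
        lines = []
        lines.append("Mixture of GLMs")
        lines.append("=" * 64)
        lines.append(f"family: {fam.name}    k: {self.k}    n: {self.nobs}"
                     f"    d: {self.model.d}")
        lines.append(f"log-likelihood: {self.llf:.4f}    converged: {self.converged}"
                     f"    iterations: {len(self.loglik_trace)}")
        lines.append(f"BIC: {self.bic:.3f}    ICL: {self.icl:.3f}")
        lines.append("-" * 64)
        bse = self.bse()
        names = ["intercept"] + [f"x{i+1}" for i in range(self.model.d)]
        for j in range(self.k):
            lines.append(f"component {j+1}:  pi = {self.params.pi[j]:.4f}"
                         f"   nhat = {self.soft_sizes[j]:.2f}"
                         f"   ybar_j = {self.soft_means[j]:.4f}")
            for nm, b, s in zip(names, self.params.beta[j], bse[j]):
                lines.append(f"    {nm:<10} {b:>12.5f}  (se {s:.5f})")
            if not fam.dispersion_known:
                lines.append(f"    sigma^2    {self.params.phi[j]:>12.5f}")
            lines.append(f"    local R2 = {dec.r2_local[j]:.4f}"
                         f"   D_j/WD = {dec.weights[j]:.4f}")
        lines.append("-" * 64)
        lines.append(f"overall R2 = {dec.r2:.4f}    NBD = {dec.nbd:.4f}"
                     f"    NEWD = {dec.newd:.4f}    NRWD = {dec.nrwd:.4f}")
        lines.append(f"adjusted R2 (descriptive only, never for model"
                     f" selection) = {dec.r2_adj:.4f}")
        return "\n".join(lines)

    def plot_decomposition(self, ax=None):
        """Stacked bar of the normalized deviance decomposition."""
        import matplotlib.pyplot as plt

        dec = self.deviance()
        if ax is None:
            _, ax = plt.subplots()
        bottom = 0.0
        for part, lab in [(dec.nbd, "NBD"), (dec.newd, "NEWD"), (dec.nrwd, "NRWD")]:
            ax.bar([0], [part], bottom=bottom, label=lab)
            bottom += part
        ax.set_ylabel("share of total deviance")
        ax.set_xticks([])
        ax.legend()
        return ax
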
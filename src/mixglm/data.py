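"""Tabular regression data container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DataValidationError
from .families import Family

__all__ = ["RegressionData"]


@dataclass
class RegressionData:
    """Response, covariates and optional offset / true labels.

    ``y`` is the response (counts on the count scale for Poisson/binomial),
    ``X`` the n x d covariate matrix without an intercept column, ``offset``
    an optional additive term on the linear-predictor scale (log scale; only
    meaningful for Poisson rate models), and ``true_labels`` an optional
    1-based ground-truth partition used by simulations and benchmarking.
    """

    y: np.ndarray
    X: np.ndarray
    offset: np.ndarray | None = None
    true_labels: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0] and self.X.shape[1] == self.y.shape[0]:
            self.X = self.X.T
        n = self.y.shape[0]
        if n < 1:
            raise DataValidationError("need at least one observation")
        if self.X.shape[0] != n:
            raise DataValidationError(
                f"X has {self.X.shape[0]} rows but y has {n} entries"
            )
        if not np.all(np.isfinite(self.X)):
            raise DataValidationError("covariates contain non-finite values")
        if self.offset is not None:
            self.offset = np.asarray(self.offset, dtype=float).ravel()
            if self.offset.shape[0] != n:
                raise DataValidationError("offset length does not match y")
            if not np.all(np.isfinite(self.offset)):
                raise DataValidationError("offset contains non-finite values")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=int).ravel()
            if self.true_labels.shape[0] != n:
                raise DataValidationError("true_labels length does not match y")
            if np.any(self.true_labels < 1):
                raise DataValidationError("true_labels must be 1-based")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def validate_for(self, family: Family) -> None:
        """Check the response support and the offset rule for ``family``."""
        family.validate_response(self.y)
        if self.offset is not None and family.name != "poisson":
            raise ConfigurationError(
                "an offset is supported for the poisson family only"
            )
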
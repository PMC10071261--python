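"""Package exceptions and warnings.

Validation problems raise :class:`DataValidationError` / :class:`ConfigurationError`
(CLI exit code 2); numerical failures raise the remaining errors (CLI exit code 3).
"""


class MixGLMError(Exception):
    """Base class for all mixglm errors."""


class DomainError(MixGLMError, ValueError):
    """A mean or response value lies outside the family's domain."""


class DataValidationError(MixGLMError, ValueError):
    """Input data violate a family's support or shape requirements."""


class ConfigurationError(MixGLMError, ValueError):
    """Inconsistent options (e.g. an offset requested for a non-Poisson family)."""


class SingularDesignError(MixGLMError):
    """The weighted design matrix is rank deficient."""


class DegenerateComponentError(MixGLMError):
    """A mixture component starved: its soft size fell below the usable minimum."""

    def __init__(self, component: int, soft_size: float, minimum: float):
        self.component = component
        self.soft_size = soft_size
        self.minimum = minimum
        super().__init__(
            f"component {component} is degenerate: soft size "
            f"{soft_size:.6g} < required minimum {minimum:.6g}"
        )


class NumericalUnderflowError(MixGLMError):
    """All component densities underflowed to zero for some observation."""

    def __init__(self, row: int):
        self.row = row
        super().__init__(f"zero total mixture density for observation {row}")


class BoundaryError(MixGLMError):
    """A local null mean sits on the boundary of the mean domain (e.g. an
    all-zero Poisson cluster), so its deviance is undefined."""


class EmptyClusterError(MixGLMError):
    """An initialization strategy produced a partition with an empty cluster."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped at the iteration cap without converging."""


class SeparationWarning(UserWarning):
    """A binomial fit drifted towards complete separation (diverging coefficients)."""
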
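"""Exception hierarchy shared across the package.

Exit-code mapping used by the command line interface:
schema problems -> 2, convergence failures -> 3, selection failures -> 4.
"""


class TVCMError(Exception):
    """Base class for all package errors."""


class InvalidPenaltyError(TVCMError):
    """Difference-penalty order is incompatible with the basis dimension."""


class OutOfDomainError(TVCMError):
    """A modifier value lies outside the basis domain."""


class SchemaError(TVCMError):
    """Input data do not match the declared schema (columns, levels, waves)."""

    exit_code = 2


class DegenerateDesignError(TVCMError):
    """A design column is constant or a term carries no information."""


class RankDeficiencyError(TVCMError):
    """The penalized normal matrix is singular."""


class ConvergenceError(TVCMError):
    """Fisher scoring failed to converge; carries the deviance trace."""

    exit_code = 3

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class NestingError(TVCMError):
    """Likelihood-ratio test requested for non-nested model specifications."""


class DegenerateTestError(TVCMError):
    """A test with non-positive degrees of freedom (or zero-rank term)."""


class SelectionError(TVCMError):
    """Forward selection could not proceed."""

    exit_code = 4


class CovarianceRepairError(TVCMError):
    """Posterior covariance was not positive semidefinite beyond repair."""


class ConfigError(TVCMError):
    """Invalid synthetic-data or run configuration."""

    exit_code = 2
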
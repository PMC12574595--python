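"""Exception hierarchy for poppk.

All package errors derive from :class:`PoppkError` so callers can catch
one base class; subclasses distinguish bad inputs from numerical failures.
"""


class PoppkError(Exception):
    """Base class for all poppk errors."""


class InvalidParameterError(PoppkError, ValueError):
    """A pharmacokinetic parameter is missing, non-positive or inconsistent."""


class InvalidInputError(PoppkError, ValueError):
    """Caller-supplied data (times, concentrations, doses) is invalid."""


class EstimationFailureError(PoppkError, RuntimeError):
    """A numerical routine (ODE integration, optimisation) failed irrecoverably."""


class UnfittableSubjectError(PoppkError, ValueError):
    """A subject has too few usable observations to attempt a fit."""


class PopulationEstimationError(PoppkError, RuntimeError):
    """Fewer than two subjects converged; population summary impossible."""


class UndefinedMetricError(PoppkError, ValueError):
    """A diagnostic metric is undefined for the supplied data."""


class InvalidEffectError(PoppkError, ValueError):
    """A covariate effect produced a non-positive parameter value."""


class InputFormatError(PoppkError, ValueError):
    """A dataset file does not conform to the expected long format."""


class WorkflowError(PoppkError, RuntimeError):
    """End-to-end analysis could not be completed."""
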
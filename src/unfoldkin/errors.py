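"""Exception hierarchy.

All library errors derive from :class:`UnfoldkinError` so callers can catch
one base class; the subclasses distinguish bad parameters, bad data, misuse
of an API contract, and numerical failures.
"""


class UnfoldkinError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(UnfoldkinError, ValueError):
    """A kinetic or design parameter violates its domain (e.g. rate <= 0)."""


class DomainError(UnfoldkinError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DataError(UnfoldkinError, ValueError):
    """Measured/loaded data violates an invariant (e.g. baseline <= 0)."""


class UsageError(UnfoldkinError, ValueError):
    """An API contract was violated (wrong normalization state, bad window...)."""


class NumericalError(UnfoldkinError, RuntimeError):
    """A numerical backend failed to converge; carries diagnostics in args."""


class FitError(UnfoldkinError, RuntimeError):
    """Model fitting failed (no start converged, degenerate design...)."""


class MultimodalFitError(FitError):
    """Top optima are indistinguishable in objective but far apart in
    parameters; the fit refuses to report a single answer."""
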
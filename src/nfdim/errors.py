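"""Exception hierarchy for the nFD pipeline.

Every anticipated failure mode maps to a distinct subclass so callers (and
the CLI exit-code logic) can discriminate configuration errors from data
errors from degenerate-analysis outcomes.
"""


class NfdimError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NfdimError, ValueError):
    """A parameter is outside its admissible range."""


class InvalidImageError(NfdimError, ValueError):
    """An image violates the single-channel grayscale contract."""


class EmptyStructureError(NfdimError):
    """An operation needing at least one foreground pixel got none."""


class InsufficientScalesError(NfdimError):
    """Fewer than the minimum number of box sizes for a log-log fit."""


class NoSignalError(NfdimError):
    """No intensity threshold produced a fittable outline for a core."""


class InconsistentInputError(NfdimError, ValueError):
    """Records that must agree (e.g. one patient's cores) do not."""


class InvalidRecordError(NfdimError, ValueError):
    """A clinical record violates a basic invariant (e.g. time <= 0)."""


class DegenerateGroupError(NfdimError):
    """A survival comparison group contributes no at-risk time."""


class NoCutpointError(NfdimError):
    """No candidate cut satisfies the minimum group-size constraint."""


class FitFailureError(NfdimError):
    """A model fit failed to converge; carries the fitter's trace."""


class UndefinedTestError(NfdimError):
    """A contingency-table test is undefined (zero margin)."""


class PlacementFailureError(NfdimError):
    """Too many nuclei requested for the core footprint's overlap budget."""
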
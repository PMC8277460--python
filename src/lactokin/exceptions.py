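"""Exception hierarchy for lactokin."""


class LactokinError(Exception):
    """Base class for all package-specific errors."""


class ParameterDomainError(LactokinError, ValueError):
    """A kinetic parameter is outside its physical domain."""


class InconsistentMacroError(LactokinError, ValueError):
    """Macro constants imply a non-physical (non-positive) micro rate."""


class DegenerateModelError(LactokinError, ValueError):
    """The model collapses to a lower-dimensional limit (e.g. alpha == beta)."""


class IntegrationError(LactokinError, RuntimeError):
    """Numerical integration of the state equations failed."""


class DetectionError(LactokinError, RuntimeError):
    """End-of-infusion detection threshold was never attained."""


class InsufficientDataError(LactokinError, ValueError):
    """Too few observations for the requested operation."""


class ConversionError(LactokinError, ValueError):
    """Unit conversion is impossible with the information supplied."""


class KeyMismatchError(LactokinError, ValueError):
    """Two dependency tables do not share an identical key set."""
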
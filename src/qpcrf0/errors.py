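"""Typed exceptions for qPCR curve analysis failures."""


class QpcrError(Exception):
    """Base class for all qpcrf0 errors."""


class ParameterDomainError(QpcrError, ValueError):
    """A model parameter is outside its mathematical domain (D <= 0, E <= 1, ...)."""


class InsufficientDataError(QpcrError, ValueError):
    """Too few cycles (or window outside the curve) for the requested operation."""


class NoAmplificationError(QpcrError):
    """The trace never rises above baseline noise; there is nothing to fit."""


class LateAmplificationError(QpcrError):
    """The inflection cycle falls at or beyond the last recorded cycle."""


class FitFailureError(QpcrError):
    """Nonlinear least squares did not converge after restarts.

    Carries optimizer diagnostics in ``.diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndeterminedCtError(QpcrError):
    """The fluorescence never crosses the threshold."""


class ThresholdLogDomainError(QpcrError):
    """No threshold crossing with positive flanking readings (threshold too low)."""


class ComparatorError(QpcrError):
    """A comparator method failed on this curve; the curve is excluded and logged."""


class DegenerateCurveError(QpcrError, ValueError):
    """A standard curve violates its slope-sign invariant or has no spread."""
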
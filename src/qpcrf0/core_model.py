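"""Closed-form evaluation of the six-parameter amplification-curve model.

The model describes one qPCR well's fluorescence ``f_x`` at cycle ``x`` as a
four-parameter sigmoid (amplification) plus a two-parameter line (background):

    f_x = f_m - f_m / (1 + D * E**(x - C_i))**(1/D) + a*x + b

where ``f_m`` is the maximum predicted fluorescence, ``D`` the rate of
efficiency decay (asymmetry), ``E`` the starting amplification efficiency
(fold-increase per cycle, 2 = perfect doubling), ``C_i`` the inflection
cycle, and ``a``/``b`` the baseline slope/intercept.  The quantification
endpoint is the predicted initial fluorescence expressed as a percentage of
the plateau,

    f0% = 100 * f_0 / f_m,   f_0 = f_m - f_m / (1 + D * E**(-C_i))**(1/D),

which is invariant to the overall fluorescence scale of the instrument.

Everything here is a pure function of the parameters; fitting lives in
:mod:`qpcrf0.fitting`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterDomainError

__all__ = [
    "ModelParams",
    "eval_model",
    "compute_f0",
    "compute_f0_percent",
    "efficiency_from_slope",
    "invert_f0_to_Ci",
]

#: Efficiencies above this are physically implausible (super-doubling) and
#: are flagged with a warning, but not rejected.
PLAUSIBLE_E_MAX = 2.0


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the sigmoid-plus-linear amplification model.

    Attributes
    ----------
    f_m : float
        Maximum predicted fluorescence (AFU), > 0.
    D : float
        Rate of efficiency decay (dimensionless), > 0.  High values mean a
        rapid cycle-to-cycle loss of efficiency near the plateau.
    E : float
        Starting efficiency (fold-amplification per cycle), > 1.  Values
        above 2 are allowed but implausible.
    C_i : float
        Inflection cycle (real-valued), the cycle of maximal slope.
    a, b : float
        Baseline slope (AFU/cycle) and intercept (AFU); either sign.
    """

    f_m: float
    D: float
    E: float
    C_i: float
    a: float = 0.0
    b: float = 0.0

    def __post_init__(self):
        if not (self.f_m > 0):
            raise ParameterDomainError(f"f_m must be > 0, got {self.f_m}")
        if not (self.D > 0):
            raise ParameterDomainError(f"D must be > 0, got {self.D}")
        if not (self.E > 1):
            raise ParameterDomainError(f"E must be > 1, got {self.E}")
        if not math.isfinite(self.C_i):
            raise ParameterDomainError(f"C_i must be finite, got {self.C_i}")


def _sigmoid(params: ModelParams, x):
    """Sigmoid part of the model, computed in log space.

    ``(1 + D*E**(x-C_i))**(-1/D)`` overflows naively once ``E**(x-C_i)``
    exceeds float range (plateau cycles); ``log1p(exp(t))`` via
    ``logaddexp`` is exact for all finite x.
    """
    t = np.log(params.D) + (np.asarray(x, dtype=float) - params.C_i) * np.log(params.E)
    return params.f_m - params.f_m * np.exp(-np.logaddexp(0.0, t) / params.D)


def eval_model(params: ModelParams, x):
    """Model fluorescence at cycle(s) ``x`` (scalar or array), in AFU."""
    out = _sigmoid(params, x) + params.a * np.asarray(x, dtype=float) + params.b
    if np.isscalar(x):
        return float(out)
    return out


def compute_f0(params: ModelParams) -> float:
    """Predicted initial fluorescence f_0 (AFU).

    This is the sigmoid part evaluated at cycle 0; the baseline terms a, b
    are background, not template signal, and are deliberately excluded.
    """
    t = math.log(params.D) - params.C_i * math.log(params.E)
    return params.f_m - params.f_m * math.exp(-np.logaddexp(0.0, t) / params.D)


def compute_f0_percent(f_0: float, f_m: float) -> float:
    """f0% = 100 * f_0 / f_m; scale-invariant quantification endpoint."""
    if not f_m > 0:
        raise ParameterDomainError(f"f_m must be > 0, got {f_m}")
    if f_0 >= f_m:
        warnings.warn(
            f"f_0 ({f_0:g}) >= f_m ({f_m:g}): pathological fit, f0% >= 100",
            stacklevel=2,
        )
    return 100.0 * f_0 / f_m


def efficiency_from_slope(slope: float) -> float:
    """Starting efficiency from a standard-curve slope: E = 2**(1/slope).

    ``slope`` is the regression slope of log10(f0%) on log10(concentration),
    which is positive for a well-behaved dilution series.
    """
    if not slope > 0:
        raise ParameterDomainError(
            f"standard-curve slope must be > 0, got {slope} (degenerate or inverted curve)"
        )
    E = 2.0 ** (1.0 / slope)
    if E > PLAUSIBLE_E_MAX:
        warnings.warn(
            f"derived efficiency E={E:.4g} exceeds 2 (super-doubling is implausible)",
            stacklevel=2,
        )
    return E


def invert_f0_to_Ci(f_0: float, f_m: float, D: float, E: float) -> float:
    """Inflection cycle that yields a given initial fluorescence.

    Algebraic inverse of :func:`compute_f0`; used by the simulator to place
    dilution levels at target initial amounts.  Requires 0 < f_0 < f_m.
    """
    if not (f_m > 0 and 0 < f_0 < f_m):
        raise ParameterDomainError(f"need 0 < f_0 < f_m, got f_0={f_0}, f_m={f_m}")
    if not (D > 0 and E > 1):
        raise ParameterDomainError(f"need D > 0 and E > 1, got D={D}, E={E}")
    # (f_m/(f_m-f_0))**D - 1 == expm1(-D*log1p(-r)), r = f_0/f_m: exact for tiny r
    r = f_0 / f_m
    g = math.expm1(-D * math.log1p(-r))
    return -(math.log(g) - math.log(D)) / math.log(E)
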
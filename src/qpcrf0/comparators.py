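"""Benchmark comparator methods: threshold C_T, Cy_0, and window-of-linearity N_0.

These are the three established qPCR quantification endpoints the f0% method
is benchmarked against:

* **C_T** — fractional cycle at which background-subtracted fluorescence
  crosses a threshold anchored to the dilution curve's baseline noise
  (threshold = multiplier x max baseline SD, multiplier 100 by default),
  with log-linear interpolation between the flanking cycles.
* **Cy_0** — the abscissa intercept of the tangent at the inflection of a
  five-parameter Richards fit to the raw trace.
* **N_0** — initial fluorescence back-projected from the exponential phase
  using a per-amplicon mean efficiency estimated from a "window of
  linearity" in log fluorescence.  This is a simplified re-implementation of
  the published iterative algorithm: the window is the best-R² contiguous
  stretch between fixed fluorescence quantile rails, with an internal
  constant-baseline search; it is adequate for benchmarking, not
  bit-compatible with the original software.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.stats import linregress

from .curves import AmplificationCurve
from .errors import (
    ComparatorError,
    InsufficientDataError,
    ThresholdLogDomainError,
    UndeterminedCtError,
)

__all__ = [
    "BaselineStats",
    "ThresholdSpec",
    "CtResult",
    "Cy0Result",
    "N0Result",
    "baseline_stats",
    "subtract_background",
    "group_threshold",
    "compute_ct",
    "compute_cy0",
    "linreg_n0",
]

DEFAULT_BASELINE_WINDOW = (3, 8)
DEFAULT_THRESHOLD_MULTIPLIER = 100.0
# window-of-linearity rails as fractions of the corrected plateau
_RAIL_LOW = 0.01
_RAIL_HIGH = 0.90
_MIN_WINDOW_POINTS = 4
_MAX_WINDOW_POINTS = 8
# implied per-cycle efficiency a window must show to count as exponential
# phase; slow baseline drift (ratio ~1.01/cycle) never qualifies
_WINDOW_E_MIN = 1.3
_WINDOW_E_MAX = 4.0


@dataclass(frozen=True)
class BaselineStats:
    """Mean, OLS slope and SD of the fluorescence over the baseline window."""

    mean: float
    slope: float
    sd: float
    window: tuple[int, int] = DEFAULT_BASELINE_WINDOW


@dataclass(frozen=True)
class ThresholdSpec:
    """Noise-anchored threshold shared by all reactions of a dilution curve."""

    multiplier: float
    noise: float
    threshold: float


@dataclass(frozen=True)
class CtResult:
    ct: float
    local_E: float
    threshold_used: float


@dataclass(frozen=True)
class Cy0Result:
    cy0: float
    richards_params: dict
    tangent_slope: float


@dataclass(frozen=True)
class N0Result:
    n0: float
    reaction_E: float
    amplicon_mean_E: float
    window: tuple[int, int]
    baseline: float = 0.0


def baseline_stats(
    curve: AmplificationCurve, window: tuple[int, int] = DEFAULT_BASELINE_WINDOW
) -> BaselineStats:
    lo, hi = window
    mask = (curve.cycles >= lo) & (curve.cycles <= hi)
    if mask.sum() < 3 or lo < curve.first_cycle or hi > curve.last_cycle:
        raise InsufficientDataError(
            f"baseline window {window} outside curve cycles "
            f"[{curve.first_cycle}, {curve.last_cycle}] or < 3 points"
        )
    x = curve.cycles[mask].astype(float)
    f = curve.fluorescence[mask]
    slope, intercept = np.polyfit(x, f, 1)
    sd = float(np.std(f, ddof=1))
    return BaselineStats(mean=float(np.mean(f)), slope=float(slope), sd=sd, window=(lo, hi))


def subtract_background(curve: AmplificationCurve, stats: BaselineStats) -> AmplificationCurve:
    """Remove the baseline line (mean + slope about the window midpoint)."""
    lo, hi = stats.window
    mask = (curve.cycles >= lo) & (curve.cycles <= hi)
    mid = float(np.mean(curve.cycles[mask])) if mask.any() else 0.5 * (lo + hi)
    line = stats.mean + stats.slope * (curve.cycles.astype(float) - mid)
    return curve.with_fluorescence(curve.fluorescence - line)


def group_threshold(
    curves: list[AmplificationCurve],
    multiplier: float = DEFAULT_THRESHOLD_MULTIPLIER,
    window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
) -> ThresholdSpec:
    """Threshold for a dilution curve: multiplier x its maximum baseline SD."""
    if not curves:
        raise ValueError("empty curve group")
    noise = max(baseline_stats(c, window).sd for c in curves)
    scale = max(float(np.max(np.abs(c.fluorescence))) for c in curves)
    floor = max(np.finfo(float).eps * max(scale, 1.0), np.finfo(float).tiny)
    if noise <= floor:
        noise = floor
        warnings.warn(
            "all baseline SDs are zero (noise-free data); threshold floored near machine epsilon",
            stacklevel=2,
        )
    return ThresholdSpec(multiplier=multiplier, noise=noise, threshold=multiplier * noise)


def compute_ct(curve: AmplificationCurve, threshold: float) -> CtResult:
    """Threshold cycle with log-linear interpolation.

    C_T = x + (ln T - ln f_x) / ln E with E = f_{x+1}/f_x, where x is the
    last cycle below threshold at the first upward crossing whose flanking
    readings are both positive.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    f = curve.fluorescence
    crossings = np.flatnonzero((f[:-1] < threshold) & (f[1:] >= threshold))
    if crossings.size == 0:
        raise UndeterminedCtError(
            f"well {curve.well_id}: fluorescence never crosses threshold {threshold:g}"
        )
    for i in crossings:
        if f[i] > 0 and f[i + 1] > 0:
            E = float(f[i + 1] / f[i])
            ct = float(curve.cycles[i]) + (math.log(threshold) - math.log(f[i])) / math.log(E)
            return CtResult(ct=ct, local_E=E, threshold_used=float(threshold))
    raise ThresholdLogDomainError(
        f"well {curve.well_id}: every threshold crossing has a non-positive flanking "
        "reading (threshold too low for the background-subtracted trace)"
    )


# --- Cy_0 -----------------------------------------------------------------

def _richards(v, x):
    fb, fmax, b, c, d = v
    # (1 + exp(-(x-c)/b))**(-d), via logs for plateau stability
    t = -(x - c) / b
    return fb + fmax * np.exp(-d * np.logaddexp(0.0, t))


def compute_cy0(curve: AmplificationCurve) -> Cy0Result:
    """Tangent-intercept quantification cycle from a Richards fit.

    Fits F(x) = Fb + Fmax / (1 + exp(-(x-c)/b))**d to the *raw* trace.  The
    inflection sits at x* = c + b*ln(d); the tangent there is extended to
    zero fluorescence after removing the fitted baseline constant Fb, giving
    Cy_0 = x* - F(x*)/F'(x*) = c + b*ln(d) - b*(1 + 1/d).
    """
    x = curve.cycles.astype(float)
    f = curve.fluorescence
    span = float(np.max(f) - np.min(f))
    base = float(np.mean(f[: min(5, len(f))]))
    noise = float(np.std(f[: min(5, len(f))], ddof=1)) if len(f) >= 3 else 0.0
    if span <= max(5.0 * noise, 1e-12 * max(abs(float(np.max(f))), 1.0)):
        raise ComparatorError(f"well {curve.well_id}: flat trace, Cy0 undefined")

    diffs = np.diff(f)
    i = int(np.argmax(diffs))
    slope_max = max(float(diffs[i]), 1e-12 * span)
    x0 = np.array([base, span, span / (4.0 * slope_max), float(x[i]) + 0.5, 1.0])
    lo = np.array([-np.inf, 1e-12 * span, 1e-3, x[0] - 10.0, 0.05])
    hi = np.array([np.inf, 10.0 * span, 50.0, x[-1] + 10.0, 20.0])
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)

    best = None
    rng = np.random.default_rng(0)
    for _ in range(4):
        try:
            res = least_squares(
                lambda v: _richards(v, x) - f, x0, bounds=(lo, hi), method="trf",
                ftol=1e-12, xtol=1e-12, max_nfev=2000,
            )
            if res.status > 0 and (best is None or res.cost < best.cost):
                best = res
            if best is not None and best.cost <= 1e-10 * span**2 * len(x):
                break
        except Exception:
            pass
        x0 = np.clip(x0 * (1 + rng.normal(0, 0.2, 5)), lo + 1e-12, hi - 1e-12)
    if best is None:
        raise ComparatorError(f"well {curve.well_id}: Richards fit failed")

    fb, fmax, b, c, d = best.x
    x_inf = c + b * math.log(d)
    if not (x[0] - 5.0 <= x_inf <= x[-1] + 5.0):
        raise ComparatorError(
            f"well {curve.well_id}: Richards inflection {x_inf:.1f} outside cycle range"
        )
    g = (1.0 + 1.0 / d) ** (-d)  # sigmoid value at inflection (baseline removed)
    slope = fmax * (1.0 + 1.0 / d) ** (-d - 1.0) / b
    cy0 = x_inf - fmax * g / slope  # == c + b*ln(d) - b*(1 + 1/d)
    return Cy0Result(
        cy0=float(cy0),
        richards_params={"Fb": float(fb), "Fmax": float(fmax), "b": float(b),
                         "c": float(c), "d": float(d)},
        tangent_slope=float(slope),
    )


# --- window-of-linearity N_0 ---------------------------------------------

def _best_window(x, f_corr):
    """Best-R² contiguous log-linear rising stretch between the quantile rails.

    Returns (r_squared, slope_log10, first_idx, last_idx) or None.  Ties
    prefer longer, then earlier windows.  Only windows with positive slope
    qualify (amplification grows); R² as the criterion also disfavors the
    flat baseline-dominated stretches a mis-estimated background produces.
    """
    top = float(np.max(f_corr))
    if top <= 0:
        return None
    ok = (f_corr > _RAIL_LOW * top) & (f_corr < _RAIL_HIGH * top) & (f_corr > 0)
    idx = np.flatnonzero(ok)
    if idx.size < _MIN_WINDOW_POINTS:
        return None
    # contiguous runs of in-rail points
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    best = None
    for run in runs:
        if run.size < _MIN_WINDOW_POINTS:
            continue
        for length in range(min(run.size, _MAX_WINDOW_POINTS), _MIN_WINDOW_POINTS - 1, -1):
            for s in range(run.size - length + 1):
                sel = run[s : s + length]
                lx, ly = x[sel], np.log10(f_corr[sel])
                r = linregress(lx, ly)
                if not (np.log10(_WINDOW_E_MIN) <= r.slope <= np.log10(_WINDOW_E_MAX)):
                    continue
                r2 = r.rvalue**2
                key = (round(r2, 12), length, -sel[0])
                if best is None or key > best[0]:
                    best = (key, r2, float(r.slope), int(sel[0]), int(sel[-1]))
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]


def _window_badness(curve, beta):
    """1 - R² of the best window after subtracting baseline ``beta``."""
    res = _best_window(curve.cycles.astype(float), curve.fluorescence - beta)
    return np.inf if res is None else 1.0 - res[0]


def _reaction_window(curve: AmplificationCurve, window=DEFAULT_BASELINE_WINDOW):
    """Pick a constant baseline and the window of linearity for one reaction."""
    candidates = [0.0]
    try:
        candidates.append(baseline_stats(curve, window).mean)
    except InsufficientDataError:
        pass
    f = curve.fluorescence
    lo = float(min(candidates)) - 0.05 * float(np.max(np.abs(f)))
    hi = float(np.max(f)) * 0.5
    try:
        opt = minimize_scalar(
            lambda b: _window_badness(curve, b), bounds=(lo, hi), method="bounded"
        )
        if opt.success and np.isfinite(opt.fun):
            candidates.append(float(opt.x))
    except Exception:
        pass
    best = None
    for beta in candidates:
        res = _best_window(curve.cycles.astype(float), f - beta)
        if res is None:
            continue
        if best is None or res[0] > best[0]:
            best = (res[0], beta, res)
    if best is None:
        raise ComparatorError(
            f"well {curve.well_id}: no >= {_MIN_WINDOW_POINTS}-point exponential stretch"
        )
    _, beta, (_, slope_log10, i0, i1) = best
    return beta, slope_log10, i0, i1


def linreg_n0(
    curves: list[AmplificationCurve],
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
) -> dict[str, N0Result]:
    """Window-of-linearity N_0 estimates for one amplicon's reactions.

    Takes raw (non-background-subtracted) curves, baselines internally, fits
    each reaction's efficiency in its window of linearity, averages E over
    the amplicon, and back-projects N_0 = F_w / mean_E**c_w from the first
    window point (c_w, F_w).  Reactions where no window can be found are
    skipped with a warning (comparator-failure record).
    """
    if not curves:
        raise ValueError("empty curve group")
    amplicons = {c.amplicon_id for c in curves}
    if len(amplicons) > 1:
        raise ValueError(f"curves span several amplicons: {sorted(amplicons)}")
    per_curve = {}
    for c in curves:
        try:
            beta, slope_log10, i0, i1 = _reaction_window(c, baseline_window)
        except ComparatorError as exc:
            warnings.warn(str(exc), stacklevel=2)
            continue
        per_curve[c.well_id] = (c, beta, 10.0 ** slope_log10, i0, i1)
    if not per_curve:
        raise ComparatorError("no reaction in the group has a usable window of linearity")
    mean_E = float(np.mean([e for (_, _, e, _, _) in per_curve.values()]))
    out: dict[str, N0Result] = {}
    for well, (c, beta, e, i0, i1) in per_curve.items():
        c_w = float(c.cycles[i0])
        f_w = float(c.fluorescence[i0] - beta)
        out[well] = N0Result(
            n0=f_w / mean_E**c_w,
            reaction_E=e,
            amplicon_mean_E=mean_E,
            window=(int(c.cycles[i0]), int(c.cycles[i1])),
            baseline=beta,
        )
    return out
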
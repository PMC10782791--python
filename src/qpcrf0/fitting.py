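"""Nonlinear least-squares estimation of the amplification-curve model.

Two modes mirror the two steps of the f0% workflow:

* **free-E** — all six parameters float; the fit window runs from the first
  retained cycle to the cycle just after the inflection cycle (found
  self-consistently by iterating the window).  The headline output is E,
  later averaged per amplicon.
* **fixed-E** — E is held at a supplied constant (amplicon mean, or derived
  from a standard-curve slope) and the remaining five parameters are fitted
  over *all* retained cycles; f0% is then computed from the fit.

An f0% estimate is only considered precise when the last fitted cycle lies
at least two cycles past the inflection (C_final >= C_i + 2); fits violating
this carry ``ci_after_final_flag`` and are excluded from default
amplicon-mean efficiencies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core_model import ModelParams, compute_f0, compute_f0_percent, eval_model
from .curves import MIN_CYCLES_FOR_FIT, AmplificationCurve
from .errors import (
    FitFailureError,
    InsufficientDataError,
    LateAmplificationError,
    NoAmplificationError,
)

__all__ = [
    "SigmoidFit",
    "trim_initial_cycles",
    "estimate_initial_params",
    "fit_free_E",
    "fit_fixed_E",
    "final_cycle_sensitivity",
    "mean_efficiency",
    "DEFAULT_BASELINE_WINDOW",
]

DEFAULT_BASELINE_WINDOW = (3, 8)

# Parameter bounds for the trust-region optimizer (scaled by max fluorescence
# where dimensional).  E is restricted to (1.001, 3]: below, no amplification;
# above, far outside anything a real reaction produces.
_D_BOUNDS = (0.01, 10.0)
_E_BOUNDS = (1.001, 3.0)
_N_RESTARTS = 3
_MAX_NFEV = 2000
_MIN_FREE_WINDOW_POINTS = 8


@dataclass
class SigmoidFit:
    """Result of fitting the six-parameter model to one trace."""

    params: ModelParams
    mode: str  # "free_E" | "fixed_E"
    fit_window: tuple[int, int]  # inclusive first/last fitted cycle labels
    rss: float
    converged: bool
    n_iter: int
    f0: float | None = None
    f0_percent: float | None = None
    ci_after_final_flag: bool = False


def trim_initial_cycles(curve: AmplificationCurve, k: int) -> AmplificationCurve:
    """Drop the first ``k`` readings (cycle labels preserved).

    Early cycles that deviate obviously from the baseline (mixing/settling
    artifacts) should be discarded before fitting.
    """
    if not 0 <= k <= 5:
        raise ValueError(f"k must be in [0, 5], got {k}")
    if len(curve) - k < MIN_CYCLES_FOR_FIT:
        raise InsufficientDataError(
            f"trimming {k} cycles leaves {len(curve) - k} readings "
            f"(< {MIN_CYCLES_FOR_FIT}) for well {curve.well_id}"
        )
    if k == 0:
        return curve
    return curve.replace(
        cycles=curve.cycles[k:],
        fluorescence=curve.fluorescence[k:],
        discarded_initial_cycles=curve.discarded_initial_cycles + k,
    )


def _baseline_points(curve: AmplificationCurve, window: tuple[int, int]):
    mask = (curve.cycles >= window[0]) & (curve.cycles <= window[1])
    if mask.sum() < 3:
        # window trimmed away or curve starts late: fall back to first 6 readings
        mask = np.zeros(len(curve), dtype=bool)
        mask[: min(6, len(curve))] = True
    return curve.cycles[mask].astype(float), curve.fluorescence[mask]


def estimate_initial_params(
    curve: AmplificationCurve, baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW
) -> ModelParams:
    """Heuristic starting values for the optimizer.

    Baseline (a, b) from an OLS line through the baseline cycles; f_m from
    the baseline-corrected maximum; C_i from the cycle of maximal first
    difference; E = 1.9 and D = 1 as neutral shape starts.
    """
    x = curve.cycles.astype(float)
    f = curve.fluorescence
    bx, bf = _baseline_points(curve, baseline_window)
    a0, b0 = np.polyfit(bx, bf, 1)
    resid_sd = float(np.std(bf - (a0 * bx + b0)))
    corrected = f - (a0 * x + b0)

    scale = max(float(np.max(np.abs(f))), 1e-300)
    amplitude = float(np.max(corrected) - np.min(corrected))
    if amplitude <= max(5.0 * resid_sd, 1e-9 * scale):
        raise NoAmplificationError(
            f"well {curve.well_id}: trace never rises above baseline noise"
        )

    diffs = np.diff(corrected)
    i = int(np.argmax(diffs))
    ci0 = float(x[i] + 0.5)  # steepest rise between cycles i and i+1
    fm0 = max(float(np.max(corrected)), 1e-12 * scale)
    return ModelParams(f_m=fm0, D=1.0, E=1.9, C_i=ci0, a=float(a0), b=float(b0))


def _pack(params: ModelParams, free_E: bool) -> np.ndarray:
    v = [params.f_m, params.D, params.C_i, params.a, params.b]
    if free_E:
        v.insert(2, params.E)
    return np.array(v, dtype=float)


def _unpack(v: np.ndarray, free_E: bool, fixed_E: float | None) -> ModelParams:
    if free_E:
        fm, D, E, ci, a, b = v
    else:
        fm, D, ci, a, b = v
        E = fixed_E
    return ModelParams(f_m=float(fm), D=float(D), E=float(E), C_i=float(ci), a=float(a), b=float(b))


def _bounds(curve_max: float, first: float, last: float, free_E: bool):
    lo = [1e-12 * curve_max, _D_BOUNDS[0], first, -0.1 * curve_max, -np.inf]
    hi = [10.0 * curve_max, _D_BOUNDS[1], last + 10.0, 0.1 * curve_max, np.inf]
    if free_E:
        lo.insert(2, _E_BOUNDS[0])
        hi.insert(2, _E_BOUNDS[1])
    return np.array(lo), np.array(hi)


def _run_nls(x, f, start: ModelParams, free_E: bool, fixed_E: float | None):
    """Bounded trust-region NLS with jittered restarts on failure."""
    curve_max = max(float(np.max(np.abs(f))), 1e-300)
    lo, hi = _bounds(curve_max, float(x[0]), float(x[-1]), free_E)

    def residuals(v):
        p = _unpack(v, free_E, fixed_E)
        return eval_model(p, x) - f

    rng = np.random.default_rng(0)  # fixed jitter seed: restarts are reproducible
    best = None
    x0 = np.clip(_pack(start, free_E), lo + 1e-15, hi - 1e-15)
    # cost below this (relative to signal) counts as machine-precision convergence
    cost_ok = 1e-10 * curve_max**2 * len(x)
    for attempt in range(1 + _N_RESTARTS):
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=_MAX_NFEV,
            )
        except Exception:
            res = None
        if res is not None and res.status > 0:
            if best is None or res.cost < best.cost:
                best = res
            if best.cost <= cost_ok:
                break
        # jitter the start for the next attempt
        jitter = rng.normal(0.0, 0.15, size=x0.size)
        x0 = np.clip(_pack(start, free_E) * (1.0 + jitter), lo + 1e-15, hi - 1e-15)
        x0[-3] += rng.normal(0.0, 2.0)  # extra C_i jitter (same slot in both modes)
        x0 = np.clip(x0, lo + 1e-15, hi - 1e-15)

    if best is None:
        raise FitFailureError(
            "nonlinear least squares failed on all restarts",
            diagnostics={"n_points": len(x), "free_E": free_E},
        )
    return best


def fit_fixed_E(
    curve: AmplificationCurve,
    E: float,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
) -> SigmoidFit:
    """Fit f_m, D, C_i, a, b over all retained cycles with E held constant.

    Computes f0 and f0% from the fitted parameters and flags the fit when
    the last cycle precedes C_i + 2 (reduced precision).
    """
    if not E > 1:
        raise ValueError(f"fixed E must be > 1, got {E}")
    if len(curve) < MIN_CYCLES_FOR_FIT:
        raise InsufficientDataError(
            f"well {curve.well_id}: {len(curve)} cycles < {MIN_CYCLES_FOR_FIT}"
        )
    start = estimate_initial_params(curve, baseline_window)
    x = curve.cycles.astype(float)
    res = _run_nls(x, curve.fluorescence, start, free_E=False, fixed_E=E)
    params = _unpack(res.x, free_E=False, fixed_E=E)
    f0 = compute_f0(params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pathological f0 >= f_m flagged via value
        f0pct = compute_f0_percent(f0, params.f_m)
    return SigmoidFit(
        params=params,
        mode="fixed_E",
        fit_window=(curve.first_cycle, curve.last_cycle),
        rss=float(2.0 * res.cost),
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
        f0=f0,
        f0_percent=f0pct,
        ci_after_final_flag=bool(curve.last_cycle < params.C_i + 2.0),
    )


def fit_free_E(
    curve: AmplificationCurve,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
    max_window_iter: int = 5,
) -> SigmoidFit:
    """Fit all six parameters on cycles up to just after the inflection.

    The window [first cycle, ceil(C_i) + 1] depends on the unknown C_i, so
    it is iterated to self-consistency (at most ``max_window_iter`` rounds).
    Raises :class:`LateAmplificationError` when the curve ends before the
    inflection can be bracketed.
    """
    if len(curve) < MIN_CYCLES_FOR_FIT:
        raise InsufficientDataError(
            f"well {curve.well_id}: {len(curve)} cycles < {MIN_CYCLES_FOR_FIT}"
        )
    start = estimate_initial_params(curve, baseline_window)
    x_all = curve.cycles.astype(float)
    f_all = curve.fluorescence
    last = curve.last_cycle

    def window_end(ci: float) -> int:
        end = int(math.ceil(ci)) + 1
        # floor: a 6-parameter fit needs at least _MIN_FREE_WINDOW_POINTS points
        floor_end = int(curve.cycles[min(_MIN_FREE_WINDOW_POINTS, len(curve)) - 1])
        return max(end, floor_end)

    if window_end(start.C_i) > last:
        # steepest observed rise sits at the trace's end: inflection never bracketed
        raise LateAmplificationError(
            f"well {curve.well_id}: estimated C_i~{start.C_i:.1f} too close to the last "
            f"cycle {last}; the inflection is not bracketed by the data"
        )
    end = window_end(start.C_i)
    res = None
    params = start
    n_windows = 0
    stable = False
    for n_windows in range(1, max_window_iter + 1):
        mask = curve.cycles <= end
        res = _run_nls(x_all[mask], f_all[mask], params, free_E=True, fixed_E=None)
        params = _unpack(res.x, free_E=True, fixed_E=None)
        new_end = window_end(params.C_i)
        if new_end > last:
            raise LateAmplificationError(
                f"well {curve.well_id}: fitted C_i={params.C_i:.2f} needs cycles up to "
                f"{new_end} but the trace ends at {last}"
            )
        if new_end == end:
            stable = True
            break
        end = new_end
    return SigmoidFit(
        params=params,
        mode="free_E",
        fit_window=(curve.first_cycle, end),
        rss=float(2.0 * res.cost),
        converged=bool(res.status > 0 and stable),
        n_iter=n_windows,
        ci_after_final_flag=bool(curve.last_cycle < params.C_i + 2.0),
    )


def mean_efficiency(
    fits: list[SigmoidFit], method: str = "arithmetic", exclude_flagged: bool = True
) -> float:
    """Combine replicate free-E estimates into one amplicon efficiency.

    Flagged fits (inflection too close to the final cycle) are excluded by
    default; if every fit is flagged they are all used, with a warning.
    """
    es = [f.params.E for f in fits if not (exclude_flagged and f.ci_after_final_flag)]
    if not es:
        if not fits:
            raise ValueError("no fits supplied")
        warnings.warn(
            "every free-E fit is flagged (C_final < C_i + 2); using all of them",
            stacklevel=2,
        )
        es = [f.params.E for f in fits]
    if method == "arithmetic":
        return float(np.mean(es))
    if method == "geometric":
        return float(np.exp(np.mean(np.log(es))))
    raise ValueError(f"unknown method {method!r}")


def final_cycle_sensitivity(
    curves: list[AmplificationCurve],
    E: float,
    offsets=range(-5, 6),
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
) -> dict[int, float]:
    """CV% of f0% across replicates as a function of the final fitted cycle.

    Each replicate is truncated at C_final = C_i + offset (its own C_i, from
    a full-trace fixed-E fit) and refitted; precision should degrade once
    C_final drops below C_i + 2.  Offsets leaving any replicate with too few
    cycles are skipped with a warning.  Returns {offset: CV%}.
    """
    if len(curves) < 2:
        raise ValueError(f"need >= 2 replicates, got {len(curves)}")
    ref_ci = [
        int(round(fit_fixed_E(c, E, baseline_window).params.C_i)) for c in curves
    ]
    table: dict[int, float] = {}
    for off in offsets:
        f0s = []
        feasible = True
        for c, ci in zip(curves, ref_ci):
            mask = c.cycles <= ci + off
            if mask.sum() < MIN_CYCLES_FOR_FIT:
                feasible = False
                break
            sub = c.replace(cycles=c.cycles[mask], fluorescence=c.fluorescence[mask])
            f0s.append(fit_fixed_E(sub, E, baseline_window).f0_percent)
        if not feasible:
            warnings.warn(f"offset {off:+d} skipped: leaves < {MIN_CYCLES_FOR_FIT} cycles")
            continue
        f0s = np.asarray(f0s)
        table[int(off)] = float(100.0 * np.std(f0s, ddof=1) / np.mean(f0s))
    return table
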
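"""Turn per-reaction endpoints into predicted concentrations.

Two quantification conditions mirror real experimental designs:

* **Condition 1 (standard curve present)** — regress the endpoint (C_T,
  Cy_0, log10 N_0 or log10 f0%) on log10(concentration) and invert the
  regression for unknowns.  For f0%, the standard-curve slope also yields
  the amplicon efficiency E = 2**(1/slope), which feeds the fixed-E refit.
* **Condition 2 (no standard curve)** — predict relative to the highest
  concentration (level 1) of each dilution curve: delta-endpoint with base 2
  for C_T/Cy_0, a direct ratio for f0%/N_0.

Relative-expression outputs (fold change against reference genes, and fold
change normalized to a control group) are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .comparators import (
    compute_ct,
    compute_cy0,
    baseline_stats,
    group_threshold,
    linreg_n0,
    subtract_background,
)
from .core_model import efficiency_from_slope
from .curves import AmplificationCurve
from .errors import ComparatorError, DegenerateCurveError, QpcrError
from .fitting import fit_fixed_E, fit_free_E, mean_efficiency

__all__ = [
    "StandardCurve",
    "build_standard_curve",
    "predict_conc_standard",
    "predict_conc_relative",
    "run_f0_pipeline",
    "quantify_all_methods",
    "fold_change",
    "normalized_fold_change",
]

#: endpoint kind -> required slope sign on log10(conc)
ENDPOINT_SLOPE_SIGN = {"ct": -1, "cy0": -1, "log10_n0": +1, "log10_f0pct": +1}
_LOG_KINDS = {"log10_n0", "log10_f0pct"}


@dataclass(frozen=True)
class StandardCurve:
    """OLS calibration of an endpoint against log10(concentration)."""

    endpoint_kind: str
    slope: float
    intercept: float
    r_squared: float
    E_derived: float | None = None  # only for log10_f0pct

    def endpoint_at(self, log10_conc: float) -> float:
        return self.intercept + self.slope * log10_conc


def _transform(endpoints, kind):
    endpoints = np.asarray(endpoints, dtype=float)
    if kind in _LOG_KINDS:
        if np.any(endpoints <= 0):
            raise DegenerateCurveError(f"{kind} endpoints must be positive for log10")
        return np.log10(endpoints)
    return endpoints


def build_standard_curve(endpoints, concs, endpoint_kind: str) -> StandardCurve:
    if endpoint_kind not in ENDPOINT_SLOPE_SIGN:
        raise ValueError(f"unknown endpoint kind {endpoint_kind!r}")
    concs = np.asarray(concs, dtype=float)
    if np.any(concs <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(concs)) < 3:
        raise DegenerateCurveError("standard curve needs >= 3 distinct concentration levels")
    y = _transform(endpoints, endpoint_kind)
    x = np.log10(concs)
    res = linregress(x, y)
    want = ENDPOINT_SLOPE_SIGN[endpoint_kind]
    if res.slope == 0 or np.sign(res.slope) != want:
        raise DegenerateCurveError(
            f"{endpoint_kind} standard curve slope {res.slope:.4g} violates expected sign {want:+d}"
        )
    E = None
    if endpoint_kind == "log10_f0pct":
        E = efficiency_from_slope(res.slope)
    return StandardCurve(
        endpoint_kind=endpoint_kind,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        E_derived=E,
    )


def predict_conc_standard(endpoint_value: float, curve: StandardCurve) -> float:
    """Invert the calibration: conc = 10**((endpoint - intercept)/slope)."""
    if curve.endpoint_kind in _LOG_KINDS:
        if not endpoint_value > 0:
            raise ValueError(f"{curve.endpoint_kind} endpoint must be positive")
        y = np.log10(endpoint_value)
    else:
        y = endpoint_value
    return float(10.0 ** ((y - curve.intercept) / curve.slope))


def predict_conc_relative(values, levels, true_conc_level1: float, method: str):
    """Concentrations relative to the first (highest) dilution level.

    For cycle-valued endpoints (ct, cy0): conc = 2**(-(v - mean(level-1)))
    * true_conc1, i.e. perfect doubling per cycle, the convention of
    delta-Ct relative quantification.  For amount-valued endpoints
    (f0pct, linreg): direct ratio to the level-1 mean.
    """
    values = np.asarray(values, dtype=float)
    levels = np.asarray(levels)
    if values.shape != levels.shape:
        raise ValueError("values and levels must align")
    m1 = levels == 1
    if not m1.any():
        raise ValueError("no level-1 (highest concentration) reactions in group")
    ref = float(np.mean(values[m1]))
    if method in ("ct", "cy0"):
        return 2.0 ** (-(values - ref)) * true_conc_level1
    if method in ("f0pct", "linreg"):
        return values / ref * true_conc_level1
    raise ValueError(f"unknown method {method!r}")


# --- the f0% pipeline ------------------------------------------------------

def run_f0_pipeline(
    curves: list[AmplificationCurve],
    has_standard_curve: bool,
    baseline_window: tuple[int, int] = (3, 8),
    e_combine: str = "arithmetic",
    e_refine_iterations: int = 1,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Full f0% quantification for a set of curves grouped by amplicon.

    With a standard curve: fixed-E fits at E=2 give approximate f0% values
    for the standards; regressing log10(f0%) on log10(conc) yields the
    amplicon E (slope rule); all reactions are refitted at that E and
    quantified by inverting the final standard curve.

    Without: free-E fits are averaged per amplicon, all reactions are
    refitted at the mean E, and concentrations are predicted relative to
    level 1 of each dilution curve.

    ``e_refine_iterations`` controls the standard-curve efficiency
    derivation: 1 (default) is the single pass of the slope rule starting
    from the E=2 assumption; higher values iterate E <- E_fit**(1/slope) to
    a fixed point, removing the small misspecification bias the single pass
    leaves when the true E is far from 2.

    Returns a tidy per-reaction table and {amplicon: E used}.
    """
    rows = []
    e_by_amplicon: dict[str, float] = {}
    for amplicon in sorted({c.amplicon_id for c in curves}):
        group = [c for c in curves if c.amplicon_id == amplicon]
        if has_standard_curve:
            standards = [c for c in group if c.true_conc is not None]
            if len({c.true_conc for c in standards}) < 3:
                raise DegenerateCurveError(
                    f"amplicon {amplicon}: a standard curve needs >= 3 known concentration levels"
                )
            E = 2.0
            for _ in range(max(1, e_refine_iterations)):
                approx = [fit_fixed_E(c, E, baseline_window).f0_percent for c in standards]
                sc0 = build_standard_curve(
                    approx, [c.true_conc for c in standards], "log10_f0pct"
                )
                # first pass from E=2 is exactly the printed slope rule 2**(1/slope)
                E = E ** (1.0 / sc0.slope)
        else:
            fits = []
            for c in group:
                try:
                    fits.append(fit_free_E(c, baseline_window))
                except QpcrError as exc:
                    warnings.warn(f"free-E fit failed for {c.well_id}: {exc}", stacklevel=2)
            if not fits:
                warnings.warn(f"amplicon {amplicon}: no successful free-E fit; unquantified",
                              stacklevel=2)
                continue
            E = mean_efficiency(fits, method=e_combine)
        e_by_amplicon[amplicon] = E

        final = {c.well_id: fit_fixed_E(c, E, baseline_window) for c in group}
        if has_standard_curve:
            sc = build_standard_curve(
                [final[c.well_id].f0_percent for c in standards],
                [c.true_conc for c in standards],
                "log10_f0pct",
            )
        for c in group:
            fit = final[c.well_id]
            row = {
                "well_id": c.well_id,
                "amplicon_id": amplicon,
                "group_id": c.group_id,
                "dilution_level": c.dilution_level,
                "true_conc": c.true_conc,
                "method": "f0pct",
                "endpoint_value": fit.f0_percent,
                "E_used": E,
                "ci_after_final_flag": fit.ci_after_final_flag,
                "condition": "standard_curve" if has_standard_curve else "relative_first_level",
            }
            if has_standard_curve:
                row["predicted_conc"] = predict_conc_standard(fit.f0_percent, sc)
            rows.append(row)

    df = pd.DataFrame(rows)
    if not has_standard_curve and not df.empty:
        df = _relative_by_group(df, "f0pct")
    return df, e_by_amplicon


def _relative_by_group(df: pd.DataFrame, method: str) -> pd.DataFrame:
    """Fill predicted_conc per dilution-curve group via the relative formulas."""
    parts = []
    for gid, sub in df.groupby("group_id", dropna=False):
        sub = sub.copy()
        lvl1 = sub.loc[sub["dilution_level"] == 1, "true_conc"]
        if lvl1.empty or lvl1.isna().all():
            raise ValueError(
                f"dilution curve {gid!r}: level-1 reactions with known concentration required"
            )
        sub["predicted_conc"] = predict_conc_relative(
            sub["endpoint_value"].to_numpy(),
            sub["dilution_level"].to_numpy(),
            float(lvl1.iloc[0]),
            method,
        )
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def quantify_all_methods(
    curves: list[AmplificationCurve],
    has_standard_curve: bool,
    threshold_multiplier: float = 100.0,
    baseline_window: tuple[int, int] = (3, 8),
) -> pd.DataFrame:
    """Quantify every reaction with all four methods (f0%, C_T, Cy_0, N_0).

    Dilution-curve groups are defined by ``group_id``; the C_T threshold is
    anchored per group.  Comparator failures on individual wells are logged
    and those wells are excluded from the failing method only.
    """
    frames = [run_f0_pipeline(curves, has_standard_curve, baseline_window)[0]]

    def meta(c):
        return {
            "well_id": c.well_id, "amplicon_id": c.amplicon_id, "group_id": c.group_id,
            "dilution_level": c.dilution_level, "true_conc": c.true_conc,
            "condition": "standard_curve" if has_standard_curve else "relative_first_level",
        }

    # C_T: per-group noise-anchored threshold on background-subtracted traces
    ct_rows, cy0_rows, n0_rows = [], [], []
    for gid in sorted({c.group_id for c in curves}, key=str):
        group = [c for c in curves if c.group_id == gid]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # noise-free floor warning is expected on synthetic data
            spec = group_threshold(group, threshold_multiplier, baseline_window)
        for c in group:
            sub = subtract_background(c, baseline_stats(c, baseline_window))
            try:
                res = compute_ct(sub, spec.threshold)
                ct_rows.append(meta(c) | {"method": "ct", "endpoint_value": res.ct})
            except QpcrError as exc:
                warnings.warn(f"C_T failed for {c.well_id}: {exc}", stacklevel=2)
            try:
                cy = compute_cy0(c)
                cy0_rows.append(meta(c) | {"method": "cy0", "endpoint_value": cy.cy0})
            except ComparatorError as exc:
                warnings.warn(f"Cy0 failed for {c.well_id}: {exc}", stacklevel=2)

    # N_0: per amplicon (mean efficiency is an amplicon property)
    for amplicon in sorted({c.amplicon_id for c in curves}):
        group = [c for c in curves if c.amplicon_id == amplicon]
        try:
            results = linreg_n0(group, baseline_window)
        except ComparatorError as exc:
            warnings.warn(f"LinReg failed for amplicon {amplicon}: {exc}", stacklevel=2)
            continue
        for c in group:
            if c.well_id in results:
                n0_rows.append(meta(c) | {"method": "linreg",
                                          "endpoint_value": results[c.well_id].n0})

    kind = {"ct": "ct", "cy0": "cy0", "linreg": "log10_n0"}
    relmethod = {"ct": "ct", "cy0": "cy0", "linreg": "linreg"}
    for rows in (ct_rows, cy0_rows, n0_rows):
        if not rows:
            continue
        df = pd.DataFrame(rows)
        method = df["method"].iloc[0]
        if has_standard_curve:
            std = df.dropna(subset=["true_conc"])
            sc = build_standard_curve(std["endpoint_value"], std["true_conc"], kind[method])
            df["predicted_conc"] = [
                predict_conc_standard(v, sc) for v in df["endpoint_value"]
            ]
        else:
            df = _relative_by_group(df, relmethod[method])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# --- relative expression ---------------------------------------------------

def _geomean(values) -> float:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if np.any(values <= 0):
        raise ValueError("all inputs must be positive")
    return float(np.exp(np.mean(np.log(values))))


def fold_change(target_f0pct: float, reference_f0pcts) -> float:
    """Target-gene quantity over the geometric mean of the reference genes."""
    if not target_f0pct > 0:
        raise ValueError("target must be positive")
    return target_f0pct / _geomean(reference_f0pcts)


def normalized_fold_change(sample_fold_changes, control_group_fold_changes):
    """Fold changes normalized so the control group's geometric mean is 1."""
    ref = _geomean(control_group_fold_changes)
    samples = np.asarray(sample_fold_changes, dtype=float)
    if np.any(samples <= 0):
        raise ValueError("all fold changes must be positive")
    return samples / ref
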
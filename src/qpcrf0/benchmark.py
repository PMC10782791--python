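"""Performance indicators and the method-comparison protocol.

Per dilution level: CV% of predicted concentrations and within-level
variance of log10(predicted concentration) measure precision; per reaction:
|relative error| measures accuracy; per dilution curve: a normalized bias
(observed dynamic range over expected) symmetrized as exp(|ln .|) so it can
be averaged.  Per-curve indicator values feed a Friedman test across
methods (paired by dilution curve), followed — when significant — by
pairwise Wilcoxon signed-rank tests with Bonferroni correction.  The effect
of using f0% instead of a comparator is summarized as the geometric mean,
over dilution curves, of the comparator/f0% indicator ratio ("fold
reduction").
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import friedmanchisquare, wilcoxon
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cv_percent",
    "level_variance",
    "relative_error",
    "absolute_re",
    "bias_indicators",
    "fold_reduction",
    "geometric_mean_fold",
    "summarize_performance",
    "fold_reduction_summary",
    "compare_methods",
    "ComparisonResult",
    "INDICATORS",
]

INDICATORS = ("cv_percent", "variance", "abs_re", "abs_bias")


def cv_percent(values) -> float:
    """100 * sample SD / mean of replicate predicted concentrations."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV% needs >= 2 replicates")
    mean = float(np.mean(values))
    if not mean > 0:
        raise ValueError("CV% needs a positive mean")
    return 100.0 * float(np.std(values, ddof=1)) / mean


def level_variance(values) -> float:
    """Sample variance of log10(predicted concentration) within a level."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("variance needs >= 2 replicates")
    if np.any(values <= 0):
        raise ValueError("concentrations must be positive")
    return float(np.var(np.log10(values), ddof=1))


def relative_error(predicted: float, true: float) -> float:
    """(predicted - true) / true; signed."""
    if not true > 0:
        raise ValueError("true concentration must be positive")
    return (predicted - true) / true


def absolute_re(predicted: float, true: float) -> float:
    return abs(relative_error(predicted, true))


def bias_indicators(level_mean_predicted, true_concs) -> tuple[float, float]:
    """(normalized bias, absolute bias) for one dilution curve.

    Normalized bias divides the observed highest/lowest level ratio of mean
    predictions by the true ratio; absolute bias = exp(|ln(normalized)|)
    >= 1, symmetric in over/under-estimation.
    """
    pred = np.asarray(level_mean_predicted, dtype=float)
    true = np.asarray(true_concs, dtype=float)
    if pred.shape != true.shape or pred.size < 2:
        raise ValueError("need aligned predictions and true concs for >= 2 levels")
    if np.any(pred <= 0) or np.any(true <= 0):
        raise ValueError("concentrations must be positive")
    hi, lo = int(np.argmax(true)), int(np.argmin(true))
    normalized = (pred[hi] / pred[lo]) / (true[hi] / true[lo])
    return float(normalized), float(math.exp(abs(math.log(normalized))))


def fold_reduction(indicator_other: float, indicator_f0pct: float) -> float:
    """Comparator indicator over the f0% indicator; > 1 favors f0%."""
    if indicator_other < 0 or indicator_f0pct < 0:
        raise ValueError("indicators must be non-negative")
    if indicator_f0pct == 0:
        if indicator_other == 0:
            return 1.0
        warnings.warn("f0% indicator is zero; fold reduction is infinite", stacklevel=2)
        return math.inf
    return indicator_other / indicator_f0pct


def geometric_mean_fold(folds) -> float:
    folds = np.asarray(folds, dtype=float)
    finite = folds[np.isfinite(folds)]
    if finite.size < folds.size:
        warnings.warn("infinite fold reductions dropped from the geometric mean", stacklevel=2)
    if finite.size == 0:
        return math.inf
    return float(np.exp(np.mean(np.log(finite))))


def summarize_performance(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-(dilution curve, method) indicator table from per-reaction results.

    Aggregation order is reaction -> level -> curve by arithmetic mean:
    CV%/variance are computed per level and averaged over levels; |RE| is
    averaged over reactions; bias uses level means of the extreme levels.
    Returns tidy rows (dilution_curve_id, method, indicator, value).
    """
    required = {"group_id", "method", "dilution_level", "true_conc", "predicted_conc"}
    missing = required - set(quant.columns)
    if missing:
        raise ValueError(f"quantification table lacks columns {sorted(missing)}")
    rows = []
    for (gid, method), sub in quant.groupby(["group_id", "method"]):
        per_level = sub.groupby("dilution_level")
        cvs, variances = [], []
        for _, lvl in per_level:
            if len(lvl) >= 2:
                cvs.append(cv_percent(lvl["predicted_conc"]))
                variances.append(level_variance(lvl["predicted_conc"]))
        abs_res = [
            absolute_re(p, t)
            for p, t in zip(sub["predicted_conc"], sub["true_conc"])
            if t is not None and not np.isnan(t)
        ]
        means = per_level.agg(pred=("predicted_conc", "mean"), true=("true_conc", "first"))
        values = {
            "cv_percent": float(np.mean(cvs)) if cvs else np.nan,
            "variance": float(np.mean(variances)) if variances else np.nan,
            "abs_re": float(np.mean(abs_res)) if abs_res else np.nan,
            "abs_bias": bias_indicators(means["pred"], means["true"])[1]
            if len(means) >= 2 else np.nan,
        }
        for indicator, value in values.items():
            rows.append({"dilution_curve_id": gid, "method": method,
                         "indicator": indicator, "value": value})
    return pd.DataFrame(rows)


def fold_reduction_summary(
    indicator_table: pd.DataFrame, reference: str = "f0pct"
) -> pd.DataFrame:
    """Geometric-mean fold reduction of each indicator vs the reference method."""
    rows = []
    for indicator in indicator_table["indicator"].unique():
        sub = indicator_table[indicator_table["indicator"] == indicator]
        wide = sub.pivot(index="dilution_curve_id", columns="method", values="value").dropna()
        if reference not in wide.columns:
            continue
        for method in wide.columns:
            if method == reference:
                continue
            folds = [fold_reduction(o, f) for o, f in zip(wide[method], wide[reference])]
            rows.append({"indicator": indicator, "method": method,
                         "geometric_mean_fold_reduction": geometric_mean_fold(folds),
                         "n_curves": len(wide)})
    return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """Friedman test over methods (paired by dilution curve) for one indicator."""

    indicator: str
    friedman_statistic: float
    friedman_p: float
    n_blocks: int
    methods: list[str]
    pairwise: list[tuple[str, str, float]] = field(default_factory=list)  # adjusted p


def compare_methods(
    indicator_table: pd.DataFrame, alpha: float = 0.05
) -> dict[str, ComparisonResult]:
    """Friedman -> pairwise Wilcoxon -> Bonferroni, per indicator.

    Blocks are dilution curves; incomplete blocks (a method missing a value)
    are dropped with a warning.  Pairwise tests run only when the Friedman
    test is significant at ``alpha``.
    """
    out: dict[str, ComparisonResult] = {}
    for indicator in indicator_table["indicator"].unique():
        sub = indicator_table[indicator_table["indicator"] == indicator]
        wide = sub.pivot(index="dilution_curve_id", columns="method", values="value")
        n_before = len(wide)
        wide = wide.dropna()
        if len(wide) < n_before:
            warnings.warn(
                f"{indicator}: dropped {n_before - len(wide)} incomplete block(s)",
                stacklevel=2,
            )
        methods = list(wide.columns)
        if len(wide) < 3:
            raise ValueError(f"{indicator}: need >= 3 complete blocks, have {len(wide)}")
        if len(methods) < 2:
            raise ValueError(f"{indicator}: need >= 2 methods")
        cols = [wide[m].to_numpy() for m in methods]
        if all(np.allclose(row, row[0]) for row in wide.to_numpy()):
            # every block constant across methods: no discrimination at all
            stat, p = 0.0, 1.0
        elif len(methods) == 2:
            stat, p = math.nan, math.nan  # Friedman needs >= 3 methods; go straight to Wilcoxon
        else:
            stat, p = friedmanchisquare(*cols)
        result = ComparisonResult(
            indicator=indicator, friedman_statistic=float(stat), friedman_p=float(p),
            n_blocks=len(wide), methods=methods,
        )
        if (math.isnan(p) and len(methods) == 2) or p < alpha:
            pairs = list(itertools.combinations(methods, 2))
            raw = []
            for a, b in pairs:
                diff = wide[a].to_numpy() - wide[b].to_numpy()
                if np.allclose(diff, 0):
                    raw.append(1.0)
                else:
                    raw.append(float(wilcoxon(wide[a], wide[b], correction=True).pvalue))
            adjusted = multipletests(raw, method="bonferroni")[1]
            result.pairwise = [(a, b, float(p_adj)) for (a, b), p_adj in zip(pairs, adjusted)]
        out[indicator] = result
    return out
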
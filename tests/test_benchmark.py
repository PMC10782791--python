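"""Performance indicators vs brute-force oracles; Friedman/Wilcoxon chain."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpcrf0 import (
    absolute_re,
    bias_indicators,
    compare_methods,
    cv_percent,
    fold_reduction,
    geometric_mean_fold,
    level_variance,
    relative_error,
    summarize_performance,
)


class TestIndicatorWorkedValues:
    def test_cv_percent(self):
        assert cv_percent([1.0, 2.0, 3.0]) == pytest.approx(50.0)
        assert cv_percent([5.0, 5.0, 5.0]) == 0.0
        assert cv_percent([2.0, 8.0]) == pytest.approx(100.0 * math.sqrt(18.0) / 5.0)
        with pytest.raises(ValueError):
            cv_percent([1.0])

    def test_level_variance(self):
        assert level_variance([1.0, 10.0]) == pytest.approx(0.5)
        assert level_variance([10.0, 10.0, 10.0]) == 0.0
        assert level_variance([1.0, 10.0, 100.0]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            level_variance([1.0, -1.0])

    def test_relative_error(self):
        assert relative_error(10.0, 10.0) == 0.0
        assert relative_error(15.0, 10.0) == pytest.approx(0.5)
        assert relative_error(5.0, 10.0) == pytest.approx(-0.5)
        assert absolute_re(5.0, 10.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0)

    def test_bias(self):
        nb, ab = bias_indicators([1000.0, 1.0], [1000.0, 1.0])
        assert (nb, ab) == (pytest.approx(1.0), pytest.approx(1.0))
        nb, ab = bias_indicators([500.0, 1.0], [1000.0, 1.0])
        assert nb == pytest.approx(0.5) and ab == pytest.approx(2.0)
        nb, ab = bias_indicators([2000.0, 1.0], [1000.0, 1.0])
        assert nb == pytest.approx(2.0) and ab == pytest.approx(2.0)
        with pytest.raises(ValueError):
            bias_indicators([1.0], [1.0])

    def test_fold_reduction(self):
        assert fold_reduction(2.0, 1.0) == pytest.approx(2.0)
        assert fold_reduction(3.0, 3.0) == pytest.approx(1.0)
        assert geometric_mean_fold([2.0, 0.5]) == pytest.approx(1.0)
        with pytest.warns(UserWarning):
            assert fold_reduction(1.0, 0.0) == math.inf


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=10))
def test_indicators_match_brute_force(values):
    """CV%, variance, fold reduction vs formulas coded from first principles."""
    v = np.asarray(values)
    n = len(v)
    mean = sum(v) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in v) / (n - 1))
    assert cv_percent(v) == pytest.approx(100.0 * sd / mean, rel=1e-10, abs=1e-10)
    logs = [math.log10(x) for x in v]
    lmean = sum(logs) / n
    lvar = sum((x - lmean) ** 2 for x in logs) / (n - 1)
    assert level_variance(v) == pytest.approx(lvar, rel=1e-10, abs=1e-12)
    # permutation invariance
    assert cv_percent(v[::-1]) == pytest.approx(cv_percent(v), rel=1e-12)
    # scale invariance (log shift cancels in the variance)
    assert cv_percent(3.0 * v) == pytest.approx(cv_percent(v), rel=1e-9)
    assert level_variance(3.0 * v) == pytest.approx(level_variance(v), rel=1e-6, abs=1e-12)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.floats(1e-3, 1e3))
def test_absolute_bias_symmetry(x):
    assert math.exp(abs(math.log(x))) == pytest.approx(
        math.exp(abs(math.log(1.0 / x))), rel=1e-12
    )
    nb, ab = bias_indicators([1000.0 * x, 1.0], [1000.0, 1.0])
    assert ab >= 1.0
    assert ab == pytest.approx(max(x, 1.0 / x), rel=1e-9)


def _friedman_brute(data):
    """Tie-free Friedman chi-square from rank sums, coded independently."""
    n, k = data.shape
    ranks = np.argsort(np.argsort(data, axis=1), axis=1) + 1.0
    rank_sums = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)


def _table(data, methods):
    rows = []
    for i, row in enumerate(data):
        for m, v in zip(methods, row):
            rows.append({"dilution_curve_id": f"dc{i}", "method": m,
                         "indicator": "cv_percent", "value": v})
    return pd.DataFrame(rows)


class TestCompareMethods:
    @pytest.mark.parametrize("shape", [(4, 3), (6, 4)])
    def test_friedman_matches_independent_ranks(self, shape):
        rng = np.random.default_rng(42)
        data = rng.uniform(1.0, 10.0, size=shape)
        methods = [f"m{j}" for j in range(shape[1])]
        res = compare_methods(_table(data, methods))["cv_percent"]
        assert res.friedman_statistic == pytest.approx(_friedman_brute(data), abs=1e-10)

    def test_identical_methods_no_pairwise(self):
        data = np.tile(np.array([[1.0, 1.0, 1.0]]), (4, 1))
        res = compare_methods(_table(data, ["a", "b", "c"]))["cv_percent"]
        assert res.friedman_statistic == 0.0
        assert res.friedman_p == 1.0
        assert res.pairwise == []

    def test_uniformly_best_method_has_min_rank_sum(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(5.0, 10.0, size=(6, 4))
        data[:, 0] = rng.uniform(0.1, 1.0, size=6)  # method 0 always smallest
        ranks = np.argsort(np.argsort(data, axis=1), axis=1) + 1
        assert ranks[:, 0].sum() == 6
        res = compare_methods(_table(data, ["w", "x", "y", "z"]))["cv_percent"]
        assert res.friedman_p < 0.05 and len(res.pairwise) == 6
        assert all(0.0 < p <= 1.0 for _, _, p in res.pairwise)

    def test_label_permutation_consistency(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(1.0, 10.0, size=(5, 3))
        a = compare_methods(_table(data, ["a", "b", "c"]))["cv_percent"]
        b = compare_methods(_table(data[:, ::-1], ["c", "b", "a"]))["cv_percent"]
        assert a.friedman_statistic == pytest.approx(b.friedman_statistic, abs=1e-12)
        pa = {frozenset([x, y]): p for x, y, p in a.pairwise}
        pb = {frozenset([x, y]): p for x, y, p in b.pairwise}
        assert pa == pytest.approx(pb)

    def test_incomplete_blocks_dropped(self):
        data = np.random.default_rng(1).uniform(1, 10, size=(5, 3))
        table = _table(data, ["a", "b", "c"]).drop(index=[0])  # dc0 missing method a
        with pytest.warns(UserWarning, match="incomplete"):
            res = compare_methods(table)["cv_percent"]
        assert res.n_blocks == 4

    def test_too_few_blocks(self):
        data = np.random.default_rng(1).uniform(1, 10, size=(2, 3))
        with pytest.raises(ValueError, match="blocks"):
            compare_methods(_table(data, ["a", "b", "c"]))


def test_summarize_performance_shapes():
    rng = np.random.default_rng(0)
    rows = []
    for gid in ("dc1", "dc2"):
        for method in ("f0pct", "ct"):
            for level, true in ((1, 100.0), (2, 10.0)):
                for _ in range(3):
                    rows.append({"group_id": gid, "method": method,
                                 "dilution_level": level, "true_conc": true,
                                 "predicted_conc": true * rng.uniform(0.8, 1.2)})
    table = summarize_performance(pd.DataFrame(rows))
    assert len(table) == 2 * 2 * 4  # curves x methods x indicators
    assert set(table["indicator"]) == {"cv_percent", "variance", "abs_re", "abs_bias"}
    assert (table.loc[table.indicator == "abs_bias", "value"] >= 1.0).all()
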
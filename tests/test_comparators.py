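"""C_T, Cy_0 and window-of-linearity comparators against algebraic oracles."""

import math

import numpy as np
import pytest

from qpcrf0 import (
    ModelParams,
    SimulationDesign,
    baseline_stats,
    compute_ct,
    compute_cy0,
    group_threshold,
    linreg_n0,
    simulate_curve,
    simulate_dilution_series,
    subtract_background,
)
from qpcrf0.curves import AmplificationCurve
from qpcrf0.errors import (
    ComparatorError,
    InsufficientDataError,
    ThresholdLogDomainError,
    UndeterminedCtError,
)


def _curve(values, first=1, **kw):
    values = np.asarray(values, dtype=float)
    return AmplificationCurve("w", np.arange(first, first + len(values)), values, **kw)


class TestBaseline:
    def test_constant(self):
        c = _curve(np.full(40, 0.1))
        s = baseline_stats(c)
        assert (s.mean, s.slope, s.sd) == (pytest.approx(0.1), pytest.approx(0.0),
                                           pytest.approx(0.0))

    def test_pure_line(self):
        c = _curve(0.01 * np.arange(1, 41))
        s = baseline_stats(c)
        assert s.slope == pytest.approx(0.01)
        assert s.mean == pytest.approx(0.055)

    def test_window_outside_curve(self):
        with pytest.raises(InsufficientDataError):
            baseline_stats(_curve([0.1] * 5))

    def test_subtraction_removes_line_and_is_idempotent(self):
        c = _curve(0.01 * np.arange(1, 41) + 0.3)
        s = baseline_stats(c)
        once = subtract_background(c, s)
        assert np.allclose(once.fluorescence, 0.0, atol=1e-12)
        twice = subtract_background(once, baseline_stats(once))
        assert np.allclose(twice.fluorescence, once.fluorescence, atol=1e-12)


class TestThreshold:
    def _with_sd(self, sd, seed):
        rng = np.random.default_rng(seed)
        return _curve(rng.normal(0.1, sd, 40))

    def test_max_noise_times_multiplier(self):
        rng = np.random.default_rng(0)
        a = _curve(rng.normal(0, 1, 40) * 0.0)
        b = _curve(np.concatenate([[0, 0], [0.1, 0.104, 0.096, 0.1, 0.104, 0.096],
                                   np.full(32, 0.1)]))
        sd_b = baseline_stats(b).sd
        spec = group_threshold([a, b], multiplier=100)
        assert spec.noise == pytest.approx(sd_b)
        assert spec.threshold == pytest.approx(100 * sd_b)
        assert group_threshold([a, b], multiplier=10).threshold == pytest.approx(10 * sd_b)

    def test_noise_free_floor_warns(self):
        c = _curve(np.full(40, 0.1))
        with pytest.warns(UserWarning, match="floored"):
            spec = group_threshold([c])
        assert spec.threshold > 0


class TestCt:
    def test_worked_doubling(self):
        f = 0.05 * 2.0 ** (np.arange(1, 41, dtype=float) - 20.0)
        r = compute_ct(_curve(f), 0.1)
        assert r.local_E == pytest.approx(2.0)
        assert r.ct == pytest.approx(21.0)

    def test_threshold_equal_to_reading(self):
        f = 0.05 * 2.0 ** (np.arange(1, 41, dtype=float) - 20.0)
        assert compute_ct(_curve(f), 0.05).ct == pytest.approx(20.0)

    def test_quadrupling(self):
        f = np.array([1e-4] * 9 + [0.04, 0.16, 0.64, 1.0, 1.0])
        r = compute_ct(_curve(f), 0.08)
        assert r.local_E == pytest.approx(4.0)
        assert r.ct == pytest.approx(10.5)

    def test_never_crossed(self):
        with pytest.raises(UndeterminedCtError):
            compute_ct(_curve(np.full(40, 0.01)), 1.0)

    def test_negative_flank_raises_log_domain(self):
        f = np.array([-0.01] * 10 + [1.0] * 10)
        with pytest.raises(ThresholdLogDomainError):
            compute_ct(_curve(f), 0.5)

    def test_monotone_spacing_on_dilution_series(self):
        design = SimulationDesign(seed=5, E_true=2.0, n_replicates=1, noise_sd=0.0,
                                  f_m_cv=0.0, baseline_a_range=(0, 0),
                                  baseline_b_range=(0, 0))
        cts = [compute_ct(c, 1e-3).ct for c in simulate_dilution_series(design)]
        spacings = np.diff(cts)
        assert np.all(spacings > 0)
        assert np.allclose(spacings, math.log2(10.0), atol=0.05)

    def test_threshold_doubling_shifts_ct_by_constant(self):
        # pure exponential at E=2: doubling the threshold adds exactly 1 cycle
        for f0 in (1e-6, 1e-8):
            f = f0 * 2.0 ** np.arange(1, 41, dtype=float)
            c = _curve(f)
            assert compute_ct(c, 2e-2).ct - compute_ct(c, 1e-2).ct == pytest.approx(
                1.0, abs=1e-3
            )


class TestCy0:
    def test_logistic_tangent_oracle(self):
        # logistic with unit log-slope and inflection at 20: Cy0 = 20 - 0.5/0.25
        p = ModelParams(f_m=1.0, D=1.0, E=math.e, C_i=20.0)
        r = compute_cy0(simulate_curve(p, 0.0, 40, 0))
        assert r.cy0 == pytest.approx(18.0, abs=0.01)
        assert r.cy0 < r.richards_params["c"] + r.richards_params["b"] * math.log(
            r.richards_params["d"]
        )

    def test_baseline_shift_invariance(self):
        p = ModelParams(f_m=1.0, D=1.0, E=math.e, C_i=20.0)
        c = simulate_curve(p, 0.0, 40, 0)
        ref = compute_cy0(c).cy0
        shifted = compute_cy0(c.with_fluorescence(c.fluorescence + 0.05)).cy0
        assert shifted == pytest.approx(ref, abs=1e-3)

    def test_flat_curve_fails(self):
        with pytest.raises(ComparatorError):
            compute_cy0(_curve(np.full(40, 0.1)))

    def test_ranks_match_ct_on_noise_free_series(self):
        # late-amplifying series so the baseline window is signal-free
        design = SimulationDesign(seed=6, E_true=1.9, n_replicates=1, noise_sd=0.0,
                                  f_m_cv=0.0, baseline_a_range=(0, 0),
                                  baseline_b_range=(0.05, 0.05), top_f0_percent=1e-4)
        curves = simulate_dilution_series(design)
        cts = [compute_ct(subtract_background(c, baseline_stats(c)), 0.01).ct
               for c in curves]
        cy0s = [compute_cy0(c).cy0 for c in curves]
        assert np.argsort(cts).tolist() == np.argsort(cy0s).tolist()


class TestLinReg:
    def test_exact_exponential_round_trip(self):
        f = 1e-6 * 2.0 ** np.arange(1, 26, dtype=float)
        res = linreg_n0([_curve(f)])
        r = res["w"]
        assert r.reaction_E == pytest.approx(2.0, abs=1e-9)
        assert r.n0 == pytest.approx(1e-6, rel=1e-9)

    def test_amplicon_mean_E_applied_to_both(self):
        x = np.arange(1, 26, dtype=float)
        curves = [
            AmplificationCurve("a", x.astype(int), 1e-6 * 2.0 ** x),
            AmplificationCurve("b", x.astype(int), 1e-6 * 1.8 ** x),
        ]
        res = linreg_n0(curves)
        assert res["a"].amplicon_mean_E == pytest.approx(1.9, abs=1e-6)
        assert res["b"].amplicon_mean_E == res["a"].amplicon_mean_E
        # back-projection uses the mean efficiency, not the reaction's own
        cw = res["a"].window[0]
        assert res["a"].n0 == pytest.approx(1e-6 * 2.0 ** cw / 1.9 ** cw, rel=1e-6)

    def test_plateau_only_fails(self):
        with pytest.raises(ComparatorError):
            linreg_n0([_curve(np.full(40, 1.0))])

    def test_sigmoid_with_baseline(self):
        p = ModelParams(f_m=1.0, D=1.0, E=1.9, C_i=20.0, b=0.05)
        res = linreg_n0([simulate_curve(p, 0.0, 40, 0, well_id="w")])
        assert res["w"].reaction_E == pytest.approx(1.9, abs=0.05)
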
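# Methods

## The amplification-curve model

qPCR monitors the fluorescence of a DNA-binding dye over 30–50 thermal
cycles.  A well-behaved trace has three regimes: a flat (possibly drifting)
background, an exponential amplification phase, and a plateau as reaction
substrates deplete.  `qpcrf0` models one reaction's fluorescence at cycle
`x` as a four-parameter sigmoid plus a two-parameter line:

    f(x) = f_m − f_m / (1 + D·E^(x − C_i))^(1/D) + a·x + b

* `f_m` — maximum predicted fluorescence (AFU), the plateau height of the
  sigmoid part.
* `E` — starting amplification efficiency: the fold-increase of product per
  cycle in the unconstrained (baseline/exponential) regime.  `E = 2` is
  perfect doubling, `E = 1` no amplification; the model enforces `E > 1`
  and flags `E > 2` as implausible rather than forbidding it.
* `D` — rate of efficiency decay (> 0): how fast the per-cycle efficiency
  falls toward 1 as the plateau is approached; it is the model's asymmetry
  parameter.  `D = 1` reduces the sigmoid part to a logistic.
* `C_i` — inflection cycle, the real-valued cycle of maximal slope.
* `a`, `b` — linear background slope and intercept, either sign; fitting
  them jointly with the sigmoid replaces a separate baselining step.

The quantification endpoint is the predicted initial fluorescence of the
sigmoid part at cycle 0,

    f_0 = f_m − f_m / (1 + D·E^(−C_i))^(1/D),

reported as a percentage of the plateau, `f0% = 100·f_0/f_m`.  Normalizing
by `f_m` cancels well-to-well scale differences (pipetting volume, optical
gain), so f0% is invariant to multiplying a trace by any constant.  The
background terms are deliberately excluded from `f_0`: they are instrument
signal, not template.

The sigmoid is evaluated in log space (`log1p(exp(·))`) because
`E^(x − C_i)` overflows double precision around 40 cycles past the
inflection.

## Fitting

Both fit modes use bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, method `trf`; `ftol = xtol = gtol =
1e-12`, up to 3 restarts from jittered starts with a fixed jitter seed).
Bounds: `f_m ∈ (0, 10·max f]`, `D ∈ [0.01, 10]`, `E ∈ (1.001, 3]`,
`C_i ∈ [first cycle, last cycle + 10]`, `|a| ≤ 0.1·max f` per cycle, `b`
free.  Starting values: `(a, b)` from an ordinary least-squares line
through the baseline cycles (default window 3–8, inclusive), `f_m` from
the baseline-corrected maximum, `C_i` from the cycle of maximal first
difference, `E = 1.9`, `D = 1`.

* **Free-E mode** fits all six parameters on cycles from the first retained
  cycle to the cycle just after the inflection, operationalized as
  `ceil(C_i) + 1`.  Since `C_i` is unknown beforehand, the window is
  iterated to self-consistency (at most 5 rounds).  The window is floored
  at 8 points so the 6-parameter fit is never underdetermined when the
  inflection is very early.  If the required window extends past the last
  recorded cycle — the steepest observed rise sits at the end of the trace —
  the reaction is a late-amplification failure: the inflection is not
  bracketed and no free-E estimate is meaningful.
* **Fixed-E mode** holds `E` constant and fits the remaining five
  parameters over *all* retained cycles, then computes f0%.

Quantification never uses a single reaction's own fitted efficiency:
replicate free-E estimates are combined per amplicon (arithmetic mean by
default, geometric optional) because reaction-specific efficiencies
amplify replicate scatter.  Fits whose last cycle precedes `C_i + 2` carry
a flag and are excluded from the default amplicon mean — with fewer than
two cycles past the inflection the plateau, and hence f0%, is poorly
identified.  `final_cycle_sensitivity` quantifies this: replicates are
truncated at `C_i + offset` for offsets −5…+5 and the replicate CV% of f0%
is tabulated per offset.  Under the package's default noise conditions the
CV% rises from ~1% (offsets ≥ +3) through ~3% at +2 to tens of percent
below the inflection.

Initial cycles that deviate obviously from the baseline can be discarded
explicitly (`trim_initial_cycles`, `k ≤ 5`); trimming is user-driven so
that analyses are reproducible, and cycle labels are never renumbered.

## Efficiency from a standard curve

With a dilution series of known concentrations, the amplicon efficiency is
derived without free-E fits: all standards are fitted in fixed-E mode
*assuming* `E = 2`, `log10(f0%)` is regressed on `log10(conc)`, and the
slope of that regression yields

    E = 2^(1/slope).

The logic: under an assumed efficiency the apparent f0% spacing between
dilution levels reflects the true inflection spacing, so the slope equals
`1/log2(E_true)`.  All reactions are then refitted in fixed-E mode at the
derived E and quantified against the final standard curve.  This single
pass carries a small misspecification bias when the true E is far from 2
(about 4×10⁻³ in E at `E_true = 1.6`, negligible at 1.9–2.0);
`run_f0_pipeline(..., e_refine_iterations=n)` optionally iterates
`E ← E_fit^(1/slope)` to a fixed point, whose first iteration from
`E_fit = 2` is exactly the single-pass rule, and which removes the bias.
The default is the single pass.

## Comparator methods

* **C_T** — the trace is background-subtracted (line through the baseline
  window) and the threshold cycle is interpolated log-linearly:
  `C_T = x + (ln T − ln f_x)/ln E_local`, `E_local = f_(x+1)/f_x`, where
  `x` is the last sub-threshold cycle.  The threshold is anchored to the
  dilution curve's noise: `T = multiplier × max baseline SD` over the
  curve's reactions, multiplier 100 by default and configurable (noisy
  datasets warrant 10–50).  When noise-free synthetic data makes every
  baseline SD zero, the threshold is floored near machine epsilon with a
  warning.  If a crossing's flanking readings are not both positive the
  next crossing is tried; if none qualifies the C_T is a log-domain
  failure rather than a silently patched value.
* **Cy_0** — a five-parameter Richards curve
  `F(x) = Fb + Fmax/(1 + exp(−(x−c)/b))^d` is fitted to the *raw* trace;
  the inflection sits at `x* = c + b·ln d`, and the tangent there is
  extended to zero fluorescence after removing the fitted constant `Fb`:
  `Cy_0 = x* − b·(1 + 1/d)`.  Removing `Fb` makes Cy_0 independent of the
  instrument offset.
* **N_0 (window of linearity)** — a simplified re-implementation of
  LinRegPCR-style analysis.  Per reaction, a constant baseline is chosen
  from candidates {0, baseline-window mean, a 1-D bounded search} scored
  by the R² of the best log-linear window; the window of linearity is the
  best-R² contiguous stretch of 4–8 points between fluorescence rails at
  1% and 90% of the corrected plateau, constrained to an implied per-cycle
  efficiency in [1.3, 4.0] (without this guard the baseline search locks
  onto drift stretches that are log-linear but not exponential).  Reaction
  efficiencies are averaged per amplicon and
  `N_0 = F_w / mean_E^(c_w)` back-projects from the window's first point.
  This is not bit-compatible with the original iterative software; it is a
  benchmarking stand-in with the same structure (per-reaction window
  slope, per-amplicon mean efficiency, back-projection).

## Quantification conditions

* **Condition 1 (standard curve)** — regress the endpoint (`C_T`, `Cy_0`,
  `log10 N_0`, `log10 f0%`) on `log10(conc)`; slope sign is checked
  (negative for cycle-valued endpoints, positive for amount-valued ones);
  unknowns are predicted by inverting the regression.
* **Condition 2 (relative to the first level)** — for cycle-valued
  endpoints, `conc = 2^(−Δ)·conc₁` with `Δ` the difference from the
  arithmetic mean of the level-1 endpoint (perfect doubling assumed, as the
  relative formulas state); for amount-valued endpoints, the direct ratio
  to the level-1 mean.  The level-1 mean prediction therefore equals the
  level-1 concentration by construction.

Relative expression: fold change = target f0% over the geometric mean of
the reference genes' f0%; normalized fold change divides by the geometric
mean of the control group's fold changes, so the control group's geometric
mean is 1 by construction.

## Performance indicators and comparison protocol

Per dilution level: CV% (100·sample SD/mean) and the sample variance of
`log10(predicted conc)`; per reaction: |relative error|
`|(pred − true)/true|`; per dilution curve: normalized bias (observed
highest/lowest ratio of level means over the true ratio) symmetrized as
`exp(|ln ·|) ≥ 1`.  Sample (n−1) denominators throughout.  Aggregation to
one value per (dilution curve, method) is arithmetic: reaction → level →
curve.  The effect of using f0% is the geometric mean over curves of the
comparator/f0% indicator ratio ("fold reduction"; > 1 favors f0%).

Methods are compared per indicator with a Friedman test (blocks = dilution
curves; ≥ 3 complete blocks required, incomplete blocks dropped with a
warning); when significant at α = 0.05, all pairwise Wilcoxon signed-rank
tests follow with Bonferroni adjustment (factor = number of pairs).  The
Wilcoxon tests use scipy's automatic exact/normal-approximation switch
with continuity correction; identical-column blocks yield a degenerate
Friedman input and are reported as statistic 0, p = 1.  The Friedman step
needs at least three methods (scipy's constraint); with exactly two the
pairwise Wilcoxon runs directly.

## Synthetic data

`simulate_dilution_series` forward-simulates a dilution curve from the
model: per-well `f_m` drawn with a stated CV (default 5%, emulating volume
and optical fluctuations), per-well baseline `(a, b)` uniform in stated
ranges, additive Gaussian reading noise (default SD 0.3% of the mean
plateau; an optional multiplicative component models signal-proportional
noise), and each level's `C_i` placed by inverting the f0 formula so level
`ℓ` carries exactly `top_f0% / dilution_factor^(ℓ−1)`.  Defaults — five
tenfold levels, six replicates, `E = 1.9`, `D = 1`, top-level f0% = 10⁻²
(inflection near cycle 14), 40 cycles — describe a realistic mid-size SYBR
green series.  Generation is bit-reproducible from (design, seed) and every
curve stores its generating parameters.

What the generator does *not* emulate: non-linear settling baselines
beyond the first cycles, well position effects, inhibitor
kinetics, probe chemistries, melt behavior, or pipetting error in the
dilution steps themselves (true concentrations are exact by construction).
Passing tests therefore demonstrate correctness of the algorithms under
the stated noise model, not instrument-level robustness.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run at sizes chosen to
exercise every code path while completing quickly on one CPU: a 3×3 grid of
(E, D) shapes for exact recovery, a 15-well noiseless series for the
efficiency pipeline, 20 noisy replicates for the truncation trend, and a
10-dilution-curve benchmark (5 tenfold levels × 6 replicates, noise SD
0.003·f_m, f_m CV 5%) for the method comparison.  The published
benchmarking studies this mirrors use 20 dilution curves of 12–376 wells;
the simulated benchmark is a scaled-down analogue, so its fold reductions
are direction-comparable but not numerically comparable to published
values (synthetic noise is kinder to curve fitting than real instrument
artifacts, and the comparators here are re-implementations).

## Known limitations

* f0% requires at least two cycles past the inflection; late-amplifying
  reactions are flagged, and free-E fitting refuses traces whose steepest
  rise is at the final cycle.
* The C_T comparator's noise-anchored threshold assumes the baseline SD is
  a fair noise proxy; on synthetic data with very low noise the 100×
  multiplier can place the threshold high on the curve where local-E
  interpolation is unreliable — mirroring why published analyses sometimes
  lower the multiplier per dataset.
* The window-of-linearity estimator is a simplified stand-in (see above)
  and slightly underestimates high efficiencies because the best-R² window
  sits where efficiency has begun to decay.
* Eq-style relative quantification of cycle endpoints assumes perfect
  doubling (base 2) regardless of the known amplicon efficiency, matching
  the stated procedure; an efficiency-aware variant would change Condition-2
  C_T/Cy_0 predictions.
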
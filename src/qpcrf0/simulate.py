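"""Synthetic dilution-series generator.

Forward-simulates SYBR-type amplification traces from the sigmoid-plus-
linear model so the whole pipeline can be exercised and validated without
instrument data.  The generator emulates the structure of published
dilution-series datasets: 4-7 dilution levels (tenfold/fivefold/fourfold),
a handful to ~100 replicates per level, per-well plateau variation (volume
and optical fluctuations), drifting linear baselines, and additive Gaussian
reading noise (an optional multiplicative component models signal-
proportional noise seen in real traces).

Each level's inflection cycle is placed by inverting the initial-
fluorescence formula, so level ``l`` carries exactly
``top_f0_percent / dilution_factor**(l-1)`` percent initial fluorescence —
the generating truth for recovery tests.  Generation is bit-reproducible
from (design, seed); every curve stores its generating parameters in
``curve.truth``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_model import ModelParams, compute_f0_percent, compute_f0, eval_model, invert_f0_to_Ci
from .curves import AmplificationCurve

__all__ = ["SimulationDesign", "simulate_curve", "simulate_dilution_series"]


@dataclass(frozen=True)
class SimulationDesign:
    """Study conditions for one simulated dilution curve.

    Defaults describe a realistic mid-size SYBR green dilution series: five
    tenfold dilutions, six replicates, starting efficiency 1.9, top-level
    initial fluorescence 1e-2 % of plateau (inflection near cycle 14),
    5% between-well plateau CV, mild baseline drift, and additive reading
    noise with SD 0.3% of the mean plateau.
    """

    seed: int
    n_levels: int = 5
    dilution_factor: float = 10.0
    n_replicates: int = 6
    top_f0_percent: float = 1e-2
    E_true: float = 1.9
    D_true: float = 1.0
    f_m_mean: float = 1.0
    f_m_cv: float = 5.0
    baseline_a_range: tuple[float, float] = (-5e-4, 5e-4)
    baseline_b_range: tuple[float, float] = (0.02, 0.08)
    noise_sd: float = 0.003
    noise_mult: float = 0.0
    n_cycles: int = 40
    group_id: str = "sim"
    amplicon_id: str = "amplicon"

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not self.dilution_factor > 1:
            raise ValueError("dilution_factor must be > 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.top_f0_percent < 100:
            raise ValueError("top_f0_percent must be in (0, 100)")
        if not self.E_true > 1 or not self.D_true > 0 or not self.f_m_mean > 0:
            raise ValueError("E_true > 1, D_true > 0, f_m_mean > 0 required")
        if self.f_m_cv < 0 or self.noise_sd < 0 or self.noise_mult < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if self.n_cycles < 12:
            raise ValueError("n_cycles must be >= 12")


def simulate_curve(
    params: ModelParams,
    noise_sd: float,
    n_cycles: int,
    seed,
    noise_mult: float = 0.0,
    well_id: str = "W1",
    **metadata,
) -> AmplificationCurve:
    """One trace: model values plus Gaussian noise, reproducible under seed.

    ``seed`` may be an int or a numpy Generator.  ``noise_mult`` adds a
    second noise component with SD proportional to the clean signal.
    """
    if n_cycles < 12:
        raise ValueError("n_cycles must be >= 12")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1)
    clean = eval_model(params, cycles)
    noise = rng.normal(0.0, noise_sd, n_cycles) if noise_sd > 0 else np.zeros(n_cycles)
    if noise_mult > 0:
        noise = noise + rng.normal(0.0, 1.0, n_cycles) * noise_mult * np.abs(clean)
    truth = {
        "f_m": params.f_m, "D": params.D, "E": params.E, "C_i": params.C_i,
        "a": params.a, "b": params.b,
        "f0": compute_f0(params),
        "f0_percent": compute_f0_percent(compute_f0(params), params.f_m),
    }
    return AmplificationCurve(
        well_id=well_id, cycles=cycles, fluorescence=clean + noise,
        truth=truth, **metadata,
    )


def simulate_dilution_series(design: SimulationDesign) -> list[AmplificationCurve]:
    """All wells of one dilution curve, with true_conc annotations.

    True concentrations are relative copy units: level 1 (highest) =
    dilution_factor**(n_levels-1), the lowest level = 1.
    """
    rng = np.random.default_rng(design.seed)
    curves = []
    late = False
    for level in range(1, design.n_levels + 1):
        f0pct = design.top_f0_percent / design.dilution_factor ** (level - 1)
        true_conc = design.dilution_factor ** (design.n_levels - level)
        for rep in range(1, design.n_replicates + 1):
            f_m = design.f_m_mean
            if design.f_m_cv > 0:
                f_m *= max(1.0 + rng.normal(0.0, design.f_m_cv / 100.0), 0.2)
            a = rng.uniform(*design.baseline_a_range)
            b = rng.uniform(*design.baseline_b_range)
            ci = invert_f0_to_Ci(f0pct / 100.0 * f_m, f_m, design.D_true, design.E_true)
            if ci + 2.0 > design.n_cycles:
                late = True
            params = ModelParams(f_m=f_m, D=design.D_true, E=design.E_true,
                                 C_i=ci, a=a, b=b)
            curve = simulate_curve(
                params, design.noise_sd, design.n_cycles, rng,
                noise_mult=design.noise_mult,
                well_id=f"{design.group_id}_L{level}R{rep}",
                amplicon_id=design.amplicon_id,
                group_id=design.group_id,
                dilution_level=level,
                true_conc=true_conc,
            )
            curve.truth["late_amplification"] = ci + 2.0 > design.n_cycles
            curves.append(curve)
    if late:
        warnings.warn(
            "some levels have C_i + 2 beyond the last cycle: f0% precision reduced there",
            stacklevel=2,
        )
    return curves
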
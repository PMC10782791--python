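"""The atomic input: one well's cycle-indexed fluorescence trace."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError

__all__ = ["AmplificationCurve", "MIN_CYCLES_FOR_FIT"]

#: Any fit needs the baseline window (cycles 3-8) plus an exponential region.
MIN_CYCLES_FOR_FIT = 12


@dataclass
class AmplificationCurve:
    """One qPCR reaction: fluorescence per cycle plus metadata.

    ``cycles`` are 1-based instrument cycle labels and are preserved under
    trimming/truncation (never renumbered).  ``dilution_level`` is 1 for the
    highest concentration of a dilution series.  ``truth`` optionally stores
    the generating parameters of a simulated curve for recovery tests.
    """

    well_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray
    amplicon_id: str = "amplicon"
    sample_id: str = ""
    group_id: str | None = None
    dilution_level: int | None = None
    true_conc: float | None = None
    discarded_initial_cycles: int = 0
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        self.cycles = np.asarray(self.cycles)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycles.ndim != 1 or self.fluorescence.ndim != 1:
            raise ValueError("cycles and fluorescence must be 1-D")
        if len(self.cycles) != len(self.fluorescence):
            raise ValueError(
                f"length mismatch: {len(self.cycles)} cycles vs "
                f"{len(self.fluorescence)} fluorescence readings"
            )
        if not np.issubdtype(self.cycles.dtype, np.integer):
            as_int = self.cycles.astype(int)
            if not np.array_equal(as_int, self.cycles):
                raise ValueError("cycles must be integers")
            self.cycles = as_int
        if len(self.cycles) > 1 and not np.all(np.diff(self.cycles) > 0):
            raise ValueError("cycles must be strictly increasing")

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def first_cycle(self) -> int:
        return int(self.cycles[0])

    @property
    def last_cycle(self) -> int:
        return int(self.cycles[-1])

    def replace(self, **changes) -> "AmplificationCurve":
        return dataclasses.replace(self, **changes)

    def with_fluorescence(self, values) -> "AmplificationCurve":
        return self.replace(fluorescence=np.asarray(values, dtype=float))

    def truncate_at(self, last_cycle: int, min_cycles: int = 1) -> "AmplificationCurve":
        """Keep readings with cycle label <= ``last_cycle``."""
        mask = self.cycles <= last_cycle
        if mask.sum() < min_cycles:
            raise InsufficientDataError(
                f"truncation at cycle {last_cycle} leaves {int(mask.sum())} readings "
                f"(< {min_cycles}) for well {self.well_id}"
            )
        return self.replace(cycles=self.cycles[mask], fluorescence=self.fluorescence[mask])
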
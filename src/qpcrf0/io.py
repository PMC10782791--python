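"""Plate readers/writers (CSV) and group normalization.

The canonical on-disk layout mirrors the cycles-by-wells tables qPCR
instruments export: a *wide* CSV whose first column is ``Cycle`` and whose
remaining columns are wells (fluorescence in AFU), or an equivalent *long*
CSV with columns (well_id, cycle, fluorescence).  A separate metadata CSV
attaches amplicon/sample/dilution annotations by well_id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import AmplificationCurve
from .errors import DegenerateCurveError

__all__ = ["RunConfig", "read_plate", "write_plate", "write_metadata",
           "write_truth", "normalize_group"]

METADATA_COLUMNS = ["well_id", "amplicon_id", "sample_id", "dilution_level",
                    "true_conc", "group_id"]


@dataclass
class RunConfig:
    """Resolved analysis configuration; logged in full by every CLI run."""

    threshold_multiplier: float = 100.0
    baseline_window: tuple[int, int] = (3, 8)
    trim_k: int = 0
    fixed_E: float | None = None
    significance_alpha: float = 0.05
    seed: int | None = None
    outdir: Path = field(default_factory=lambda: Path("."))


def _curves_from_wide(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    if df.columns[0].lower() != "cycle":
        raise ValueError(f"wide plate must start with a 'Cycle' column, got {df.columns[0]!r}")
    cycles = df.iloc[:, 0].to_numpy()
    wells = {}
    for col in df.columns[1:]:
        values = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        wells[str(col)] = (cycles, values)
    return wells


def _curves_from_long(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    need = {"well_id", "cycle", "fluorescence"}
    if not need.issubset(df.columns):
        raise ValueError(f"long plate needs columns {sorted(need)}, got {list(df.columns)}")
    wells = {}
    for well, sub in df.groupby("well_id", sort=False):
        sub = sub.sort_values("cycle")
        wells[str(well)] = (sub["cycle"].to_numpy(), sub["fluorescence"].to_numpy(dtype=float))
    return wells


def read_plate(
    path, fmt: str = "wide", metadata_path=None
) -> list[AmplificationCurve]:
    """Load a plate CSV (wide or long) with optional metadata join.

    Metadata rows naming wells absent from the plate are an error; plate
    wells without metadata load with defaults and a warning.
    """
    path = Path(path)
    header = path.read_text().splitlines()
    if header:
        names = [h.strip() for h in header[0].split(",")]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate well_ids in {path.name}: {sorted(dupes)}")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty or len(df.columns) < 2:
        raise ValueError(f"{path.name}: empty or malformed plate table")
    wells = _curves_from_wide(df) if fmt == "wide" else _curves_from_long(df)

    meta: dict[str, dict] = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path)
        unknown = sorted(set(mdf["well_id"].astype(str)) - set(wells))
        if unknown:
            raise ValueError(f"metadata references absent wells: {unknown}")
        for _, row in mdf.iterrows():
            level = row.get("dilution_level")
            conc = row.get("true_conc")
            meta[str(row["well_id"])] = {
                "amplicon_id": str(row.get("amplicon_id", "amplicon")),
                "sample_id": str(row.get("sample_id", "")) if pd.notna(row.get("sample_id")) else "",
                "group_id": str(row.get("group_id")) if pd.notna(row.get("group_id")) else None,
                "dilution_level": int(level) if pd.notna(level) else None,
                "true_conc": float(conc) if pd.notna(conc) else None,
            }
        missing = sorted(set(wells) - set(meta))
        if missing:
            warnings.warn(f"wells without metadata loaded with defaults: {missing}",
                          stacklevel=2)
    curves = []
    for well, (cycles, values) in wells.items():
        curves.append(AmplificationCurve(well_id=well, cycles=cycles,
                                         fluorescence=values, **meta.get(well, {})))
    return curves


def write_plate(curves: list[AmplificationCurve], path, fmt: str = "wide") -> None:
    path = Path(path)
    if fmt == "wide":
        cycles = curves[0].cycles
        for c in curves[1:]:
            if not np.array_equal(c.cycles, cycles):
                raise ValueError("wide format requires identical cycles across wells")
        df = pd.DataFrame({"Cycle": cycles})
        for c in curves:
            df[c.well_id] = c.fluorescence
    elif fmt == "long":
        df = pd.concat(
            [pd.DataFrame({"well_id": c.well_id, "cycle": c.cycles,
                           "fluorescence": c.fluorescence}) for c in curves],
            ignore_index=True,
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    # %.17g round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")


def write_metadata(curves: list[AmplificationCurve], path) -> None:
    rows = [{
        "well_id": c.well_id, "amplicon_id": c.amplicon_id, "sample_id": c.sample_id,
        "dilution_level": c.dilution_level, "true_conc": c.true_conc,
        "group_id": c.group_id,
    } for c in curves]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, index=False)


def write_truth(curves: list[AmplificationCurve], path) -> None:
    """Sidecar table of generating parameters for simulated plates."""
    rows = []
    for c in curves:
        if c.truth is None:
            continue
        rows.append({"well_id": c.well_id} | {k: v for k, v in c.truth.items()})
    pd.DataFrame(rows).to_csv(path, index=False)


def normalize_group(curves: list[AmplificationCurve]) -> list[AmplificationCurve]:
    """Divide every reaction by the single group-wide maximum fluorescence.

    Puts all reactions of a dilution curve on a common [~0, 1] scale; f0% is
    unaffected (it is scale-invariant by construction).
    """
    if not curves:
        raise ValueError("empty group")
    gmax = max(float(np.max(c.fluorescence)) for c in curves)
    if not gmax > 0:
        raise DegenerateCurveError("group maximum fluorescence is not positive")
    return [c.with_fluorescence(c.fluorescence / gmax) for c in curves]
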
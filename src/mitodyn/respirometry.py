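"""Mito-stress-test respirometry: plate parsing, background correction, profiles.

A plate run measures oxygen consumption rate (OCR, pmol O₂/min) per well
through four injection stages:

* ``baseline`` — pre-injection respiration,
* ``oligomycin`` — ATP synthase inhibited; what remains is proton leak,
* ``fccp`` — uncoupled; maximal respiration,
* ``rotenone`` — Complex I inhibited; non-mitochondrial OCR.

Derived parameters use the exact identities ``SRC = maximal − baseline`` and
``ATP-linked = baseline − leak``.  Wells without cells provide a background
trace that is subtracted, timepoint by timepoint, from every cell well;
erratic background wells are excluded by a robust (3×MAD) rule.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

STAGES = ("baseline", "oligomycin", "fccp", "rotenone")
MIN_BACKGROUND_WELLS = 3

_CSV_COLUMNS = ["well", "stage", "measurement_index", "time_s", "ocr"]


@dataclass
class PlateOCR:
    """One plate of OCR traces.

    ``data`` is tidy with columns ``well, stage, measurement_index, time_s,
    ocr``; ``background_wells`` identifies the unseeded wells.
    """

    data: pd.DataFrame
    background_wells: frozenset[str]
    cells_per_well: int | None = None
    excluded_background_wells: frozenset[str] = frozenset()

    @property
    def cell_wells(self) -> list[str]:
        return sorted(set(self.data["well"]) - self.background_wells)

    def well_trace(self, well: str) -> pd.DataFrame:
        return self.data[self.data["well"] == well]

    def validate(self) -> "PlateOCR":
        unknown = set(self.data["stage"]) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown respiration stages: {sorted(unknown)}")
        if len(self.background_wells) < MIN_BACKGROUND_WELLS:
            raise ValueError(
                f"need at least {MIN_BACKGROUND_WELLS} background wells, "
                f"got {len(self.background_wells)}"
            )
        missing = set(self.background_wells) - set(self.data["well"])
        if missing:
            raise ValueError(f"background wells absent from data: {sorted(missing)}")
        for w in self.cell_wells:
            stages = set(self.data.loc[self.data["well"] == w, "stage"])
            lacking = set(STAGES) - stages
            if lacking:
                raise ValueError(f"well {w} missing stages {sorted(lacking)}")
        return self


@dataclass(frozen=True)
class RespirationProfile:
    """Respiration parameters for one well (pmol O₂/min).

    ``baseline``, ``leak`` and ``maximal`` are corrected for both the plate
    background and the non-mitochondrial (rotenone-stage) OCR, so the two
    identities ``src == maximal - baseline`` and ``atp_linked == baseline -
    leak`` hold exactly.  ``flagged`` marks physiologically implausible
    profiles (negative maximal respiration after correction).
    """

    well: str
    baseline: float
    leak: float
    maximal: float
    nonmito: float
    src: float
    atp_linked: float
    flagged: bool = False
    notes: tuple[str, ...] = ()


def parse_plate(
    source: str | Path | io.IOBase | pd.DataFrame,
    *,
    background_wells: Sequence[str] | None = None,
    cells_per_well: int | None = None,
) -> PlateOCR:
    """Read a tidy plate CSV into a validated :class:`PlateOCR`.

    The CSV must carry columns ``well, stage, measurement_index, time_s,
    ocr`` and may carry ``is_background`` (0/1).  Background wells are taken
    from the ``background_wells`` argument, else from ``is_background``,
    else from well ids starting with ``"BG"``.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV missing columns {missing}")
    if background_wells is not None:
        bg = frozenset(background_wells)
    elif "is_background" in df.columns:
        bg = frozenset(df.loc[df["is_background"].astype(bool), "well"])
    else:
        bg = frozenset(w for w in df["well"].unique() if str(w).startswith("BG"))
    plate = PlateOCR(
        data=df[_CSV_COLUMNS].copy(),
        background_wells=bg,
        cells_per_well=cells_per_well,
    )
    return plate.validate()


def background_correct(plate: PlateOCR) -> PlateOCR:
    """Subtract the mean background OCR from every cell well, per timepoint.

    Background wells whose trace median deviates from the across-well median
    by more than 3 scaled median absolute deviations (MAD × 1.4826) are
    excluded as erratic before averaging.  With noiseless identical
    background traces the MAD is zero and any deviating well is excluded.
    Background wells are removed from the corrected plate.
    """
    plate.validate()
    df = plate.data
    bg_df = df[df["well"].isin(plate.background_wells)]
    medians = bg_df.groupby("well")["ocr"].median()
    center = float(medians.median())
    mad = float(np.median(np.abs(medians - center)))
    cutoff = 3.0 * 1.4826 * mad
    keep = medians.index[np.abs(medians - center) <= cutoff]
    excluded = frozenset(medians.index) - frozenset(keep)
    if len(keep) == 0:
        raise ValueError("all background wells excluded as erratic")
    correction = (
        bg_df[bg_df["well"].isin(keep)]
        .groupby(["stage", "measurement_index"])["ocr"]
        .mean()
    )
    cells = df[~df["well"].isin(plate.background_wells)].copy()
    key = pd.MultiIndex.from_frame(cells[["stage", "measurement_index"]])
    cells["ocr"] = cells["ocr"].to_numpy() - correction.reindex(key).to_numpy()
    if cells["ocr"].isna().any():
        raise ValueError("background trace does not cover all cell-well timepoints")
    return replace(
        plate,
        data=cells.reset_index(drop=True),
        background_wells=frozenset(),
        excluded_background_wells=excluded,
    )


def compute_profile(
    trace: pd.DataFrame,
    *,
    well: str | None = None,
    nonmito_correct: bool = True,
    cells_per_well: int | None = None,
    per_cell: bool = False,
) -> RespirationProfile:
    """Respiration parameters from one background-corrected well trace.

    Each stage value is the mean of that stage's measurements.  The
    rotenone-stage mean is the non-mitochondrial OCR and, by default, is
    subtracted from the baseline/oligomycin/fccp stage means before the
    derived parameters are formed (``nonmito_correct=False`` restores the
    uncorrected stage means).  ``per_cell=True`` divides everything by the
    seeded cell count.
    """
    lacking = set(STAGES) - set(trace["stage"])
    if lacking:
        raise ValueError(f"trace missing stages {sorted(lacking)}")
    if well is None:
        wells = trace["well"].unique()
        if len(wells) != 1:
            raise ValueError("trace must contain exactly one well (or pass well=)")
        well = str(wells[0])
    means = trace.groupby("stage")["ocr"].mean()
    nonmito = float(means["rotenone"])
    offset = nonmito if nonmito_correct else 0.0
    baseline = float(means["baseline"]) - offset
    leak = float(means["oligomycin"]) - offset
    maximal = float(means["fccp"]) - offset
    scale = 1.0
    notes: list[str] = []
    if per_cell:
        if not cells_per_well or cells_per_well <= 0:
            raise ValueError("per-cell normalization requires a positive cell count")
        scale = 1.0 / cells_per_well
        notes.append(f"per-cell normalized by {cells_per_well} cells")
    flagged = maximal < 0
    if flagged:
        notes.append("negative maximal respiration after correction")
    return RespirationProfile(
        well=well,
        baseline=baseline * scale,
        leak=leak * scale,
        maximal=maximal * scale,
        nonmito=nonmito * scale,
        src=(maximal - baseline) * scale,
        atp_linked=(baseline - leak) * scale,
        flagged=flagged,
        notes=tuple(notes),
    )


def analyze_plate(
    plate: PlateOCR,
    *,
    nonmito_correct: bool = True,
    per_cell: bool = False,
) -> list[RespirationProfile]:
    """Background-correct a plate and compute one profile per cell well."""
    corrected = background_correct(plate)
    return [
        compute_profile(
            corrected.well_trace(w),
            well=w,
            nonmito_correct=nonmito_correct,
            cells_per_well=plate.cells_per_well,
            per_cell=per_cell,
        )
        for w in corrected.cell_wells
    ]


def summarize_profiles(profiles: Sequence[RespirationProfile]) -> pd.DataFrame:
    """Group mean ± SD table over per-well profiles."""
    if not profiles:
        raise ValueError("no profiles to summarize")
    df = pd.DataFrame(
        {
            "baseline": [p.baseline for p in profiles],
            "leak": [p.leak for p in profiles],
            "maximal": [p.maximal for p in profiles],
            "nonmito": [p.nonmito for p in profiles],
            "src": [p.src for p in profiles],
            "atp_linked": [p.atp_linked for p in profiles],
        }
    )
    return df.agg(["mean", "std"]).T.rename(columns={"std": "sd"})
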
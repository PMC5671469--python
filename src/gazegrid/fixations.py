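"""Mapping fixation sequences onto the scene grid.

A fixation report (one row per fixation, with subject, image, ordinal
index and pixel coordinates) is converted, per trial, into a per-cell
binary "fixated" indicator and a fixation count.  Two rules apply:

* The trial-initial fixation (the one continuing from the pre-trial
  fixation cross) is excluded, and the cell it fell on is excluded from
  the trial entirely — later revisits to that cell are discarded too.
* Fixations landing outside the image are dropped with a log message;
  real eye-tracker exports routinely contain them.

Cell membership follows the half-open rectangle convention of the
regions module, so boundary fixations belong to the cell to their
right/below and the assignment is a partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import RegionSet

log = logging.getLogger(__name__)

__all__ = [
    "OUTSIDE",
    "FixationRecord",
    "TrialGridResponse",
    "ExclusionResult",
    "read_fixation_report",
    "assign_fixation_to_cell",
    "apply_initial_fixation_exclusion",
    "trial_responses",
    "all_trial_responses",
]

#: Sentinel cell index for fixations outside the image.
OUTSIDE = -1

#: Default column names of a fixation report; a mapping from these names
#: to the actual columns of an eye-tracker export can be supplied when
#: reading.
REPORT_COLUMNS = ("subject", "image", "fix_index", "fix_x", "fix_y", "onset_ms", "duration_ms")


@dataclass(frozen=True)
class FixationRecord:
    subject: str
    image: str
    fix_index: int  # 1-based ordinal within the trial
    x: float
    y: float
    onset_ms: float = np.nan
    duration_ms: float = np.nan


@dataclass
class TrialGridResponse:
    """Per-cell responses for one (subject, image) trial.

    ``excluded_cell`` is the grid cell of the trial-initial fixation
    (``None`` when that fixation fell outside the image); it carries no
    response values.
    """

    subject: str
    image: str
    fixated: np.ndarray  # (n_cells,) 0/1
    count: np.ndarray  # (n_cells,) non-negative int
    excluded_cell: int | None


def read_fixation_report(
    path: str | Path,
    *,
    sep: str | None = None,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a tab- or comma-delimited fixation report with a header row.

    ``column_map`` maps standard names (subject, image, fix_index, fix_x,
    fix_y, onset_ms, duration_ms) to the column names used in the file,
    so a standard fixation-report export can be column-mapped directly.
    The delimiter is sniffed when not given.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REPORT_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"fixation report is missing columns: {missing}")
    for c in ("onset_ms", "duration_ms"):
        if c not in df.columns:
            df[c] = np.nan
    df = df[list(REPORT_COLUMNS)].copy()
    df["subject"] = df["subject"].astype(str)
    df["image"] = df["image"].astype(str)
    if not np.isfinite(df[["fix_x", "fix_y"]].to_numpy()).all():
        raise ValueError("fixation coordinates must be finite")
    bad = df.groupby(["subject", "image"])["fix_index"].apply(
        lambda s: not s.is_monotonic_increasing or s.duplicated().any()
    )
    if bad.any():
        raise ValueError(
            f"fixation indices not strictly increasing within trials: "
            f"{list(bad[bad].index[:5])}"
        )
    return df


def assign_fixation_to_cell(x: float, y: float, regions: RegionSet) -> int:
    """Cell index containing pixel (x, y), or ``OUTSIDE``.

    Only grid region sets are supported here (constant-time index
    arithmetic); membership is half-open, so x = cell boundary belongs to
    the cell on the right.
    """
    if regions.grid_shape is None or regions.cell_size is None:
        raise ValueError("assign_fixation_to_cell requires a grid RegionSet")
    cols, rows = regions.grid_shape
    cw, ch = regions.cell_size
    if not (0 <= x < cols * cw and 0 <= y < rows * ch):
        return OUTSIDE
    return int(y // ch) * cols + int(x // cw)


def _assign_many(xs: np.ndarray, ys: np.ndarray, regions: RegionSet) -> np.ndarray:
    cols, rows = regions.grid_shape
    cw, ch = regions.cell_size
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    inside = (xs >= 0) & (xs < cols * cw) & (ys >= 0) & (ys < rows * ch)
    cells = np.full(xs.shape, OUTSIDE, dtype=int)
    cells[inside] = (ys[inside] // ch).astype(int) * cols + (xs[inside] // cw).astype(int)
    return cells


@dataclass(frozen=True)
class ExclusionResult:
    """Retained fixation cells after the initial-fixation exclusion."""

    retained: np.ndarray
    excluded_cell: int | None


def apply_initial_fixation_exclusion(
    cells: "Sequence[int] | ExclusionResult",
) -> ExclusionResult:
    """Drop the trial-initial fixation and every revisit of its cell.

    ``cells`` are the grid-cell indices of a trial's fixations in order
    (``OUTSIDE`` allowed).  Returns the retained cell indices and the
    excluded cell (``None`` when the initial fixation was outside the
    image, in which case only that fixation is dropped).  Applying the
    rule to an already-excluded result is a no-op, so re-running it is
    idempotent.
    """
    if isinstance(cells, ExclusionResult):
        return cells
    cells = np.asarray(cells, dtype=int)
    if cells.size == 0:
        raise ValueError("trial has no fixations")
    first = int(cells[0])
    rest = cells[1:]
    if first == OUTSIDE:
        log.info("trial-initial fixation outside image: no cell excluded")
        return ExclusionResult(rest.copy(), None)
    return ExclusionResult(rest[rest != first], first)


def trial_responses(
    subject: str,
    image: str,
    retained_cells: Sequence[int],
    regions: RegionSet,
    excluded_cell: int | None,
) -> TrialGridResponse:
    """Per-cell count and fixated indicator from retained fixations.

    Immediate refixations and later revisits each count; out-of-image
    fixations are dropped (logged).
    """
    n = len(regions)
    retained = np.asarray(retained_cells, dtype=int)
    outside = retained == OUTSIDE
    if outside.any():
        log.info(
            "trial (%s, %s): dropping %d out-of-image fixation(s)",
            subject, image, int(outside.sum()),
        )
    count = np.bincount(retained[~outside], minlength=n).astype(int)
    fixated = (count >= 1).astype(int)
    return TrialGridResponse(
        subject=subject,
        image=image,
        fixated=fixated,
        count=count,
        excluded_cell=excluded_cell,
    )


def all_trial_responses(
    report: pd.DataFrame,
    regions: RegionSet,
    *,
    exclude_initial: bool = True,
) -> list[TrialGridResponse]:
    """Process every (subject, image) trial of a fixation report.

    Trials absent from the report simply produce no responses; the
    observation matrix is built from trials for which fixation data
    exist.
    """
    report = report.sort_values(["subject", "image", "fix_index"], kind="stable")
    out: list[TrialGridResponse] = []
    for (subject, image), tr in report.groupby(["subject", "image"], sort=True):
        cells = _assign_many(tr["fix_x"].to_numpy(), tr["fix_y"].to_numpy(), regions)
        if exclude_initial:
            excl = apply_initial_fixation_exclusion(cells)
            retained, excluded = excl.retained, excl.excluded_cell
        else:
            retained, excluded = cells, None
        out.append(trial_responses(str(subject), str(image), retained, regions, excluded))
    return out
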
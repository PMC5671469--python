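"""Assembly of the long-format observation matrix.

One row per available (subject, image, cell), carrying the binary
``fixated`` response, the fixation ``count``, and one column per
per-(image, cell) predictor.  Excluded cells (from the initial-fixation
rule) and missing trials produce no rows.  For a fully crossed design of
150 images x 42 subjects x 48 cells with no exclusions the matrix would
have 302,400 rows; eight missing trials reduce it to 302,016.

Predictors are standardized over the rows that actually enter the model
(z-transform, sample SD with the n-1 denominator); raw columns are
retained and standardized copies get a ``_z`` suffix.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fixations import TrialGridResponse

__all__ = [
    "predictor_frame",
    "assemble",
    "standardize",
    "correlate_predictors",
    "stack_for_comparison",
    "export",
]

_KEY = ["subject", "image", "cell"]


def predictor_frame(per_image_cell: Mapping[str, Mapping[str, np.ndarray]]) -> pd.DataFrame:
    """Build a tidy (image, cell) predictor table.

    ``per_image_cell[name][image_id]`` is the per-cell vector of predictor
    ``name`` for that image; all vectors must share length.
    """
    names = list(per_image_cell)
    if not names:
        raise ValueError("no predictors supplied")
    frames = []
    for image_id, vec in per_image_cell[names[0]].items():
        n = len(vec)
        row = {"image": str(image_id), "cell": np.arange(n)}
        for name in names:
            v = np.asarray(per_image_cell[name][image_id], dtype=float)
            if len(v) != n:
                raise ValueError(f"predictor {name!r} length mismatch for image {image_id!r}")
            row[name] = v
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)


def assemble(trials: Sequence[TrialGridResponse], predictors: pd.DataFrame) -> pd.DataFrame:
    """Join trial responses with per-(image, cell) predictors.

    ``predictors`` must have ``image`` and ``cell`` columns covering every
    (image, cell) pair present in ``trials``; a missing pair is an error.
    Rows for each trial's excluded cell are dropped.
    """
    if not len(trials):
        raise ValueError("no trials supplied")
    n = len(trials[0].fixated)
    cells = np.arange(n)
    keep_masks = np.ones((len(trials), n), dtype=bool)
    for i, t in enumerate(trials):
        if len(t.fixated) != n:
            raise ValueError("trials disagree on the number of cells")
        if t.excluded_cell is not None:
            keep_masks[i, t.excluded_cell] = False
    keep = keep_masks.reshape(-1)
    table = pd.DataFrame(
        {
            "subject": np.repeat(np.array([t.subject for t in trials], dtype=object), n)[keep],
            "image": np.repeat(np.array([t.image for t in trials], dtype=object), n)[keep],
            "cell": np.tile(cells, len(trials))[keep],
            "fixated": np.concatenate([t.fixated for t in trials])[keep],
            "count": np.concatenate([t.count for t in trials])[keep],
        }
    )
    predictors = predictors.copy()
    predictors["image"] = predictors["image"].astype(str)
    merged = table.merge(predictors, on=["image", "cell"], how="left", validate="many_to_one")
    pred_cols = [c for c in predictors.columns if c not in ("image", "cell")]
    if merged[pred_cols].isna().any().any():
        bad = merged.loc[merged[pred_cols].isna().any(axis=1), ["image", "cell"]].drop_duplicates()
        raise ValueError(
            f"predictor values missing for (image, cell) pairs, e.g. "
            f"{bad.head(3).to_records(index=False).tolist()}"
        )
    if merged.duplicated(_KEY).any():
        raise ValueError("duplicate (subject, image, cell) rows")
    return merged


def standardize(table: pd.DataFrame, columns: Iterable[str], *, suffix: str = "_z") -> pd.DataFrame:
    """Add z-transformed copies of the named columns (mean 0, SD 1).

    The sample SD (n-1 denominator) is computed over the rows of the
    table, i.e. over the observations entering the model.  Raw columns
    are kept.  A constant column has no SD and is rejected by name.
    """
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize constant column {col!r}")
        out[col + suffix] = (x - x.mean()) / sd
    return out


def correlate_predictors(table: pd.DataFrame, col_a: str, col_b: str) -> float:
    """Spearman rank correlation between two predictors over (image, cell).

    The correlation is computed on one row per (image, cell) — predictor
    values are a property of the stimulus, not of the subject — so
    subject replication does not inflate n.
    """
    per_cell = table.drop_duplicates(["image", "cell"])
    if len(per_cell) < 3:
        raise ValueError("need at least 3 distinct (image, cell) pairs")
    a = per_cell[col_a].to_numpy(dtype=float)
    b = per_cell[col_b].to_numpy(dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("cannot rank-correlate a constant column")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def stack_for_comparison(
    table: pd.DataFrame,
    saliency_columns: Mapping[str, str],
    *,
    map_column: str = "map",
    value_column: str = "saliency",
) -> pd.DataFrame:
    """Stack the table long with one replicate per saliency map.

    ``saliency_columns`` maps map labels to the per-map saliency column
    names.  Each (subject, image, cell) row is replicated once per map
    with its label in ``map_column`` and its saliency value in
    ``value_column`` — the structure required to express a saliency-map
    factor and its interactions; the response is shared across
    replicates.
    """
    parts = []
    for label, col in saliency_columns.items():
        part = table.copy()
        part[map_column] = label
        part[value_column] = part[col]
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    if out.duplicated(_KEY + [map_column]).any():
        raise ValueError("duplicate (subject, image, cell, map) rows after stacking")
    return out


def export(table: pd.DataFrame, path: str | Path) -> None:
    """Write the observation matrix as a comma-separated file.

    Header row, stable column order, '.' decimal point regardless of
    locale (pandas default), full float precision so a round trip is
    lossless to 1e-12.
    """
    table.to_csv(path, index=False)
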
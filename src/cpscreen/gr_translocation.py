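"""Glucocorticoid-receptor nuclear-translocation scoring.

Upon agonist binding the GR moves from cytoplasm to nucleus.  A cell is
called nuclear-enriched when ALL six intensity-ratio criteria hold
(strict inequalities; cells on a boundary fail):

    GR nuc sum  / Hoechst nuc sum  > 0.35
    GR nuc sum  / GR cyto sum      > 0.25
    GR nuc mean / GR cyto mean     > 1.7
    GR nuc median / GR cyto median > 1.7
    GR nuc quantile / GR cyto quantile > 1.7
    GR nuc contrast / GR cyto contrast > 0.3

Cells with a non-positive denominator are excluded from both numerator and
denominator of the well summary.  The well summary is the percent of valid
cells that are nuclear-enriched, pooled over cells by default with a
per-field option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CPScreenError, get_logger

log = get_logger(__name__)

#: (numerator column, denominator column, strict lower threshold)
CRITERIA = (
    ("gr_nuc_sum", "hoechst_nuc_sum", 0.35),
    ("gr_nuc_sum", "gr_cyto_sum", 0.25),
    ("gr_nuc_mean", "gr_cyto_mean", 1.7),
    ("gr_nuc_median", "gr_cyto_median", 1.7),
    ("gr_nuc_quantile", "gr_cyto_quantile", 1.7),
    ("gr_nuc_contrast", "gr_cyto_contrast", 0.3),
)


@dataclass(frozen=True)
class GRCellRecord:
    """Intensity measurements of one segmented cell in the GR assay."""

    hoechst_nuc_sum: float
    gr_nuc_mean: float
    gr_nuc_median: float
    gr_nuc_sum: float
    gr_nuc_quantile: float
    gr_nuc_contrast: float
    gr_cyto_mean: float
    gr_cyto_median: float
    gr_cyto_sum: float
    gr_cyto_quantile: float
    gr_cyto_contrast: float


def _as_frame(cells) -> pd.DataFrame:
    if isinstance(cells, pd.DataFrame):
        return cells
    return pd.DataFrame([c.__dict__ if hasattr(c, "__dict__") else vars(c) for c in cells])


def classify_nuclear_enriched(cell: GRCellRecord | dict) -> bool:
    """True iff all six strict ratio criteria hold.

    Raises on a non-positive denominator — such cells must be excluded from
    well summaries, not classified.
    """
    values = cell if isinstance(cell, dict) else vars(cell)
    for _, den, _ in CRITERIA:
        if values[den] <= 0:
            raise CPScreenError(
                f"non-positive denominator {den}={values[den]}; cell must be excluded"
            )
    return all(values[num] / values[den] > threshold for num, den, threshold in CRITERIA)


def classify_cells(cells) -> pd.DataFrame:
    """Vectorized classification of a cell table.

    Returns the table with ``valid`` (all denominators positive) and
    ``nuclear_enriched`` columns; invalid cells are flagged, never
    classified.
    """
    df = _as_frame(cells).copy()
    denominators = {den for _, den, _ in CRITERIA}
    valid = np.ones(len(df), dtype=bool)
    for den in denominators:
        valid &= df[den].to_numpy(dtype=float) > 0
    n_excluded = int((~valid).sum())
    if n_excluded:
        log.info("GR classification: excluded %d cells with non-positive denominators", n_excluded)
    enriched = valid.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        for num, den, threshold in CRITERIA:
            ratio = df[num].to_numpy(dtype=float) / df[den].to_numpy(dtype=float)
            enriched &= ratio > threshold
    df["valid"] = valid
    df["nuclear_enriched"] = enriched & valid
    return df


def percent_nuclear(cells, per_field: bool = False):
    """Percent of valid cells with nuclear-enriched GR signal.

    Pooled over all cells by default; with ``per_field=True`` (requires a
    ``field`` column) the percent is computed per field of view and
    averaged.  Returns NaN, flagged in the log, when no valid cells remain.
    """
    df = classify_cells(cells)
    if per_field:
        if "field" not in df.columns:
            raise CPScreenError("per_field summary needs a 'field' column")
        per = (
            df[df["valid"]]
            .groupby("field")["nuclear_enriched"]
            .mean()
            .mul(100.0)
        )
        if per.empty:
            log.warning("percent_nuclear: no valid cells in any field")
            return float("nan")
        return float(per.mean())
    n_valid = int(df["valid"].sum())
    if n_valid == 0:
        log.warning("percent_nuclear: no valid cells; value is missing")
        return float("nan")
    return 100.0 * float(df["nuclear_enriched"].sum()) / n_valid


def well_summary(cells: pd.DataFrame, well_column: str = "well") -> pd.DataFrame:
    """Per-well GR summary: percent nuclear, valid and excluded counts."""
    df = classify_cells(cells)
    rows = []
    for well, grp in df.groupby(well_column):
        n_valid = int(grp["valid"].sum())
        rows.append(
            {
                "well": well,
                "percent_nuclear": (
                    100.0 * float(grp["nuclear_enriched"].sum()) / n_valid if n_valid else float("nan")
                ),
                "n_valid": n_valid,
                "n_excluded": int((~grp["valid"]).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["well", "percent_nuclear", "n_valid", "n_excluded"])
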
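"""HistDiff fingerprinting: per-well, per-feature histogram-difference
scores against the plate's pooled reference-control population.

For each feature, the cell-value histogram of a treated well is compared to
the histogram of the pooled reference-control cells of the same plate.
Histograms share bin edges (20 uniform bins spanning the plate's pooled
per-feature range), are smoothed once with a 3-tap (0.25, 0.5, 0.25) kernel
and normalized to unit sum.  The score is

    sign * sum_b (T_b - R_b)^2

with the sign set by the bin-midpoint-weighted mean displacement of the
treatment histogram relative to the reference — positive when the treated
population shifted to higher values.  The score is dimensionless, zero for
identical histograms and bounded by 2 in magnitude for unit-sum histograms.

Plates with staining stripes are handled by block normalization:
the plate is partitioned into row blocks, each block is fingerprinted
independently against its own reference wells, and the per-block results
are concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PLATE_ROWS, CPScreenError, PlateMap, SingleCellTable, get_logger

log = get_logger(__name__)

DEFAULT_BINS = 20
SMOOTHING_KERNEL = (0.25, 0.5, 0.25)
DEFAULT_MIN_CELLS = 10


@dataclass
class FeatureHistogram:
    """Smoothed, unit-normalized histogram of one feature in one population."""

    feature: str
    bin_edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise CPScreenError(f"{self.feature}: bin edges not strictly increasing")
        if len(self.density) != len(self.bin_edges) - 1:
            raise CPScreenError(f"{self.feature}: density/edge length mismatch")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean(self) -> float:
        return float(np.dot(self.midpoints, self.density))


def _smooth(counts: np.ndarray) -> np.ndarray:
    """One pass of the (0.25, 0.5, 0.25) kernel along the last axis,
    truncated at the edges (same as ``np.convolve(..., mode='same')``)."""
    out = 0.5 * counts
    out[..., 1:] += 0.25 * counts[..., :-1]
    out[..., :-1] += 0.25 * counts[..., 1:]
    return out


def build_histogram(values, bin_edges, feature: str = "") -> FeatureHistogram:
    """Bin cell values (half-open bins, last bin closed), smooth, normalize.

    Raises on an empty value list — an empty well has no histogram.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise CPScreenError(f"{feature or 'feature'}: empty well, no values to bin")
    counts, edges = np.histogram(values, bins=np.asarray(bin_edges, dtype=float))
    smoothed = _smooth(counts.astype(float))
    total = smoothed.sum()
    return FeatureHistogram(feature=feature, bin_edges=edges, density=smoothed / total)


def histdiff_score(treatment: FeatureHistogram, reference: FeatureHistogram) -> float:
    """Signed sum of squared density differences between two histograms
    sharing bin edges; sign from the treatment-vs-reference mean shift."""
    if not np.array_equal(treatment.bin_edges, reference.bin_edges):
        raise CPScreenError("histograms have mismatched bin edges")
    d = treatment.density - reference.density
    s = float(np.dot(d, d))
    if s == 0.0:
        return 0.0
    sign = -1.0 if treatment.mean < reference.mean else 1.0
    return sign * s


def _uniform_edges(lo: np.ndarray, hi: np.ndarray, bins: int) -> np.ndarray:
    """Per-feature uniform bin edges over [lo, hi]; degenerate (zero-range)
    features fall back to [v - 0.5, v + 0.5]."""
    lo = lo.astype(float).copy()
    hi = hi.astype(float).copy()
    degenerate = hi <= lo
    lo[degenerate] -= 0.5
    hi[degenerate] += 0.5
    steps = np.arange(bins + 1) / bins
    return lo[:, None] + steps[None, :] * (hi - lo)[:, None]


def _well_densities(
    x: np.ndarray, well_codes: np.ndarray, n_wells: int, lo: np.ndarray, hi: np.ndarray, bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-well, per-feature bin counts via arithmetic binning.

    Returns (counts[n_wells, F, bins], cells_per_well).  Uniform bins make
    binning a vectorized floor; values at the top edge close into the last
    bin, matching :func:`build_histogram`'s convention.
    """
    n_cells, f = x.shape
    counts = np.zeros((n_wells, f, bins), dtype=np.float64)
    inv_width = bins / (hi - lo)
    chunk = max(1, int(8_000_000 / max(n_cells, 1)))
    base = well_codes.astype(np.int64) * bins
    for start in range(0, f, chunk):
        stop = min(start + chunk, f)
        idx = (x[:, start:stop].astype(np.float64) - lo[start:stop]) * inv_width[start:stop]
        idx = np.clip(idx.astype(np.int64), 0, bins - 1)
        for j in range(start, stop):
            flat = np.bincount(base + idx[:, j - start], minlength=n_wells * bins)
            counts[:, j, :] += flat.reshape(n_wells, bins)
    cells = np.bincount(well_codes, minlength=n_wells)
    return counts, cells


def _score_block(
    counts: np.ndarray, ref_counts: np.ndarray
) -> np.ndarray:
    """HistDiff scores for all wells × features from raw bin counts.

    ``ref_counts`` is either one pooled reference (F, B) or a per-well
    reference (n_wells, F, B) — the latter carries leave-one-out pools for
    the reference wells themselves.
    """
    bins = counts.shape[-1]
    dens = _smooth(counts)
    totals = dens.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(totals > 0, dens / np.where(totals > 0, totals, 1.0), np.nan)
    ref = _smooth(ref_counts)
    ref = ref / ref.sum(axis=-1, keepdims=True)
    if ref.ndim == 2:
        ref = ref[None, :, :]
    d = dens - ref
    s = np.sum(d * d, axis=-1)
    # sign from midpoint-weighted mean shift; midpoints are affine in the bin
    # index, and sum(d)=0 kills the affine offset, so bin indices suffice
    w = np.arange(bins) + 0.5
    shift = np.sum(d * w, axis=-1)
    scores = np.where(shift < 0, -s, s)
    scores[s == 0.0] = 0.0
    return scores


def _fingerprint_wells(
    table: SingleCellTable,
    well_labels: list[str],
    reference_labels: list[str],
    bins: int,
    min_cells: int,
) -> tuple[pd.DataFrame, dict]:
    feats = table.feature_names
    data = table.data[table.data["well"].isin(well_labels)]
    code_of = {w: i for i, w in enumerate(well_labels)}
    well_codes = data["well"].map(code_of).to_numpy()
    x = data[feats].to_numpy()
    if x.shape[0] == 0:
        raise CPScreenError("no cells in any scored well")
    lo = x.min(axis=0).astype(np.float64)
    hi = x.max(axis=0).astype(np.float64)
    degenerate = hi <= lo
    lo[degenerate] -= 0.5
    hi[degenerate] += 0.5
    counts, cells = _well_densities(x, well_codes, len(well_labels), lo, hi, bins)
    ref_idx = [code_of[w] for w in reference_labels if cells[code_of[w]] > 0]
    if not ref_idx:
        raise CPScreenError("reference wells contain no cells")
    ref_counts = counts[ref_idx].sum(axis=0)
    # reference wells are scored leave-one-out (own cells removed from the
    # pool) so their null score distribution is exchangeable with untreated
    # wells; with a single reference well the full pool is the only option
    per_well_ref = np.broadcast_to(ref_counts, counts.shape).copy()
    if len(ref_idx) > 1:
        per_well_ref[ref_idx] = ref_counts[None, :, :] - counts[ref_idx]
    scores = _score_block(counts, per_well_ref)
    fp = pd.DataFrame(scores, index=pd.Index(well_labels, name="well"), columns=feats)
    info = {
        "bins": bins,
        "n_reference_wells": len(ref_idx),
        "n_reference_cells": int(cells[ref_idx].sum()),
        "low_count_wells": [w for w in well_labels if 0 < cells[code_of[w]] < min_cells],
        "empty_wells": [w for w in well_labels if cells[code_of[w]] == 0],
        "cells_per_well": {w: int(cells[code_of[w]]) for w in well_labels},
    }
    for w in info["low_count_wells"]:
        log.warning("well %s: only %d cells (< %d); fingerprint flagged", w, info["cells_per_well"][w], min_cells)
    for w in info["empty_wells"]:
        log.warning("well %s: empty; fingerprint is all-missing", w)
    return fp, info


def fingerprint_plate(
    table: SingleCellTable,
    platemap: PlateMap,
    bins: int = DEFAULT_BINS,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.DataFrame:
    """One HistDiff fingerprint per non-dye well of a plate.

    The per-feature reference histogram pools the cells of all
    reference-control wells of the same plate.  Wells with fewer than
    ``min_cells`` cells are emitted but flagged (in the log and in
    ``.attrs``); empty wells yield all-missing fingerprints.
    """
    fp, info = _fingerprint_wells(
        table, platemap.scored_wells, platemap.reference_wells, bins, min_cells
    )
    fp.attrs.update(info)
    return fp


def parse_blocks(spec: str) -> list[set[str]]:
    """Parse a row-block spec like ``"A-H,I-P"`` into row-letter sets."""
    blocks = []
    for part in spec.split(","):
        part = part.strip()
        if "-" in part:
            a, b = part.split("-")
            i, j = PLATE_ROWS.index(a.strip()), PLATE_ROWS.index(b.strip())
            blocks.append(set(PLATE_ROWS[i : j + 1]))
        else:
            blocks.append(set(part))
    return blocks


def fingerprint_plate_blocked(
    table: SingleCellTable,
    platemap: PlateMap,
    blocks: list[set[str]] | str,
    bins: int = DEFAULT_BINS,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> pd.DataFrame:
    """Block-normalized HistDiff: each row block is fingerprinted
    independently against only its own reference wells, then the block
    results are concatenated into one plate matrix.

    Used to recover plates with staining stripes — the many randomly placed
    reference wells give each block enough reference representation.
    """
    if isinstance(blocks, str):
        blocks = parse_blocks(blocks)
    covered: set[str] = set()
    for b in blocks:
        overlap = covered & b
        if overlap:
            raise CPScreenError(f"blocks overlap on rows {sorted(overlap)}")
        covered |= b
    missing_rows = {w.address.row for w in platemap.wells} - covered
    if missing_rows:
        raise CPScreenError(f"blocks do not cover rows {sorted(missing_rows)}")
    pieces = []
    infos = []
    for b in blocks:
        wells = [w for w in platemap.scored_wells if w[0] in b]
        refs = [w for w in platemap.reference_wells if w[0] in b]
        if not wells:
            continue
        if not refs:
            raise CPScreenError(
                f"block {''.join(sorted(b))} contains no reference_control wells"
            )
        fp, info = _fingerprint_wells(table, wells, refs, bins, min_cells)
        pieces.append(fp)
        infos.append({"rows": "".join(sorted(b)), **{k: info[k] for k in ("n_reference_wells", "n_reference_cells")}})
    out = pd.concat(pieces)
    out = out.loc[[w for w in platemap.scored_wells if w in out.index]]
    out.attrs["blocks"] = infos
    out.attrs["bins"] = bins
    return out
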
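"""CP Activity scoring, activity thresholds and illumination summaries.

The CP Activity Score condenses a HistDiff fingerprint into a single
non-negative magnitude of phenotypic perturbation:

    CPscore = (1/n) * sum_i x_i^2

with x_i the per-feature HistDiff scores and n the number of features.
Wells are called *active* when their score exceeds a threshold derived from
the reference-control score distribution by one of three methods:

* ``iqr``   — drop controls above the third quartile as outliers; the
  highest remaining control is the threshold;
* ``fdr5``  — drop the top q (default 5%) of controls; the highest
  remaining control is the threshold;
* ``elbow`` — sort all scores ascending and take the knee (the point of
  maximum perpendicular distance to the first-to-last chord, on axes
  normalized to [0, 1]).

The illumination summary partitions compounds into a Venn of
active-in-both / activated-only / resting-only / dark, quantifying how much
phenotypic dark space cell activation illuminates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CPScreenError, PlateMap, get_logger

log = get_logger(__name__)

VENN_CATEGORIES = ("both", "activated_only", "resting_only", "dark")


@dataclass
class ThresholdResult:
    """An activity threshold plus the provenance needed to audit it."""

    method: str
    value: float
    provenance: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return self.value


def cp_activity_score(fingerprint) -> float:
    """Mean of squared HistDiff feature scores.

    Missing features are excluded from both numerator and denominator (and
    logged); an all-missing fingerprint is an error.
    """
    x = np.asarray(fingerprint, dtype=float)
    valid = np.isfinite(x)
    if not valid.any():
        raise CPScreenError("all-missing fingerprint has no CP Activity Score")
    n_missing = int((~valid).sum())
    if n_missing:
        log.info("cp_activity_score: excluded %d missing features", n_missing)
    v = x[valid]
    return float(np.dot(v, v) / v.size)


def cp_activity_scores(fingerprints: pd.DataFrame) -> pd.Series:
    """Row-wise CP Activity Scores of a fingerprint matrix."""
    x = fingerprints.to_numpy(dtype=float)
    valid = np.isfinite(x)
    n = valid.sum(axis=1)
    if (n == 0).any():
        bad = fingerprints.index[n == 0].tolist()
        log.warning("wells with all-missing fingerprints get no score: %s", bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.nansum(x * x, axis=1) / np.where(n > 0, n, 1)
    s[n == 0] = np.nan
    return pd.Series(s, index=fingerprints.index, name="cp_score")


def threshold_iqr(control_scores, fence: str = "above_q3") -> ThresholdResult:
    """IQR threshold: the highest-scoring control at or below Q3.

    Controls above the 75th percentile are excluded as outliers (they do
    not conform to the bell of the control distribution); the highest
    remaining control is the threshold.  ``fence="tukey"`` instead uses the
    conventional Q3 + 1.5*IQR fence, for sensitivity analysis.
    """
    s = np.asarray(control_scores, dtype=float)
    if s.size < 4:
        raise CPScreenError("IQR threshold needs at least 4 control scores")
    q1, q3 = np.quantile(s, [0.25, 0.75])  # linear interpolation (type 7)
    cut = q3 if fence == "above_q3" else q3 + 1.5 * (q3 - q1)
    eligible = s[s <= cut]
    value = float(eligible.max())
    return ThresholdResult(
        method="iqr",
        value=value,
        provenance={
            "fence": fence,
            "q3": float(q3),
            "quantile_convention": "linear interpolation (type 7)",
            "n_controls": int(s.size),
            "n_excluded": int(s.size - eligible.size),
        },
    )


def threshold_fdr(control_scores, q: float = 0.05) -> ThresholdResult:
    """FDR threshold: exclude the top ceil(q*N) controls as outliers and
    take the highest remaining control."""
    if not 0.0 < q < 1.0:
        raise CPScreenError(f"q={q} not in (0, 1)")
    s = np.asarray(control_scores, dtype=float)
    n = s.size
    if n == 0:
        raise CPScreenError("no control scores")
    k = math.ceil(q * n)
    if k >= n:
        warnings.warn(
            f"excluding ceil({q}*{n})={k} controls would leave nothing; "
            f"threshold falls back to max(control)"
        )
        value = float(s.max())
        k = 0
    else:
        # descending order with stable index tie-break
        order = np.argsort(-s, kind="stable")
        value = float(s[order[k:]].max())
    return ThresholdResult(
        method="fdr5",
        value=value,
        provenance={"q": q, "n_controls": int(n), "n_excluded": int(k)},
    )


def threshold_elbow(all_scores, tolerance: float = 1e-9) -> ThresholdResult:
    """Elbow threshold: scores sorted ascending; the knee is the index of
    maximum perpendicular distance to the chord from the first to the last
    point, with both axes normalized to [0, 1] (which makes the knee
    invariant under affine rescaling of the scores)."""
    s = np.sort(np.asarray(all_scores, dtype=float))
    n = s.size
    if n < 10:
        raise CPScreenError("elbow threshold needs at least 10 scores")
    span = s[-1] - s[0]
    if span <= 0:
        raise CPScreenError("degenerate elbow curve: all scores identical")
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / span
    dist = np.abs(y - x) / math.sqrt(2.0)
    if dist.max() < tolerance:
        raise CPScreenError("degenerate elbow curve: scores are collinear")
    knee = int(np.argmax(dist))
    return ThresholdResult(
        method="elbow",
        value=float(s[knee]),
        provenance={"knee_index": knee, "n_scores": int(n), "max_distance": float(dist.max())},
    )


THRESHOLD_METHODS = {"iqr": threshold_iqr, "fdr5": threshold_fdr, "elbow": threshold_elbow}


def flag_cytotoxic(n_cells, control_cell_counts) -> np.ndarray:
    """Cytotoxic wells have fewer than 50% of the mean control cell count
    (strict <)."""
    controls = np.asarray(control_cell_counts, dtype=float)
    if controls.size == 0:
        raise CPScreenError("no control cell counts")
    cut = 0.5 * controls.mean()
    return np.asarray(n_cells, dtype=float) < cut


def build_activity_table(
    fingerprints: pd.DataFrame,
    platemap: PlateMap,
    threshold: ThresholdResult | float,
    condition: str,
    cell_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-well activity table: CP score, active and cytotoxic flags.

    ``active`` is a strict comparison against the recorded threshold; the
    cytotoxicity flag compares cell counts to half the reference-control
    mean (omitted when counts are unavailable).
    """
    thr = float(threshold)
    scores = cp_activity_scores(fingerprints)
    meta = platemap.to_frame().set_index("well")
    rows = []
    counts = cell_counts or fingerprints.attrs.get("cells_per_well") or {}
    ref_counts = [counts[w] for w in platemap.reference_wells if w in counts]
    cyto_cut = 0.5 * float(np.mean(ref_counts)) if ref_counts else None
    for well, score in scores.items():
        m = meta.loc[well]
        n = counts.get(well)
        rows.append(
            {
                "well": well,
                "compound_id": m["compound_id"],
                "dose_uM": m["dose_uM"],
                "condition": condition,
                "role": m["role"],
                "cp_score": score,
                "active": bool(score > thr) if np.isfinite(score) else False,
                "cytotoxic": (n is not None and cyto_cut is not None and n < cyto_cut),
                "n_cells": n if n is not None else -1,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["threshold"] = thr
    df.attrs["threshold_method"] = getattr(threshold, "method", "fixed")
    return df


def _per_compound_active(activity: pd.DataFrame) -> pd.Series:
    comp = activity[activity["compound_id"].notna() & (activity["role"] == "experimental")]
    return comp.groupby("compound_id")["active"].any()


def illumination_summary(
    activity_resting: pd.DataFrame, activity_activated: pd.DataFrame
) -> dict:
    """Venn partition of compounds by the conditions in which they are
    active: both / activated_only / resting_only / dark, with counts and
    percentages, plus the per-compound category assignment."""
    rest = _per_compound_active(activity_resting)
    act = _per_compound_active(activity_activated)
    if set(rest.index) != set(act.index):
        only_r = sorted(set(rest.index) - set(act.index))[:5]
        only_a = sorted(set(act.index) - set(rest.index))[:5]
        raise CPScreenError(
            f"compound keys differ between conditions: only-resting {only_r}, "
            f"only-activated {only_a}"
        )
    act = act.reindex(rest.index)
    category = pd.Series(
        np.select(
            [rest & act, ~rest & act, rest & ~act],
            ["both", "activated_only", "resting_only"],
            default="dark",
        ),
        index=rest.index,
        name="category",
    )
    counts = {c: int((category == c).sum()) for c in VENN_CATEGORIES}
    total = int(category.size)
    return {
        "counts": counts,
        "percentages": {c: 100.0 * counts[c] / total if total else 0.0 for c in VENN_CATEGORIES},
        "total": total,
        "categories": category,
    }
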
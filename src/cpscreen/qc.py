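"""Quality-control checkpoints for the screening pipeline.

* **ChP2** — before fixation, control wells are imaged in brightfield and a
  linear classifier on 23 cell features estimates each well's percent of
  activated cells; a plate passes when at most two no-PMA controls show
  >15% activated cells and at most two PMA controls show <30%.
* **ChP5** — after CP Activity scoring, abnormal controls (reference
  controls scoring active, or positive controls scoring inactive) trigger a
  renormalize / rescreen / repeat decision based on the printed 10%-(3-well)
  and 22% rules.
* **Paired-condition tables** — per-well resting-vs-activated score
  scatters with quadrant assignment at the activity threshold (the
  QCGauntlet view).  Convention: x = resting score, y = activated score.
* **JUMP reproducibility** — pairwise Pearson correlations of replicated
  control-compound fingerprints within plates, between plates and between
  batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .activity import ThresholdResult, threshold_iqr
from .core import CPScreenError, get_logger
from .synthetic_screen import BRIGHTFIELD_FEATURES

log = get_logger(__name__)

#: ChP2 cell pre-filters: putative cells that are too big or too dark are
#: removed before classification.
MAX_CELL_AREA = 2000.0
MIN_BRIGHTFIELD_MEAN = 10000.0

CHP2_MAX_OFFENDING_WELLS = 2
CHP2_RESTING_MAX_PERCENT = 15.0
CHP2_ACTIVATED_MIN_PERCENT = 30.0

CHP5_REPEAT_FRACTION = 0.22
# "more than 10% (3 wells)": the printed rule equates 10% of the control set
# with 3 wells, so the trigger is the well count, not a recomputed fraction
CHP5_RENORM_WELLS = 3
CHP5_RESCREEN_MIN_ABNORMAL = 3


@dataclass
class QCDecision:
    plate_id: str
    checkpoint: str
    verdict: str  # pass | renormalize | rescreen | repeat
    evidence: dict = field(default_factory=dict)


@dataclass
class LinearClassifierModel:
    """Strict linear decision rule on the 23 brightfield features:
    activated iff ``x @ weights + offset > 0``."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    offset: float
    training_accuracy: float
    training_wells: tuple[str, ...] = ()

    def decision_values(self, cells: pd.DataFrame) -> np.ndarray:
        x = cells[list(self.feature_names)].to_numpy(dtype=float)
        return x @ self.weights + self.offset

    def predict_activated(self, cells: pd.DataFrame) -> np.ndarray:
        return self.decision_values(cells) > 0.0


def prefilter_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Remove putative cells with area > 2,000 μm² or brightfield mean
    < 10,000 (both strict); removal counts are logged."""
    too_big = cells["area"] > MAX_CELL_AREA
    too_dark = cells["intensity_mean"] < MIN_BRIGHTFIELD_MEAN
    removed = too_big | too_dark
    if removed.any():
        log.info(
            "prefilter: removed %d/%d cells (%d oversized, %d dark)",
            int(removed.sum()), len(cells), int(too_big.sum()), int(too_dark.sum()),
        )
    return cells[~removed].reset_index(drop=True)


def train_activation_classifier(
    train: pd.DataFrame, label_column: str = "truth_label"
) -> LinearClassifierModel:
    """Fit the ChP2 linear classifier on prefiltered training cells.

    A regularized logistic regression on standardized features, folded back
    into a single raw-feature linear rule (the decision interface is the
    contract, not specific weights).  Training cells come from a pair of
    resting and a pair of activated wells in practice; any labeled table
    with both classes present works.
    """
    cells = prefilter_cells(train)
    labels = (cells[label_column] == "activated").to_numpy()
    if labels.all() or not labels.any():
        raise CPScreenError("training set must contain both resting and activated cells")
    feats = list(BRIGHTFIELD_FEATURES)
    x = cells[feats].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    clf = LogisticRegression(max_iter=2000)
    clf.fit((x - mu) / sd, labels)
    w_std = clf.coef_[0]
    w = w_std / sd
    offset = float(clf.intercept_[0] - np.dot(w_std, mu / sd))
    model = LinearClassifierModel(
        feature_names=tuple(feats),
        weights=w,
        offset=offset,
        training_accuracy=0.0,
        training_wells=tuple(sorted(cells["well"].unique())) if "well" in cells else (),
    )
    acc = float((model.predict_activated(cells) == labels).mean())
    model.training_accuracy = acc
    log.info("activation classifier trained: accuracy %.1f%% on %d cells", 100 * acc, len(cells))
    return model


def percent_activated(model: LinearClassifierModel, well_cells: pd.DataFrame) -> float:
    """Percent of retained cells classified activated: 100*a/(a+b).

    Returns NaN (flagged in the log) when no cells survive the prefilter.
    """
    cells = prefilter_cells(well_cells)
    if len(cells) == 0:
        log.warning("percent_activated: no retained cells; value is missing")
        return float("nan")
    a = int(model.predict_activated(cells).sum())
    return 100.0 * a / len(cells)


def chp2_gate(well_percents: pd.DataFrame, plate_id: str = "") -> QCDecision:
    """ChP2 plate gate on control-well activation percentages.

    ``well_percents`` needs columns ``well``, ``condition`` (the well's PMA
    state) and ``percent_activated``.  Pass iff at most two no-PMA controls
    have >15% activated cells AND at most two PMA controls have <30%;
    otherwise the plate is rescreened.  Comparisons are strict, so exactly
    15.0% does not offend.
    """
    resting = well_percents[well_percents["condition"] == "resting"]
    activated = well_percents[well_percents["condition"] == "activated"]
    offending_resting = int((resting["percent_activated"] > CHP2_RESTING_MAX_PERCENT).sum())
    offending_activated = int((activated["percent_activated"] < CHP2_ACTIVATED_MIN_PERCENT).sum())
    ok = (
        offending_resting <= CHP2_MAX_OFFENDING_WELLS
        and offending_activated <= CHP2_MAX_OFFENDING_WELLS
    )
    return QCDecision(
        plate_id=plate_id,
        checkpoint="ChP2",
        verdict="pass" if ok else "rescreen",
        evidence={
            "offending_resting_controls": offending_resting,
            "offending_activated_controls": offending_activated,
            "n_resting_controls": int(len(resting)),
            "n_activated_controls": int(len(activated)),
        },
    )


def _abnormal_mask(roles: pd.Series, scores: pd.Series, threshold: float) -> pd.Series:
    """Abnormal controls: reference controls scoring active, or positive
    (condition-swapped) controls scoring inactive, at the given threshold."""
    is_ref = roles == "reference_control"
    is_pos = roles.isin(["activator_control", "jump_control"])
    return (is_ref & (scores > threshold)) | (is_pos & (scores <= threshold))


def chp5_gate(
    control_scores: pd.DataFrame,
    threshold: ThresholdResult | float,
    plate_id: str = "",
    recompute=None,
) -> QCDecision:
    """ChP5 control-anomaly decision for one plate.

    ``control_scores`` needs columns ``role`` and ``cp_score`` for the
    plate's control wells.  Decision order: *repeat* if more than 22% of
    controls are abnormal at the outset; else if more than 3 control wells
    (the printed "10% (3 wells)" rule) are abnormal, the abnormal wells are
    dropped, the threshold is recomputed on the remaining reference
    controls (``recompute`` defaults to the IQR method) and the plate is
    *rescreened* if 3 or more controls remain abnormal, else the verdict is
    *renormalize*; otherwise *pass*.
    """
    if len(control_scores) == 0:
        raise CPScreenError("chp5_gate: no control wells")
    thr = float(threshold)
    roles = control_scores["role"]
    scores = control_scores["cp_score"]
    abnormal = _abnormal_mask(roles, scores, thr)
    n_controls = len(control_scores)
    n_abnormal = int(abnormal.sum())
    frac = n_abnormal / n_controls
    evidence = {
        "n_controls": n_controls,
        "n_abnormal_outset": n_abnormal,
        "fraction_abnormal_outset": frac,
        "threshold": thr,
    }
    if frac > CHP5_REPEAT_FRACTION:
        return QCDecision(plate_id, "ChP5", "repeat", evidence)
    if n_abnormal > CHP5_RENORM_WELLS:
        kept = control_scores[~abnormal]
        ref_scores = kept.loc[kept["role"] == "reference_control", "cp_score"]
        if recompute is None:
            recompute = lambda s: threshold_iqr(s).value  # noqa: E731
        new_thr = float(recompute(ref_scores.to_numpy()))
        abnormal_after = _abnormal_mask(kept["role"], kept["cp_score"], new_thr)
        n_after = int(abnormal_after.sum())
        evidence.update({"threshold_renormalized": new_thr, "n_abnormal_after": n_after})
        if n_after >= CHP5_RESCREEN_MIN_ABNORMAL:
            return QCDecision(plate_id, "ChP5", "rescreen", evidence)
        return QCDecision(plate_id, "ChP5", "renormalize", evidence)
    return QCDecision(plate_id, "ChP5", "pass", evidence)


def paired_condition_table(
    activity_resting: pd.DataFrame,
    activity_activated: pd.DataFrame,
    threshold: ThresholdResult | float,
) -> pd.DataFrame:
    """Per-well paired-condition records for the QCGauntlet-style scatter.

    x = resting score, y = activated score (this convention is recorded in
    ``.attrs``); the quadrant is a strict threshold comparison on each
    axis: both / activated_only / resting_only / dark.
    """
    thr = float(threshold)
    rest = activity_resting.set_index("well")
    act = activity_activated.set_index("well")
    if set(rest.index) != set(act.index):
        diff = sorted(set(rest.index) ^ set(act.index))[:8]
        raise CPScreenError(f"unmatched wells between conditions: {diff}")
    act = act.reindex(rest.index)
    x = rest["cp_score"].to_numpy(dtype=float)
    y = act["cp_score"].to_numpy(dtype=float)
    quadrant = np.select(
        [(x > thr) & (y > thr), (y > thr), (x > thr)],
        ["both", "activated_only", "resting_only"],
        default="dark",
    )
    out = pd.DataFrame(
        {
            "well": rest.index,
            "compound_id": rest["compound_id"].to_numpy(),
            "role": rest["role"].to_numpy(),
            "x_resting": x,
            "y_activated": y,
            "quadrant": quadrant,
        }
    )
    out.attrs["axis_convention"] = {"x": "resting", "y": "activated"}
    out.attrs["threshold"] = thr
    return out


def jump_reproducibility(
    fingerprints: pd.DataFrame,
    replicate_meta: pd.DataFrame,
    grouping: str = "within_plate",
) -> pd.DataFrame:
    """Pairwise Pearson correlations of replicate control-compound
    fingerprints at one grouping level.

    ``replicate_meta`` is index-aligned with ``fingerprints`` and carries
    ``compound_id``, ``plate_id`` and ``batch`` columns.  Groupings:
    ``within_plate`` (replicate pairs on the same plate), ``between_plate``
    (same batch, different plates), ``between_batch`` (different batches).
    Compounds with fewer than two replicates are skipped with a warning.
    The result is long-format, one row per replicate pair, ready for violin
    plotting.
    """
    if grouping not in ("within_plate", "between_plate", "between_batch"):
        raise CPScreenError(f"unknown grouping {grouping!r}")
    rows = []
    x = fingerprints.to_numpy(dtype=float)
    meta = replicate_meta.reset_index(drop=True)
    for compound, idx in meta.groupby("compound_id").groups.items():
        idx = list(idx)
        if len(idx) < 2:
            log.warning("jump_reproducibility: compound %s has a single replicate; skipped", compound)
            continue
        for i, j in combinations(idx, 2):
            same_plate = meta.loc[i, "plate_id"] == meta.loc[j, "plate_id"]
            same_batch = meta.loc[i, "batch"] == meta.loc[j, "batch"]
            if grouping == "within_plate" and not same_plate:
                continue
            if grouping == "between_plate" and (same_plate or not same_batch):
                continue
            if grouping == "between_batch" and same_batch:
                continue
            r = float(np.corrcoef(x[i], x[j])[0, 1])
            rows.append({"compound_id": compound, "grouping": grouping, "pearson_r": r})
    return pd.DataFrame(rows, columns=["compound_id", "grouping", "pearson_r"])
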
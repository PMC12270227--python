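"""End-to-end orchestration of the screen analysis on cell tables.

:func:`run_screen` is the canonical composition used by the CLI ``demo``
subcommand and the examples: simulate (or load) per-plate cell tables for
both conditions, fingerprint each plate against its reference controls,
pool reference CP Activity Scores into a threshold, build activity tables,
run the ChP5 control gate per plate, and summarize illumination.  Every
stage is also individually importable; this module only wires them
together and persists artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as act
from . import histdiff as hd
from . import qc as qcmod
from .core import PlateMap, get_logger, write_fingerprints, write_platemap
from .synthetic_screen import ScreenDesign, generate_platemap, simulate_single_cells

log = get_logger(__name__)

CONDITIONS = ("resting", "activated")


@dataclass
class ScreenResult:
    """Everything one pass over a (synthetic or loaded) screen produces."""

    platemaps: dict[str, list[PlateMap]]
    fingerprints: dict[str, list[pd.DataFrame]]
    thresholds: dict[str, act.ThresholdResult]
    activity: dict[str, pd.DataFrame]
    illumination: dict
    qc_decisions: list[qcmod.QCDecision] = field(default_factory=list)

    @property
    def worst_verdict(self) -> str:
        order = ["pass", "renormalize", "rescreen", "repeat"]
        worst = "pass"
        for d in self.qc_decisions:
            if order.index(d.verdict) > order.index(worst):
                worst = d.verdict
        return worst


def pooled_reference_scores(
    fingerprints: list[pd.DataFrame], platemaps: list[PlateMap]
) -> np.ndarray:
    """Reference-control CP Activity Scores pooled across plates."""
    pieces = []
    for fp, pm in zip(fingerprints, platemaps):
        refs = [w for w in pm.reference_wells if w in fp.index]
        pieces.append(act.cp_activity_scores(fp.loc[refs]).to_numpy())
    return np.concatenate(pieces)


def run_screen(
    design: ScreenDesign,
    threshold_method: str = "fdr5",
    bins: int = hd.DEFAULT_BINS,
    blocks: str | None = None,
    outdir: str | Path | None = None,
) -> ScreenResult:
    """Simulate and analyse a full two-condition screen.

    The activity threshold is derived per condition from the pooled
    reference-control scores of all plates (the elbow method instead pools
    all well scores, as it operates on the full score curve).
    """
    platemaps: dict[str, list[PlateMap]] = {}
    fingerprints: dict[str, list[pd.DataFrame]] = {}
    thresholds: dict[str, act.ThresholdResult] = {}
    activities: dict[str, pd.DataFrame] = {}
    decisions: list[qcmod.QCDecision] = []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    for condition in CONDITIONS:
        pms, fps = [], []
        for p in range(design.n_plates):
            pm = generate_platemap(design, p, condition=condition)
            cells = simulate_single_cells(design, pm, condition)
            if blocks:
                fp = hd.fingerprint_plate_blocked(cells, pm, blocks, bins=bins)
            else:
                fp = hd.fingerprint_plate(cells, pm, bins=bins)
            pms.append(pm)
            fps.append(fp)
            if outdir is not None:
                write_platemap(pm, outdir / f"platemap_{pm.plate_id}_{condition}.csv")
                write_fingerprints(fp, outdir / f"fingerprints_{pm.plate_id}_{condition}.tsv")
        platemaps[condition] = pms
        fingerprints[condition] = fps

        ref_scores = pooled_reference_scores(fps, pms)
        if threshold_method == "elbow":
            all_scores = np.concatenate(
                [act.cp_activity_scores(fp).dropna().to_numpy() for fp in fps]
            )
            thr = act.threshold_elbow(all_scores)
        else:
            thr = act.THRESHOLD_METHODS[threshold_method](ref_scores)
        thresholds[condition] = thr

        tabs = []
        for pm, fp in zip(pms, fps):
            tab = act.build_activity_table(fp, pm, thr, condition)
            tabs.append(tab)
            controls = tab[tab["role"].isin(["reference_control", "activator_control", "jump_control"])]
            decisions.append(
                qcmod.chp5_gate(controls[["role", "cp_score"]], thr, plate_id=f"{pm.plate_id}:{condition}")
            )
        activities[condition] = pd.concat(tabs, ignore_index=True)
        activities[condition].attrs["threshold"] = thr.value

    illumination = act.illumination_summary(activities["resting"], activities["activated"])
    result = ScreenResult(
        platemaps=platemaps,
        fingerprints=fingerprints,
        thresholds=thresholds,
        activity=activities,
        illumination=illumination,
        qc_decisions=decisions,
    )
    if outdir is not None:
        for condition in CONDITIONS:
            activities[condition].to_csv(outdir / f"activity_{condition}.csv", index=False)
        summary = {
            "thresholds": {c: thresholds[c].value for c in CONDITIONS},
            "threshold_method": threshold_method,
            "illumination_counts": illumination["counts"],
            "illumination_percentages": illumination["percentages"],
            "qc_verdicts": {d.plate_id: d.verdict for d in decisions},
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return result
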
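"""Synthetic activated-screen generator with planted ground truth.

The screen's image-derived single-cell data are not publicly deposited, so
this module emulates the parts of the study design every downstream stage
needs to be exercised against:

* 384-well plates with the study's control layout (dye wells at A01/P24,
  randomized reference / JUMP / positive-control positions, the remainder
  experimental);
* per-cell feature tables: reference wells draw each feature from a base
  distribution (Normal by default, log-normal option for intensity-like
  skew); treated wells apply a per-compound location shift (in control-SD
  units) and SD scaling on a planted feature subset; the activated (PMA)
  condition adds a global activation signature — a fixed +1 SD shift on a
  configurable 30% of features — to every activated well;
* cytotoxic cell-count reduction, over-dispersed negative-binomial cell
  counts, and plate-stripe staining artifacts;
* brightfield two-phenotype cell populations for the activation classifier
  and GR-assay intensity records for the nuclear-translocation classifier.

Planted truth (compound → effect, cell → label) is always carried alongside
the data so downstream recovery is measurable.  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    PLATE_ROWS,
    CPScreenError,
    PlateMap,
    SingleCellTable,
    WellAddress,
    WellAnnotation,
    all_well_labels,
    get_logger,
    spawn_rng,
)

log = get_logger(__name__)

COMPARTMENT_PREFIXES = ("ER_", "Nuc_", "Mito_", "AGP_", "RNA_")

CONDITION_SPECIFICITIES = ("both", "activated_only", "resting_only", "none")

#: The 23 brightfield features used by the activation classifier:
#: 6 morphology, 9 intensity, 8 SER texture.
BRIGHTFIELD_FEATURES = (
    "area",
    "roundness",
    "perimeter",
    "width",
    "length",
    "width_to_length",
    "intensity_mean",
    "intensity_sd",
    "intensity_cv",
    "intensity_median",
    "intensity_sum",
    "intensity_max",
    "intensity_min",
    "intensity_quantile",
    "intensity_contrast",
    "ser_spot",
    "ser_hole",
    "ser_edge",
    "ser_ridge",
    "ser_valley",
    "ser_saddle",
    "ser_bright",
    "ser_dark",
)

#: Features separating activated from resting cells (the discriminative
#: texture and intensity properties).
_BF_DISCRIMINATIVE = (
    "ser_dark",
    "ser_valley",
    "ser_edge",
    "intensity_mean",
    "intensity_median",
    "intensity_contrast",
    "intensity_max",
)

#: GR nuclear-enrichment criteria: ratio name -> strict lower threshold.
GR_CRITERIA = {
    "gr_nuc_sum/hoechst_nuc_sum": 0.35,
    "gr_nuc_sum/gr_cyto_sum": 0.25,
    "gr_nuc_mean/gr_cyto_mean": 1.7,
    "gr_nuc_median/gr_cyto_median": 1.7,
    "gr_nuc_quantile/gr_cyto_quantile": 1.7,
    "gr_nuc_contrast/gr_cyto_contrast": 0.3,
}


def make_feature_names(n: int = 482) -> list[str]:
    """Feature names cycled over compartment prefixes (ER_, Nuc_, ...)."""
    return [f"{COMPARTMENT_PREFIXES[i % len(COMPARTMENT_PREFIXES)]}{i:04d}" for i in range(n)]


@dataclass(frozen=True)
class EffectModel:
    """Planted phenotypic effect of one compound.

    ``shift`` is a location shift in control-SD units applied to each
    affected feature; ``scale`` multiplies the control SD.  Condition
    specificity mirrors the screen's central question — a compound may
    perturb only activated (PMA) cells, only resting cells, both, or
    neither.  ``cytotoxicity_fraction`` is the fractional reduction of the
    expected cell count when the effect applies.
    """

    compound_id: str
    affected_features: tuple[str, ...] = ()
    shift: float = 0.0
    scale: float = 1.0
    condition_specificity: str = "both"
    cytotoxicity_fraction: float = 0.0
    dose_uM: float = 10.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.shift):
            raise CPScreenError(f"{self.compound_id}: shift must be finite")
        if not 0.0 <= self.cytotoxicity_fraction <= 1.0:
            raise CPScreenError(f"{self.compound_id}: cytotoxicity_fraction not in [0,1]")
        if self.condition_specificity not in CONDITION_SPECIFICITIES:
            raise CPScreenError(
                f"{self.compound_id}: unknown condition_specificity "
                f"{self.condition_specificity!r}"
            )
        if self.condition_specificity == "none" and (
            self.shift != 0.0 or self.scale != 1.0 or self.cytotoxicity_fraction != 0.0
        ):
            raise CPScreenError(
                f"{self.compound_id}: specificity 'none' requires a null effect"
            )

    def applies(self, condition: str) -> bool:
        return self.condition_specificity == "both" or (
            self.condition_specificity == "activated_only" and condition == "activated"
        ) or (
            self.condition_specificity == "resting_only" and condition == "resting"
        )


@dataclass
class ScreenDesign:
    """Full parameterization of a synthetic screen."""

    seed: int
    n_plates: int = 1
    feature_names: list[str] = field(default_factory=make_feature_names)
    cells_per_well_mean: float = 400.0
    cells_per_well_dispersion: float = 10.0
    control_layout: dict[str, int] = field(
        default_factory=lambda: {
            "reference_control": 32,
            "jump_control": 24,
            "activator_control": 8,
        }
    )
    compounds: list[EffectModel] = field(default_factory=list)
    classes: dict[str, frozenset[str]] = field(default_factory=dict)
    base_distribution: str = "normal"
    activation_feature_fraction: float = 0.3
    activation_shift: float = 1.0
    n_jump_compounds: int = 8

    def __post_init__(self) -> None:
        if self.base_distribution not in ("normal", "lognormal"):
            raise CPScreenError(f"unknown base distribution {self.base_distribution!r}")
        if self.control_layout.get("reference_control", 0) < 1:
            raise CPScreenError("control layout has no reference_control wells")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_experimental_wells(self) -> int:
        return 384 - 2 - sum(self.control_layout.values())

    def base_params(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-feature (mean, SD) of the reference distribution in value
        space, drawn once per screen from the screen-level stream."""
        rng = spawn_rng(self.seed, 0)
        f = self.n_features
        if self.base_distribution == "normal":
            mu = rng.uniform(100.0, 1000.0, f)
            sigma = rng.uniform(10.0, 100.0, f)
        else:
            mu_log = rng.uniform(4.0, 7.0, f)
            sigma_log = rng.uniform(0.2, 0.5, f)
            mu = np.exp(mu_log + sigma_log**2 / 2)
            sigma = mu * np.sqrt(np.expm1(sigma_log**2))
            # stash the log-space parameters for the sampler
            self._lognormal_params = (mu_log, sigma_log)
        return mu, sigma

    def activation_features(self) -> np.ndarray:
        """Index array of the features carrying the global PMA signature."""
        rng = spawn_rng(self.seed, 0)
        rng.uniform(size=2 * self.n_features)  # advance past base_params draws
        k = int(round(self.activation_feature_fraction * self.n_features))
        return np.sort(rng.choice(self.n_features, size=k, replace=False))

    def jump_effects(self) -> dict[str, EffectModel]:
        """Planted effects for the replicated JUMP positive-control
        compounds: each gets a distinct, condition-independent shift on its
        own 10% feature subset, so positive controls score active and
        replicate fingerprints are correlated across plates."""
        rng = spawn_rng(self.seed, 5)
        k = max(1, int(round(0.1 * self.n_features)))
        effects = {}
        for j in range(1, self.n_jump_compounds + 1):
            cols = np.sort(rng.choice(self.n_features, size=k, replace=False))
            effects[f"JUMP-{j}"] = EffectModel(
                f"JUMP-{j}",
                affected_features=tuple(self.feature_names[c] for c in cols),
                shift=1.5,
            )
        return effects

    def truth_frame(self) -> pd.DataFrame:
        """Planted compound-level truth, for downstream recovery checks."""
        return pd.DataFrame(
            {
                "compound_id": [c.compound_id for c in self.compounds],
                "condition_specificity": [c.condition_specificity for c in self.compounds],
                "shift": [c.shift for c in self.compounds],
                "n_affected": [len(c.affected_features) for c in self.compounds],
                "cytotoxicity_fraction": [c.cytotoxicity_fraction for c in self.compounds],
                "classes": [";".join(sorted(self.classes.get(c.compound_id, ()))) for c in self.compounds],
            }
        )


def make_default_screen(
    seed: int,
    n_compounds: int = 1000,
    n_both: int = 50,
    n_activated_only: int = 30,
    n_resting_only: int = 20,
    shift: float = 1.5,
    n_affected_features: int = 20,
    n_features: int = 482,
    cytotoxic_fraction_of_active: float = 0.1,
    class_size: int = 5,
    **kwargs,
) -> ScreenDesign:
    """Default synthetic screen: mostly inert compounds plus planted
    both-active / activated-only / resting-only effects at a fixed shift.

    One in ``1/cytotoxic_fraction_of_active`` active compounds additionally
    kills 60% of cells, to exercise the cytotoxicity flag.  Active compounds
    are grouped into target classes of ``class_size`` members sharing the
    same affected-feature block.
    """
    n_active = n_both + n_activated_only + n_resting_only
    if n_active > n_compounds:
        raise CPScreenError("more planted actives than compounds")
    feature_names = make_feature_names(n_features)
    rng = spawn_rng(seed, 9)
    specs = (
        ["both"] * n_both
        + ["activated_only"] * n_activated_only
        + ["resting_only"] * n_resting_only
        + ["none"] * (n_compounds - n_active)
    )
    compounds: list[EffectModel] = []
    classes: dict[str, frozenset[str]] = {}
    n_cls = 0
    class_features: dict[int, tuple[str, ...]] = {}
    for i, spec in enumerate(specs):
        cid = f"C{i + 1:05d}"
        if spec == "none":
            compounds.append(EffectModel(cid, condition_specificity="none"))
            continue
        cls_idx = len([c for c in compounds if c.condition_specificity != "none"]) // class_size
        if cls_idx not in class_features:
            class_features[cls_idx] = tuple(
                feature_names[j]
                for j in np.sort(rng.choice(n_features, size=n_affected_features, replace=False))
            )
            n_cls += 1
        cyto = 0.6 if rng.uniform() < cytotoxic_fraction_of_active else 0.0
        compounds.append(
            EffectModel(
                cid,
                affected_features=class_features[cls_idx],
                shift=shift,
                condition_specificity=spec,
                cytotoxicity_fraction=cyto,
            )
        )
        classes[cid] = frozenset({f"class_{cls_idx:03d}"})
    design = ScreenDesign(
        seed=seed,
        feature_names=feature_names,
        compounds=compounds,
        classes=classes,
        **kwargs,
    )
    design.n_plates = max(1, math.ceil(n_compounds / design.n_experimental_wells))
    return design


def generate_platemap(design: ScreenDesign, plate_index: int, condition: str = "resting") -> PlateMap:
    """Randomized plate layout: dye wells fixed at A01/P24, control roles
    and compounds at randomized positions, deterministic in (seed, plate)."""
    rng = spawn_rng(design.seed, 1, plate_index)
    n_exp = design.n_experimental_wells
    if n_exp < 0:
        raise CPScreenError("control layout exceeds plate capacity")
    capacity = design.n_plates * n_exp
    if len(design.compounds) > capacity:
        raise CPScreenError(
            f"{len(design.compounds)} compounds exceed the {capacity} experimental "
            f"wells of {design.n_plates} plates"
        )
    plate_id = f"P{plate_index + 1:02d}"
    labels = all_well_labels()
    free = [l for l in labels if l not in ("A01", "P24")]
    order = [free[i] for i in rng.permutation(len(free))]
    wells = [
        WellAnnotation(WellAddress.from_label(plate_id, "A01"), "dye_control", condition=condition),
        WellAnnotation(WellAddress.from_label(plate_id, "P24"), "dye_control", condition=condition),
    ]
    pos = 0
    for _ in range(design.control_layout.get("reference_control", 0)):
        wells.append(
            WellAnnotation(
                WellAddress.from_label(plate_id, order[pos]), "reference_control", condition=condition
            )
        )
        pos += 1
    n_jump = design.control_layout.get("jump_control", 0)
    for j in range(n_jump):
        cid = f"JUMP-{j % design.n_jump_compounds + 1}"
        wells.append(
            WellAnnotation(
                WellAddress.from_label(plate_id, order[pos]),
                "jump_control",
                compound_id=cid,
                dose_uM=10.0,
                condition=condition,
            )
        )
        pos += 1
    opposite = "activated" if condition == "resting" else "resting"
    for _ in range(design.control_layout.get("activator_control", 0)):
        # condition-swapped wells: PMA on the resting plate / no PMA on the
        # activated plate; these are the plate's positive controls
        wells.append(
            WellAnnotation(
                WellAddress.from_label(plate_id, order[pos]), "activator_control", condition=opposite
            )
        )
        pos += 1
    chunk = design.compounds[plate_index * n_exp : (plate_index + 1) * n_exp]
    for k in range(n_exp):
        compound = chunk[k] if k < len(chunk) else None
        wells.append(
            WellAnnotation(
                WellAddress.from_label(plate_id, order[pos]),
                "experimental",
                compound_id=compound.compound_id if compound else None,
                dose_uM=compound.dose_uM if compound else 0.0,
                condition=condition,
            )
        )
        pos += 1
    return PlateMap(plate_id=plate_id, wells=wells)


def _effective_condition(well: WellAnnotation, plate_condition: str) -> str:
    """Activator controls are condition-swapped relative to their plate."""
    if well.role == "activator_control":
        return "activated" if plate_condition == "resting" else "resting"
    return plate_condition


def simulate_single_cells(
    design: ScreenDesign, platemap: PlateMap, condition: str
) -> SingleCellTable:
    """Draw a plate's per-cell feature table.

    Reference wells sample the base distribution; every activated well
    additionally receives the global activation signature; treated wells
    apply their compound's shift/scale on its affected features, honoring
    condition specificity; cell counts are negative-binomial, reduced by
    the compound's cytotoxicity fraction when its effect applies.
    """
    if condition not in ("resting", "activated"):
        raise CPScreenError(f"unknown condition {condition!r}")
    effects = {c.compound_id: c for c in design.compounds}
    effects.update(design.jump_effects())
    for w in platemap.wells:
        if w.role == "experimental" and w.compound_id is not None and w.compound_id not in effects:
            raise CPScreenError(f"well {w.address.label}: no EffectModel for {w.compound_id}")
    rng = spawn_rng(design.seed, 2, zlib.crc32(platemap.plate_id.encode()), condition == "activated")
    mu, sigma = design.base_params()
    f = design.n_features
    feat_index = {name: i for i, name in enumerate(design.feature_names)}
    act_features = design.activation_features()

    wells = [w for w in platemap.wells if w.role != "dye_control"]
    mean = design.cells_per_well_mean
    disp = design.cells_per_well_dispersion
    counts = np.empty(len(wells), dtype=np.int64)
    for i, w in enumerate(wells):
        eff = effects.get(w.compound_id) if w.compound_id else None
        m = mean
        if eff is not None and eff.applies(_effective_condition(w, condition)):
            m = mean * (1.0 - eff.cytotoxicity_fraction)
        if m <= 0:
            counts[i] = 0
        else:
            counts[i] = rng.negative_binomial(disp, disp / (disp + m))
    total = int(counts.sum())

    if design.base_distribution == "normal":
        x = rng.standard_normal((total, f), dtype=np.float32)
        x *= sigma.astype(np.float32)
        x += mu.astype(np.float32)
    else:
        mu_log, sigma_log = design._lognormal_params
        x = rng.standard_normal((total, f), dtype=np.float32)
        x *= sigma_log.astype(np.float32)
        x += mu_log.astype(np.float32)
        np.exp(x, out=x)

    starts = np.concatenate([[0], np.cumsum(counts)])
    sigma32 = sigma.astype(np.float32)
    mu32 = mu.astype(np.float32)
    for i, w in enumerate(wells):
        rows = slice(starts[i], starts[i + 1])
        if counts[i] == 0:
            continue
        eff_cond = _effective_condition(w, condition)
        if eff_cond == "activated":
            x[rows, act_features] += (design.activation_shift * sigma32[act_features])[None, :]
        eff = effects.get(w.compound_id) if w.compound_id else None
        if eff is not None and eff.affected_features and eff.applies(eff_cond):
            cols = np.array([feat_index[n] for n in eff.affected_features])
            block = x[rows][:, cols]
            if eff.scale != 1.0:
                block = (block - mu32[cols]) * np.float32(eff.scale) + mu32[cols]
            block = block + (np.float32(eff.shift) * sigma32[cols])[None, :]
            for j, c in enumerate(cols):
                x[rows, c] = block[:, j]

    data = pd.DataFrame(x, columns=design.feature_names)
    data.insert(0, "well", np.repeat([w.address.label for w in wells], counts))
    data.insert(
        1,
        "cell_index",
        np.concatenate([np.arange(c) for c in counts]) if total else np.array([], dtype=int),
    )
    return SingleCellTable(plate_id=platemap.plate_id, data=data)


def inject_stripe_artifact(
    table: SingleCellTable,
    rows: set[str] | list[str],
    offset: float | np.ndarray | dict[str, float],
) -> SingleCellTable:
    """Add a staining-intensity stripe: every cell in the named plate rows
    gets ``offset`` added to its features; other cells are untouched."""
    rows = set(rows)
    if not rows:
        raise CPScreenError("stripe rows must be non-empty")
    unknown = rows - set(PLATE_ROWS)
    if unknown:
        raise CPScreenError(f"unknown plate rows {sorted(unknown)}")
    feats = table.feature_names
    if isinstance(offset, dict):
        offset = np.array([offset.get(f1, 0.0) for f1 in feats])
    mask = table.data["well"].str[0].isin(rows).to_numpy()
    values = table.data[feats].to_numpy().copy()
    values[mask] = (values[mask].astype(float) + offset).astype(values.dtype)
    data = table.data[["well", "cell_index"]].copy()
    data[feats] = values
    return SingleCellTable(plate_id=table.plate_id, data=data)


# ---------------------------------------------------------------------------
# Brightfield (activation-classifier) generator

_BF_BASE_MEAN = {
    "area": 900.0, "roundness": 0.8, "perimeter": 110.0, "width": 30.0,
    "length": 42.0, "width_to_length": 0.72,
    "intensity_mean": 20000.0, "intensity_sd": 2500.0, "intensity_cv": 0.12,
    "intensity_median": 19800.0, "intensity_sum": 1.6e7, "intensity_max": 32000.0,
    "intensity_min": 11000.0, "intensity_quantile": 19900.0, "intensity_contrast": 0.25,
    "ser_spot": 0.02, "ser_hole": 0.015, "ser_edge": 0.03, "ser_ridge": 0.02,
    "ser_valley": 0.025, "ser_saddle": 0.018, "ser_bright": 0.02, "ser_dark": 0.03,
}
_BF_BASE_SD = {
    "area": 220.0, "roundness": 0.08, "perimeter": 18.0, "width": 5.0,
    "length": 7.0, "width_to_length": 0.1,
    "intensity_mean": 1800.0, "intensity_sd": 400.0, "intensity_cv": 0.03,
    "intensity_median": 1800.0, "intensity_sum": 3.0e6, "intensity_max": 3000.0,
    "intensity_min": 1500.0, "intensity_quantile": 1800.0, "intensity_contrast": 0.05,
    "ser_spot": 0.005, "ser_hole": 0.004, "ser_edge": 0.007, "ser_ridge": 0.005,
    "ser_valley": 0.006, "ser_saddle": 0.004, "ser_bright": 0.005, "ser_dark": 0.007,
}


def simulate_brightfield_cells(
    activation_fractions: dict[str, float],
    cells_per_well: int = 200,
    junk_rate: float = 0.0,
    separation: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell brightfield records for the 23 activation-classifier
    features, drawn from two overlapping populations (resting vs activated).

    ``activation_fractions`` maps well label → fraction of activated cells.
    Planted junk cells (oversized area > 2,000 μm² or dark mean < 10,000,
    half each) appear at ``junk_rate``; the ground-truth label and junk flag
    are stored alongside the features.
    """
    for w, frac in activation_fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise CPScreenError(f"well {w}: activation fraction {frac} not in [0,1]")
    rng = spawn_rng(seed, 3)
    feats = list(BRIGHTFIELD_FEATURES)
    mean = np.array([_BF_BASE_MEAN[f] for f in feats])
    sd = np.array([_BF_BASE_SD[f] for f in feats])
    shift = np.array(
        [separation * _BF_BASE_SD[f] if f in _BF_DISCRIMINATIVE else 0.0 for f in feats]
    )
    frames = []
    for w in sorted(activation_fractions):
        frac = activation_fractions[w]
        labels = rng.uniform(size=cells_per_well) < frac
        x = rng.standard_normal((cells_per_well, len(feats))) * sd + mean
        x[labels] += shift
        junk = rng.uniform(size=cells_per_well) < junk_rate
        i_area = feats.index("area")
        i_mean = feats.index("intensity_mean")
        # keep non-junk cells inside the prefilter gates
        x[:, i_area] = np.clip(x[:, i_area], 100.0, 1990.0)
        x[:, i_mean] = np.maximum(x[:, i_mean], 10500.0)
        oversized = junk & (rng.uniform(size=cells_per_well) < 0.5)
        dark = junk & ~oversized
        x[oversized, i_area] = rng.uniform(2001.0, 4000.0, int(oversized.sum()))
        x[dark, i_mean] = rng.uniform(0.0, 9999.0, int(dark.sum()))
        df = pd.DataFrame(x, columns=feats)
        df.insert(0, "well", w)
        df["truth_label"] = np.where(labels, "activated", "resting")
        df["is_junk"] = junk
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# GR-assay generator

GR_FIELDS = (
    "hoechst_nuc_sum",
    "gr_nuc_mean", "gr_nuc_median", "gr_nuc_sum", "gr_nuc_quantile", "gr_nuc_contrast",
    "gr_cyto_mean", "gr_cyto_median", "gr_cyto_sum", "gr_cyto_quantile", "gr_cyto_contrast",
)


def simulate_gr_cells(
    n_cells: int, nuclear_enriched_fraction: float, seed: int = 0
) -> pd.DataFrame:
    """GR-assay cell records whose six criterion ratios come from a "pass"
    regime (all six strictly satisfied) with probability
    ``nuclear_enriched_fraction``, else from a "fail" regime with at least
    one criterion violated.  Ground truth is stored in ``truth_enriched``.
    """
    if not 0.0 <= nuclear_enriched_fraction <= 1.0:
        raise CPScreenError("nuclear_enriched_fraction not in [0,1]")
    rng = spawn_rng(seed, 4)
    enriched = rng.uniform(size=n_cells) < nuclear_enriched_fraction
    thresholds = np.array(list(GR_CRITERIA.values()))
    k = len(thresholds)
    ratios = np.empty((n_cells, k))
    ratios[enriched] = thresholds * rng.uniform(1.1, 2.0, (int(enriched.sum()), k))
    n_fail = int((~enriched).sum())
    ratios[~enriched] = thresholds * rng.uniform(0.5, 2.0, (n_fail, k))
    forced = rng.integers(0, k, n_fail)  # guarantee >=1 violated criterion
    ratios[np.flatnonzero(~enriched), forced] = thresholds[forced] * rng.uniform(
        0.3, 0.95, n_fail
    )
    cyto_mean = rng.uniform(500.0, 1500.0, n_cells)
    cyto_median = cyto_mean * rng.uniform(0.9, 1.1, n_cells)
    cyto_sum = rng.uniform(1e5, 5e5, n_cells)
    cyto_quantile = cyto_mean * rng.uniform(0.9, 1.1, n_cells)
    cyto_contrast = rng.uniform(0.1, 0.5, n_cells)
    nuc_sum = ratios[:, 1] * cyto_sum
    df = pd.DataFrame(
        {
            "hoechst_nuc_sum": nuc_sum / ratios[:, 0],
            "gr_nuc_mean": ratios[:, 2] * cyto_mean,
            "gr_nuc_median": ratios[:, 3] * cyto_median,
            "gr_nuc_sum": nuc_sum,
            "gr_nuc_quantile": ratios[:, 4] * cyto_quantile,
            "gr_nuc_contrast": ratios[:, 5] * cyto_contrast,
            "gr_cyto_mean": cyto_mean,
            "gr_cyto_median": cyto_median,
            "gr_cyto_sum": cyto_sum,
            "gr_cyto_quantile": cyto_quantile,
            "gr_cyto_contrast": cyto_contrast,
        }
    )
    df["truth_enriched"] = enriched
    return df
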
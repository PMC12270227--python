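"""Shared domain types and tabular I/O for the screening pipeline.

The screen is organised around 384-well plates (rows A–P, columns 1–24).
Every stage of the pipeline consumes or produces one of a small set of
tabular objects:

* a :class:`SingleCellTable` — one row per segmented cell, one column per
  morphology/intensity/texture feature;
* a :class:`PlateMap` — per-well annotations (role, compound, dose,
  activation condition) that define the reference-control population;
* a fingerprint matrix — wells × features of dimensionless HistDiff
  scores, stored as a plain :class:`pandas.DataFrame`;
* a class annotation — compound → set of target-class labels.

All delimited-text readers validate their invariants on ingest and all
reader/writer pairs round-trip bit-exactly (floats are written with
shortest-repr formatting).
"""

from __future__ import annotations

import logging
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLUMNS = tuple(range(1, 25))
WELLS_PER_PLATE = len(PLATE_ROWS) * len(PLATE_COLUMNS)

#: Valid well roles.  ``dye_control`` wells (dispensing QC) are excluded from
#: every statistic; ``reference_control`` wells are carrier-only and define
#: the null phenotype for normalization and thresholds.
ROLES = (
    "reference_control",
    "activator_control",
    "jump_control",
    "experimental",
    "dye_control",
)
CONDITIONS = ("resting", "activated")

_WELL_RE = re.compile(r"^([A-P])(\d{2})$")

_METADATA_COLUMNS = ("well", "cell_index")


class CPScreenError(ValueError):
    """Base error for invariant violations in screen data."""


def get_logger(name: str = "cpscreen") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


log = get_logger(__name__)


def well_label(row: str, column: int) -> str:
    """Format a well as letter + zero-padded column, e.g. ``A01``."""
    return f"{row}{column:02d}"


def parse_well_label(label: str) -> tuple[str, int]:
    m = _WELL_RE.match(str(label))
    if m is None:
        raise CPScreenError(
            f"unknown well label {label!r}: expected row A-P + zero-padded "
            f"column 01-24 (e.g. 'A01')"
        )
    row, column = m.group(1), int(m.group(2))
    if not 1 <= column <= 24:
        raise CPScreenError(f"well column out of range in {label!r}")
    return row, column


def all_well_labels() -> list[str]:
    """All 384 well labels in row-major order (A01 ... P24)."""
    return [well_label(r, c) for r in PLATE_ROWS for c in PLATE_COLUMNS]


@dataclass(frozen=True)
class WellAddress:
    """Position of a well on a named plate."""

    plate_id: str
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in PLATE_ROWS:
            raise CPScreenError(f"row {self.row!r} not in A-P")
        if self.column not in PLATE_COLUMNS:
            raise CPScreenError(f"column {self.column} not in 1-24")

    @property
    def label(self) -> str:
        return well_label(self.row, self.column)

    @classmethod
    def from_label(cls, plate_id: str, label: str) -> "WellAddress":
        row, column = parse_well_label(label)
        return cls(plate_id, row, column)


@dataclass(frozen=True)
class WellAnnotation:
    """Role, treatment and condition of one well."""

    address: WellAddress
    role: str
    compound_id: str | None = None
    dose_uM: float = 0.0
    condition: str = "resting"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise CPScreenError(f"unknown role {self.role!r} for well {self.address.label}")
        if self.condition not in CONDITIONS:
            raise CPScreenError(
                f"unknown condition {self.condition!r} for well {self.address.label}"
            )
        if self.dose_uM < 0:
            raise CPScreenError(f"negative dose for well {self.address.label}")
        if self.role == "reference_control" and self.compound_id is not None:
            raise CPScreenError(
                f"reference_control well {self.address.label} must be carrier-only "
                f"(compound_id={self.compound_id!r})"
            )


@dataclass
class PlateMap:
    """Complete annotation of one 384-well plate.

    Invariants: every well appears exactly once and at least one
    ``reference_control`` well is present (HistDiff needs a reference
    population).  Control counts are derived, never hard-coded — the paper
    reports 38, 62 and 64 controls in different sections, so the layout is
    data-driven.
    """

    plate_id: str
    wells: list[WellAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [w.address.label for w in self.wells]
        seen = set(labels)
        if len(labels) != len(seen):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise CPScreenError(f"plate {self.plate_id}: duplicate wells {dupes}")
        missing = sorted(set(all_well_labels()) - seen)
        if missing:
            raise CPScreenError(
                f"plate {self.plate_id}: missing wells {missing[:8]}"
                + ("..." if len(missing) > 8 else "")
            )
        if self.control_counts.get("reference_control", 0) < 1:
            raise CPScreenError(
                f"plate {self.plate_id}: no reference_control wells; HistDiff "
                f"requires a reference population"
            )

    @property
    def control_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for w in self.wells:
            counts[w.role] = counts.get(w.role, 0) + 1
        return counts

    def wells_with_role(self, role: str) -> list[WellAnnotation]:
        return [w for w in self.wells if w.role == role]

    @property
    def reference_wells(self) -> list[str]:
        return [w.address.label for w in self.wells_with_role("reference_control")]

    @property
    def scored_wells(self) -> list[str]:
        """Well labels entering statistics (everything but dye controls)."""
        return [w.address.label for w in self.wells if w.role != "dye_control"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well": [w.address.label for w in self.wells],
                "role": [w.role for w in self.wells],
                "compound_id": [w.compound_id for w in self.wells],
                "dose_uM": [w.dose_uM for w in self.wells],
                "condition": [w.condition for w in self.wells],
            }
        )

    def annotation(self, label: str) -> WellAnnotation:
        for w in self.wells:
            if w.address.label == label:
                return w
        raise KeyError(label)


@dataclass
class SingleCellTable:
    """Per-cell feature values for one plate.

    ``data`` is long-by-cell, wide-by-feature: metadata columns ``well`` and
    ``cell_index`` followed by F real-valued feature columns.  Rows with any
    missing feature value are dropped at ingest (and logged), so a validated
    table carries no NaNs.
    """

    plate_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        for m in _METADATA_COLUMNS:
            if m not in cols:
                raise CPScreenError(f"single-cell table missing column {m!r}")
        feats = self.feature_names
        if len(feats) != len(set(feats)):
            dupes = sorted({f for f in feats if feats.count(f) > 1})
            raise CPScreenError(f"duplicate feature names {dupes}")
        for label in self.data["well"].unique():
            parse_well_label(label)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in _METADATA_COLUMNS]

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def feature_matrix(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy()

    def cells_in_well(self, label: str) -> pd.DataFrame:
        return self.data[self.data["well"] == label]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise CPScreenError(f"{path}: duplicate column names {dupes}")
    # round_trip: correctly rounded float parsing, so writer/reader pairs
    # are bit-exact
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_single_cell_table(path: str | Path, plate_id: str | None = None) -> SingleCellTable:
    """Read a per-cell feature table from delimited text (CSV/TSV).

    Malformed rows (missing feature values) are dropped and reported with
    their file line numbers; duplicate feature columns and unknown well
    labels are hard errors.
    """
    path = Path(path)
    df = _read_delimited(path)
    if plate_id is None:
        plate_id = path.stem
    feat_cols = [c for c in df.columns if c not in _METADATA_COLUMNS]
    bad = df[feat_cols].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based indexing
        lines = [int(i) + 2 for i in df.index[bad][:10]]
        log.warning(
            "%s: dropped %d malformed rows with missing feature values "
            "(file lines %s%s)",
            path,
            int(bad.sum()),
            lines,
            "..." if bad.sum() > 10 else "",
        )
        df = df[~bad].reset_index(drop=True)
    return SingleCellTable(plate_id=plate_id, data=df)


def write_single_cell_table(table: SingleCellTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    table.data.to_csv(path, sep=sep, index=False)


def read_platemap(path: str | Path, plate_id: str | None = None) -> PlateMap:
    """Read a plate map CSV with columns well, role, compound_id, dose_uM, condition."""
    path = Path(path)
    df = _read_delimited(path)
    required = {"well", "role", "compound_id", "dose_uM", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise CPScreenError(f"{path}: plate map missing columns {sorted(missing)}")
    if plate_id is None:
        plate_id = path.stem
    wells = []
    for i, row in df.iterrows():
        try:
            compound = row["compound_id"]
            if pd.isna(compound) or compound == "":
                compound = None
            wells.append(
                WellAnnotation(
                    address=WellAddress.from_label(plate_id, row["well"]),
                    role=row["role"],
                    compound_id=compound,
                    dose_uM=float(row["dose_uM"]) if not pd.isna(row["dose_uM"]) else 0.0,
                    condition=row["condition"],
                )
            )
        except CPScreenError as e:
            raise CPScreenError(f"{path}: row {int(i) + 2}: {e}") from e
    return PlateMap(plate_id=plate_id, wells=wells)


def write_platemap(platemap: PlateMap, path: str | Path) -> None:
    platemap.to_frame().to_csv(path, index=False)


def write_fingerprints(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a fingerprint matrix as tab-delimited text, wells as rows.

    Floats use shortest-repr formatting so a read-back reproduces values
    bit-exactly.
    """
    matrix.to_csv(path, sep="\t", index_label="well")


def read_fingerprints(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="well", float_precision="round_trip")


def read_class_annotation(path: str | Path) -> dict[str, frozenset[str]]:
    """Read compound → target-class labels from a long-format CSV.

    Expected columns: ``compound_id``, ``target_class``; a compound may
    appear on several rows (one per class).
    """
    df = _read_delimited(path)
    for col in ("compound_id", "target_class"):
        if col not in df.columns:
            raise CPScreenError(f"{path}: class annotation missing column {col!r}")
    if df["target_class"].isna().any() or (df["target_class"].astype(str) == "").any():
        raise CPScreenError(f"{path}: empty target-class labels")
    out: dict[str, set[str]] = {}
    for cid, cls in zip(df["compound_id"], df["target_class"]):
        out.setdefault(str(cid), set()).add(str(cls))
    return {k: frozenset(v) for k, v in out.items()}


def write_class_annotation(classes: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"compound_id": cid, "target_class": cls}
        for cid in sorted(classes)
        for cls in sorted(classes[cid])
    ]
    pd.DataFrame(rows, columns=["compound_id", "target_class"]).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for a (seed, stream-key) pair.

    Every stochastic operation in the package derives its generator through
    this helper, so identical seeds give identical outputs no matter the
    order stages run in.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))
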
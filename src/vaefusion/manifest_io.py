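"""Study-manifest handling: parsing, label policy, view pairing, splitting.

Manifests follow the CheXpert dialect: one row per image with a ``Path``
column, a ``Frontal/Lateral`` view column, an ``AP/PA/Lateral`` projection
column and per-finding label columns coded ``1.0`` (positive), ``0.0``
(negative), ``-1.0`` (uncertain) or blank (missing). The label policy for the
target finding is uncertain-to-positive: uncertain labels are treated as
positive, and rows whose target label is missing are dropped before pairing.
Patients contribute one frontal/lateral image pair each; patients with only
one view are excluded. Train/test splitting is at patient level so no patient
appears on both sides.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = ["View", "Projection", "RawLabel", "DROP", "StudyRecord",
           "PairedStudy", "DatasetSplit", "parse_manifest", "resolve_label",
           "build_pairs", "split_dataset", "write_pairs_table"]


class View(Enum):
    FRONTAL = "frontal"
    LATERAL = "lateral"


class Projection(Enum):
    AP = "AP"
    PA = "PA"
    LA = "LA"
    UNKNOWN = "unknown"


class RawLabel(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNCERTAIN = "uncertain"
    MISSING = "missing"


class _Drop:
    """Sentinel: record excluded from pairing by the label policy."""

    def __repr__(self) -> str:
        return "DROP"


DROP = _Drop()

#: manifest cell value -> raw label
_LABEL_CODING = {1.0: RawLabel.POSITIVE, 0.0: RawLabel.NEGATIVE,
                 -1.0: RawLabel.UNCERTAIN}

#: CheXpert convention: the patient folder component of the image path
DEFAULT_PATIENT_PATTERN = r"(patient\d+)"

_REQUIRED_COLUMNS = ("Path", "Frontal/Lateral", "AP/PA/Lateral")


@dataclass(frozen=True)
class StudyRecord:
    """One manifest row for the target finding."""

    patient_id: str
    study_id: str
    view: View
    projection: Projection
    image_path: str
    raw_label: RawLabel


@dataclass(frozen=True)
class PairedStudy:
    """The unit of learning: a frontal and a lateral image with one label."""

    patient_id: str
    frontal: StudyRecord
    lateral: StudyRecord
    label: int


@dataclass(frozen=True)
class DatasetSplit:
    train: list[PairedStudy]
    test: list[PairedStudy]
    split_seed: int


def _parse_label_cell(cell: str) -> RawLabel:
    text = str(cell).strip()
    if text == "" or text.lower() == "nan":
        return RawLabel.MISSING
    value = float(text)
    if value not in _LABEL_CODING:
        raise ValueError(f"unrecognised label code {cell!r}")
    return _LABEL_CODING[value]


def _parse_view_projection(view_cell: str, proj_cell: str) -> tuple[View, Projection]:
    view_text = str(view_cell).strip().lower()
    proj_text = str(proj_cell).strip().upper()
    if view_text == "frontal":
        view = View.FRONTAL
    elif view_text == "lateral":
        view = View.LATERAL
    else:
        raise ValueError(f"unrecognised view {view_cell!r}")
    if proj_text in ("AP", "PA"):
        proj = Projection[proj_text]
    elif proj_text in ("LA", "LATERAL"):
        proj = Projection.LA
    else:
        proj = Projection.UNKNOWN
    # lateral records carry LA/unknown projections; frontal ones AP or PA
    if view is View.FRONTAL and proj not in (Projection.AP, Projection.PA):
        raise ValueError(f"frontal row with projection {proj_cell!r}")
    if view is View.LATERAL and proj not in (Projection.LA, Projection.UNKNOWN):
        raise ValueError(f"lateral row with projection {proj_cell!r}")
    return view, proj


def parse_manifest(csv_path: str | Path, target_column: str,
                   patient_pattern: str = DEFAULT_PATIENT_PATTERN) -> list[StudyRecord]:
    """Parse a CheXpert-dialect manifest into study records.

    Rows that cannot be interpreted (bad view/projection combination,
    unmatched patient id, unparseable label code) are skipped with a logged
    warning carrying the row index; a missing required column raises
    :class:`ConfigurationError` naming the column.
    """
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    for column in (*_REQUIRED_COLUMNS, target_column):
        if column not in frame.columns:
            raise ConfigurationError(
                f"manifest {csv_path} is missing required column {column!r}")
    pattern = re.compile(patient_pattern)
    records: list[StudyRecord] = []
    for index in range(len(frame)):
        try:
            path = frame.iloc[index]["Path"].strip()
            if not path:
                raise ValueError("empty image path")
            match = pattern.search(path)
            if match is None:
                raise ValueError(f"no patient id matching {patient_pattern!r} in path")
            view, proj = _parse_view_projection(frame.iloc[index]["Frontal/Lateral"],
                                                frame.iloc[index]["AP/PA/Lateral"])
            raw_label = _parse_label_cell(frame.iloc[index][target_column])
        except ValueError as exc:
            logger.warning("skipping manifest row %d: %s", index, exc)
            continue
        patient_id = match.group(1) if match.groups() else match.group(0)
        study_match = re.search(r"(study\d+)", path)
        study_id = study_match.group(1) if study_match else patient_id
        records.append(StudyRecord(patient_id=patient_id, study_id=study_id,
                                   view=view, projection=proj, image_path=path,
                                   raw_label=raw_label))
    return records


def resolve_label(raw_label: RawLabel) -> int | _Drop:
    """Apply the uncertain-to-positive label policy for the target finding.

    positive -> 1, uncertain -> 1, negative -> 0, missing -> DROP (the record
    is excluded before pairing).
    """
    if raw_label is RawLabel.POSITIVE or raw_label is RawLabel.UNCERTAIN:
        return 1
    if raw_label is RawLabel.NEGATIVE:
        return 0
    if raw_label is RawLabel.MISSING:
        return DROP
    raise ConfigurationError(f"invalid raw label {raw_label!r}")


def build_pairs(records: list[StudyRecord]) -> list[PairedStudy]:
    """Pair each patient's frontal and lateral records.

    Records whose label resolves to DROP are excluded first. Patients with
    only one surviving view contribute nothing. When a patient has several
    candidates for a view, the lexicographically smallest image path wins,
    which makes pairing independent of manifest row order. The pair label is
    the frontal record's resolved label; a frontal/lateral disagreement is
    logged as a warning.
    """
    surviving = [r for r in records if resolve_label(r.raw_label) is not DROP]
    by_patient: dict[str, dict[View, list[StudyRecord]]] = {}
    for record in surviving:
        by_patient.setdefault(record.patient_id, {}).setdefault(record.view, []).append(record)
    pairs: list[PairedStudy] = []
    for patient_id in sorted(by_patient):
        views = by_patient[patient_id]
        if View.FRONTAL not in views or View.LATERAL not in views:
            continue
        frontal = min(views[View.FRONTAL], key=lambda r: r.image_path)
        lateral = min(views[View.LATERAL], key=lambda r: r.image_path)
        label_f = resolve_label(frontal.raw_label)
        label_l = resolve_label(lateral.raw_label)
        if label_f != label_l:
            logger.warning("patient %s: frontal label %s disagrees with lateral %s; "
                           "using frontal", patient_id, label_f, label_l)
        pairs.append(PairedStudy(patient_id=patient_id, frontal=frontal,
                                 lateral=lateral, label=int(label_f)))
    return pairs


def split_dataset(pairs: list[PairedStudy], ratio: float, seed: int) -> DatasetSplit:
    """Patient-level train/test split: seeded shuffle of patient ids, then a
    prefix/suffix cut at `ratio`. Deterministic for a fixed seed."""
    if not 0.0 < ratio < 1.0:
        raise ConfigurationError(f"split ratio must be in (0, 1), got {ratio}")
    patients = sorted({p.patient_id for p in pairs})
    if len(patients) < 2:
        raise DegenerateInputError(
            f"need at least 2 distinct patients to split, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    n_train = int(round(ratio * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_ids = set(order[:n_train])
    train = [p for p in pairs if p.patient_id in train_ids]
    test = [p for p in pairs if p.patient_id not in train_ids]
    return DatasetSplit(train=train, test=test, split_seed=seed)


def write_pairs_table(split: DatasetSplit, path: str | Path) -> None:
    """Persist the canonical pairs table (patient, paths, label, split side)."""
    rows = [
        {"patient_id": p.patient_id, "frontal_path": p.frontal.image_path,
         "lateral_path": p.lateral.image_path, "label": p.label, "split": side}
        for side, members in (("train", split.train), ("test", split.test))
        for p in members
    ]
    pd.DataFrame(rows, columns=["patient_id", "frontal_path", "lateral_path",
                                "label", "split"]).to_csv(path, index=False)
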
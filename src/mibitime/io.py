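"""Reading and writing images, segmentation masks and clinical tables.

Canonical on-disk formats:

* expression images — multi-page TIFF, one page per marker channel, read
  into ``(row, column, channel)`` order;
* segmentation masks — single-channel integer TIFF (or PNG), value 0
  reserved for background;
* clinical tables and marker panels — CSV with fixed column names; unknown
  grade/stage/architecture are empty cells and stay unknown (never imputed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .panel import MarkerPanel, PanelError

DIALECTS = ("instance_labels", "type_grayscale")

#: Clinical CSV column contract.
CLINICAL_COLUMNS = [
    "patient_id",
    "age",
    "grade",
    "stage",
    "architecture",
    "recurrence_time",
    "recurrence_event",
    "os_time",
    "os_event",
]

ARCHITECTURES = ("cold", "mixed", "compartmentalized", "unknown")


class DataError(ValueError):
    """Raised when input data violate the format contract."""


@dataclass
class MultichannelImage:
    """H×W×C nonnegative expression array, one channel per panel marker."""

    pixels: np.ndarray
    patient_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise DataError("expression image must be H×W×C")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise DataError("empty image")
        if not np.all(np.isfinite(self.pixels)):
            raise DataError("non-finite expression values")
        if np.any(self.pixels < 0):
            raise DataError("negative expression values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class SegmentationMap:
    """H×W integer label image; 0 = background.

    Two dialects exist in the wild.  ``instance_labels``: every nonzero
    label is one cell instance, and ``type_table`` maps instance id →
    cell-type name.  ``type_grayscale``: the gray value encodes the cell
    *type* and individual cells are recovered as connected components (the
    paper's released masks use this encoding; touching same-type cells
    merge — a documented limitation).
    """

    labels: np.ndarray
    dialect: str = "instance_labels"
    type_table: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DataError("segmentation must be a single-channel 2-D image")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.any(self.labels != np.round(self.labels)):
                raise DataError("segmentation has non-integer pixel values")
            self.labels = self.labels.astype(np.int64)
        if np.any(self.labels < 0):
            raise DataError("negative segmentation labels")
        if self.dialect not in DIALECTS:
            raise DataError(f"unknown segmentation dialect {self.dialect!r}")
        present = set(np.unique(self.labels).tolist()) - {0}
        if self.dialect == "instance_labels":
            if self.type_table is None:
                raise DataError("instance_labels dialect requires a type_table")
            missing = present - set(self.type_table)
            if missing:
                raise DataError(f"labels with no type_table entry: {sorted(missing)}")
        else:
            if self.type_table is None:
                raise DataError("type_grayscale dialect requires a gray-value → type map")
            missing = present - set(self.type_table)
            if missing:
                raise DataError(f"gray values with no type mapping: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass
class ClinicalRecord:
    """One patient's clinical covariates and outcomes.

    ``grade`` is 1–4 or None (unknown); ``stage`` a TNM string or None;
    ``architecture`` the immune-architecture label from prior spatial work
    (cold / mixed / compartmentalized) or ``"unknown"``.  Either outcome may
    be missing (time None) — such patients are excluded from survival
    analyses, not imputed.
    """

    patient_id: str
    age: float | None = None
    grade: int | None = None
    stage: str | None = None
    architecture: str = "unknown"
    recurrence_time: float | None = None
    recurrence_event: bool | None = None
    os_time: float | None = None
    os_event: bool | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise DataError("missing patient_id")
        for t, label in ((self.recurrence_time, "recurrence_time"), (self.os_time, "os_time")):
            if t is not None and t < 0:
                raise DataError(f"negative {label} for patient {self.patient_id}")
        if self.architecture not in ARCHITECTURES:
            raise DataError(f"unknown architecture {self.architecture!r}")
        if self.grade is not None and not 1 <= self.grade <= 4:
            raise DataError(f"grade out of range for patient {self.patient_id}")

    @property
    def has_recurrence_outcome(self) -> bool:
        return self.recurrence_time is not None and self.recurrence_event is not None

    @property
    def has_os_outcome(self) -> bool:
        return self.os_time is not None and self.os_event is not None


# ---------------------------------------------------------------------------
# images


def write_multichannel_image(path: str | Path, image: MultichannelImage) -> None:
    """Write as a multi-page TIFF, one page per channel."""
    pages = np.moveaxis(image.pixels, -1, 0).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")


def read_multichannel_image(
    path: str | Path, panel: MarkerPanel, patient_id: str | None = None
) -> MultichannelImage:
    """Read a multi-channel TIFF; channel k holds panel marker k.

    Accepts page-ordered (C, H, W) and interleaved (H, W, C) layouts; the
    channel axis is identified as the one matching the panel size.
    """
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise DataError(f"{path}: expected a 2-D or 3-D TIFF, got shape {arr.shape}")
    C = len(panel)
    if arr.shape[0] == C:
        arr = np.moveaxis(arr, 0, -1)
    elif arr.shape[-1] != C:
        raise PanelError(
            f"{path}: image channel count {arr.shape} does not match panel size {C}"
        )
    panel.validate_channel_count(arr.shape[-1])
    if np.any(arr < 0):
        raise DataError(f"{path}: negative expression values")
    pid = patient_id if patient_id is not None else Path(path).stem
    return MultichannelImage(pixels=arr.astype(float), patient_id=pid)


def write_segmentation(path: str | Path, seg: SegmentationMap) -> None:
    labels = seg.labels
    dtype = np.uint16 if labels.max(initial=0) < 2**16 else np.uint32
    tifffile.imwrite(path, labels.astype(dtype))


def read_segmentation(
    path: str | Path,
    dialect: str = "instance_labels",
    type_map: Mapping[int, str] | None = None,
) -> SegmentationMap:
    """Read a single-channel label image (TIFF or PNG) and canonicalise it."""
    if str(path).lower().endswith(".png"):
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
    else:
        arr = np.asarray(tifffile.imread(path))
    if arr.ndim != 2:
        raise DataError(f"{path}: segmentation must be single-channel, got shape {arr.shape}")
    return SegmentationMap(labels=arr, dialect=dialect, type_table=type_map)


def read_type_table(path: str | Path) -> dict[int, str]:
    """CSV with columns (label, cell_type) → mapping."""
    df = pd.read_csv(path)
    if not {"label", "cell_type"} <= set(df.columns):
        raise DataError("type table CSV needs columns 'label' and 'cell_type'")
    return {int(r["label"]): str(r["cell_type"]) for _, r in df.iterrows()}


# ---------------------------------------------------------------------------
# clinical tables


def _parse_optional_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _parse_event(v, patient_id: str, col: str) -> bool | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    if isinstance(v, bool):
        return v
    if isinstance(v, (int, np.integer)) or (isinstance(v, float) and v in (0.0, 1.0)):
        if int(v) in (0, 1):
            return bool(int(v))
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("0", "1"):
            return bool(int(s))
        if s in ("true", "false"):
            return s == "true"
    raise DataError(f"non-boolean event value {v!r} in column {col} for patient {patient_id}")


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str, "stage": str})
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"clinical table missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        pid = row["patient_id"]
        if pid is None or (isinstance(pid, float) and math.isnan(pid)) or str(pid) == "":
            raise DataError("clinical table row with missing patient_id")
        grade = _parse_optional_float(row["grade"])
        stage = row["stage"]
        if stage is None or (isinstance(stage, float) and math.isnan(stage)) or stage == "":
            stage = None
        arch = row["architecture"]
        if arch is None or (isinstance(arch, float) and math.isnan(arch)) or arch == "":
            arch = "unknown"
        records.append(
            ClinicalRecord(
                patient_id=str(pid),
                age=_parse_optional_float(row["age"]),
                grade=int(grade) if grade is not None else None,
                stage=str(stage) if stage is not None else None,
                architecture=str(arch),
                recurrence_time=_parse_optional_float(row["recurrence_time"]),
                recurrence_event=_parse_event(row["recurrence_event"], str(pid), "recurrence_event"),
                os_time=_parse_optional_float(row["os_time"]),
                os_event=_parse_event(row["os_event"], str(pid), "os_event"),
            )
        )
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate patient_id in clinical table")
    return records


def write_clinical_table(path: str | Path, records: Sequence[ClinicalRecord]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "grade": r.grade,
                "stage": r.stage,
                "architecture": r.architecture if r.architecture != "unknown" else "",
                "recurrence_time": r.recurrence_time,
                "recurrence_event": int(r.recurrence_event) if r.recurrence_event is not None else "",
                "os_time": r.os_time,
                "os_event": int(r.os_event) if r.os_event is not None else "",
            }
        )
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def survival_eligible(
    records: Sequence[ClinicalRecord], endpoint: str = "both"
) -> tuple[list[ClinicalRecord], list[ClinicalRecord]]:
    """Split a cohort into patients usable for survival analysis and the rest.

    ``endpoint`` is 'recurrence', 'overall_survival' or 'both' (require
    both outcomes, the convention for a cohort analysed against both
    endpoints).  Patients lacking the required outcome(s) are excluded,
    never imputed.
    """
    def ok(r: ClinicalRecord) -> bool:
        if endpoint == "recurrence":
            return r.has_recurrence_outcome
        if endpoint == "overall_survival":
            return r.has_os_outcome
        if endpoint == "both":
            return r.has_recurrence_outcome and r.has_os_outcome
        raise ValueError(f"unknown endpoint {endpoint!r}")

    kept = [r for r in records if ok(r)]
    dropped = [r for r in records if not ok(r)]
    return kept, dropped
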
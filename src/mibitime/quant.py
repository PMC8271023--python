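"""Per-cell marker quantification and positivity calling.

The quantification follows the background-as-negative-control scheme: a
cell's expression of a marker is the *average per-pixel* channel value over
the cell's pixels, and a cell is called positive for a marker when that
average strictly exceeds the marker's threshold, defined as the pooled mean
per-pixel expression over all background (label-0) pixels of the whole
cohort.  Background pixels lack cells, so their mean level estimates the
non-specific signal floor of each channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .io import DataError, MultichannelImage, SegmentationMap
from .panel import MarkerPanel, PanelError

#: Cell-type vocabulary of the tumor cohort (immune, tumor and stromal
#: populations assigned upstream by lineage gating).
CELL_TYPE_VOCABULARY = (
    "Monocyte/neutrophil",
    "CD8+ T",
    "Macrophage",
    "Mesenchyme",
    "CD4+ T",
    "Tumor",
    "Natural killer",
    "Dendritic/monocyte",
    "Endothelial",
    "B",
    "Neutrophil",
    "Dendritic",
    "CD3+ T",
    "Other",
    "Regulatory T",
)


@dataclass
class ExtractedCell:
    cell_id: int
    cell_type: str
    pixels: np.ndarray  # (N, 2) array of (row, col) coordinates


@dataclass
class CellRecord:
    """One cell's quantified state."""

    cell_id: int
    patient_id: str
    cell_type: str
    size_pixels: int
    centroid: tuple[float, float]
    mean_expression: np.ndarray | None = None  # length-P, panel order
    positive_markers: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.size_pixels < 1:
            raise DataError("cell with no pixels")


@dataclass
class PositivityThresholds:
    """Per-marker positivity thresholds from pooled background pixels."""

    panel: MarkerPanel
    thresholds: np.ndarray  # length-P, per-pixel expression units
    background_pixel_count: int

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.background_pixel_count <= 0:
            raise DataError("thresholds require at least one background pixel")
        if np.any(self.thresholds < 0) or not np.all(np.isfinite(self.thresholds)):
            raise DataError("invalid threshold values")

    def __getitem__(self, marker: str) -> float:
        return float(self.thresholds[self.panel.index(marker)])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"marker": self.panel.names, "threshold": self.thresholds}
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------


def instance_labels(seg: SegmentationMap) -> tuple[np.ndarray, dict[int, str]]:
    """Canonical instance-label image and id → type map for either dialect.

    ``instance_labels`` masks are passed through.  ``type_grayscale`` masks
    are decomposed one gray value at a time into 8-connected components,
    each component becoming one cell; ids are assigned sequentially in
    (gray value, scan order).
    """
    if seg.dialect == "instance_labels":
        return seg.labels.astype(np.int64), dict(seg.type_table)  # type: ignore[arg-type]
    out = np.zeros(seg.labels.shape, dtype=np.int64)
    types: dict[int, str] = {}
    next_id = 1
    for gray in sorted(int(g) for g in np.unique(seg.labels) if g != 0):
        comp = measure.label(seg.labels == gray, connectivity=2)
        n = int(comp.max())
        out[comp > 0] = comp[comp > 0] + (next_id - 1)
        for k in range(n):
            types[next_id + k] = seg.type_table[gray]  # type: ignore[index]
        next_id += n
    return out, types


def extract_cells(seg: SegmentationMap) -> list[ExtractedCell]:
    """One ExtractedCell per cell instance, deterministic scan-order ids."""
    labels, types = instance_labels(seg)
    flat = labels.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    ids, starts = np.unique(sorted_labels, return_index=True)
    H, W = labels.shape
    cells = []
    bounds = list(starts) + [flat.size]
    for i, cid in enumerate(ids):
        if cid == 0:
            continue
        lin = order[bounds[i] : bounds[i + 1]]
        pix = np.column_stack((lin // W, lin % W))
        cells.append(ExtractedCell(int(cid), types[int(cid)], pix))
    cells.sort(key=lambda c: c.cell_id)
    return cells


def centroid(cell: ExtractedCell) -> tuple[float, float]:
    """Unweighted mean pixel coordinate, 0-based (row, col)."""
    m = cell.pixels.mean(axis=0)
    return float(m[0]), float(m[1])


def mean_expression(
    image: MultichannelImage,
    cells: Sequence[ExtractedCell],
    panel: MarkerPanel,
) -> list[CellRecord]:
    """Average per-pixel expression of every marker for every cell.

    For each cell, channel values are summed over the cell's pixels and
    divided by its size in pixels.
    """
    H, W, C = image.pixels.shape
    panel.validate_channel_count(C)
    records = []
    chan_order = [m.channel_index for m in panel.markers]
    for cell in cells:
        r, c = cell.pixels[:, 0], cell.pixels[:, 1]
        if r.max(initial=0) >= H or c.max(initial=0) >= W:
            raise DataError("segmentation and image dimensions do not match")
        sums = image.pixels[r, c, :].sum(axis=0)
        records.append(
            CellRecord(
                cell_id=cell.cell_id,
                patient_id=image.patient_id,
                cell_type=cell.cell_type,
                size_pixels=len(cell.pixels),
                centroid=centroid(cell),
                mean_expression=sums[chan_order] / len(cell.pixels),
            )
        )
    return records


def background_thresholds(
    pairs: Iterable[tuple[MultichannelImage, SegmentationMap]],
    panel: MarkerPanel,
) -> PositivityThresholds:
    """Pooled cohort-wide background mean per marker.

    threshold[m] = (sum of channel m over every background pixel of every
    image) / (total background pixels across the cohort).  Background is
    every label-0 pixel.
    """
    total = np.zeros(len(panel), dtype=float)
    n_bg = 0
    chan_order = [m.channel_index for m in panel.markers]
    for image, seg in pairs:
        if image.pixels.shape[:2] != seg.labels.shape:
            raise DataError(
                f"image/mask shape mismatch for patient {image.patient_id}"
            )
        bg = seg.labels == 0
        n = int(bg.sum())
        if n:
            total += image.pixels[bg][:, chan_order].sum(axis=0)
            n_bg += n
    if n_bg == 0:
        raise DataError("cohort has zero background pixels; cannot derive thresholds")
    return PositivityThresholds(panel=panel, thresholds=total / n_bg, background_pixel_count=n_bg)


def positivity_calls(
    records: Sequence[CellRecord], thresholds: PositivityThresholds
) -> list[CellRecord]:
    """Fill ``positive_markers``: mean expression strictly above threshold.

    The boundary case (mean equal to the background level) is negative —
    background-equal expression carries no evidence of signal.
    """
    names = thresholds.panel.names
    for rec in records:
        if rec.mean_expression is None:
            raise DataError("positivity_calls requires mean_expression")
        pos = np.asarray(rec.mean_expression) > thresholds.thresholds
        rec.positive_markers = {names[i] for i in np.nonzero(pos)[0]}
    return list(records)


def positivity_proportions(
    records: Sequence[CellRecord], panel: MarkerPanel
) -> pd.DataFrame:
    """Per patient, the fraction of cells positive for each marker."""
    pids = sorted({r.patient_id for r in records})
    out = pd.DataFrame(0.0, index=pids, columns=panel.names)
    counts = pd.Series(0, index=pids, dtype=int)
    for r in records:
        counts[r.patient_id] += 1
        for m in r.positive_markers:
            out.loc[r.patient_id, m] += 1
    if (counts == 0).any():
        raise DataError("patient with zero cells")
    out = out.div(counts, axis=0)
    out.index.name = "patient_id"
    return out


def composition_proportions(
    records: Sequence[CellRecord],
    vocabulary: Sequence[str] = CELL_TYPE_VOCABULARY,
) -> pd.DataFrame:
    """Per patient, each cell type's share of the patient's total cells.

    Dividing by the total cell count controls for the large variation in
    cells per image.  Columns cover the standard vocabulary plus any extra
    types present; each row sums to 1.
    """
    if not records:
        raise DataError("no cells")
    extra = sorted({r.cell_type for r in records} - set(vocabulary))
    cols = list(vocabulary) + extra
    pids = sorted({r.patient_id for r in records})
    out = pd.DataFrame(0.0, index=pids, columns=cols)
    for r in records:
        out.loc[r.patient_id, r.cell_type] += 1
    totals = out.sum(axis=1)
    if (totals == 0).any():
        raise DataError("patient with zero cells")
    out = out.div(totals, axis=0)
    out.index.name = "patient_id"
    return out


# ---------------------------------------------------------------------------
# CSV interchange


def records_to_frame(records: Sequence[CellRecord], panel: MarkerPanel) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "cell_id": r.cell_id,
            "patient_id": r.patient_id,
            "cell_type": r.cell_type,
            "size_pixels": r.size_pixels,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
        }
        if r.mean_expression is not None:
            for name, v in zip(panel.names, r.mean_expression):
                row[f"mean_{name}"] = v
        row["positive_markers"] = "|".join(sorted(r.positive_markers))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame, panel: MarkerPanel) -> list[CellRecord]:
    mean_cols = [f"mean_{n}" for n in panel.names]
    have_means = all(c in df.columns for c in mean_cols)
    records = []
    for _, row in df.iterrows():
        pos = row.get("positive_markers", "")
        if not isinstance(pos, str):
            pos = ""
        records.append(
            CellRecord(
                cell_id=int(row["cell_id"]),
                patient_id=str(row["patient_id"]),
                cell_type=str(row["cell_type"]),
                size_pixels=int(row["size_pixels"]),
                centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
                mean_expression=row[mean_cols].to_numpy(dtype=float) if have_means else None,
                positive_markers=set(p for p in pos.split("|") if p),
            )
        )
    return records
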
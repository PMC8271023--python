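"""Marker-pair count matrices and their flattening to feature vectors.

Two flavors share one container.  *Co-expression*: a single cell positive
for a pair of markers contributes one count to that pair — a cell positive
for k markers contributes all k(k−1)/2 unordered pairs (e.g. a cell
positive for IDO, Lag3 and PD-1 yields IDO/Lag3, IDO/PD-1 and Lag3/PD-1).
*Interaction*: counts come from adjacent cell pairs (see
:mod:`mibitime.spatial`).

Per-patient matrices are symmetric; the upper triangle is flattened into a
named feature vector so patients can be compared and clustered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DataError
from .panel import PanelError
from .quant import CellRecord

FLAVORS = ("coexpression", "interaction")


@dataclass
class PairCountMatrix:
    """Symmetric P×P nonnegative integer tally over an ordered marker list."""

    markers: tuple[str, ...]
    counts: np.ndarray
    flavor: str = "coexpression"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        P = len(self.markers)
        if self.counts.shape != (P, P):
            raise DataError("counts shape does not match marker list")
        if self.flavor not in FLAVORS:
            raise DataError(f"unknown flavor {self.flavor!r}")
        if np.any(self.counts < 0):
            raise DataError("negative counts")
        if not np.array_equal(self.counts, self.counts.T):
            raise DataError("pair-count matrix must be symmetric")

    def submatrix(self, markers: Sequence[str]) -> "PairCountMatrix":
        idx = [self.markers.index(m) for m in markers]
        return PairCountMatrix(
            markers=tuple(markers),
            counts=self.counts[np.ix_(idx, idx)],
            flavor=self.flavor,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.markers, columns=self.markers)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, flavor: str = "coexpression") -> "PairCountMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(markers=tuple(df.columns), counts=df.to_numpy(), flavor=flavor)


def pair_name(a: str, b: str) -> str:
    """Canonical alphabetical name of an unordered marker pair."""
    return "+".join(sorted((a, b)))


def coexpression_matrix(
    records: Sequence[CellRecord], marker_subset: Sequence[str]
) -> PairCountMatrix:
    """Count, over all cells, joint positivity of every marker pair.

    counts[A][B] (A≠B) = number of cells positive for both A and B; the
    diagonal holds plain positivity counts (cells positive for A).
    """
    if not marker_subset:
        raise PanelError("empty marker subset")
    markers = tuple(marker_subset)
    index = {m: i for i, m in enumerate(markers)}
    P = len(markers)
    counts = np.zeros((P, P), dtype=np.int64)
    for rec in records:
        pos = [index[m] for m in rec.positive_markers if m in index]
        for i in pos:
            for j in pos:
                counts[i, j] += 1
    return PairCountMatrix(markers=markers, counts=counts, flavor="coexpression")


def flatten_features(
    matrix: PairCountMatrix, include_diagonal: bool = False
) -> pd.Series:
    """Upper-triangle entries as a named vector.

    Entries run row-major in marker order; names are canonical alphabetical
    "A+B" so vectors align across patients regardless of marker ordering.
    Length is P(P−1)/2 without the diagonal, P(P+1)/2 with it.
    """
    P = len(matrix.markers)
    k = 0 if include_diagonal else 1
    rows, cols = np.triu_indices(P, k=k)
    names = [pair_name(matrix.markers[i], matrix.markers[j]) for i, j in zip(rows, cols)]
    return pd.Series(matrix.counts[rows, cols].astype(float), index=names)


def unflatten_features(
    features: Mapping[str, float] | pd.Series, markers: Sequence[str], flavor: str = "coexpression"
) -> PairCountMatrix:
    """Inverse of :func:`flatten_features` with the diagonal included."""
    markers = tuple(markers)
    P = len(markers)
    counts = np.zeros((P, P))
    for i in range(P):
        for j in range(i, P):
            counts[i, j] = counts[j, i] = features[pair_name(markers[i], markers[j])]
    return PairCountMatrix(markers=markers, counts=counts, flavor=flavor)


def cohort_feature_table(
    matrices: Mapping[str, PairCountMatrix], include_diagonal: bool = False
) -> pd.DataFrame:
    """Patients × named pair features, rows in sorted patient order."""
    rows = {
        pid: flatten_features(m, include_diagonal=include_diagonal)
        for pid, m in matrices.items()
    }
    df = pd.DataFrame(rows).T.sort_index()
    df.index.name = "patient_id"
    return df


def cube_root_display(matrix: PairCountMatrix) -> pd.DataFrame:
    """Cube-root transform of the counts, for heatmap display only."""
    return pd.DataFrame(
        np.cbrt(matrix.counts.astype(float)), index=matrix.markers, columns=matrix.markers
    )
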
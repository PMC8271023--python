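"""Synthetic MIBI-like cohorts with planted spatial phenotypes.

Generates multi-channel expression images, instance segmentation masks,
clinical tables and a ground-truth table with the statistical structure
the downstream analysis assumes:

* cell centers from a minimum-distance (blue-noise) point process; every
  pixel joins its nearest center, then each region is shrunk by one pixel
  so a background skeleton always exists for thresholding;
* per-cell marker positivity drawn from per-(cell type, marker)
  probabilities; per-pixel channel intensities are gamma distributed
  (nonnegative, right-skewed, ion-count-like) with mean ``expr_pos_mean``
  where the cell is positive, ``expr_neg_mean`` where negative, and
  ``background_mean`` off-cell.  Negative cells sit *below* the background
  level so that the background-derived positivity threshold is meaningful;
* patients alternate between two groups; in group 1, each Voronoi-adjacent
  cell pair independently receives the planted (A+, B+) phenotype with
  probability ``colocalization_rho``, enriching the planted marker-pair
  interaction count;
* recurrence and overall-survival times are exponential with group-0 rate
  ``hazard_rate_group0`` and group-1 rate scaled by ``hazard_ratio``
  (shared group effect, independent noise per endpoint), censored
  independently at the requested rate.

One global seed; per-patient substreams are derived deterministically so
any patient can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import (
    ClinicalRecord,
    MultichannelImage,
    SegmentationMap,
    write_clinical_table,
    write_multichannel_image,
    write_segmentation,
)
from .panel import MarkerPanel
from .spatial import voronoi_adjacency

DEFAULT_FUNCTIONAL = (
    "PD-1",
    "PD-L1",
    "IDO",
    "Lag3",
    "CD45RO",
    "Ki67",
    "HLA-DR",
    "phospho-S6",
)
DEFAULT_LINEAGE = ("Pan-Keratin", "CD45")

DEFAULT_TYPE_PROPORTIONS = {
    "Tumor": 0.45,
    "CD8+ T": 0.15,
    "CD4+ T": 0.15,
    "Macrophage": 0.15,
    "B": 0.10,
}

#: Baseline chance that a cell of a given type expresses a marker; pairs
#: not listed fall back to ``DEFAULT_POSITIVITY``.
DEFAULT_POSITIVITY_PROBS = {
    ("CD8+ T", "PD-1"): 0.35,
    ("CD4+ T", "PD-1"): 0.25,
    ("CD8+ T", "Lag3"): 0.20,
    ("CD4+ T", "Lag3"): 0.15,
    ("Tumor", "PD-L1"): 0.30,
    ("Macrophage", "PD-L1"): 0.30,
    ("Tumor", "IDO"): 0.20,
    ("Macrophage", "IDO"): 0.15,
    ("CD8+ T", "CD45RO"): 0.45,
    ("CD4+ T", "CD45RO"): 0.45,
    ("B", "CD45RO"): 0.25,
    ("Tumor", "Ki67"): 0.40,
    ("Macrophage", "HLA-DR"): 0.55,
    ("B", "HLA-DR"): 0.50,
    ("Tumor", "phospho-S6"): 0.25,
    ("CD8+ T", "phospho-S6"): 0.15,
    ("Tumor", "Pan-Keratin"): 0.90,
    ("CD8+ T", "CD45"): 0.90,
    ("CD4+ T", "CD45"): 0.90,
    ("Macrophage", "CD45"): 0.90,
    ("B", "CD45"): 0.90,
}
DEFAULT_POSITIVITY = 0.05


def default_panel() -> MarkerPanel:
    names = list(DEFAULT_FUNCTIONAL) + list(DEFAULT_LINEAGE)
    categories = ["functional"] * len(DEFAULT_FUNCTIONAL) + ["lineage"] * len(DEFAULT_LINEAGE)
    return MarkerPanel.from_names(names, categories)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the desk-scale analogue of the tumor cohort: 40 patients,
    ~400 cells per image (cell-count coefficient of variation 0.1 — modest
    dispersion beyond the point process; the heavier heterogeneity of real
    cohorts is deliberately not emulated), a 10-marker panel
    containing the four immunoregulatory proteins, a planted PD-1/IDO
    adjacency phenotype at rho = 0.9 and a group hazard ratio of 3 with
    ~30% censoring.
    """

    n_patients: int = 40
    image_size: tuple[int, int] = (384, 384)
    mean_cells_per_image: int = 400
    cell_count_cv: float = 0.1
    panel: MarkerPanel = field(default_factory=default_panel)
    type_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS)
    )
    positivity_probs: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_POSITIVITY_PROBS)
    )
    default_positivity: float = DEFAULT_POSITIVITY
    expr_pos_mean: float = 20.0
    expr_neg_mean: float = 0.5
    background_mean: float = 1.0
    gamma_shape: float = 3.0
    colocalization_rho: float = 0.9
    planted_pair: tuple[str, str] = ("PD-1", "IDO")
    hazard_rate_group0: float = 0.02
    hazard_ratio: float = 3.0
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.expr_pos_mean > self.background_mean > 0):
            raise ValueError("require expr_pos_mean > background_mean > 0")
        if not self.expr_pos_mean > self.expr_neg_mean:
            raise ValueError("require expr_pos_mean > expr_neg_mean")
        if not 0 <= self.colocalization_rho <= 1:
            raise ValueError("colocalization_rho must be in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        probs = list(self.type_proportions.values())
        if abs(sum(probs) - 1) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("type_proportions must be a probability vector")
        for a in self.planted_pair:
            if a not in self.panel.names:
                raise ValueError(f"planted marker {a!r} not in panel")


@dataclass
class PatientTruth:
    """Generator-side ground truth for one patient."""

    patient_id: str
    group: int
    cell_types: list[str]
    positivity: pd.DataFrame  # cells × markers, bool; index = cell_id
    planted_pair_count: int
    centers: np.ndarray  # (n_cells, 2) float (row, col)


def patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    """Deterministic per-patient substream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, patient_index]))


def _blue_noise_centers(
    rng: np.random.Generator, H: int, W: int, n: int
) -> np.ndarray:
    """Uniform proposals with minimum-distance rejection."""
    min_dist = 0.7 * np.sqrt(H * W / n)
    centers: list[np.ndarray] = []
    max_tries = 400 * n
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"image {H}×{W} too small to place {n} cells at spacing {min_dist:.1f}"
            )
        p = rng.uniform([0, 0], [H, W])
        if centers:
            arr = np.array(centers)
            if np.min(np.sum((arr - p) ** 2, axis=1)) < min_dist**2:
                continue
        centers.append(p)
    return np.array(centers)


def _label_image(centers: np.ndarray, H: int, W: int) -> np.ndarray:
    """Nearest-center tiling, then shrink every region by one pixel."""
    rows, cols = np.mgrid[0:H, 0:W]
    grid = np.column_stack([rows.ravel(), cols.ravel()])
    _, nearest = cKDTree(centers).query(grid)
    labels = (nearest + 1).reshape(H, W).astype(np.int64)
    interior = (
        ndimage.maximum_filter(labels, size=3) == ndimage.minimum_filter(labels, size=3)
    )
    eroded = np.where(interior, labels, 0)
    # a sliver region can vanish entirely; restore it at its center pixel
    present = set(np.unique(eroded).tolist())
    for cid in range(1, len(centers) + 1):
        if cid not in present:
            r = int(np.clip(round(centers[cid - 1][0]), 0, H - 1))
            c = int(np.clip(round(centers[cid - 1][1]), 0, W - 1))
            eroded[r, c] = cid
    return eroded


def _draw_positivity(
    rng: np.random.Generator,
    config: SyntheticConfig,
    cell_types: Sequence[str],
) -> np.ndarray:
    n = len(cell_types)
    markers = config.panel.names
    pos = np.zeros((n, len(markers)), dtype=bool)
    for j, m in enumerate(markers):
        p = np.array(
            [
                config.positivity_probs.get((t, m), config.default_positivity)
                for t in cell_types
            ]
        )
        pos[:, j] = rng.random(n) < p
    return pos


def generate_patient(
    config: SyntheticConfig, patient_index: int
) -> tuple[MultichannelImage, SegmentationMap, PatientTruth]:
    """Generate one patient's image, mask and ground truth.

    Group membership alternates with patient index (balanced by
    construction); randomness comes from the per-patient substream so the
    patient is reproducible in isolation.
    """
    rng = patient_rng(config.seed, patient_index)
    H, W = config.image_size
    pid = f"P{patient_index:03d}"
    group = patient_index % 2

    n_cells = int(
        max(
            8,
            round(
                rng.normal(
                    config.mean_cells_per_image,
                    config.cell_count_cv * config.mean_cells_per_image,
                )
            ),
        )
    )
    if n_cells * 9 > H * W:
        raise ValueError(
            f"image {H}×{W} too small for {n_cells} cells: each cell needs at "
            "least a 3×3 pixel footprint to survive boundary erosion"
        )
    centers = _blue_noise_centers(rng, H, W, n_cells)
    labels = _label_image(centers, H, W)

    type_names = list(config.type_proportions)
    type_p = np.array([config.type_proportions[t] for t in type_names])
    cell_types = [type_names[i] for i in rng.choice(len(type_names), n_cells, p=type_p)]
    pos = _draw_positivity(rng, config, cell_types)

    markers = config.panel.names
    ia = markers.index(config.planted_pair[0])
    ib = markers.index(config.planted_pair[1])
    cents = {i + 1: (float(centers[i][0]), float(centers[i][1])) for i in range(n_cells)}
    graph = voronoi_adjacency(cents)
    if group == 1 and config.colocalization_rho > 0:
        # Exclusive pairing: each cell joins at most one planted pairing, so
        # planted A+ cells are guaranteed adjacent to planted B+ cells while
        # marker marginals stay far from saturation — the enrichment is
        # genuinely spatial, not a side effect of inflated positivity.
        edge_list = sorted(tuple(sorted(edge)) for edge in graph.edges)
        rng.shuffle(edge_list)
        planted_cells: set[int] = set()
        for u, v in edge_list:
            if u in planted_cells or v in planted_cells:
                continue
            if rng.random() < config.colocalization_rho:
                if rng.random() < 0.5:
                    u, v = v, u
                pos[u - 1, ia] = True
                pos[v - 1, ib] = True
                planted_cells.update((u, v))

    # true planted-pair interaction count (ordered assignments over edges)
    planted = 0
    for e in graph.edges:
        u, v = tuple(e)
        planted += int(pos[u - 1, ia] and pos[v - 1, ib])
        if ia != ib:
            planted += int(pos[u - 1, ib] and pos[v - 1, ia])

    # render channels: gamma noise around the per-pixel mean level
    chan_indices = [m.channel_index for m in config.panel.markers]
    C = max(chan_indices) + 1
    pixels = np.empty((H, W, C), dtype=float)
    cell_idx = labels - 1  # -1 where background
    on_cell = labels > 0
    for j, chan in enumerate(chan_indices):
        cell_mean = np.where(pos[:, j], config.expr_pos_mean, config.expr_neg_mean)
        mean_map = np.full((H, W), config.background_mean)
        mean_map[on_cell] = cell_mean[cell_idx[on_cell]]
        pixels[:, :, chan] = rng.gamma(
            config.gamma_shape, mean_map / config.gamma_shape
        )

    image = MultichannelImage(pixels=pixels, patient_id=pid)
    type_table = {i + 1: cell_types[i] for i in range(n_cells)}
    seg = SegmentationMap(labels=labels, dialect="instance_labels", type_table=type_table)
    truth = PatientTruth(
        patient_id=pid,
        group=group,
        cell_types=list(cell_types),
        positivity=pd.DataFrame(pos, index=range(1, n_cells + 1), columns=markers),
        planted_pair_count=planted,
        centers=centers,
    )
    return image, seg, truth


def generate_survival(
    groups: Sequence[int],
    hazard_rate_group0: float,
    hazard_ratio: float,
    censoring_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times under independent uniform censoring.

    Group-g rate is ``hazard_rate_group0 * hazard_ratio**g``.  Censoring
    times are Uniform(0, c_max), drawn independently of the event times;
    ``c_max`` is calibrated so the expected fraction censored equals
    ``censoring_rate``.  A subject is an event iff the event time precedes
    the censoring time.
    """
    from scipy.optimize import brentq

    groups = np.asarray(groups)
    rates = hazard_rate_group0 * hazard_ratio**groups
    t_event = rng.exponential(1.0 / rates)
    if censoring_rate <= 0:
        return t_event, np.ones(len(groups), dtype=bool)

    # P(C < T) for C ~ U(0, c) and T ~ Exp(lam) is (1 - exp(-lam c))/(lam c)
    def expected_censoring(c: float) -> float:
        x = rates * c
        return float(np.mean((1 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1.0
    while expected_censoring(hi) > censoring_rate:
        hi *= 2
    c_max = brentq(lambda c: expected_censoring(c) - censoring_rate, lo, hi)
    t_cens = rng.uniform(0, c_max, len(groups))
    events = t_event <= t_cens
    return np.where(events, t_event, t_cens), events


def generate_clinical(
    config: SyntheticConfig,
    patient_ids: Sequence[str],
    groups: Sequence[int],
    rng: np.random.Generator,
) -> list[ClinicalRecord]:
    """Clinical covariates plus both survival endpoints.

    Ages ~ N(54, 15); grade drawn with the tumor-cohort frequencies
    (mostly grade 3); architecture uniform over the three immune-
    architecture labels.  Covariates are outcome-independent noise; only
    the group carries hazard signal.
    """
    n = len(patient_ids)
    rec_t, rec_e = generate_survival(
        groups, config.hazard_rate_group0, config.hazard_ratio, config.censoring_rate, rng
    )
    os_t, os_e = generate_survival(
        groups, config.hazard_rate_group0, config.hazard_ratio, config.censoring_rate, rng
    )
    ages = np.clip(rng.normal(54, 15, n), 25, 92)
    grades = rng.choice([1, 2, 3, 4], n, p=[0.03, 0.13, 0.76, 0.08])
    archs = rng.choice(["cold", "mixed", "compartmentalized"], n)
    stages = rng.choice(["1", "2A", "2B", "3A", ""], n)
    records = []
    for i, pid in enumerate(patient_ids):
        records.append(
            ClinicalRecord(
                patient_id=pid,
                age=float(round(ages[i], 1)),
                grade=int(grades[i]),
                stage=str(stages[i]) or None,
                architecture=str(archs[i]),
                recurrence_time=float(rec_t[i]),
                recurrence_event=bool(rec_e[i]),
                os_time=float(os_t[i]),
                os_event=bool(os_e[i]),
            )
        )
    return records


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    images: list[MultichannelImage]
    segmentations: list[SegmentationMap]
    truths: list[PatientTruth]
    clinical: list[ClinicalRecord]

    @property
    def patient_ids(self) -> list[str]:
        return [t.patient_id for t in self.truths]

    @property
    def groups(self) -> dict[str, int]:
        return {t.patient_id: t.group for t in self.truths}

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "group": [t.group for t in self.truths],
                "n_cells": [len(t.cell_types) for t in self.truths],
                "planted_pair_count": [t.planted_pair_count for t in self.truths],
            }
        )


def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate the whole cohort in memory."""
    images, segs, truths = [], [], []
    for i in range(config.n_patients):
        img, seg, truth = generate_patient(config, i)
        images.append(img)
        segs.append(seg)
        truths.append(truth)
    rng = patient_rng(config.seed, config.n_patients)  # clinical substream
    clinical = generate_clinical(
        config, [t.patient_id for t in truths], [t.group for t in truths], rng
    )
    return SyntheticCohort(config, images, segs, truths, clinical)


def generate_cohort(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Generate and write a cohort in the exact formats the readers consume.

    Layout: ``images/<pid>.tiff``, ``masks/<pid>.tiff``,
    ``types/<pid>.csv``, ``panel.csv``, ``clinical.csv``, ``truth.csv``.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)
    (outdir / "types").mkdir(exist_ok=True)
    cohort = simulate_cohort(config)
    for img, seg, truth in zip(cohort.images, cohort.segmentations, cohort.truths):
        write_multichannel_image(outdir / "images" / f"{img.patient_id}.tiff", img)
        write_segmentation(outdir / "masks" / f"{img.patient_id}.tiff", seg)
        pd.DataFrame(
            {
                "label": list(seg.type_table),  # type: ignore[arg-type]
                "cell_type": [seg.type_table[k] for k in seg.type_table],  # type: ignore[index]
            }
        ).to_csv(outdir / "types" / f"{img.patient_id}.csv", index=False)
    config.panel.to_csv(outdir / "panel.csv")
    write_clinical_table(outdir / "clinical.csv", cohort.clinical)
    cohort.truth_table().to_csv(outdir / "truth.csv", index=False)
    return {
        "outdir": str(outdir),
        "n_patients": config.n_patients,
        "patient_ids": cohort.patient_ids,
    }
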
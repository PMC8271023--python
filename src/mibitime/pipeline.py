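"""End-to-end orchestration: quantify → features → cluster → survival →
importance → report.

Every stage exchanges plain CSV/JSON through the output directory, so any
stage can be inspected, replaced, or resumed independently.  All
randomness flows from the seeds recorded in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import ClusterAssignment, cluster_cohort
from .coexpression import (
    PairCountMatrix,
    coexpression_matrix,
    cohort_feature_table,
    cube_root_display,
)
from .io import (
    ClinicalRecord,
    read_clinical_table,
    read_multichannel_image,
    read_segmentation,
    read_type_table,
    survival_eligible,
)
from .panel import MarkerPanel
from .quant import (
    CellRecord,
    background_thresholds,
    composition_proportions,
    extract_cells,
    mean_expression,
    positivity_calls,
    positivity_proportions,
    records_to_frame,
)
from .spatial import interaction_matrix, radius_adjacency, subset_features, voronoi_adjacency
from .stats import (
    cox_fit,
    logrank_test,
    rf_importance,
    survival_rf_shap,
    univariate_cox_table,
)

logger = logging.getLogger(__name__)

FEATURE_FAMILIES = ("coexpression", "interaction", "immunoregulatory", "homotypic", "lineage")


class StageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts are retained."""


@dataclass
class PipelineConfig:
    images_dir: str = "images"
    masks_dir: str = "masks"
    types_dir: str = "types"
    panel_csv: str = "panel.csv"
    clinical_csv: str = "clinical.csv"
    output_dir: str = "output"
    dialect: str = "instance_labels"
    adjacency: str = "voronoi"  # or "radius" (comparison only)
    adjacency_radius: float | None = None
    linkage: str = "ward"
    metric: str = "euclidean"
    k: int | None = None  # None → silhouette selection
    k_range: tuple[int, int] = (2, 6)
    include_diagonal_coexpression: bool = False
    include_diagonal_interaction: bool = True
    endpoints: tuple[str, ...] = ("recurrence", "overall_survival")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        d["endpoints"] = list(self.endpoints)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:12]


ENDPOINT_COLS = {
    "recurrence": ("recurrence_time", "recurrence_event"),
    "overall_survival": ("os_time", "os_event"),
}


# ---------------------------------------------------------------------------
# in-memory core (reused by the CLI, tests and the acceptance script)


def quantify_cohort(
    pairs: Sequence[tuple], panel: MarkerPanel
) -> tuple[list[CellRecord], "PositivityThresholds"]:
    """Extract cells, quantify expression, threshold and call positivity."""
    from .quant import PositivityThresholds  # noqa: F401  (type reference)

    thresholds = background_thresholds(pairs, panel)
    records: list[CellRecord] = []
    for image, seg in pairs:
        cells = extract_cells(seg)
        recs = mean_expression(image, cells, panel)
        positivity_calls(recs, thresholds)
        records.extend(recs)
    return records, thresholds


def build_adjacency(records: Sequence[CellRecord], config: PipelineConfig):
    cents = {r.cell_id: r.centroid for r in records}
    if config.adjacency == "radius":
        if not config.adjacency_radius:
            raise StageError("radius adjacency requires adjacency_radius")
        return radius_adjacency(cents, config.adjacency_radius)
    return voronoi_adjacency(cents)


def feature_tables(
    records: Sequence[CellRecord],
    panel: MarkerPanel,
    config: PipelineConfig | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, dict[str, PairCountMatrix]]]:
    """Per-patient feature families from quantified cell records.

    Returns (feature tables by family, per-patient matrices by family).
    Families: co-expression of functional markers; interactions of
    functional markers; immunoregulatory-only interactions; homotypic
    (diagonal) interactions; lineage-only interactions.
    """
    config = config or PipelineConfig()
    functional = panel.functional_names
    by_patient: dict[str, list[CellRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)

    co_mats: dict[str, PairCountMatrix] = {}
    int_mats: dict[str, PairCountMatrix] = {}
    all_mats: dict[str, PairCountMatrix] = {}
    sub_rows: dict[str, dict[str, pd.Series]] = {m: {} for m in ("immunoregulatory", "homotypic", "lineage")}
    for pid, recs in sorted(by_patient.items()):
        co_mats[pid] = coexpression_matrix(recs, functional)
        graph = build_adjacency(recs, config)
        full = interaction_matrix(graph, recs, panel.names)
        all_mats[pid] = full
        int_mats[pid] = full.submatrix(functional)
        sub_rows["immunoregulatory"][pid] = subset_features(
            full, "immunoregulatory", panel=panel,
            include_diagonal=config.include_diagonal_interaction,
        )
        sub_rows["homotypic"][pid] = subset_features(full.submatrix(functional), "homotypic_diagonal")
        if panel.lineage_names:
            sub_rows["lineage"][pid] = subset_features(
                full, "lineage_only", panel=panel,
                include_diagonal=config.include_diagonal_interaction,
            )

    tables = {
        "coexpression": cohort_feature_table(
            co_mats, include_diagonal=config.include_diagonal_coexpression
        ),
        "interaction": cohort_feature_table(
            int_mats, include_diagonal=config.include_diagonal_interaction
        ),
        "immunoregulatory": pd.DataFrame(sub_rows["immunoregulatory"]).T.sort_index(),
        "homotypic": pd.DataFrame(sub_rows["homotypic"]).T.sort_index(),
    }
    if sub_rows["lineage"]:
        tables["lineage"] = pd.DataFrame(sub_rows["lineage"]).T.sort_index()
    for t in tables.values():
        t.index.name = "patient_id"
    matrices = {"coexpression": co_mats, "interaction": int_mats, "full": all_mats}
    return tables, matrices


def cluster_families(
    tables: Mapping[str, pd.DataFrame], config: PipelineConfig
) -> dict[str, ClusterAssignment]:
    k_range = range(config.k_range[0], config.k_range[1] + 1)
    return {
        fam: cluster_cohort(
            tbl, k=config.k, k_range=k_range, linkage=config.linkage, metric=config.metric
        )
        for fam, tbl in tables.items()
    }


def survival_frame(clinical: Sequence[ClinicalRecord], endpoint: str) -> pd.DataFrame:
    tcol, ecol = ENDPOINT_COLS[endpoint]
    kept, dropped = survival_eligible(clinical, endpoint)
    if dropped:
        logger.info("excluding %d patient(s) lacking %s outcome", len(dropped), endpoint)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in kept],
            "time": [getattr(r, tcol) for r in kept],
            "event": [bool(getattr(r, ecol)) for r in kept],
            "age": [r.age for r in kept],
            "grade": [r.grade for r in kept],
            "architecture": [r.architecture for r in kept],
        }
    ).set_index("patient_id")


def survival_analysis(
    clusters: Mapping[str, ClusterAssignment],
    clinical: Sequence[ClinicalRecord],
    endpoints: Sequence[str] = ("recurrence", "overall_survival"),
) -> dict:
    """Log-rank tests and multivariate Cox fits per feature family.

    Each multivariate model holds the family's (binary, 1 vs 2+) cluster
    variable together with grade, age and the immune-architecture label.
    """
    out: dict = {}
    for endpoint in endpoints:
        surv = survival_frame(clinical, endpoint)
        out[endpoint] = {}
        for fam, assign in clusters.items():
            labels = assign.labels.reindex(surv.index)
            if labels.isna().any():
                missing = list(labels.index[labels.isna()])
                raise StageError(f"cluster labels missing for patients {missing}")
            lr = logrank_test(surv["time"], surv["event"], labels)
            res = {
                "k": assign.k,
                "logrank_chi2": lr.chi_square,
                "logrank_df": lr.df,
                "logrank_p": lr.p,
            }
            df = surv.copy()
            df["cluster"] = (labels == 1).astype(float)  # cluster-1 indicator
            cox_cols = ["cluster"]
            if df["grade"].notna().all():
                cox_cols.append("grade")
            if df["age"].notna().all():
                cox_cols.append("age")
            use_arch = (df["architecture"] != "unknown").all()
            try:
                fit = cox_fit(
                    df.assign(grade=pd.to_numeric(df["grade"], errors="coerce")),
                    "time",
                    "event",
                    covariates=cox_cols + (["architecture"] if use_arch else []),
                    categorical=("architecture",) if use_arch else (),
                )
                res["cox"] = {
                    "converged": fit.converged,
                    "cluster_coef": fit.coef("cluster"),
                    "cluster_hr": fit.hazard_ratio("cluster"),
                    "cluster_p": fit.p("cluster"),
                }
                res["cox_table"] = fit.summary.reset_index().to_dict(orient="records")
            except ValueError as exc:
                res["cox"] = {"error": str(exc)}
            out[endpoint][fam] = res
    return out


def composition_survival_tables(
    composition: pd.DataFrame,
    clinical: Sequence[ClinicalRecord],
    endpoints: Sequence[str] = ("recurrence", "overall_survival"),
) -> dict[str, pd.DataFrame]:
    """Univariate Cox screens of cell-type proportions, BH-adjusted.

    The per-endpoint output mirrors the standard prognostic-screen table
    (Coefficient, Hazard ratio, Coefficient P, BH-corrected FDR).
    """
    out = {}
    for endpoint in endpoints:
        surv = survival_frame(clinical, endpoint)
        joined = surv.join(composition, how="inner")
        covs = [c for c in composition.columns if joined[c].nunique() > 1]
        out[endpoint] = univariate_cox_table(joined, "time", "event", covs)
    return out


def importance_analysis(
    tables: Mapping[str, pd.DataFrame],
    clusters: Mapping[str, ClusterAssignment],
    clinical: Sequence[ClinicalRecord],
    seed: int,
    endpoints: Sequence[str] = ("recurrence", "overall_survival"),
) -> dict:
    """Gini importances per family plus survival-forest Shapley importance.

    The survival forest uses the six standard predictors: the three
    cluster variables (co-expression, functional-interaction and
    immunoregulatory-interaction), tumor grade, age and the immune
    architecture label.
    """
    out: dict = {"gini": {}, "shap": {}}
    for fam in ("coexpression", "interaction"):
        if fam in tables and fam in clusters:
            out["gini"][fam] = rf_importance(
                tables[fam], clusters[fam].labels.reindex(tables[fam].index), seed=seed
            )
    predictor_fams = [f for f in ("coexpression", "interaction", "immunoregulatory") if f in clusters]
    for endpoint in endpoints:
        surv = survival_frame(clinical, endpoint)
        X = pd.DataFrame(index=surv.index)
        for fam in predictor_fams:
            X[f"{fam}_cluster"] = (clusters[fam].labels.reindex(surv.index) == 1).astype(float)
        X["grade"] = pd.to_numeric(surv["grade"], errors="coerce")
        X["age"] = surv["age"].astype(float)
        X["architecture"] = surv["architecture"].astype("category").cat.codes.astype(float)
        X = X.dropna(axis=1)
        res = survival_rf_shap(X, surv["time"], surv["event"], seed=seed)
        out["shap"][endpoint] = {
            "mean_abs_shap": res.mean_abs_shap.to_dict(),
            "c_index": res.c_index,
            "base_value": res.base_value,
        }
    return out


# ---------------------------------------------------------------------------
# disk orchestration


def _load_cohort(root: Path, config: PipelineConfig):
    panel = MarkerPanel.from_csv(root / config.panel_csv)
    images_dir = root / config.images_dir
    masks_dir = root / config.masks_dir
    types_dir = root / config.types_dir
    pairs = []
    for img_path in sorted(images_dir.glob("*.tif*")):
        pid = img_path.stem
        mask_path = next(iter(masks_dir.glob(f"{pid}.tif*")), None)
        if mask_path is None:
            raise StageError(f"no mask for patient {pid}")
        type_map = None
        tpath = types_dir / f"{pid}.csv"
        if tpath.exists():
            type_map = read_type_table(tpath)
        image = read_multichannel_image(img_path, panel, patient_id=pid)
        seg = read_segmentation(mask_path, dialect=config.dialect, type_map=type_map)
        pairs.append((image, seg))
    if not pairs:
        raise StageError(f"no images found under {images_dir}")
    return panel, pairs


def _provenance(config: PipelineConfig) -> dict:
    return {"config_digest": config.digest(), "seed": config.seed, "version": __version__}


def run(root: str | Path, config: PipelineConfig, stages: Sequence[str] | None = None) -> Path:
    """Run the pipeline (or selected stages) over a cohort directory.

    Stages: quantify, features, cluster, survive, importance, report.
    Later stages read the CSV artifacts of earlier ones, so a partial run
    can resume from any stage.
    """
    root = Path(root)
    out = root / config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    (out / "provenance.json").write_text(json.dumps(_provenance(config), indent=2))
    all_stages = ["quantify", "features", "cluster", "survive", "importance", "report"]
    stages = list(stages) if stages else all_stages

    panel = MarkerPanel.from_csv(root / config.panel_csv)

    if "quantify" in stages:
        try:
            panel, pairs = _load_cohort(root, config)
            records, thresholds = quantify_cohort(pairs, panel)
            records_to_frame(records, panel).to_csv(out / "cells.csv", index=False)
            thresholds.to_csv(out / "thresholds.csv")
            logger.info("quantify: %d cells, %d background pixels",
                        len(records), thresholds.background_pixel_count)
        except Exception as exc:
            raise StageError(f"stage quantify failed: {exc}") from exc

    if "features" in stages:
        try:
            from .quant import frame_to_records

            records = frame_to_records(pd.read_csv(out / "cells.csv"), panel)
            tables, matrices = feature_tables(records, panel, config)
            for fam, tbl in tables.items():
                tbl.to_csv(out / f"features_{fam}.csv")
            mdir = out / "matrices"
            mdir.mkdir(exist_ok=True)
            for flavor in ("coexpression", "interaction"):
                for pid, m in matrices[flavor].items():
                    m.to_csv(mdir / f"{flavor}_{pid}.csv")
            composition_proportions(records).to_csv(out / "composition.csv")
            positivity_proportions(records, panel).to_csv(out / "positivity_proportions.csv")
            logger.info("features: %d families", len(tables))
        except Exception as exc:
            raise StageError(f"stage features failed: {exc}") from exc

    if "cluster" in stages:
        try:
            tables = {
                fam: pd.read_csv(out / f"features_{fam}.csv", index_col="patient_id")
                for fam in FEATURE_FAMILIES
                if (out / f"features_{fam}.csv").exists()
            }
            clusters = cluster_families(tables, config)
            rows = []
            for fam, a in clusters.items():
                for pid, lbl in a.labels.items():
                    rows.append({"family": fam, "patient_id": pid, "cluster": int(lbl), "k": a.k})
            pd.DataFrame(rows).to_csv(out / "clusters.csv", index=False)
            (out / "silhouettes.json").write_text(
                json.dumps({f: {str(k): v for k, v in a.silhouettes.items()} for f, a in clusters.items()}, indent=2)
            )
        except Exception as exc:
            raise StageError(f"stage cluster failed: {exc}") from exc

    if "survive" in stages or "importance" in stages:
        clinical_path = root / config.clinical_csv
        if not clinical_path.exists():
            raise StageError(f"stage survive failed: clinical table {clinical_path} not found")
        clinical = read_clinical_table(clinical_path)
        cl = pd.read_csv(out / "clusters.csv")
        clusters_loaded: dict[str, ClusterAssignment] = {}
        for fam, grp in cl.groupby("family"):
            labels = pd.Series(
                grp["cluster"].to_numpy(), index=grp["patient_id"].astype(str), name="cluster"
            )
            clusters_loaded[fam] = ClusterAssignment(
                labels=labels, k=int(grp["k"].iloc[0]), linkage_tree=np.empty((0, 4))
            )

    if "survive" in stages:
        try:
            results = survival_analysis(clusters_loaded, clinical, config.endpoints)
            (out / "survival.json").write_text(json.dumps(results, indent=2, default=float))
            composition = pd.read_csv(out / "composition.csv", index_col="patient_id")
            for endpoint, tbl in composition_survival_tables(
                composition, clinical, config.endpoints
            ).items():
                tbl.to_csv(out / f"cox_composition_{endpoint}.csv")
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage survive failed: {exc}") from exc

    if "importance" in stages:
        try:
            tables = {
                fam: pd.read_csv(out / f"features_{fam}.csv", index_col="patient_id")
                for fam in FEATURE_FAMILIES
                if (out / f"features_{fam}.csv").exists()
            }
            for fam in tables:
                tables[fam].index = tables[fam].index.astype(str)
            imp = importance_analysis(tables, clusters_loaded, clinical, config.seed, config.endpoints)
            for fam, df in imp["gini"].items():
                df.to_csv(out / f"gini_importance_{fam}.csv")
            (out / "shap_importance.json").write_text(json.dumps(imp["shap"], indent=2, default=float))
        except Exception as exc:
            raise StageError(f"stage importance failed: {exc}") from exc

    if "report" in stages:
        try:
            report(out)
        except Exception as exc:
            raise StageError(f"stage report failed: {exc}") from exc
    return out


def report(outdir: str | Path) -> list[Path]:
    """Regenerate plots and display tables from a completed run's CSVs.

    Emits KM curves per cluster family (log-rank p in the legend) and
    cube-root heatmaps of each patient's matrices.  Pure re-rendering — no
    recomputation.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    outdir = Path(outdir)
    made: list[Path] = []
    surv_path = outdir / "survival.json"
    clusters_path = outdir / "clusters.csv"
    if not surv_path.exists() or not clusters_path.exists():
        raise StageError("report requires completed survive and cluster stages")
    survival = json.loads(surv_path.read_text())
    clusters = pd.read_csv(clusters_path)
    cfg = PipelineConfig.from_yaml(outdir / "config.yaml")
    clinical = None
    for candidate in (outdir.parent / cfg.clinical_csv, Path(cfg.clinical_csv)):
        if candidate.exists():
            clinical = read_clinical_table(candidate)
            break
    plots_dir = outdir / "plots"
    plots_dir.mkdir(exist_ok=True)
    if clinical is not None:
        for endpoint, fams in survival.items():
            surv = survival_frame(clinical, endpoint)
            for fam, res in fams.items():
                labels = clusters[clusters["family"] == fam].set_index("patient_id")["cluster"]
                labels.index = labels.index.astype(str)
                fig, ax = plt.subplots(figsize=(5, 4))
                for lbl in sorted(labels.unique()):
                    pids = labels.index[labels == lbl]
                    sub = surv.loc[surv.index.intersection(pids)]
                    if len(sub) == 0:
                        continue
                    KaplanMeierFitter().fit(
                        sub["time"], sub["event"], label=f"cluster {lbl}"
                    ).plot_survival_function(ax=ax, ci_show=False)
                ax.set_title(f"{fam} / {endpoint} (log-rank p={res['logrank_p']:.3g})")
                ax.set_xlabel("time")
                ax.set_ylabel("survival probability")
                fig.tight_layout()
                p = plots_dir / f"km_{fam}_{endpoint}.png"
                fig.savefig(p, dpi=100)
                plt.close(fig)
                made.append(p)
    mdir = outdir / "matrices"
    if mdir.exists():
        hdir = outdir / "heatmaps"
        hdir.mkdir(exist_ok=True)
        for mpath in sorted(mdir.glob("*.csv"))[:4]:
            m = PairCountMatrix.from_csv(mpath)
            disp = cube_root_display(m)
            fig, ax = plt.subplots(figsize=(5, 4.2))
            im = ax.imshow(disp.to_numpy(), cmap="viridis")
            ax.set_xticks(range(len(m.markers)), m.markers, rotation=90, fontsize=6)
            ax.set_yticks(range(len(m.markers)), m.markers, fontsize=6)
            fig.colorbar(im, ax=ax, label="cube root of count")
            fig.tight_layout()
            p = hdir / f"{mpath.stem}.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            made.append(p)
    return made
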
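# mibitime

Analysis of the tumor-immune microenvironment (TIME) from multiplexed ion
beam imaging (MIBI), aimed at researchers who want to relate single-cell
spatial protein expression to clinical outcome. MIBI produces multi-channel
images (one channel per antibody marker) together with cell segmentation
masks; `mibitime` turns a cohort of such images into per-patient features
and survival statistics:

1. **Per-cell quantification.** For every segmented cell and marker *m*,
   the mean per-pixel expression
   x̄ᵢₘ = (Σ pixels of cell i of channel m) / |cell i|.
2. **Background positivity thresholds.** Pixels outside every cell lack
   tissue and act as a negative control: the threshold for marker *m* is
   the pooled cohort-wide background mean τₘ; cell *i* is *positive* for
   *m* iff x̄ᵢₘ > τₘ.
3. **Co-expression matrices.** Cₐᵦ = number of cells positive for both
   markers *a* and *b*; a cell with *k* positive markers contributes all
   k(k−1)/2 unordered pairs.
4. **Voronoi interaction matrices.** Cell centroids seed a Voronoi
   tessellation; cells whose polygons share a positive-length border are
   adjacent. For each adjacency, every pair in the Cartesian product of
   the two cells' positive-marker sets is tallied: Iₐᵦ = number of times
   an *a*-positive cell borders a *b*-positive cell (the diagonal holds
   homotypic interactions). Subset views (immunoregulatory-only,
   single-marker ablation, homotypic diagonal, lineage-only) come for
   free.
5. **Patient stratification.** Flattened upper-triangle features are
   z-scored across patients, clustered (Ward/Euclidean by default) with
   the number of clusters picked by mean silhouette, and the clusters are
   compared by Kaplan–Meier curves, the two-sided log-rank test, and Cox
   proportional-hazards regression (Efron ties, Wald tests,
   Benjamini–Hochberg FDR across feature families), plus random-forest
   variable importance (mean decrease in Gini; Shapley attributions on a
   random survival forest with Harrell's c-index).

A synthetic-cohort generator (`mibitime.synthetic`) emulates all inputs —
images, masks, marker panel, clinical tables — with planted spatial
phenotypes (a marker pair enriched on adjacent cells in one patient group)
and a configurable group hazard ratio, so the entire pipeline is testable
end to end without any imaging data.

## Worked example

Generate a 20-patient synthetic cohort with a PD-1/IDO adjacency phenotype
planted in half the patients (hazard ratio 3 for recurrence), run the
pipeline in memory, and compare the recovered clusters to the planted
groups:

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from mibitime import SyntheticConfig, simulate_cohort, logrank_test
from mibitime.pipeline import (
    PipelineConfig, cluster_families, feature_tables, quantify_cohort,
)

cfg = SyntheticConfig(n_patients=20, image_size=(256, 256),
                      mean_cells_per_image=250, seed=42)
cohort = simulate_cohort(cfg)
records, thresholds = quantify_cohort(
    list(zip(cohort.images, cohort.segmentations)), cfg.panel)
print(f"cells quantified: {len(records)}")
print(f"background pixels pooled: {thresholds.background_pixel_count}")
print(f"PD-1 positivity threshold: {thresholds['PD-1']:.3f}")

pcfg = PipelineConfig(seed=42, k=2)
tables, mats = feature_tables(records, cfg.panel, pcfg)
print(f"P001 PD-1/IDO interactions: "
      f"{int(mats['interaction']['P001'].to_frame().loc['PD-1', 'IDO'])}")

assign = cluster_families({"interaction": tables["interaction"]}, pcfg)["interaction"]
truth = [cohort.groups[p] for p in assign.labels.index]
print(f"ARI vs planted groups: "
      f"{adjusted_rand_score(truth, assign.labels.to_numpy()):.2f}")

clin = {r.patient_id: (r.recurrence_time, r.recurrence_event)
        for r in cohort.clinical}
t = [clin[p][0] for p in assign.labels.index]
e = [clin[p][1] for p in assign.labels.index]
lr = logrank_test(t, e, assign.labels)
print(f"log-rank chi2={lr.chi_square:.2f} (df={lr.df}), p={lr.p:.4f}")
```

Output:

```
cells quantified: 4958
background pixels pooled: 352361
PD-1 positivity threshold: 1.003
P001 PD-1/IDO interactions: 414
ARI vs planted groups: 1.00
log-rank chi2=0.97 (df=1), p=0.3242
```

The threshold lands on the generator's background level (1.0), patient
P001 (a group-1 patient) shows a large planted PD-1/IDO interaction count,
and Ward clustering of the interaction features recovers the planted
groups exactly (ARI 1.0). The log-rank test on recurrence is not
significant here — at 10 patients per group the test has limited power
even at hazard ratio 3; at the default study scale (n = 40) its power is
about 0.8 (see `docs/methods.md`).

## Command line

The same stages are available as a CLI over an on-disk cohort:

```sh
mibitime generate cohort/ --n-patients 20 --seed 42
mibitime run cohort/ --seed 42          # quantify → features → cluster →
                                        # survive → importance → report
```

Every stage exchanges plain CSV/JSON under `cohort/output/`, so any stage
can be inspected, rerun (`--stage`), or replaced.

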
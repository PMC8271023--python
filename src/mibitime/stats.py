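"""Survival and association statistics for cohort stratification.

Kaplan–Meier product-limit curves, the two-sided log-rank (Mantel–Cox)
test, Cox proportional-hazards regression (Efron ties, Wald z inference),
Benjamini–Hochberg FDR control, the Wilcoxon rank-sum test, Harrell's
c-index, random-forest variable importance (mean decrease in Gini and
Shapley attributions on a survival forest), and a seeded 2-D embedding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .shapley import exact_shapley

logger = logging.getLogger(__name__)

ENDPOINTS = ("recurrence", "overall_survival")


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.chi_square < 0 or self.df < 1:
            raise ValueError("invalid log-rank result")


@dataclass
class CoxFit:
    """Per-covariate coefficients, HRs and Wald tests from a Cox model."""

    summary: pd.DataFrame  # index covariate; columns coef, hazard_ratio, se, z, p
    log_likelihood: float
    converged: bool
    ties_method: str = "efron"
    dropped: tuple[str, ...] = ()

    def coef(self, name: str) -> float:
        return float(self.summary.loc[name, "coef"])

    def hazard_ratio(self, name: str) -> float:
        return float(self.summary.loc[name, "hazard_ratio"])

    def p(self, name: str) -> float:
        return float(self.summary.loc[name, "p"])


@dataclass
class ShapImportanceResult:
    mean_abs_shap: pd.Series
    shap_values: pd.DataFrame  # samples × predictors
    base_value: float
    risk_scores: np.ndarray
    c_index: float


# ---------------------------------------------------------------------------
# survival curves and tests


def km_curve(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a frame with columns ``time``, ``survival`` and ``at_risk``,
    starting at t=0 with survival 1.  Censored subjects leave the risk set
    without a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival sample")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
    return pd.DataFrame(
        {"time": surv.index.to_numpy(), "survival": surv.to_numpy(), "at_risk": at_risk.to_numpy()}
    ).reset_index(drop=True)


def logrank_test(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> LogRankResult:
    """Two-sided log-rank (Mantel–Cox) test across ≥2 groups.

    Uses the hypergeometric variance with tie sharing across groups; the
    statistic is referred to a chi-square with (groups − 1) df.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=len(uniq) - 1,
        p=float(res.p_value),
    )


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str] | None = None,
    categorical: Sequence[str] = (),
) -> CoxFit:
    """Cox proportional-hazards fit (Efron tie handling, Wald z tests).

    Constant covariates are inestimable and dropped with a warning;
    categorical covariates are reference-coded (first level dropped).
    Non-convergence (monotone likelihood / complete separation) is flagged
    rather than raised, with the last iterate's coefficients reported.
    """
    if covariates is None:
        covariates = [c for c in data.columns if c not in (duration_col, event_col)]
    df = data[[duration_col, event_col, *covariates]].copy()
    if df[covariates].isna().any().any():
        raise ValueError("missing covariate values")
    if not df[event_col].astype(bool).any():
        raise ValueError("no events in sample")
    for c in categorical:
        df[c] = df[c].astype("category")
    df = pd.get_dummies(df, columns=list(categorical), drop_first=True, dtype=float)
    cov_cols = [c for c in df.columns if c not in (duration_col, event_col)]
    dropped = tuple(c for c in cov_cols if df[c].nunique() <= 1)
    if dropped:
        logger.warning("dropping constant covariate(s): %s", dropped)
        df = df.drop(columns=list(dropped))
    if df.shape[1] <= 2:
        raise ValueError("no estimable covariates")
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        except ConvergenceError:
            converged = False
            cph = CoxPHFitter(penalizer=1e-6)
            cph.fit(
                df,
                duration_col=duration_col,
                event_col=event_col,
                fit_options={"step_size": 0.5},
            )
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hazard_ratio": np.exp(s["coef"]),
            "se": s["se(coef)"],
            "z": s["z"],
            "p": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        converged=converged,
        dropped=dropped,
    )


def univariate_cox_table(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
) -> pd.DataFrame:
    """One univariate Cox fit per covariate with BH-adjusted p values.

    Emits the columns of the standard prognostic-screen table:
    Coefficient, Hazard ratio, Coefficient P, BH-corrected FDR.
    """
    rows = []
    for cov in covariates:
        fit = cox_fit(data, duration_col, event_col, covariates=[cov])
        rows.append(
            {
                "covariate": cov,
                "coef": fit.coef(cov),
                "hazard_ratio": fit.hazard_ratio(cov),
                "p": fit.p(cov),
            }
        )
    out = pd.DataFrame(rows).set_index("covariate")
    out["bh_fdr"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_ranksum(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (z, p): z is the tie-corrected normal-approximation statistic
    of the rank sum; the p value is computed by exact enumeration when both
    samples are small (< 8) and tie-free, otherwise from the normal
    reference.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    R1 = ranks[:n1].sum()
    U1 = R1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    z = 0.0 if var <= 0 else (U1 - mu) / np.sqrt(var)
    has_ties = np.any(tie_counts > 1)
    if min(n1, n2) < 8 and not has_ties:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(2 * sps.norm.sf(abs(z)))
    return float(z), min(p, 1.0)


def concordance_index(
    times: Sequence[float], events: Sequence[bool], risk_scores: Sequence[float]
) -> float:
    """Harrell's C: agreement between risk ordering and event-time ordering.

    Higher risk score is expected to pair with shorter time; score ties
    count 0.5.  Only event-anchored comparable pairs contribute.
    """
    from sksurv.metrics import concordance_index_censored

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    risk = np.asarray(risk_scores, dtype=float)
    c, *_ = concordance_index_censored(events, times, risk)
    return float(c)


# ---------------------------------------------------------------------------
# forests and importance


def rf_importance(
    features: pd.DataFrame,
    labels: Sequence,
    seed: int,
    n_trees: int = 500,
) -> pd.DataFrame:
    """Mean decrease in Gini impurity per feature from a classification
    forest predicting the given labels (typically cluster assignments).

    Returns both the raw importances and a max=1 normalisation.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least 2 classes")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(features.to_numpy(dtype=float), y)
    raw = rf.feature_importances_
    norm = raw / raw.max() if raw.max() > 0 else raw
    out = pd.DataFrame(
        {"gini_importance": raw, "gini_importance_max1": norm}, index=features.columns
    )
    return out.sort_values("gini_importance", ascending=False)


def survival_rf_shap(
    predictors: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[bool],
    seed: int,
    n_trees: int = 200,
) -> ShapImportanceResult:
    """Variable importance for a survival forest via exact Shapley values.

    Fits a random survival forest (log-rank split rule) on the predictors,
    scores risk per sample, attributes the risk score to predictors with
    exact interventional Shapley values (the predictors themselves are the
    background), and reports mean |attribution| per predictor plus the
    forest's Harrell c-index.  Attributions satisfy local accuracy: per
    sample they sum to risk − base.
    """
    from sksurv.ensemble import RandomSurvivalForest
    from sksurv.util import Surv

    X = predictors.astype(float)
    if X.isna().any().any():
        raise ValueError("predictors must be numeric with no missing values")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    y = Surv.from_arrays(event=events, time=times)
    rsf = RandomSurvivalForest(
        n_estimators=n_trees, random_state=seed, min_samples_leaf=3, n_jobs=1
    )
    rsf.fit(X.to_numpy(), y)
    risk = rsf.predict(X.to_numpy())
    phi, base = exact_shapley(rsf.predict, X.to_numpy())
    shap_df = pd.DataFrame(phi, index=X.index, columns=X.columns)
    return ShapImportanceResult(
        mean_abs_shap=shap_df.abs().mean(axis=0).sort_values(ascending=False),
        shap_values=shap_df,
        base_value=base,
        risk_scores=risk,
        c_index=concordance_index(times, events, risk),
    )


def embed_2d(
    features: pd.DataFrame | np.ndarray,
    seed: int,
    n_neighbors: int = 15,
) -> np.ndarray:
    """Seeded 2-D UMAP embedding of a feature matrix.

    The neighbor count is clamped to n−1 with a warning when the sample is
    small.  Deterministic for a fixed seed.
    """
    import umap

    X = np.asarray(features, dtype=float)
    n = len(X)
    if n < 4:
        raise ValueError("embedding needs at least 4 samples")
    if n_neighbors >= n:
        logger.warning("reducing n_neighbors from %d to %d", n_neighbors, n - 1)
        n_neighbors = n - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors, random_state=seed)
        return np.asarray(reducer.fit_transform(X))
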
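"""Survival risk signatures built on hub lncRNAs, and their evaluation.

The risk model is a linear score over N signature lncRNAs,

    risk(s) = sum_i W_i * Exp_i(s),

with weights W_i taken from a multivariate Cox proportional-hazards fit of
the signature genes against overall survival. Patients are dichotomized at
the cohort median score (ties go to the low-risk group), and the split is
evaluated with Kaplan-Meier curves, the two-sided log-rank test,
univariate/multivariate Cox tables over clinical covariates, stratified
analyses, and a time-dependent ROC curve for events occurring by a fixed
horizon (default 60 months, i.e. 5-year survival).

Cox fitting relies on lifelines (Efron tie handling); the time-dependent
ROC uses the Kaplan-Meier-based cumulative-cases/dynamic-controls estimator.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_io import ClinicalTable, ExpressionMatrix

CATEGORICAL_REFERENCES = {
    "stage": "II",
    "grade": "G1/G2",
    "residual": "0-10mm",
}


@dataclass
class RiskModel:
    """Signature lncRNA ids, their Cox weights, and the training cutoff."""

    lncrna_ids: list
    coefficients: np.ndarray
    cutoff: float
    training_summary: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.lncrna_ids) != self.coefficients.size:
            raise ValueError("one coefficient per signature lncRNA required")


@dataclass
class SurvivalComparison:
    """KM curves, medians, survival rates, log-rank and HR for a grouping."""

    groups: pd.Series  # sample -> group label
    curves: dict  # label -> DataFrame(time, survival, at_risk)
    median_os: dict  # label -> months (NaN when the curve never reaches 0.5)
    statistic: float
    p_value: float
    survival_rates: dict  # label -> {time: KM survival probability}
    hazard_ratio: float | None = None
    hr_ci: tuple | None = None


@dataclass
class CoxTable:
    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    reference_levels: dict = field(default_factory=dict)
    warnings_: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# risk model


def _survival_frame(clinical: ClinicalTable, samples: list) -> pd.DataFrame:
    df = clinical.data.loc[list(samples), ["os_months", "event"]].copy()
    if df["event"].sum() < 1:
        raise ValueError("no events in the cohort; survival model undefined")
    return df


def fit_risk_model(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    lncrna_ids: list | None = None,
    penalizer: float = 0.0,
) -> RiskModel:
    """Multivariate Cox fit of the signature lncRNAs against OS.

    ``expr`` must already be (or is restricted to) the signature lncRNAs;
    the model cutoff is set to the median training risk score. Requires at
    least two events. Non-convergence surfaces as a lifelines error with
    diagnostics attached.
    """
    if lncrna_ids is not None:
        expr = expr.restrict_molecules(list(lncrna_ids))
    ids = expr.molecule_ids
    if not ids:
        raise ValueError("no signature lncRNAs supplied")
    frame = expr.data.T.join(_survival_frame(clinical, expr.sample_ids))
    if frame["event"].sum() < 2:
        raise ValueError("need >= 2 events to fit a Cox model")
    fitter = CoxPHFitter(penalizer=penalizer)
    fitter.fit(frame, duration_col="os_months", event_col="event")
    coefficients = fitter.params_.loc[ids].to_numpy()
    model = RiskModel(ids, coefficients, cutoff=np.nan, training_summary=fitter.summary)
    scores = risk_scores(model, expr)
    model.cutoff = float(np.median(scores))
    return model


def risk_scores(model: RiskModel, expr: ExpressionMatrix) -> pd.Series:
    """Per-sample linear risk score sum_i W_i * Exp_i."""
    missing = [l for l in model.lncrna_ids if l not in expr.data.index]
    if missing:
        raise KeyError(f"signature lncRNAs missing from expression matrix: {missing}")
    values = expr.data.loc[list(model.lncrna_ids)].to_numpy()
    scores = model.coefficients @ values
    return pd.Series(scores, index=expr.sample_ids, name="risk_score")


def dichotomize(scores: pd.Series, cutoff="median") -> pd.Series:
    """Split samples into 'high' (score > cutoff) and 'low' (score <= cutoff).

    With ``cutoff="median"`` the cohort median is used (even n: midpoint of
    the central pair); scores exactly at the cutoff fall into the low-risk
    group, so an odd cohort of distinct scores splits (n-1)/2 high vs
    (n+1)/2 low.
    """
    if scores.size < 2:
        raise ValueError("need >= 2 samples to dichotomize")
    if isinstance(cutoff, str):
        if cutoff != "median":
            raise ValueError(f"unknown cutoff rule {cutoff!r}")
        cutoff = float(np.median(scores))
    if scores.nunique() == 1:
        raise ValueError("all risk scores identical: degenerate split")
    groups = pd.Series(
        np.where(scores > cutoff, "high", "low"), index=scores.index, name="risk_group"
    )
    if groups.nunique() < 2:
        warnings.warn("cutoff outside the score range: one-sided split", stacklevel=2)
    return groups


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


def _km_curve(durations, events) -> tuple[KaplanMeierFitter, pd.DataFrame]:
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    curve = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        }
    )
    at_risk = kmf.event_table["at_risk"]
    curve["at_risk"] = at_risk.reindex(curve["time"]).to_numpy()
    return kmf, curve


def km_logrank(
    groups: pd.Series,
    clinical: ClinicalTable,
    rate_times: tuple = (60.0,),
    hazard_ratio_for: str | None = "high",
) -> SurvivalComparison:
    """Product-limit curves per group plus the two-sided log-rank test.

    Median OS is the earliest time at which the KM curve drops to <= 0.5
    (NaN, flagged with a warning, for groups whose curve never does).
    ``rate_times`` queries the KM survival probability at fixed horizons
    (60 months = the 5-year survival rate). For two groups a univariate Cox
    fit on the group indicator supplies the hazard ratio of
    ``hazard_ratio_for`` vs the other group, with a Wald 95% CI
    (``hazard_ratio_for=None`` skips that fit).
    """
    surv = _survival_frame(clinical, groups.index.tolist())
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 groups to compare")
    curves: dict = {}
    medians: dict = {}
    rates: dict = {}
    for label in labels:
        mask = groups == label
        sub = surv.loc[mask.index[mask]]
        if sub["event"].sum() == 0:
            warnings.warn(f"group {label!r} has no events; its median OS is undefined", stacklevel=2)
        kmf, curve = _km_curve(sub["os_months"], sub["event"])
        curves[label] = curve
        medians[label] = float(kmf.median_survival_time_)
        rates[label] = {
            float(t): float(kmf.predict(t)) for t in rate_times
        }
    if len(labels) == 2:
        a, b = labels
        mask_a = groups == a
        result = logrank_test(
            surv.loc[mask_a.index[mask_a], "os_months"],
            surv.loc[groups.index[groups == b], "os_months"],
            surv.loc[mask_a.index[mask_a], "event"],
            surv.loc[groups.index[groups == b], "event"],
        )
    else:
        result = multivariate_logrank_test(surv["os_months"], groups, surv["event"])
    hazard_ratio, hr_ci = None, None
    if len(labels) == 2 and hazard_ratio_for is not None:
        indicator = (groups == hazard_ratio_for).astype(int).rename("group")
        frame = surv.join(indicator)
        try:
            fitter = CoxPHFitter()
            fitter.fit(frame, duration_col="os_months", event_col="event")
            hazard_ratio = float(np.exp(fitter.params_["group"]))
            ci = fitter.confidence_intervals_.loc["group"]
            hr_ci = (float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1])))
        except Exception as exc:  # degenerate groups (e.g. no events in one arm)
            warnings.warn(f"hazard ratio unavailable: {exc}", stacklevel=2)
    medians = {
        k: (v if np.isfinite(v) else float("nan")) for k, v in medians.items()
    }
    return SurvivalComparison(
        groups=groups,
        curves=curves,
        median_os=medians,
        statistic=float(result.test_statistic),
        p_value=float(result.p_value),
        survival_rates=rates,
        hazard_ratio=hazard_ratio,
        hr_ci=hr_ci,
    )


# ---------------------------------------------------------------------------
# Cox covariate tables


def _design_blocks(clinical: ClinicalTable, risk, covariates: tuple) -> dict:
    """Covariate name -> DataFrame of its design columns (dummies for
    categoricals, stated reference levels dropped)."""
    blocks: dict[str, pd.DataFrame] = {}
    if risk is not None:
        if risk.dtype == object:  # group labels -> indicator for 'high'
            col = (risk == "high").astype(float).rename("risk_high")
        else:
            col = risk.astype(float).rename("risk_score")
        blocks["risk"] = col.to_frame()
    for cov in covariates:
        series = clinical.data[cov]
        if cov in CATEGORICAL_REFERENCES:
            ref = CATEGORICAL_REFERENCES[cov]
            levels = [l for l in sorted(series.dropna().unique()) if l != ref]
            block = pd.DataFrame(
                {f"{cov}_{level}": (series == level).astype(float) for level in levels}
            )
            block[series.isna()] = np.nan
            blocks[cov] = block
        else:
            blocks[cov] = pd.to_numeric(series).astype(float).to_frame(cov)
    return blocks


def _fit_block(surv: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame | None:
    frame = surv.join(design).dropna()
    fitter = CoxPHFitter()
    try:
        fitter.fit(frame, duration_col="os_months", event_col="event")
    except Exception:
        return None
    summary = fitter.summary
    return pd.DataFrame(
        {
            "HR": np.exp(summary["coef"]),
            "ci_lower": np.exp(summary["coef lower 95%"]),
            "ci_upper": np.exp(summary["coef upper 95%"]),
            "p": summary["p"],
            "n": len(frame),
        }
    )


def cox_table(
    clinical: ClinicalTable,
    risk: pd.Series | None = None,
    covariates: tuple = ("age", "stage", "grade", "residual"),
) -> CoxTable:
    """Univariate and multivariate Cox regression over clinical covariates.

    ``risk`` may be continuous scores or 'high'/'low' group labels (entering
    as an indicator for the high-risk group). Categorical covariates use the
    conventional reference levels (stage II, grade G1/G2, residual 0-10mm).
    Univariate fits use all samples non-missing for that covariate; the
    multivariate fit uses complete cases. Covariates whose fit fails to
    converge (e.g. separation) are flagged rather than fatal.
    """
    samples = clinical.sample_ids if risk is None else risk.index.tolist()
    surv = _survival_frame(clinical, samples)
    blocks = _design_blocks(clinical.restrict_samples(samples), risk, covariates)
    notes: list[str] = []
    uni_parts = []
    for name, design in blocks.items():
        fit = _fit_block(surv, design)
        if fit is None:
            notes.append(f"univariate fit failed for {name}")
            continue
        uni_parts.append(fit)
    full_design = pd.concat(blocks.values(), axis=1)
    multi = _fit_block(surv, full_design)
    if multi is None:
        notes.append("multivariate fit failed")
        multi = pd.DataFrame(columns=["HR", "ci_lower", "ci_upper", "p", "n"])
    return CoxTable(
        univariate=pd.concat(uni_parts) if uni_parts else pd.DataFrame(),
        multivariate=multi,
        reference_levels={k: v for k, v in CATEGORICAL_REFERENCES.items() if k in covariates},
        warnings_=notes,
    )


# ---------------------------------------------------------------------------
# time-dependent ROC


def _km_at(durations: np.ndarray, events: np.ndarray, t: float) -> float:
    if durations.size == 0:
        return np.nan
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    return float(kmf.predict(t))


def time_dependent_roc(
    scores: pd.Series, clinical: ClinicalTable, eval_time: float = 60.0
) -> tuple[float, pd.DataFrame]:
    """Time-dependent ROC for events by ``eval_time`` (cumulative/dynamic).

    Sensitivity and specificity at each score threshold c are estimated from
    Kaplan-Meier curves within the two threshold strata (Bayes' rule over
    S(t)), the estimator of the classic survivalROC "KM" method:

        sens(c) = (1 - S(t | X > c)) P(X > c) / (1 - S(t))
        spec(c) = S(t | X <= c) P(X <= c) / S(t)

    AUC is the trapezoid area over the (1 - spec, sens) curve. Requires both
    expected cases (S(t) < 1) and expected controls (S(t) > 0) at the
    horizon, and an horizon within follow-up.
    """
    surv = _survival_frame(clinical, scores.index.tolist())
    durations = surv["os_months"].to_numpy()
    events = surv["event"].to_numpy()
    if eval_time > durations.max():
        raise ValueError(
            f"eval_time {eval_time} exceeds the observed follow-up ({durations.max():.1f})"
        )
    s_marginal = _km_at(durations, events, eval_time)
    if s_marginal >= 1.0:
        raise ValueError("no cases (events) expected by eval_time")
    if s_marginal <= 0.0:
        raise ValueError("no controls (survivors) expected by eval_time")
    x = scores.to_numpy()
    # walk thresholds from high to low so the curve runs (0,0) -> (1,1);
    # integrating in threshold order avoids re-sorting nearly-tied points
    points = []
    for c in np.unique(x)[::-1]:
        above = x > c
        p_above = above.mean()
        s_above = _km_at(durations[above], events[above], eval_time) if above.any() else np.nan
        s_below = _km_at(durations[~above], events[~above], eval_time)
        sens = (1.0 - s_above) * p_above / (1.0 - s_marginal) if above.any() else 0.0
        spec = s_below * (1.0 - p_above) / s_marginal
        points.append((float(np.clip(1.0 - spec, 0, 1)), float(np.clip(sens, 0, 1))))
    points.append((1.0, 1.0))  # threshold below the minimum score
    frame = pd.DataFrame(points, columns=["fpr", "tpr"])
    auc = float(np.trapezoid(frame["tpr"], frame["fpr"]))
    return auc, frame


# ---------------------------------------------------------------------------
# stratified analysis and unsupervised split


def stratified_analysis(
    scores: pd.Series,
    clinical: ClinicalTable,
    stratify_by: str,
    splits,
    cutoff: float | str = "median",
    rate_times: tuple = (60.0,),
) -> dict:
    """Risk-group survival comparison within strata of a clinical field.

    ``splits`` is either a numeric threshold (numeric field: strata
    ``<=x`` / ``>x``, as in an age split at 65) or a mapping of field values
    to stratum labels (e.g. stage II and III pooled vs IV). Samples are
    dichotomized at the *global* cutoff (default: the cohort median score),
    then compared within each stratum; strata with fewer than 2 samples or
    only one risk group are skipped with a warning.
    """
    if isinstance(cutoff, str):
        cutoff = float(np.median(scores))
    field_values = clinical.data.loc[scores.index, stratify_by]
    if np.isscalar(splits) and not isinstance(splits, (dict, str)):
        numeric = pd.to_numeric(field_values)
        strata = pd.Series(
            np.where(numeric <= splits, f"{stratify_by}<={splits}", f"{stratify_by}>{splits}"),
            index=scores.index,
        )
        strata[numeric.isna()] = None
    else:
        strata = field_values.map(splits)
    results: dict = {}
    for label in sorted(strata.dropna().unique()):
        members = strata.index[strata == label]
        if len(members) < 2:
            warnings.warn(f"stratum {label!r}: fewer than 2 samples, skipped", stacklevel=2)
            continue
        groups = pd.Series(
            np.where(scores.loc[members] > cutoff, "high", "low"), index=members
        )
        if groups.nunique() < 2:
            warnings.warn(f"stratum {label!r}: only one risk group, skipped", stacklevel=2)
            continue
        results[label] = km_logrank(
            groups, clinical.restrict_samples(list(members)), rate_times=rate_times
        )
    return results


def cluster_split(
    expr: ExpressionMatrix,
    metric: str = "euclidean",
    linkage: str = "complete",
    zscore: bool = True,
) -> tuple[pd.Series, np.ndarray]:
    """Two-group split of samples at the first bifurcation of a dendrogram.

    Samples are clustered agglomeratively on the signature-gene expression
    profile (per-gene z-scored by default, Euclidean distance, complete
    linkage) and the tree is cut at its root, yielding exactly two nonempty
    groups. Returns (assignment Series with labels 'cluster1'/'cluster2',
    scipy linkage matrix).
    """
    if expr.n_samples < 2:
        raise ValueError("need >= 2 samples to cluster")
    values = expr.values
    if zscore:
        sd = values.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=1, keepdims=True)) / sd
    observations = values.T  # samples as rows
    z = hierarchy.linkage(pdist(observations, metric=metric), method=linkage)
    flat = hierarchy.fcluster(z, t=2, criterion="maxclust")
    if len(np.unique(flat)) < 2:
        # all pairwise distances zero: cut cannot separate; split the root manually
        flat = np.ones(expr.n_samples, dtype=int)
        flat[hierarchy.leaves_list(z)[: expr.n_samples // 2]] = 2
    assignment = pd.Series(
        [f"cluster{c}" for c in flat], index=expr.sample_ids, name="cluster"
    )
    return assignment, z


# ---------------------------------------------------------------------------
# packaged example signature


def load_example_signature() -> RiskModel:
    """The packaged ten-lncRNA ovarian-cancer signature (Cox weights from a
    TCGA ovarian-cancer cohort analysis); cutoff is NaN and must be set on
    a cohort of interest before dichotomizing."""
    ref = importlib.resources.files("cernanet.data").joinpath(
        "ovca_ten_lncrna_signature.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t")
    return RiskModel(
        frame["lncrna"].tolist(), frame["coefficient"].to_numpy(), cutoff=np.nan
    )
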
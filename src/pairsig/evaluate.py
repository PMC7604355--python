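"""Risk scoring, cutoff selection and survival evaluation.

A fitted signature turns an expression matrix into per-sample risk scores
``r_i = sum_k beta_k * s_k(i)`` over its pair indicators; a cutoff (cohort
median, Youden-optimal on a time-dependent ROC, or a fixed published value)
splits the cohort into high (> cutoff) and low risk. The evaluation layer
provides Kaplan–Meier curves with log-rank comparison, Harrell's C-index
with an asymptotic 95% CI, cumulative/dynamic time-dependent AUC at year
horizons, univariate/multivariate Cox models of the score against clinical
covariates, and stratified (age / stage / sex) subgroup analyses.

Censoring in the time-dependent ROC is handled by redistributing each
subject censored before the horizon into case/control pseudo-membership via
the whole-cohort Kaplan–Meier curve: a subject censored at ``c < t`` is a
case with probability ``1 - S(t)/S(c)``. With no censoring before ``t`` this
reduces exactly to the Mann–Whitney AUC of the binary dead-by-``t`` outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .datatypes import ExpressionMatrix, PrognosticSignature, RiskScoreTable, SurvivalTable
from .pairs import compute_pair_indicators

logger = logging.getLogger(__name__)

__all__ = [
    "compute_risk_scores",
    "select_cutoff",
    "assign_groups",
    "km_logrank_compare",
    "concordance_index",
    "td_auc",
    "TimeDependentROC",
    "cox_regression",
    "CoxResult",
    "stratified_analysis",
    "EvaluationReport",
    "evaluate_cohort",
    "YEAR_HORIZONS",
]

# 1-, 3- and 5-year horizons with time measured in days
YEAR_HORIZONS = {1: 365.0, 3: 1095.0, 5: 1825.0}


def compute_risk_scores(
    expr: ExpressionMatrix,
    signature: PrognosticSignature,
    missing_policy: str = "error",
) -> RiskScoreTable:
    """Score every sample with the signature's coefficient-weighted indicators.

    ``missing_policy='drop_pairs'`` silently (but loggedly) excludes pairs
    whose genes are absent from the matrix; ``'error'`` aborts on the first
    missing gene. Scores are exactly invariant to strictly increasing
    per-sample transforms of ``expr``.
    """
    if missing_policy not in ("error", "drop_pairs"):
        raise ValueError("missing_policy must be 'error' or 'drop_pairs'")
    if len(signature) == 0:
        raise ValueError(
            "signature has no pair entries"
            + (
                " (this published signature ships cutoff metadata only; supply entries)"
                if signature.name == "irgp_obs"
                else ""
            )
        )
    present = set(expr.gene_symbols)
    usable = [(p, b) for p, b in signature.entries if p.gene_a in present and p.gene_b in present]
    dropped = [p for p, _ in signature.entries if p.gene_a not in present or p.gene_b not in present]
    if dropped:
        if missing_policy == "error":
            raise KeyError(
                "signature genes absent from expression matrix: "
                + ", ".join(sorted({g for p in dropped for g in p if g not in present}))
            )
        logger.warning("dropping %d signature pairs with missing genes: %s",
                       len(dropped), ", ".join(p.label for p in dropped))
    if not usable:
        raise ValueError("every signature pair has a missing gene; cannot score")
    ind = compute_pair_indicators(expr, [p for p, _ in usable])
    betas = np.array([b for _, b in usable])
    scores = betas @ ind.indicators
    return RiskScoreTable(pd.DataFrame({"score": scores}, index=expr.sample_ids))


@dataclass
class TimeDependentROC:
    """Cumulative-case / dynamic-control ROC at a fixed horizon ``t`` (days)."""

    horizon: float
    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def youden_cutoff(self) -> float:
        """Threshold maximizing J = sensitivity + specificity - 1."""
        j = self.sensitivity + self.specificity - 1.0
        return float(self.thresholds[int(np.argmax(j))])


def _km_survival_function(time: np.ndarray, event: np.ndarray):
    km = KaplanMeierFitter().fit(time, event)
    sf = km.survival_function_.iloc[:, 0]

    def S(t: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(sf.index.to_numpy(), t, side="right") - 1
        out = np.where(idx >= 0, sf.to_numpy()[np.maximum(idx, 0)], 1.0)
        return out

    return S


def _case_control_weights(
    time: np.ndarray, event: np.ndarray, t: float
) -> tuple[np.ndarray, np.ndarray]:
    """(case weight, control weight) per subject for horizon ``t``.

    Known events by t are cases; subjects still at risk past t are controls;
    subjects censored at c <= t split into both with KM-derived probability
    1 - S(t)/S(c) of being a case.
    """
    S = _km_survival_function(time, event)
    w_case = np.zeros(len(time))
    w_ctrl = np.zeros(len(time))
    is_event_by_t = (time <= t) & (event == 1)
    is_past_t = time > t
    w_case[is_event_by_t] = 1.0
    w_ctrl[is_past_t] = 1.0
    censored_by_t = (time <= t) & (event == 0)
    if censored_by_t.any():
        s_c = S(time[censored_by_t])
        s_t = float(S(t)[0])
        with np.errstate(divide="ignore", invalid="ignore"):
            p_surv = np.where(s_c > 0, s_t / s_c, 0.0)
        p_surv = np.clip(p_surv, 0.0, 1.0)
        w_case[censored_by_t] = 1.0 - p_surv
        w_ctrl[censored_by_t] = p_surv
    return w_case, w_ctrl


def td_auc(scores: RiskScoreTable, surv: SurvivalTable, t: float) -> TimeDependentROC:
    """Time-dependent ROC and AUC at horizon ``t`` days."""
    if scores.sample_ids != surv.sample_ids:
        raise ValueError("score table and survival table sample ids differ")
    time, event = surv.time, surv.event
    if not ((time <= t) & (event == 1)).any():
        raise ValueError(f"no events observed by horizon t={t}")
    w_case, w_ctrl = _case_control_weights(time, event, t)
    W, V = w_case.sum(), w_ctrl.sum()
    if V == 0:
        raise ValueError(f"no controls at risk past horizon t={t}")
    x = scores.score
    order = np.argsort(-x, kind="stable")
    xs, wc, wv = x[order], w_case[order], w_ctrl[order]
    # merge tied scores so the ROC polyline has one vertex per distinct value
    uniq, first = np.unique(-xs, return_index=True)
    thresholds = -uniq  # descending
    bounds = np.concatenate((first, [len(xs)]))
    case_by_thr = np.add.reduceat(wc, bounds[:-1])
    ctrl_by_thr = np.add.reduceat(wv, bounds[:-1])
    tpr = np.concatenate(([0.0], np.cumsum(case_by_thr))) / W
    fpr = np.concatenate(([0.0], np.cumsum(ctrl_by_thr))) / V
    auc = float(np.trapezoid(tpr, fpr))
    # sensitivity/specificity at "positive iff score > threshold"
    sens = tpr[:-1]
    spec = 1.0 - fpr[:-1]
    return TimeDependentROC(
        horizon=float(t),
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
    )


def select_cutoff(
    scores: RiskScoreTable,
    surv: SurvivalTable | None = None,
    strategy: str = "median",
    t: float = YEAR_HORIZONS[5],
) -> float:
    """Choose a risk-score cutoff: cohort ``median`` or ``roc_youden`` at
    horizon ``t`` (the published signatures used the 5-year ROC)."""
    x = scores.score
    if np.ptp(x) == 0:
        raise ValueError("all risk scores equal; no cutoff can stratify the cohort")
    if strategy == "median":
        return float(np.median(x))
    if strategy == "roc_youden":
        if surv is None:
            raise ValueError("roc_youden cutoff requires a survival table")
        roc = td_auc(scores, surv, t)
        return roc.youden_cutoff()
    raise ValueError(f"unknown cutoff strategy {strategy!r}")


def assign_groups(scores: RiskScoreTable, cutoff: float) -> RiskScoreTable:
    """Label samples high (score > cutoff) or low risk."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    frame = scores.frame.copy()
    frame["group"] = np.where(frame["score"] > cutoff, "high", "low")
    if frame["group"].nunique() < 2:
        warnings.warn(f"cutoff {cutoff} leaves one risk group empty", stacklevel=2)
    return RiskScoreTable(frame)


def km_logrank_compare(
    groups: pd.Series, surv: SurvivalTable
) -> tuple[dict[str, pd.DataFrame], float]:
    """Kaplan–Meier curve per group plus the log-rank p-value between groups.

    ``groups`` maps sample id to a group label; two groups use the standard
    two-sample log-rank test, more use its multi-group generalization.
    """
    groups = groups.reindex(surv.sample_ids)
    if groups.isna().any():
        raise ValueError("group labels missing for some samples")
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty groups to compare")
    curves: dict[str, pd.DataFrame] = {}
    for label in labels:
        members = groups.index[groups == label]
        sub = surv.subset(list(members))
        km = KaplanMeierFitter().fit(sub.time, sub.event, label=str(label))
        curves[str(label)] = km.survival_function_.rename(
            columns={km._label: "survival"}
        ).rename_axis("time").reset_index()
    if len(labels) == 2:
        a = surv.subset(list(groups.index[groups == labels[0]]))
        b = surv.subset(list(groups.index[groups == labels[1]]))
        res = logrank_test(a.time, b.time, a.event, b.event)
    else:
        res = multivariate_logrank_test(surv.time, groups.to_numpy(), surv.event)
    return curves, float(res.p_value)


def concordance_index(
    scores: RiskScoreTable, surv: SurvivalTable, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Harrell's C with an asymptotic normal 95% CI.

    A pair of subjects is usable iff their observed times differ and the
    shorter time ended in an event; it is concordant when the shorter-lived
    subject has the higher risk score, with score ties counting 0.5. The CI
    uses the U-statistic (per-subject projection) standard error.
    """
    if scores.sample_ids != surv.sample_ids:
        raise ValueError("score table and survival table sample ids differ")
    x, time, event = scores.score, surv.time, surv.event
    n = len(x)
    dt = time[:, None] - time[None, :]
    usable = (dt > 0) & (event[None, :] == 1)  # (i, j) usable iff j died first
    better = x[None, :] > x[:, None]  # j (shorter-lived) riskier than i
    tied = x[None, :] == x[:, None]
    conc = np.where(usable, better + 0.5 * tied, 0.0)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no comparable pairs (check censoring pattern)")
    c = float(conc.sum() / n_usable)
    # per-subject projections of the two U-statistic kernels
    a_i = conc.sum(axis=0) + conc.sum(axis=1)  # concordance mass touching i
    w_i = usable.sum(axis=0) + usable.sum(axis=1)
    pc_i = a_i / (n - 1)
    pw_i = w_i / (n - 1)
    resid = pc_i - c * pw_i
    var_c = 4.0 * np.var(resid, ddof=1) / n / max(np.mean(pw_i), 1e-300) ** 2 if n > 1 else 0.0
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var_c, 0.0))
    return c, (max(c - half, 0.0), min(c + half, 1.0))


@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs and p-values, one row per covariate."""

    frame: pd.DataFrame  # index covariate; columns hr, ci_low, ci_high, p
    model_type: str

    def __post_init__(self) -> None:
        if not ((self.frame["ci_low"] <= self.frame["hr"]).all() and (self.frame["hr"] <= self.frame["ci_high"]).all()):
            raise ValueError("hazard ratio outside its confidence interval")
        if (self.frame["hr"] <= 0).any():
            raise ValueError("hazard ratios must be positive")


_SEX_CODES = {"male": 1, "m": 1, "female": 0, "f": 0}
_STAGE_CODES = {"I": 1, "II": 2, "III": 3, "IV": 4}


def _encode_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    out = cov.copy()
    if "sex" in out.columns and not pd.api.types.is_numeric_dtype(out["sex"]):
        out["sex"] = out["sex"].astype(str).str.strip().str.lower().map(_SEX_CODES)
    if "stage" in out.columns and not pd.api.types.is_numeric_dtype(out["stage"]):
        out["stage"] = out["stage"].astype(str).str.strip().str.upper().map(_STAGE_CODES)
    return out.astype(float)


def cox_regression(
    surv: SurvivalTable, covariates: pd.DataFrame, mode: str = "multivariate"
) -> CoxResult:
    """Cox proportional-hazards regression of the endpoint on covariates.

    Efron handling of tied event times; sex is encoded binary
    (male=1/female=0), tumor stage ordinal 1–4, age stays continuous.
    ``mode='univariate'`` fits each covariate alone; ``'multivariate'`` fits
    them jointly. Rows with missing covariates are dropped with a logged
    count.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    if surv.event.sum() < 2:
        raise ValueError("need at least 2 events for Cox regression")
    cov = _encode_covariates(covariates.reindex(surv.sample_ids))
    base = surv.frame[["time", "event"]]

    def _fit(cols: list[str]) -> pd.DataFrame:
        df = base.join(cov[cols]).dropna()
        n_dropped = len(base) - len(df)
        if n_dropped:
            logger.info("Cox fit dropped %d rows with missing covariates", n_dropped)
        cph = CoxPHFitter()
        # tighter Newton stopping rule than the default so small-sample
        # coefficients agree with a direct partial-likelihood maximizer
        cph.fit(df, duration_col="time", event_col="event", fit_options={"precision": 1e-9})
        s = cph.summary
        return pd.DataFrame(
            {
                "hr": np.exp(s["coef"]),
                "ci_low": np.exp(s["coef lower 95%"]),
                "ci_high": np.exp(s["coef upper 95%"]),
                "p": s["p"],
            }
        )

    if mode == "multivariate":
        frame = _fit(list(cov.columns))
    else:
        frame = pd.concat([_fit([c]) for c in cov.columns])
    return CoxResult(frame=frame, model_type=mode)


_STRATUM_DEFS = {
    "age": ("age", lambda v: np.where(v <= 65, "age<=65", "age>65")),
    "stage": ("stage", lambda v: np.where(v <= 2, "stage I-II", "stage III-IV")),
    "sex": ("sex", lambda v: np.where(v == 1, "male", "female")),
}


def stratified_analysis(
    scores: RiskScoreTable, surv: SurvivalTable, strata: tuple[str, ...] = ("age", "stage", "sex")
) -> dict[str, dict[str, dict]]:
    """Risk-group KM/log-rank comparison inside clinical strata.

    Supported strata: ``age`` (<=65 vs >65 years), ``stage`` (I–II vs
    III–IV) and ``sex``. Stratum levels with fewer than 2 subjects in either
    risk group are skipped with a warning.
    """
    if scores.group is None:
        raise ValueError("scores must carry high/low group labels (run assign_groups)")
    out: dict[str, dict[str, dict]] = {}
    cov = _encode_covariates(
        surv.frame[[c for c in ("age", "sex", "stage") if c in surv.frame.columns]]
    )
    for name in strata:
        if name not in _STRATUM_DEFS:
            raise ValueError(f"unknown stratum {name!r}; choose from {sorted(_STRATUM_DEFS)}")
        column, classify = _STRATUM_DEFS[name]
        if column not in cov.columns:
            raise ValueError(f"survival table lacks covariate {column!r} needed for stratum {name!r}")
        levels = pd.Series(classify(cov[column]), index=cov.index).where(cov[column].notna())
        out[name] = {}
        for level in sorted(levels.dropna().unique()):
            members = levels.index[levels == level]
            sub_surv = surv.subset(list(members))
            sub_groups = scores.group.reindex(members)
            counts = sub_groups.value_counts()
            if len(counts) < 2 or (counts < 2).any():
                warnings.warn(f"stratum {level!r} lacks 2 subjects per risk group; skipped", stacklevel=2)
                continue
            _, p = km_logrank_compare(sub_groups, sub_surv)
            out[name][str(level)] = {"n": int(len(members)), "logrank_p": p}
    return out


@dataclass
class EvaluationReport:
    """Everything the survival evaluation computes for one scored cohort."""

    endpoint_name: str
    cutoff: float
    km_curves: dict[str, pd.DataFrame]
    logrank_p: float
    c_index: float
    c_index_ci: tuple[float, float]
    auc: dict[int, float]  # year horizon -> AUC
    cox: dict[str, CoxResult] = field(default_factory=dict)
    stratified: dict[str, dict] = field(default_factory=dict)
    n_samples: int = 0
    n_events: int = 0

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint_name,
            "cutoff": self.cutoff,
            "n_samples": self.n_samples,
            "n_events": self.n_events,
            "logrank_p": self.logrank_p,
            "c_index": self.c_index,
            "c_index_ci": list(self.c_index_ci),
            "auc": {f"{k}y": v for k, v in self.auc.items()},
            "km_curves": {
                g: {"time": df["time"].tolist(), "survival": df["survival"].tolist()}
                for g, df in self.km_curves.items()
            },
            "cox": {
                m: {
                    cov: {
                        "hr": float(r["hr"]),
                        "ci": [float(r["ci_low"]), float(r["ci_high"])],
                        "p": float(r["p"]),
                    }
                    for cov, r in res.frame.iterrows()
                }
                for m, res in self.cox.items()
            },
            "stratified": self.stratified,
        }


def evaluate_cohort(
    scores: RiskScoreTable,
    surv: SurvivalTable,
    cutoff: float | None = None,
    cutoff_strategy: str = "median",
    horizons: tuple[int, ...] = (1, 3, 5),
    strata: tuple[str, ...] = (),
    with_cox: bool = True,
) -> EvaluationReport:
    """Full evaluation of scored samples against their survival endpoint."""
    surv = surv.subset(scores.sample_ids)
    if cutoff is None:
        cutoff = select_cutoff(scores, surv, strategy=cutoff_strategy)
    grouped = assign_groups(scores, cutoff)
    if grouped.group.nunique() == 2:
        curves, p = km_logrank_compare(grouped.group, surv)
    else:
        curves, p = {}, float("nan")
    c, ci = concordance_index(scores, surv)
    aucs: dict[int, float] = {}
    for years in horizons:
        t = YEAR_HORIZONS.get(years, years * 365.0)
        try:
            aucs[years] = td_auc(scores, surv, t).auc
        except ValueError:
            logger.warning("no events by the %d-year horizon; AUC omitted", years)
    cox: dict[str, CoxResult] = {}
    if with_cox:
        clinical = [c_ for c_ in ("age", "sex", "stage") if c_ in surv.frame.columns]
        cov = surv.frame[clinical].copy() if clinical else pd.DataFrame(index=surv.sample_ids)
        cov["risk_score"] = scores.frame["score"]
        try:
            cox["univariate"] = cox_regression(surv, cov, mode="univariate")
            cox["multivariate"] = cox_regression(surv, cov, mode="multivariate")
        except Exception as err:  # separation / convergence on tiny cohorts
            logger.warning("Cox regression skipped: %s", err)
    stratified = stratified_analysis(grouped, surv, strata) if strata else {}
    return EvaluationReport(
        endpoint_name=surv.endpoint_name,
        cutoff=float(cutoff),
        km_curves=curves,
        logrank_p=p,
        c_index=c,
        c_index_ci=ci,
        auc=aucs,
        cox=cox,
        stratified=stratified,
        n_samples=len(scores.sample_ids),
        n_events=int(surv.event.sum()),
    )
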
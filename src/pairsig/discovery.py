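"""Signature discovery: log-rank screening with FDR control and LASSO Cox.

The discovery funnel mirrors the published workflow: restrict to an
immune-gene universe, drop low-variance genes (MAD filter), enumerate all
gene pairs, compute binary pair indicators, drop near-constant pairs
(prevalence filter applied jointly to the training and testing halves),
screen each surviving pair with a univariate two-group log-rank test under
Benjamini–Hochberg FDR control, and fit an L1-penalized Cox model on the
significant pairs. The nonzero-coefficient pairs form the signature.

The many-pair log-rank screen is computed with vectorized risk-set counting
(the standard hypergeometric-variance form, aggregate handling of tied event
times), since per-pair calls are impractical at ~2e5 candidate pairs. The
LASSO path is solved by scikit-survival's coxnet; the penalty is chosen by
repeated K-fold cross-validation of the Verweij–van Houwelingen partial
likelihood, averaging the deviance curves over repetitions before applying
the ``min`` or ``1se`` rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    ExpressionMatrix,
    GenePair,
    PairIndicatorMatrix,
    PrognosticSignature,
    ScreeningRecord,
    SurvivalTable,
)
from . import pairs as _pairs

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningResult",
    "LassoFitSpec",
    "logrank_screen",
    "fit_lasso_cox",
    "discover_signature",
    "split_cohort",
]


@dataclass
class ScreeningResult:
    """All per-pair screening records, sorted by ascending p-value."""

    records: list[ScreeningRecord]
    fdr_threshold: float

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.p_value, r.pair))

    @property
    def n_tested(self) -> int:
        return len(self.records)

    @property
    def significant_pairs(self) -> list[GenePair]:
        return [r.pair for r in self.records if r.fdr_q < self.fdr_threshold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": [r.pair.gene_a for r in self.records],
                "gene_b": [r.pair.gene_b for r in self.records],
                "logrank_statistic": [r.logrank_statistic for r in self.records],
                "p_value": [r.p_value for r in self.records],
                "fdr_q": [r.fdr_q for r in self.records],
                "prevalence": [r.prevalence for r in self.records],
            }
        )


@dataclass(frozen=True)
class LassoFitSpec:
    """Cross-validation settings for the penalized Cox fit.

    ``cv_repetitions`` defaults to 1000 repeated K-fold rounds whose deviance
    curves are averaged before the ``lambda_rule`` (``min`` or ``1se``) picks
    the penalty; reduce it for interactive work. ``fixed_alpha`` bypasses
    cross-validation entirely.
    """

    cv_folds: int = 10
    cv_repetitions: int = 1000
    lambda_rule: str = "min"
    seed: int = 0
    n_alphas: int = 50
    fixed_alpha: float | None = None

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repetitions < 1:
            raise ValueError("cv_repetitions must be >= 1")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


def _grouped_logrank(ind: np.ndarray, time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-group log-rank chi-square statistic and p for each row of ``ind``.

    Standard observed-minus-expected form over shared risk sets with the
    hypergeometric variance and aggregate treatment of tied event times.
    Rows where one group is empty (or the variance is zero) get stat 0, p 1.
    """
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    e_s = event[order].astype(float)
    starts = np.concatenate(([0], np.nonzero(np.diff(t_s))[0] + 1))
    n = len(t_s)
    n_at_risk = n - starts
    d_j = np.add.reduceat(e_s, starts)

    stat = np.empty(ind.shape[0])
    # block over pairs to bound memory at ~tens of MB per intermediate
    block = max(1, int(2e7 // max(len(starts), 1)))
    for lo in range(0, ind.shape[0], block):
        X = ind[lo : lo + block, :][:, order].astype(float)
        d1_j = np.add.reduceat(X * e_s[None, :], starts, axis=1)
        entries = np.add.reduceat(X, starts, axis=1)
        n1_at_risk = np.cumsum(entries[:, ::-1], axis=1)[:, ::-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = n1_at_risk / n_at_risk[None, :]
            expected = d_j[None, :] * frac
            var_j = (
                d_j[None, :]
                * frac
                * (1.0 - frac)
                * (n_at_risk[None, :] - d_j[None, :])
                / np.maximum(n_at_risk[None, :] - 1.0, 1.0)
            )
        o_minus_e = (d1_j - expected).sum(axis=1)
        v = var_j.sum(axis=1)
        s = np.zeros(len(v))
        np.divide(o_minus_e**2, v, out=s, where=v > 0)
        stat[lo : lo + block] = s
    p = stats.chi2.sf(stat, df=1)
    p[stat == 0] = 1.0
    return stat, p


def logrank_screen(
    ind: PairIndicatorMatrix, surv: SurvivalTable, fdr_threshold: float = 0.001
) -> ScreeningResult:
    """Univariate log-rank test per pair (indicator 1 vs 0) with BH q-values."""
    if ind.sample_ids != surv.sample_ids:
        raise ValueError("indicator matrix and survival table sample ids differ")
    if not ind.pairs:
        return ScreeningResult(records=[], fdr_threshold=fdr_threshold)
    prev = ind.prevalence
    degenerate = (prev == 0) | (prev == 1)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} pairs split the cohort into one empty group; "
            "their p-values are set to 1 (prevalence_filter should preclude this)",
            stacklevel=2,
        )
    stat, p = _grouped_logrank(ind.indicators, surv.time, surv.event)
    stat[degenerate] = 0.0
    p[degenerate] = 1.0
    _, q, _, _ = multipletests(p, method="fdr_bh")
    records = [
        ScreeningRecord(pair, float(s), float(pv), float(qv), float(pr))
        for pair, s, pv, qv, pr in zip(ind.pairs, stat, p, q, prev)
    ]
    return ScreeningResult(records=records, fdr_threshold=fdr_threshold)


def _breslow_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Breslow partial log-likelihood per column of ``lp`` (n × n_models)."""
    lp = np.atleast_2d(lp.T).T  # ensure 2-D, columns = models
    order = np.argsort(-time, kind="stable")
    lp_s, t_s, e_s = lp[order], time[order], event[order]
    log_risk = np.logaddexp.accumulate(lp_s, axis=0)
    # ties share a risk set: use the prefix up to the last member of the tie
    starts = np.concatenate(([0], np.nonzero(np.diff(t_s))[0] + 1))
    block_last = np.concatenate((starts[1:], [len(t_s)])) - 1
    block_of = np.repeat(np.arange(len(starts)), np.diff(np.concatenate((starts, [len(t_s)]))))
    denom = log_risk[block_last[block_of]]
    mask = e_s == 1
    return (lp_s[mask] - denom[mask]).sum(axis=0)


def _cv_deviance(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    alphas: np.ndarray,
    spec: LassoFitSpec,
) -> np.ndarray:
    """Mean Verweij–van Houwelingen CV deviance per alpha over repeated folds."""
    rng = np.random.default_rng(spec.seed)
    n = len(time)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    dev_curves = []
    for _ in range(spec.cv_repetitions):
        assignment = rng.permutation(n) % spec.cv_folds
        fold_dev = np.zeros(len(alphas))
        for fold in range(spec.cv_folds):
            train = assignment != fold
            if event[train].sum() < 2:
                continue
            model = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=alphas, fit_baseline_model=False
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[train], y[train])
            coefs = model.coef_  # (n_features, n_fitted_alphas)
            fitted = np.isin(alphas, model.alphas_)
            lp_all = X @ coefs
            lp_train = X[train] @ coefs
            cvpl = _breslow_loglik(lp_all, time, event) - _breslow_loglik(
                lp_train, time[train], event[train]
            )
            full = np.full(len(alphas), np.nan)
            full[fitted] = -2.0 * cvpl
            fold_dev += np.where(np.isnan(full), np.nanmax(full), full)
        dev_curves.append(fold_dev)
    return np.mean(dev_curves, axis=0)


def fit_lasso_cox(
    ind_selected: PairIndicatorMatrix, surv: SurvivalTable, spec: LassoFitSpec | None = None
) -> PrognosticSignature:
    """L1-penalized Cox fit on binary pair features; nonzero pairs form the signature.

    The penalty path is solved once on the full data; the reported signature
    refits at the cross-validation-selected penalty (or ``spec.fixed_alpha``).
    Deterministic given ``spec.seed``.
    """
    spec = spec or LassoFitSpec()
    if ind_selected.sample_ids != surv.sample_ids:
        raise ValueError("indicator matrix and survival table sample ids differ")
    if surv.event.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    X = ind_selected.indicators.T.astype(float)
    if X.shape[1] == 0:
        raise ValueError("no candidate pairs to fit")
    if (X.std(axis=0) == 0).all():
        raise ValueError("all candidate pair indicators are constant")
    y = Surv.from_arrays(event=surv.event.astype(bool), time=surv.time)

    if spec.fixed_alpha is not None:
        chosen = float(spec.fixed_alpha)
    else:
        path_model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=spec.n_alphas, fit_baseline_model=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path_model.fit(X, y)
        alphas = np.asarray(path_model.alphas_)
        dev = _cv_deviance(X, surv.time, surv.event, alphas, spec)
        if spec.lambda_rule == "min":
            chosen = float(alphas[int(np.argmin(dev))])
        else:
            # 1se rule on the averaged curve: largest alpha within one SE of
            # the minimum (SE over the per-alpha spread of the curve grid)
            i_min = int(np.argmin(dev))
            se = float(np.std(dev)) / np.sqrt(len(dev)) if len(dev) > 1 else 0.0
            within = np.nonzero(dev <= dev[i_min] + se)[0]
            chosen = float(alphas[within.min()])  # alphas descend along the path

    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[chosen], fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            final.fit(X, y)
            coefs = final.coef_[:, 0]
        except ArithmeticError:
            coefs = np.zeros(X.shape[1])
    entries = [
        (pair, float(beta))
        for pair, beta in zip(ind_selected.pairs, coefs)
        if beta != 0.0
    ]
    if not entries:
        warnings.warn("penalty removed every pair; signature is empty", stacklevel=2)
    return PrognosticSignature(
        entries=entries, cutoff=None, cutoff_strategy="median", endpoint_name=surv.endpoint_name
    )


def split_cohort(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    fraction: float = 0.5,
    seed: int = 0,
    stratify_on: str | None = None,
) -> tuple[list[str], list[str]]:
    """Random disjoint covering train/test split of the shared samples.

    ``stratify_on='event'`` balances the event fraction between halves
    (event proportions differ by less than one subject's worth).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    ids = [s for s in surv.sample_ids if s in set(expr.sample_ids)]
    if len(ids) < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    if stratify_on is None:
        strata = [ids]
    elif stratify_on == "event":
        ev = surv.frame.loc[ids, "event"]
        strata = [[s for s in ids if ev[s] == 1], [s for s in ids if ev[s] == 0]]
    else:
        raise ValueError(f"unknown stratification {stratify_on!r}")
    train: list[str] = []
    test: list[str] = []
    for stratum in strata:
        perm = list(rng.permutation(stratum))
        k = int(round(fraction * len(stratum)))
        train.extend(perm[:k])
        test.extend(perm[k:])
    return sorted(train), sorted(test)


def discover_signature(
    expr_train: ExpressionMatrix,
    surv_train: SurvivalTable,
    expr_test: ExpressionMatrix | None = None,
    gene_list: list[str] | None = None,
    mad_threshold: float = 0.5,
    prevalence_bounds: tuple[float, float] = (0.2, 0.8),
    fdr_threshold: float = 0.001,
    lasso_spec: LassoFitSpec | None = None,
) -> tuple[PrognosticSignature, ScreeningResult, dict]:
    """Run the full discovery funnel on a training cohort.

    Returns the fitted signature, the screening table, and a provenance log
    with the count surviving each stage (gene-universe restriction, MAD
    filter, pair enumeration, prevalence filter on train AND test, FDR
    screen, penalized fit).
    """
    provenance: dict[str, object] = {"genes_initial": len(expr_train.gene_symbols)}
    stage = "restrict_to_gene_list"
    try:
        if gene_list is not None:
            expr_train = _pairs.restrict_to_gene_list(expr_train, gene_list)
            if expr_test is not None:
                expr_test = _pairs.restrict_to_gene_list(expr_test, gene_list)
        provenance["genes_after_list"] = len(expr_train.gene_symbols)

        stage = "mad_filter"
        kept_train = set(_pairs.mad_filter(expr_train, mad_threshold).gene_symbols)
        if expr_test is not None:
            kept_train &= set(_pairs.mad_filter(expr_test, mad_threshold).gene_symbols)
        genes = [g for g in expr_train.gene_symbols if g in kept_train]
        provenance["genes_after_mad"] = len(genes)
        if len(genes) < 2:
            raise ValueError("fewer than 2 genes survive the MAD filter")

        stage = "enumerate_candidate_pairs"
        candidates = _pairs.enumerate_candidate_pairs(genes)
        provenance["pairs_enumerated"] = len(candidates)

        stage = "compute_pair_indicators"
        ind_train = _pairs.compute_pair_indicators(expr_train.subset_genes(genes), candidates)
        ind_test = (
            _pairs.compute_pair_indicators(expr_test.subset_genes(genes), candidates)
            if expr_test is not None
            else None
        )

        stage = "prevalence_filter"
        low, high = prevalence_bounds
        surviving = _pairs.prevalence_filter(ind_train, ind_test, low=low, high=high)
        provenance["pairs_after_prevalence"] = len(surviving)
        if not surviving:
            warnings.warn("no pairs survive the prevalence filter; empty signature", stacklevel=2)
            empty = PrognosticSignature([], endpoint_name=surv_train.endpoint_name)
            return empty, ScreeningResult([], fdr_threshold), provenance
        ind_train = ind_train.subset_pairs(surviving)

        stage = "logrank_screen"
        aligned = surv_train.subset(ind_train.sample_ids)
        screening = logrank_screen(ind_train, aligned, fdr_threshold)
        significant = screening.significant_pairs
        provenance["pairs_after_fdr"] = len(significant)
        if not significant:
            warnings.warn("no pairs pass the FDR screen; empty signature", stacklevel=2)
            empty = PrognosticSignature([], endpoint_name=surv_train.endpoint_name)
            return empty, screening, provenance

        stage = "fit_lasso_cox"
        signature = fit_lasso_cox(ind_train.subset_pairs(significant), aligned, lasso_spec)
        provenance["pairs_final"] = len(signature)
        return signature, screening, provenance
    except Exception as err:
        raise type(err)(f"[stage {stage}] {err}") from err
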
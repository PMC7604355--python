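"""Model/Results interface over the gene-pair signature workflow.

:class:`PairSignatureCox` is the modelling object: it is built from a
training expression matrix and survival table (plus, optionally, the testing
half used by the joint prevalence filter and a gene universe), and its
``fit()`` runs the discovery funnel — MAD filter, pair enumeration,
prevalence filter, log-rank/FDR screen, LASSO-penalized Cox — returning a
:class:`PairSignatureResults`.

The results object carries the fitted :class:`~pairsig.datatypes.PrognosticSignature`,
the screening table and stage-count provenance, and exposes ``summary()``,
``predict_risk()`` (scores any cohort on any monotone per-sample scale) and
``evaluate()`` (KM/log-rank, C-index, time-dependent AUC, Cox models).

Example
-------
>>> from pairsig.simulate import SimulationConfig, generate_cohort
>>> expr, surv, _ = generate_cohort(SimulationConfig(seed=1))
>>> model = PairSignatureCox(expr, surv, mad_threshold=0.5, fdr_threshold=0.001)
>>> res = model.fit(cv_folds=5, cv_repetitions=2, seed=1)
>>> print(res.summary())                      # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datatypes import ExpressionMatrix, PrognosticSignature, RiskScoreTable, SurvivalTable
from .discovery import LassoFitSpec, ScreeningResult, discover_signature
from .evaluate import EvaluationReport, compute_risk_scores, evaluate_cohort

__all__ = ["PairSignatureCox", "PairSignatureResults"]


class PairSignatureCox:
    """Penalized Cox model on binary within-sample gene-pair indicators.

    Parameters
    ----------
    expr_train, surv_train
        Training cohort. Sample ids must overlap; the model aligns them.
    expr_test
        Optional second cohort whose pair prevalences must also fall inside
        ``prevalence_bounds`` for a pair to be retained (the joint filter of
        the published workflow).
    gene_list
        Optional gene universe (e.g. an immune-gene list); ``None`` keeps all.
    mad_threshold
        Genes with (unscaled) median absolute deviation <= this are dropped.
    prevalence_bounds, fdr_threshold
        The pair-retention band and the BH-FDR cut of the log-rank screen.
    """

    def __init__(
        self,
        expr_train: ExpressionMatrix,
        surv_train: SurvivalTable,
        expr_test: ExpressionMatrix | None = None,
        gene_list: list[str] | None = None,
        mad_threshold: float = 0.5,
        prevalence_bounds: tuple[float, float] = (0.2, 0.8),
        fdr_threshold: float = 0.001,
    ):
        shared = [s for s in surv_train.sample_ids if s in set(expr_train.sample_ids)]
        if len(shared) < 2:
            raise ValueError("training expression and survival share fewer than 2 samples")
        self.expr_train = expr_train.subset_samples(shared)
        self.surv_train = surv_train.subset(shared)
        self.expr_test = expr_test
        self.gene_list = gene_list
        self.mad_threshold = mad_threshold
        self.prevalence_bounds = prevalence_bounds
        self.fdr_threshold = fdr_threshold

    @classmethod
    def from_dataframes(
        cls, expr: pd.DataFrame, surv: pd.DataFrame, endpoint_name: str = "OS", **kwargs
    ) -> "PairSignatureCox":
        """Build from plain DataFrames (genes × samples; survival indexed by sample)."""
        return cls(ExpressionMatrix(expr), SurvivalTable(surv, endpoint_name=endpoint_name), **kwargs)

    def fit(
        self,
        cv_folds: int = 10,
        cv_repetitions: int = 1000,
        lambda_rule: str = "min",
        seed: int = 0,
        fixed_alpha: float | None = None,
    ) -> "PairSignatureResults":
        """Run discovery and return a results object. Deterministic given seed."""
        spec = LassoFitSpec(
            cv_folds=cv_folds,
            cv_repetitions=cv_repetitions,
            lambda_rule=lambda_rule,
            seed=seed,
            fixed_alpha=fixed_alpha,
        )
        signature, screening, provenance = discover_signature(
            self.expr_train,
            self.surv_train,
            expr_test=self.expr_test,
            gene_list=self.gene_list,
            mad_threshold=self.mad_threshold,
            prevalence_bounds=self.prevalence_bounds,
            fdr_threshold=self.fdr_threshold,
            lasso_spec=spec,
        )
        return PairSignatureResults(self, signature, screening, provenance)


@dataclass
class PairSignatureResults:
    """Fitted pair signature plus screening table and provenance."""

    model: PairSignatureCox
    signature: PrognosticSignature
    screening: ScreeningResult
    provenance: dict = field(default_factory=dict)

    def summary(self) -> str:
        """Human-readable fit summary: funnel counts and the signature table."""
        lines = ["Gene-pair penalized Cox signature", "=" * 40]
        for key in (
            "genes_initial",
            "genes_after_list",
            "genes_after_mad",
            "pairs_enumerated",
            "pairs_after_prevalence",
            "pairs_after_fdr",
            "pairs_final",
        ):
            if key in self.provenance:
                lines.append(f"{key:>24}: {self.provenance[key]}")
        lines.append("")
        if len(self.signature):
            lines.append(self.signature.to_frame().to_string(index=False))
        else:
            lines.append("(empty signature)")
        return "\n".join(lines)

    def predict_risk(
        self, expr: ExpressionMatrix | None = None, missing_policy: str = "error"
    ) -> RiskScoreTable:
        """Risk scores for a cohort (training cohort when ``expr`` is None)."""
        expr = expr if expr is not None else self.model.expr_train
        return compute_risk_scores(expr, self.signature, missing_policy=missing_policy)

    def evaluate(
        self,
        expr: ExpressionMatrix | None = None,
        surv: SurvivalTable | None = None,
        cutoff: float | None = None,
        cutoff_strategy: str = "median",
        horizons: tuple[int, ...] = (1, 3, 5),
        strata: tuple[str, ...] = (),
    ) -> EvaluationReport:
        """Score and fully evaluate a cohort (defaults to the training cohort)."""
        expr = expr if expr is not None else self.model.expr_train
        surv = surv if surv is not None else self.model.surv_train
        scores = compute_risk_scores(expr, self.signature)
        shared = [s for s in scores.sample_ids if s in set(surv.sample_ids)]
        scores = RiskScoreTable(scores.frame.loc[shared])
        return evaluate_cohort(
            scores,
            surv.subset(shared),
            cutoff=cutoff,
            cutoff_strategy=cutoff_strategy,
            horizons=horizons,
            strata=strata,
        )
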
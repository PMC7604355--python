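"""One-command orchestration: split, discover, score and evaluate cohorts.

``run_full_pipeline`` reproduces the end-to-end workflow on synthetic or
user-supplied data and writes every artefact to an output directory:

* ``config.yaml`` — the validated configuration, verbatim;
* ``signature.tsv`` — the discovered signature;
* ``scores_<cohort>.tsv`` / ``report_<cohort>.json`` — per evaluated cohort;
* ``provenance.json`` — stage counts, package version and seed;
* ``run.log`` — the structured log of the run.

A single global seed fans out to per-stage seeds by fixed offsets, so equal
configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .datatypes import ExpressionMatrix, RiskScoreTable, SurvivalTable
from .discovery import split_cohort
from .evaluate import compute_risk_scores, evaluate_cohort, select_cutoff
from .io import (
    read_expression_matrix,
    read_survival_table,
    write_risk_scores,
    write_signature,
)
from .model import PairSignatureCox

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline"]

# fixed seed offsets per randomized stage
_SEED_SPLIT = 11
_SEED_LASSO = 23


@dataclass
class PipelineConfig:
    """All pipeline knobs; mirrors the CLI flags one-to-one."""

    expr_path: str
    surv_path: str
    out_dir: str
    validation_expr_paths: tuple[str, ...] = ()
    validation_surv_paths: tuple[str, ...] = ()
    gene_list_path: str | None = None
    endpoint_name: str = "OS"
    split_fraction: float = 0.5
    stratify_split: bool = True
    mad_threshold: float = 0.5
    prevalence_low: float = 0.2
    prevalence_high: float = 0.8
    fdr_threshold: float = 0.001
    cv_folds: int = 10
    cv_repetitions: int = 1000
    lambda_rule: str = "min"
    cutoff_strategy: str = "median"
    horizons: tuple[int, ...] = (1, 3, 5)
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.expr_path).exists():
            raise FileNotFoundError(self.expr_path)
        if not Path(self.surv_path).exists():
            raise FileNotFoundError(self.surv_path)
        if len(self.validation_expr_paths) != len(self.validation_surv_paths):
            raise ValueError("validation expression and survival path lists differ in length")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if not 0 <= self.prevalence_low < self.prevalence_high <= 1:
            raise ValueError("prevalence bounds must satisfy 0 <= low < high <= 1")
        if self.cutoff_strategy not in ("median", "roc_youden"):
            raise ValueError("cutoff_strategy must be 'median' or 'roc_youden'")


def _evaluate_and_write(
    name: str,
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    signature,
    config: PipelineConfig,
    out: Path,
    cutoff: float | None,
) -> dict:
    scores = compute_risk_scores(expr, signature, missing_policy="drop_pairs")
    shared = [s for s in scores.sample_ids if s in set(surv.sample_ids)]
    scores = RiskScoreTable(scores.frame.loc[shared])
    report = evaluate_cohort(
        scores,
        surv.subset(shared),
        cutoff=cutoff,
        cutoff_strategy=config.cutoff_strategy,
        horizons=config.horizons,
        strata=tuple(c for c in ("age", "stage", "sex") if c in surv.frame.columns),
    )
    from .evaluate import assign_groups

    write_risk_scores(assign_groups(scores, report.cutoff), out / f"scores_{name}.tsv")
    (out / f"report_{name}.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    logger.info(
        "cohort %s: n=%d events=%d logrank_p=%.3g c=%.3f",
        name, report.n_samples, report.n_events, report.logrank_p, report.c_index,
    )
    return report.to_dict()


def run_full_pipeline(config: PipelineConfig) -> Path:
    """Execute split → discover → score → evaluate; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("pairsig")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))
        stage = "load"
        expr = read_expression_matrix(config.expr_path)
        surv = read_survival_table(config.surv_path, endpoint_name=config.endpoint_name)
        gene_list = None
        if config.gene_list_path:
            gene_list = [
                line.strip().upper()
                for line in Path(config.gene_list_path).read_text().splitlines()
                if line.strip()
            ]

        stage = "split"
        train_ids, test_ids = split_cohort(
            expr,
            surv,
            fraction=config.split_fraction,
            seed=config.seed + _SEED_SPLIT,
            stratify_on="event" if config.stratify_split else None,
        )

        stage = "discover"
        model = PairSignatureCox(
            expr.subset_samples(train_ids),
            surv.subset(train_ids),
            expr_test=expr.subset_samples(test_ids),
            gene_list=gene_list,
            mad_threshold=config.mad_threshold,
            prevalence_bounds=(config.prevalence_low, config.prevalence_high),
            fdr_threshold=config.fdr_threshold,
        )
        results = model.fit(
            cv_folds=config.cv_folds,
            cv_repetitions=config.cv_repetitions,
            lambda_rule=config.lambda_rule,
            seed=config.seed + _SEED_LASSO,
        )
        signature = results.signature.replace(endpoint_name=config.endpoint_name)
        write_signature(signature, out / "signature.tsv")
        results.screening.to_frame().to_csv(out / "screening.tsv", sep="\t", index=False)
        if len(signature) == 0:
            raise RuntimeError("discovery produced an empty signature; nothing to score")

        stage = "score_evaluate"
        # cutoff derived on the training cohort, then applied to every cohort
        train_scores = compute_risk_scores(expr.subset_samples(train_ids), signature)
        if config.cutoff_strategy == "median":
            cutoff = select_cutoff(train_scores, strategy="median")
        else:
            cutoff = select_cutoff(train_scores, surv.subset(train_ids), strategy="roc_youden")
        reports = {}
        reports["train"] = _evaluate_and_write(
            "train", expr.subset_samples(train_ids), surv.subset(train_ids), signature, config, out, cutoff
        )
        reports["test"] = _evaluate_and_write(
            "test", expr.subset_samples(test_ids), surv.subset(test_ids), signature, config, out, cutoff
        )
        for i, (epath, spath) in enumerate(
            zip(config.validation_expr_paths, config.validation_surv_paths), start=1
        ):
            vex = read_expression_matrix(epath)
            vsu = read_survival_table(spath, endpoint_name=config.endpoint_name)
            # external cohorts use their own median, as in the published validation
            reports[f"validation{i}"] = _evaluate_and_write(
                f"validation{i}", vex, vsu, signature, config, out, None
            )

        provenance = dict(results.provenance)
        provenance.update(
            {
                "version": __version__,
                "seed": config.seed,
                "endpoint": config.endpoint_name,
                "n_train": len(train_ids),
                "n_test": len(test_ids),
                "cutoff": cutoff,
            }
        )
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
        return out
    except Exception as err:
        logger.error("pipeline failed at stage %s: %s", stage, err)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    finally:
        root.removeHandler(handler)
        handler.close()
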
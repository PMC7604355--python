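"""Synthetic survival cohorts whose hazard is driven by planted pair indicators.

The generator emulates the statistical structure the pair-signature analysis
assumes, not any particular tumor biology:

* Expression is log-normal per gene: gene *g* has a latent log-mean
  ``m_g ~ Normal(gene_log_mean, gene_log_mean_sd)`` and sample values
  ``exp(Normal(m_g, within_sample_log_sd))``.
* ``n_signal_pairs`` gene-disjoint pairs are planted. The two genes of a
  signal pair share the same log-mean, so the pair's binary indicator
  ``s_k(i) = 1{expr[a,i] > expr[b,i]}`` has prevalence near 0.5 rather than
  being degenerate.
* Each sample's hazard is proportional-hazards in the planted indicators:
  ``h_i = h0 * exp(sum_k beta_k s_k(i))``, with exponential event times,
  exponential random censoring and administrative censoring.

Multi-"platform" replicates apply strictly monotone within-sample distortions
(log1p, power, positive affine, rank), under which every pair indicator — and
hence every downstream risk score — is exactly invariant.

Reproducibility: a single ``numpy`` Generator seeded from ``config.seed``
drives each call, with sub-draws in a documented fixed order (signal-gene
choice, gene log-means, expression, event times, censoring times), so equal
seeds give bitwise-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenePair, SurvivalTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_cohort",
    "apply_monotone_distortion",
    "generate_multiplatform_suite",
    "DISTORTION_MODES",
]

DISTORTION_MODES = ("log1p", "power", "per_sample_affine_pos", "rank")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults give a melanoma-sized discovery problem: 150 immune genes,
    400 patients, 5 planted gene-disjoint signal pairs with log-hazard
    ratios of +-1, a baseline hazard of 1e-3 per day (median baseline
    survival ~ 693 days) and random + 10-year administrative censoring
    tuned to censor roughly 30% of subjects.
    """

    n_genes: int = 150
    n_samples: int = 400
    n_signal_pairs: int = 5
    true_coefficients: tuple[float, ...] | None = None  # default: alternating +-1
    baseline_hazard: float = 1e-3  # events per day
    censoring_rate: float = 5.3e-4  # per day
    admin_censor_time: float = 3650.0  # days
    gene_log_mean: float = 2.0
    gene_log_mean_sd: float = 1.0
    within_sample_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_pairs * 2 > self.n_genes:
            raise ValueError("need n_genes >= 2 * n_signal_pairs for gene-disjoint pairs")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0 or self.admin_censor_time <= 0:
            raise ValueError("censoring_rate must be >= 0 and admin_censor_time > 0")
        if self.within_sample_log_sd <= 0:
            raise ValueError("within_sample_log_sd must be > 0")
        betas = self.resolved_coefficients()
        if len(betas) != self.n_signal_pairs:
            raise ValueError("true_coefficients length must equal n_signal_pairs")

    def resolved_coefficients(self) -> np.ndarray:
        if self.true_coefficients is not None:
            return np.asarray(self.true_coefficients, dtype=float)
        return np.array([1.0 if k % 2 == 0 else -1.0 for k in range(self.n_signal_pairs)])


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort: planted pairs and linear predictor."""

    signal_pairs: list[GenePair]
    true_coefficients: np.ndarray
    linear_predictor: pd.Series  # per sample, sum_k beta_k * s_k(i)
    gene_log_means: pd.Series

    def __post_init__(self) -> None:
        genes = [g for p in self.signal_pairs for g in p]
        if len(set(genes)) != len(genes):
            raise ValueError("signal pairs must be gene-disjoint")


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_cohort(
    config: SimulationConfig, truth: SyntheticTruth | None = None
) -> tuple[ExpressionMatrix, SurvivalTable, SyntheticTruth]:
    """Draw one cohort; pass a previous ``truth`` to resample new patients from
    the same planted signal (gene log-means and pairs reused)."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    betas = config.resolved_coefficients()

    if truth is None:
        # draw order is fixed: (1) signal genes, (2) gene log-means,
        # (3) expression, (4) event times, (5) censoring times
        chosen = rng.choice(config.n_genes, size=2 * config.n_signal_pairs, replace=False)
        signal_pairs = [
            GenePair(genes[chosen[2 * k]], genes[chosen[2 * k + 1]])
            for k in range(config.n_signal_pairs)
        ]
        log_means = rng.normal(config.gene_log_mean, config.gene_log_mean_sd, size=config.n_genes)
        for k in range(config.n_signal_pairs):
            # matched baselines keep the planted indicator's prevalence near 0.5
            log_means[chosen[2 * k + 1]] = log_means[chosen[2 * k]]
        gene_log_means = pd.Series(log_means, index=genes)
    else:
        rng.choice(config.n_genes, size=2 * config.n_signal_pairs, replace=False)  # keep draw order
        rng.normal(size=config.n_genes)
        signal_pairs = list(truth.signal_pairs)
        gene_log_means = truth.gene_log_means.reindex(genes)
        if gene_log_means.isna().any():
            raise ValueError("truth gene universe does not match config.n_genes")
        betas = np.asarray(truth.true_coefficients, dtype=float)

    log_expr = rng.normal(
        gene_log_means.to_numpy()[:, None],
        config.within_sample_log_sd,
        size=(config.n_genes, config.n_samples),
    )
    expr = ExpressionMatrix(
        pd.DataFrame(np.exp(log_expr), index=genes, columns=samples), platform_tag="truth"
    )

    gene_row = {g: i for i, g in enumerate(genes)}
    values = expr.values
    indicators = np.stack(
        [values[gene_row[p.gene_a]] > values[gene_row[p.gene_b]] for p in signal_pairs]
    ).astype(float)
    lp = betas @ indicators

    hazard = config.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, size=config.n_samples)
    else:
        censor_time = np.full(config.n_samples, np.inf)
    censor_time = np.minimum(censor_time, config.admin_censor_time)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    surv = SurvivalTable(
        pd.DataFrame({"time": observed, "event": event}, index=samples), endpoint_name="OS"
    )
    out_truth = SyntheticTruth(
        signal_pairs=signal_pairs,
        true_coefficients=betas,
        linear_predictor=pd.Series(lp, index=samples),
        gene_log_means=gene_log_means,
    )
    return expr, surv, out_truth


def apply_monotone_distortion(
    expr: ExpressionMatrix, mode: str, seed: int = 0
) -> ExpressionMatrix:
    """Apply a strictly increasing within-sample transform of the values.

    Modes: ``log1p`` (requires values > -1), ``power`` (x^gamma on positive
    data, random gamma in (0.3, 3)), ``per_sample_affine_pos`` (a_j*x + b_j
    with random a_j > 0 per sample), ``rank`` (within-sample ranks 1..n_genes,
    average ranks on ties). All preserve within-sample orderings exactly, so
    pair indicators are unchanged.
    """
    rng = np.random.default_rng(seed)
    values = expr.values.copy()
    if mode == "log1p":
        if (values <= -1).any():
            raise ValueError("log1p distortion requires values > -1")
        out = np.log1p(values)
    elif mode == "power":
        if (values < 0).any():
            raise ValueError("power distortion requires non-negative values")
        gamma = rng.uniform(0.3, 3.0)
        out = values**gamma
    elif mode == "per_sample_affine_pos":
        scale = rng.uniform(0.5, 5.0, size=values.shape[1])
        offset = rng.normal(0.0, 10.0, size=values.shape[1])
        if (scale <= 0).any():  # impossible by construction
            raise AssertionError("non-positive affine scale drawn")
        out = values * scale[None, :] + offset[None, :]
    elif mode == "rank":
        order = np.argsort(values, axis=0, kind="stable")
        out = np.empty_like(values)
        ranks = np.arange(1, values.shape[0] + 1, dtype=float)
        for j in range(values.shape[1]):
            col = np.empty(values.shape[0])
            col[order[:, j]] = ranks
            # average ranks across ties so equal values stay equal
            _, inv, counts = np.unique(values[:, j], return_inverse=True, return_counts=True)
            if (counts > 1).any():
                sums = np.bincount(inv, weights=col)
                col = sums[inv] / counts[inv]
            out[:, j] = col
    else:
        raise ValueError(f"unknown distortion mode {mode!r}; choose from {DISTORTION_MODES}")
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.gene_symbols, columns=expr.sample_ids),
        platform_tag=f"{expr.platform_tag}+{mode}" if expr.platform_tag else mode,
    )


def generate_multiplatform_suite(
    config: SimulationConfig, n_platforms: int
) -> tuple[list[tuple[ExpressionMatrix, str]], SurvivalTable, SyntheticTruth]:
    """One undistorted cohort plus ``n_platforms - 1`` monotone-distorted
    replicates of the same expression matrix (same patients, same survival)."""
    if n_platforms < 1:
        raise ValueError("n_platforms must be >= 1")
    expr, surv, truth = generate_cohort(config)
    suite = [(expr, "truth")]
    for j in range(n_platforms - 1):
        mode = DISTORTION_MODES[j % len(DISTORTION_MODES)]
        distorted = apply_monotone_distortion(expr, mode, seed=config.seed + 1000 + j)
        suite.append((distorted, distorted.platform_tag))
    return suite, surv, truth
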
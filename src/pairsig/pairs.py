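"""Gene-pair feature construction.

The feature for an ordered gene pair (a, b) in sample *i* is the binary
indicator ``s(i) = 1 if expr[a, i] > expr[b, i] else 0`` (ties score 0).
Because it only compares two genes *within* the same sample, the indicator is
exactly invariant to any strictly increasing per-sample transform of the
expression values — log, positive affine, power, rank — which is what makes
pair signatures portable across platforms without normalization.

This module provides the filters around that primitive: variance (MAD)
filtering of genes, restriction to an immune-gene universe, candidate pair
enumeration, indicator computation, and prevalence filtering of near-constant
pairs.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np

from .datatypes import ExpressionMatrix, GenePair, PairIndicatorMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "mad_filter",
    "restrict_to_gene_list",
    "enumerate_candidate_pairs",
    "compute_pair_indicators",
    "prevalence_filter",
]


def gene_mad(expr: ExpressionMatrix, scaled: bool = False) -> np.ndarray:
    """Per-gene median absolute deviation from the gene's own median.

    Unscaled by default; ``scaled=True`` applies the 1.4826 normal-consistency
    constant.
    """
    values = expr.values
    med = np.median(values, axis=1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=1)
    return mad * 1.4826 if scaled else mad


def mad_filter(expr: ExpressionMatrix, threshold: float = 0.5, scaled: bool = False) -> ExpressionMatrix:
    """Keep genes whose MAD strictly exceeds ``threshold``; order preserved."""
    if threshold < 0:
        raise ValueError("MAD threshold must be >= 0")
    keep = gene_mad(expr, scaled=scaled) > threshold
    if not keep.any():
        warnings.warn(f"MAD filter at {threshold} removed every gene", stacklevel=2)
    kept = expr.data.loc[keep]
    if kept.empty:
        # preserve an (0 x samples)-shaped frame without tripping the
        # empty-matrix constructor guard
        out = ExpressionMatrix.__new__(ExpressionMatrix)
        out.data = kept
        out.platform_tag = expr.platform_tag
        return out
    return ExpressionMatrix(kept, platform_tag=expr.platform_tag)


def restrict_to_gene_list(expr: ExpressionMatrix, gene_list: Iterable[str]) -> ExpressionMatrix:
    """Intersect the matrix with a gene universe (e.g. an immune-gene list)."""
    universe = {str(g).strip().upper() for g in gene_list}
    keep = [g for g in expr.gene_symbols if g in universe]
    if not keep:
        raise ValueError("no genes in common between matrix and gene list")
    return ExpressionMatrix(expr.data.loc[keep], platform_tag=expr.platform_tag)


def enumerate_candidate_pairs(gene_symbols: Sequence[str]) -> list[GenePair]:
    """All unordered pairs, emitted once in canonical (lexicographic) order.

    Returns n(n-1)/2 pairs with ``gene_a`` < ``gene_b`` lexicographically.
    """
    symbols = list(dict.fromkeys(gene_symbols))
    if len(symbols) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    return [GenePair(a, b) for a, b in itertools.combinations(sorted(symbols), 2)]


def compute_pair_indicators(expr: ExpressionMatrix, pairs: Sequence[GenePair]) -> PairIndicatorMatrix:
    """Binary indicator matrix: 1 iff gene_a strictly exceeds gene_b per sample."""
    pairs = [GenePair(*p).validate() for p in pairs]
    gene_index = {g: i for i, g in enumerate(expr.gene_symbols)}
    missing = sorted({g for p in pairs for g in p if g not in gene_index})
    if missing:
        raise KeyError(f"genes absent from expression matrix: {', '.join(missing)}")
    values = expr.values
    a_idx = np.fromiter((gene_index[p.gene_a] for p in pairs), dtype=np.intp, count=len(pairs))
    b_idx = np.fromiter((gene_index[p.gene_b] for p in pairs), dtype=np.intp, count=len(pairs))
    ind = (values[a_idx, :] > values[b_idx, :]).astype(np.uint8)
    return PairIndicatorMatrix(pairs, expr.sample_ids, ind)


def prevalence_filter(
    ind: PairIndicatorMatrix,
    ind_secondary: PairIndicatorMatrix | None = None,
    low: float = 0.2,
    high: float = 0.8,
) -> list[GenePair]:
    """Drop near-constant pairs: keep those with indicator mean in [low, high].

    When a secondary cohort's indicator matrix is supplied (the held-out half
    of a split, say), a pair must satisfy the band in *both* cohorts.
    """
    if not 0 <= low < high <= 1:
        raise ValueError("require 0 <= low < high <= 1")
    keep = (ind.prevalence >= low) & (ind.prevalence <= high)
    if ind_secondary is not None:
        sec = {p: q for p, q in zip(ind_secondary.pairs, ind_secondary.prevalence)}
        missing = [p for p in ind.pairs if p not in sec]
        if missing:
            raise KeyError(f"{len(missing)} pairs absent from secondary indicator matrix")
        prev2 = np.array([sec[p] for p in ind.pairs])
        keep &= (prev2 >= low) & (prev2 <= high)
    kept = [p for p, k in zip(ind.pairs, keep) if k]
    logger.info("prevalence filter [%g, %g]: %d of %d pairs kept", low, high, len(kept), len(ind.pairs))
    return kept
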
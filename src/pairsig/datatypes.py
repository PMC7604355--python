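"""Core domain containers for rank-based gene-pair survival signatures.

Everything downstream operates on five small containers:

* :class:`ExpressionMatrix` — a genes × samples numeric matrix on any
  per-sample monotone scale (TPM, FPKM, microarray intensity, ranks ...).
* :class:`SurvivalTable` — per-sample time-to-event data plus optional
  clinical covariates.
* :class:`GenePair` — an *ordered* pair of gene symbols; the binary pair
  indicator is 1 when the first gene's expression strictly exceeds the
  second's within a sample.
* :class:`PairIndicatorMatrix` — pairs × samples binary matrix of those
  indicators.
* :class:`PrognosticSignature` — gene pairs with Cox coefficients and an
  optional risk-score cutoff.

All containers validate their invariants at construction time.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "GenePair",
    "PairIndicatorMatrix",
    "PrognosticSignature",
    "RiskScoreTable",
    "ScreeningRecord",
]


class GenePair(NamedTuple):
    """Ordered gene pair; indicator is 1 iff ``gene_a`` > ``gene_b`` in a sample.

    Order matters: ``GenePair("A", "B")`` and ``GenePair("B", "A")`` encode
    complementary indicators (on tie-free data).
    """

    gene_a: str
    gene_b: str

    def validate(self) -> "GenePair":
        if self.gene_a == self.gene_b:
            raise ValueError(f"gene pair members must differ, got ({self.gene_a}, {self.gene_b})")
        return self

    @property
    def label(self) -> str:
        return f"{self.gene_a}__{self.gene_b}"


def _clean_symbol(sym: object) -> str:
    return str(sym).strip().upper()


@dataclass
class ExpressionMatrix:
    """Genes × samples expression matrix with unique uppercase gene symbols.

    ``data`` is a DataFrame indexed by gene symbol with sample ids as
    columns. Duplicated gene symbols or sample ids are collapsed by the
    arithmetic mean at construction (the standard probe/replicate collapsing
    rule). Values must be finite.
    """

    data: pd.DataFrame
    platform_tag: str = ""

    def __post_init__(self) -> None:
        df = self.data
        if df.size == 0:
            raise ValueError("expression matrix is empty")
        df = df.copy()
        df.index = [_clean_symbol(g) for g in df.index]
        df.columns = [str(c).strip() for c in df.columns]
        if df.index.has_duplicates:
            n = int(df.index.duplicated().sum())
            logger.info("collapsing %d duplicate gene symbol rows by mean", n)
            df = df.groupby(level=0, sort=False).mean()
        if df.columns.has_duplicates:
            n = int(df.columns.duplicated().sum())
            logger.info("collapsing %d duplicate sample columns by mean", n)
            df = df.T.groupby(level=0, sort=False).mean().T
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )
        self.data = df

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_symbols if g in set(genes)]
        return ExpressionMatrix(self.data.loc[keep], platform_tag=self.platform_tag)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], platform_tag=self.platform_tag)


@dataclass
class SurvivalTable:
    """Per-sample survival endpoint (time in days, event flag) plus covariates.

    ``frame`` is indexed by unique sample id and carries columns ``time``
    (days, >= 0) and ``event`` (0 = censored, 1 = event), plus any of the
    optional clinical covariates ``age`` (years), ``sex`` (category) and
    ``stage`` (ordinal 1–4).
    """

    frame: pd.DataFrame
    endpoint_name: str = "OS"

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if "time" not in df.columns or "event" not in df.columns:
            raise ValueError("survival table requires 'time' and 'event' columns")
        df.index = [str(s).strip() for s in df.index]
        if pd.Index(df.index).has_duplicates:
            raise ValueError("duplicate sample ids in survival table")
        df["time"] = pd.to_numeric(df["time"], errors="raise").astype(float)
        df["event"] = pd.to_numeric(df["event"], errors="raise")
        if (df["time"] < 0).any():
            bad = df.index[df["time"] < 0][0]
            raise ValueError(f"negative survival time for sample {bad!r}")
        if not df["event"].isin([0, 1]).all():
            bad = df.index[~df["event"].isin([0, 1])][0]
            raise ValueError(f"event flag outside {{0,1}} for sample {bad!r}")
        df["event"] = df["event"].astype(int)
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.frame["event"].to_numpy(dtype=int)

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.frame.loc[list(sample_ids)], endpoint_name=self.endpoint_name)


@dataclass
class PairIndicatorMatrix:
    """Binary pairs × samples matrix of within-sample ordering indicators.

    ``indicators[k, i]`` is 1 iff gene_a of pair ``k`` strictly exceeds
    gene_b in sample ``i`` (ties score 0). By construction the matrix is
    invariant under any strictly increasing within-sample transform of the
    source expression.
    """

    pairs: list[GenePair]
    sample_ids: list[str]
    indicators: np.ndarray

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicators, dtype=np.uint8)
        if ind.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValueError(
                f"indicator shape {ind.shape} does not match "
                f"{len(self.pairs)} pairs x {len(self.sample_ids)} samples"
            )
        if ind.size and not np.isin(ind, [0, 1]).all():
            raise ValueError("indicator entries must be 0 or 1")
        self.pairs = [GenePair(*p).validate() for p in self.pairs]
        self.indicators = ind

    @property
    def prevalence(self) -> np.ndarray:
        """Fraction of samples scoring 1, per pair."""
        return self.indicators.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.indicators, index=[p.label for p in self.pairs], columns=self.sample_ids
        )

    def subset_pairs(self, pairs: Sequence[GenePair]) -> "PairIndicatorMatrix":
        index = {p: k for k, p in enumerate(self.pairs)}
        rows = [index[GenePair(*p)] for p in pairs]
        return PairIndicatorMatrix(
            [self.pairs[r] for r in rows], self.sample_ids, self.indicators[rows]
        )


@dataclass
class PrognosticSignature:
    """A gene-pair risk signature: pairs with Cox coefficients and a cutoff.

    The risk score of sample *i* is ``r_i = sum_k beta_k * s_k(i)`` over the
    signature's pair indicators. ``cutoff`` (if set) splits a cohort into
    high (> cutoff) and low risk; ``cutoff_strategy`` records how it was, or
    should be, obtained (``median``, ``roc_youden`` or ``fixed``).
    """

    entries: list[tuple[GenePair, float]]
    cutoff: float | None = None
    cutoff_strategy: str = "median"
    endpoint_name: str = "OS"
    name: str = ""

    def __post_init__(self) -> None:
        if self.cutoff_strategy not in ("median", "roc_youden", "fixed"):
            raise ValueError(f"unknown cutoff strategy {self.cutoff_strategy!r}")
        entries = [(GenePair(*p).validate(), float(b)) for p, b in self.entries]
        pairs = [p for p, _ in entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate gene pairs in signature")
        if entries:
            coefs = np.array([b for _, b in entries])
            if not np.isfinite(coefs).all():
                raise ValueError("non-finite signature coefficient")
            if not (coefs != 0).any():
                raise ValueError("signature has no nonzero coefficient")
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def pairs(self) -> list[GenePair]:
        return [p for p, _ in self.entries]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([b for _, b in self.entries], dtype=float)

    @property
    def genes(self) -> list[str]:
        """Unique gene symbols across both pair members, in first-seen order."""
        seen: dict[str, None] = {}
        for p, _ in self.entries:
            seen.setdefault(p.gene_a)
            seen.setdefault(p.gene_b)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": [p.gene_a for p, _ in self.entries],
                "gene_b": [p.gene_b for p, _ in self.entries],
                "coefficient": [b for _, b in self.entries],
            }
        )

    def replace(self, **kwargs) -> "PrognosticSignature":
        return dataclasses.replace(self, **kwargs)


@dataclass
class RiskScoreTable:
    """Per-sample signature risk scores, optionally with high/low group labels."""

    frame: pd.DataFrame  # index sample_id; columns score[, group]

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if "score" not in df.columns:
            raise ValueError("risk score table requires a 'score' column")
        df["score"] = df["score"].astype(float)
        if not np.isfinite(df["score"]).all():
            raise ValueError("non-finite risk score")
        if "group" in df.columns and not df["group"].isin(["high", "low"]).all():
            raise ValueError("group labels must be 'high' or 'low'")
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def score(self) -> np.ndarray:
        return self.frame["score"].to_numpy(dtype=float)

    @property
    def group(self) -> pd.Series | None:
        return self.frame["group"] if "group" in self.frame.columns else None


@dataclass
class ScreeningRecord:
    """One pair's univariate log-rank screening result."""

    pair: GenePair
    logrank_statistic: float
    p_value: float
    fdr_q: float
    prevalence: float

    def __post_init__(self) -> None:
        if self.logrank_statistic < 0:
            raise ValueError("log-rank statistic must be non-negative")
        for name in ("p_value", "fdr_q", "prevalence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0, 1]: {v}")
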
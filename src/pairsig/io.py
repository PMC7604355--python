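"""Readers and writers for expression matrices, survival tables and signatures.

File conventions
----------------
Expression: TSV/CSV, genes in rows (first column = gene symbol), samples in
columns, numeric body.

Survival: TSV/CSV with header ``sample_id, time, event[, age, sex, stage]``;
time in days, event in {0, 1}.

Signature: TSV with columns ``gene_a, gene_b, coefficient`` preceded by
optional ``#key=value`` metadata lines (``#cutoff=``, ``#cutoff_strategy=``,
``#endpoint=``, ``#name=``). Coefficients are serialized at full precision so
write/read round-trips exactly.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd

from .datatypes import ExpressionMatrix, GenePair, PrognosticSignature, RiskScoreTable, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_survival_table",
    "write_survival_table",
    "read_signature",
    "write_signature",
    "read_risk_scores",
    "write_risk_scores",
]

_SEPS = {"tsv": "\t", "csv": ","}


def _sep_for(path: str | Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if str(path).lower().endswith(".csv") else "tsv"
    try:
        return _SEPS[fmt]
    except KeyError:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'csv'") from None


def read_expression_matrix(
    path: str | Path, format: str | None = None, platform_tag: str = ""
) -> ExpressionMatrix:
    """Load a genes × samples matrix; duplicate genes/samples collapse by mean.

    Raises a ``ValueError`` naming the offending (gene, sample) cell on any
    non-numeric or missing value.
    """
    sep = _sep_for(path, format)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.size == 0:
        raise ValueError(f"empty expression matrix in {path}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & ~df[col].isna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"non-numeric expression value at gene {gene!r}, sample {col!r}")
        if coerced.isna().any():
            gene = df.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(f"missing expression value at gene {gene!r}, sample {col!r}")
        df[col] = coerced
    return ExpressionMatrix(df, platform_tag=platform_tag)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    expr.data.to_csv(path, sep=_sep_for(path, format), index_label="gene")


def read_survival_table(
    path: str | Path, endpoint_name: str = "OS", format: str | None = None
) -> SurvivalTable:
    """Load a survival table; rows with missing time/event are dropped and counted."""
    sep = _sep_for(path, format)
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    df = df.set_index("sample_id")
    incomplete = df["time"].isna() | df["event"].isna()
    if incomplete.any():
        logger.warning("dropping %d rows with missing time/event", int(incomplete.sum()))
        df = df[~incomplete]
    if df.empty:
        raise ValueError(f"no usable survival rows in {path}")
    return SurvivalTable(df, endpoint_name=endpoint_name)


def write_survival_table(surv: SurvivalTable, path: str | Path, format: str | None = None) -> None:
    surv.frame.to_csv(path, sep=_sep_for(path, format), index_label="sample_id")


def write_signature(signature: PrognosticSignature, path: str | Path) -> None:
    """Serialize a signature as TSV with '#key=value' metadata lines."""
    lines = []
    if signature.name:
        lines.append(f"#name={signature.name}")
    lines.append(f"#endpoint={signature.endpoint_name}")
    lines.append(f"#cutoff_strategy={signature.cutoff_strategy}")
    if signature.cutoff is not None:
        lines.append(f"#cutoff={signature.cutoff!r}")
    lines.append("gene_a\tgene_b\tcoefficient")
    for pair, beta in signature.entries:
        lines.append(f"{pair.gene_a}\t{pair.gene_b}\t{beta!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_signature(path: str | Path) -> PrognosticSignature:
    """Parse a signature TSV; exact round-trip partner of :func:`write_signature`."""
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"empty signature file {path}")
    meta: dict[str, str] = {}
    rows: list[tuple[GenePair, float]] = []
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if not header_seen:
            if [f.strip() for f in fields[:3]] != ["gene_a", "gene_b", "coefficient"]:
                raise ValueError(f"{path}:{lineno}: expected header gene_a/gene_b/coefficient")
            header_seen = True
            continue
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        # tolerate Unicode minus signs in hand-edited files
        coef = float(fields[2].replace("−", "-"))
        rows.append((GenePair(fields[0].strip().upper(), fields[1].strip().upper()), coef))
    if not rows:
        raise ValueError(f"signature file {path} has no pair rows")
    cutoff = None
    if "cutoff" in meta:
        cutoff = float(meta["cutoff"].replace("−", "-"))
        if not math.isfinite(cutoff):
            raise ValueError("non-finite cutoff in signature metadata")
    return PrognosticSignature(
        entries=rows,
        cutoff=cutoff,
        cutoff_strategy=meta.get("cutoff_strategy", "fixed" if cutoff is not None else "median"),
        endpoint_name=meta.get("endpoint", "OS"),
        name=meta.get("name", ""),
    )


def write_risk_scores(scores: RiskScoreTable, path: str | Path, format: str | None = None) -> None:
    scores.frame.to_csv(path, sep=_sep_for(path, format), index_label="sample_id")


def read_risk_scores(path: str | Path, format: str | None = None) -> RiskScoreTable:
    df = pd.read_csv(path, sep=_sep_for(path, format), index_col="sample_id")
    return RiskScoreTable(df)
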
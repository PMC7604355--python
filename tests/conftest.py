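import numpy as np
import pandas as pd
import pytest

from pairsig.datatypes import ExpressionMatrix, SurvivalTable
from pairsig.published import load_published_signature
from pairsig.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def irgp23():
    return load_published_signature("irgp23_os")


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-signal cohort shared across tests (read-only)."""
    cfg = SimulationConfig(n_genes=60, n_samples=200, n_signal_pairs=3, seed=42)
    expr, surv, truth = generate_cohort(cfg)
    return cfg, expr, surv, truth


def make_expr(values: np.ndarray, genes=None, samples=None) -> ExpressionMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def make_surv(time, event, **covariates) -> SurvivalTable:
    n = len(time)
    df = pd.DataFrame({"time": time, "event": event, **covariates},
                      index=[f"S{j}" for j in range(n)])
    return SurvivalTable(df)


def topological_values(pairs, ascending=False) -> dict[str, float]:
    """Assign expression values so every pair's ordering constraint holds.

    With ``ascending=False`` gene_a > gene_b for every pair (all indicators 1);
    with ``ascending=True`` gene_a < gene_b (all indicators 0). Kahn's
    algorithm on the a->b edge set; raises if the pair graph has a cycle.
    """
    nodes = {g for p in pairs for g in (p.gene_a, p.gene_b)}
    edges = {(p.gene_a, p.gene_b) for p in pairs}
    indeg = {g: 0 for g in nodes}
    for _, b in edges:
        indeg[b] += 1
    order, queue = [], sorted(g for g in nodes if indeg[g] == 0)
    while queue:
        g = queue.pop(0)
        order.append(g)
        for a, b in sorted(edges):
            if a == g:
                indeg[b] -= 1
                if indeg[b] == 0:
                    queue.append(b)
    if len(order) != len(nodes):
        raise ValueError("pair graph has a cycle; cannot realize all indicators")
    n = len(order)
    ranks = {g: i for i, g in enumerate(order)}
    return {g: float(1 + ranks[g] if ascending else n - ranks[g]) for g in nodes}
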
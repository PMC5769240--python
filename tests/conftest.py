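import numpy as np
import pandas as pd
import pytest

from eqtl_ensemble.binet import BipartiteNetwork
from eqtl_ensemble.synthdata import SimulationPlan, make_snp_panel


@pytest.fixture(scope="session")
def small_panel() -> pd.DataFrame:
    return make_snp_panel(n_snps=60, seed=7, chroms=("1", "2"), spacing_bp=10_000)


@pytest.fixture
def null_plan() -> SimulationPlan:
    """No planted effects anywhere."""
    return SimulationPlan(n_cases=10, n_controls=10, n_snps=20, seed=5)


def make_network(edges) -> BipartiteNetwork:
    edges = set(edges)
    return BipartiteNetwork(
        snp_nodes={s for s, _ in edges},
        gene_nodes={g for _, g in edges},
        edges=edges,
    )


def random_bipartite(rng: np.random.Generator, max_nodes: int = 8, max_edges: int = 12) -> BipartiteNetwork:
    """Random small bipartite network with no isolated nodes."""
    while True:
        n_s = int(rng.integers(2, max_nodes - 1))
        n_g = int(rng.integers(2, max_nodes - n_s + 1))
        possible = [(f"s{i}", f"g{j}") for i in range(n_s) for j in range(n_g)]
        n_e = int(rng.integers(min(len(possible), 3), min(len(possible), max_edges) + 1))
        idx = rng.choice(len(possible), size=n_e, replace=False)
        edges = {possible[i] for i in idx}
        snps = {s for s, _ in edges}
        genes = {g for _, g in edges}
        if len(snps) == n_s and len(genes) == n_g:
            return make_network(edges)


def set_partitions(items):
    """All partitions of a list (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part
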
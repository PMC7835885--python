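import networkx as nx
import numpy as np
import pandas as pd
import pytest

import physnet as pn


def make_table(array, names=None):
    """Wrap a 2-D array as a CohortTable with minimal metadata."""
    array = np.asarray(array, dtype=float)
    n, p = array.shape
    names = names or [f"v{i+1}" for i in range(p)]
    values = pd.DataFrame(array, columns=names, index=pd.RangeIndex(1, n + 1, name="subject"))
    meta = pd.DataFrame(
        {"id": np.arange(1, p + 1), "short_name": names, "category": "test", "units": "a.u."}
    )
    return pn.CohortTable(values, meta)


@pytest.fixture
def planted_spec():
    """Six planted blocks (sizes 8-12), the structure-recovery benchmark."""
    sizes = [8, 9, 10, 10, 11, 12]
    def factory(seed):
        return pn.CohortSpec(
            n_subjects=150,
            blocks=[pn.BlockSpec(f"B{i+1}", s, 0.6) for i, s in enumerate(sizes)],
            between_rho=0.1,
            seed=seed,
        )
    return factory


@pytest.fixture
def two_cliques_bridge():
    """Two unit-weight K4s joined by one edge; known best bipartition."""
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    g.add_edge(0, 4)
    return g


def weighted_random_graph(n, m, seed, lo=0.1, hi=1.0):
    rng = np.random.default_rng(seed)
    g = nx.gnm_random_graph(n, m, seed=seed)
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(lo, hi))
    return g
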
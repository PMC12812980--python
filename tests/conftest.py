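import numpy as np
import pandas as pd
import pytest

from trophonet import AbundanceTable
from trophonet.community import rarefy
from trophonet.network import build_network, filter_low_abundance
from trophonet.simulate import GradientScenario, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic gradient study under the default conditions."""
    return generate_dataset(GradientScenario(seed=7))


@pytest.fixture(scope="session")
def combined_table(default_dataset):
    """Filtered phytoplankton + rarefied bacteria in one table, the input
    to per-group network construction."""
    ds = default_dataset
    bact_r = rarefy(ds.bact, 27000, seed=7)
    phyto_f = filter_low_abundance(ds.phyto)
    bact_f = filter_low_abundance(bact_r)
    counts = pd.concat([phyto_f.counts, bact_f.counts]).fillna(0.0)
    return AbundanceTable(counts=counts, taxonomy=ds.taxonomy, group=ds.phyto.group)


@pytest.fixture(scope="session")
def group_networks(combined_table):
    return {g: build_network(combined_table, group=g) for g in ("L", "M", "H")}


def random_graph_edges(rng, n, p):
    """Random simple graph as an edge list over nodes 0..n-1."""
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((i, j))
    return edges
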
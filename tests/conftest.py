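import networkx as nx
import pandas as pd
import pytest

import paleonet as pn


def make_table(rows):
    """Build an OccurrenceTable from (taxon, point, formation, *meta) rows."""
    records = []
    for row in rows:
        taxon, point, formation = row[:3]
        extra = row[3] if len(row) > 3 else {}
        records.append({
            "taxon": taxon,
            "collection_id": point,
            "formation": formation,
            **extra,
        })
    return pn.read_occurrences(pd.DataFrame(records))


@pytest.fixture(scope="session")
def synthetic_default():
    """One draw from the reference generator configuration."""
    return pn.generate(pn.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def synthetic_small():
    """A reduced planted dataset for cheap end-to-end checks."""
    config = pn.SyntheticConfig(
        n_biozones=3,
        formations_per_biozone=4,
        taxon_pool_size_per_biozone=12,
        collections_per_formation=(5, 10),
        seed=5,
    )
    return pn.generate(config)


@pytest.fixture
def two_cliques():
    """Two 4-cliques joined by a single bridge edge."""
    G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    G.add_edge(0, 4)
    return G


def incidence_from_dict(taxa_sets, samples):
    """IncidenceMatrix from {taxon: set of samples}."""
    mat = pd.DataFrame(
        {s: [s in taxa_sets[t] for t in taxa_sets] for s in samples},
        index=list(taxa_sets),
    )
    return pn.IncidenceMatrix(mat)
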
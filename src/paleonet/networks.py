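"""Construction of fossil co-occurrence and bipartite networks plus metrics.

Networks are :class:`networkx.Graph` objects. Every node carries a
``node_type`` attribute (``taxon`` | ``environment`` | ``formation``); a
bipartite graph additionally records its two classes in
``G.graph["bipartite_classes"]`` and marks each node with the standard
``bipartite`` 0/1 attribute. Taxon nodes carry the taxon metadata useful for
assortativity (preservational mode, morphogroup, form category,
paleocommunity).
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx
import pandas as pd

from .errors import InputDataError, ParameterError, UndefinedMetricError
from .occurrences import BODY_GENUS, ICHNOGENUS, OccurrenceTable

TAXON = "taxon"
ENVIRONMENT = "environment"
FORMATION = "formation"


def _taxon_attrs(table: OccurrenceTable, name: str) -> dict:
    t = table.taxa[name]
    return {
        "node_type": TAXON,
        "kind": t.kind,
        "preservational_mode": t.preservational_mode or "",
        "morphogroup": t.morphogroup or "",
        "trace_architecture": t.trace_architecture or "",
        "form_category": t.form_category or "",
        "paleocommunity": t.paleocommunity or "",
    }


def cooccurrence_network(
    table: OccurrenceTable, include_ichnogenera: bool = False
) -> nx.Graph:
    """Unipartite genus network: a link joins taxa sharing >= 1 collection point.

    Genera isolated after construction (no co-occurrence anywhere) are
    excluded, mirroring the index-taxon filter rules.
    """
    kinds = {BODY_GENUS} | ({ICHNOGENUS} if include_ichnogenera else set())
    wanted = {n for n, t in table.taxa.items() if t.kind in kinds}
    if len(wanted) < 2:
        raise InputDataError("co-occurrence network needs >= 2 genera")
    by_point: dict[str, set[str]] = {}
    for taxon, pid in table.occurrences:
        if taxon in wanted:
            by_point.setdefault(pid, set()).add(taxon)
    G = nx.Graph(network_kind="cooccurrence")
    for members in by_point.values():
        ms = sorted(members)
        for i, a in enumerate(ms):
            for b in ms[i + 1:]:
                G.add_edge(a, b)
    for n in G.nodes:
        G.nodes[n].update(_taxon_attrs(table, n))
    return G


def bipartite_network(
    table: OccurrenceTable,
    partner: str = "formations",
    taxa_filter: Callable[[str], bool] | Iterable[str] | None = None,
    include_ichnogenera: bool = True,
) -> nx.Graph:
    """Bipartite taxa x formations or taxa x environments network.

    Taxon-formation links record >= 1 occurrence of the taxon in the
    formation; taxon-environment links record membership of the environment
    code in the taxon's environment set.
    """
    if partner not in ("formations", "environments"):
        raise ParameterError(f"unknown partner side {partner!r}")
    kinds = {BODY_GENUS} | ({ICHNOGENUS} if include_ichnogenera else set())
    if taxa_filter is None:
        selector = lambda n: True  # noqa: E731
    elif callable(taxa_filter):
        selector = taxa_filter
    else:
        allowed = set(taxa_filter)
        selector = lambda n: n in allowed  # noqa: E731
    wanted = {
        n for n, t in table.taxa.items() if t.kind in kinds and selector(n)
    }

    partner_type = FORMATION if partner == "formations" else ENVIRONMENT
    G = nx.Graph(
        network_kind=f"bipartite_{partner}",
        bipartite_classes=(partner_type, TAXON),
    )
    edges: set[tuple[str, str]] = set()
    if partner == "formations":
        for taxon, pid in table.occurrences:
            if taxon in wanted:
                edges.add((table.points[pid].formation, taxon))
    else:
        for taxon in wanted:
            for env in table.taxon_environments.get(taxon, set()):
                edges.add((env, taxon))
    if not edges:
        raise InputDataError(f"no links to partner side {partner!r}")
    for p, t in sorted(edges):
        G.add_edge(p, t)
    for n in G.nodes:
        if n in wanted:
            G.nodes[n].update(_taxon_attrs(table, n))
            G.nodes[n]["bipartite"] = 1
        else:
            G.nodes[n]["node_type"] = partner_type
            G.nodes[n]["bipartite"] = 0
    return G


def is_bipartite_typed(net: nx.Graph) -> bool:
    """True when the graph records explicit bipartite classes."""
    return "bipartite_classes" in net.graph


def bipartite_sides(net: nx.Graph) -> tuple[list, list]:
    """Nodes of class 0 and class 1, in sorted order."""
    c0, c1 = net.graph["bipartite_classes"]
    side0 = sorted(n for n, d in net.nodes(data=True) if d["node_type"] == c0)
    side1 = sorted(n for n, d in net.nodes(data=True) if d["node_type"] == c1)
    return side0, side1


def one_mode_projection(
    net: nx.Graph, side: str, weighted: bool = False
) -> nx.Graph:
    """Project a bipartite network onto one node class.

    Two nodes are linked iff they share at least one neighbor on the other
    side. By default the projection is unweighted; with ``weighted=True`` the
    shared-neighbor count is stored as the ``weight`` edge attribute.
    """
    if not is_bipartite_typed(net):
        raise ParameterError("projection requires a bipartite network")
    if side not in net.graph["bipartite_classes"]:
        raise ParameterError(
            f"{side!r} is not a class of this network "
            f"{net.graph['bipartite_classes']}"
        )
    keep = [n for n, d in net.nodes(data=True) if d["node_type"] == side]
    if weighted:
        P = nx.bipartite.weighted_projected_graph(net, keep)
    else:
        P = nx.bipartite.projected_graph(net, keep)
    P.graph.clear()
    P.graph["network_kind"] = f"projection_{side}"
    return P


def degree_centrality(net: nx.Graph) -> dict:
    """Number of distinct neighbors of each node, excluding self-loops."""
    return {
        n: len(set(net.neighbors(n)) - {n}) for n in net.nodes
    }


def betweenness_centrality(net: nx.Graph) -> dict:
    """Unnormalized betweenness with equal splitting over shortest paths."""
    return nx.betweenness_centrality(net, normalized=False)


def assortativity(net: nx.Graph, attribute: str = "degree") -> float:
    """Homophily coefficient in [-1, 1].

    ``attribute="degree"`` gives the Pearson correlation of endpoint degrees;
    any other name is treated as a nominal node attribute and scored with
    Newman's nominal assortativity.

    Raises
    ------
    UndefinedMetricError
        when the coefficient is undefined (zero variance, e.g. a regular
        graph for degree assortativity or a single-category attribute).
    """
    if net.number_of_edges() == 0:
        raise UndefinedMetricError("assortativity undefined: no links")
    if attribute == "degree":
        degrees = {d for _, d in net.degree()}
        if len(degrees) == 1:
            raise UndefinedMetricError(
                "degree assortativity undefined: regular graph (zero variance)"
            )
        r = nx.degree_assortativity_coefficient(net)
    else:
        values = {net.nodes[n].get(attribute) for n in net.nodes}
        if None in values:
            raise ParameterError(
                f"attribute {attribute!r} missing on some nodes"
            )
        if len(values) == 1:
            raise UndefinedMetricError(
                f"assortativity undefined: single {attribute!r} category"
            )
        r = nx.attribute_assortativity_coefficient(net, attribute)
    if math.isnan(r):
        raise UndefinedMetricError(
            f"assortativity undefined for attribute {attribute!r}"
        )
    return float(r)


# -- import/export ------------------------------------------------------

def write_edgelist_csv(net: nx.Graph, path: str | Path) -> None:
    rows = [{"source": u, "target": v} for u, v in sorted(net.edges())]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    G = net.copy()
    if "bipartite_classes" in G.graph:  # GraphML values must be scalar
        G.graph["bipartite_classes"] = ",".join(G.graph["bipartite_classes"])
    nx.write_graphml(G, path)


def read_graphml(path: str | Path) -> nx.Graph:
    G = nx.read_graphml(path)
    if "bipartite_classes" in G.graph:
        G.graph["bipartite_classes"] = tuple(
            G.graph["bipartite_classes"].split(",")
        )
    return G
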
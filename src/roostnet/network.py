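"""Binary co-roosting association networks.

An association exists between two individuals iff they were recorded in
the same roost on the same calendar date at least once.  Edges are
undirected and unweighted (A-B is the same link as B-A); the number of
shared occasions is kept as an edge attribute for diagnostics only and
plays no role in any analysis.  The two study species never share a
roost simultaneously, so networks are built per species.
"""

from __future__ import annotations

import csv
import logging
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .records import capture_counts

logger = logging.getLogger("roostnet")


def build_network(records: pd.DataFrame, species: str | None = None) -> nx.Graph:
    """Build the association network from validated capture records.

    Parameters
    ----------
    records
        Validated capture table.
    species
        Restrict to one species; None uses all records (no cross-species
        edge can arise if the data respect roost exclusivity, but
        filtering is explicit and recommended).

    Nodes carry ``species``, ``sex`` and ``age_class`` attributes; edges
    carry ``n_shared`` (number of shared roost-date occasions).
    """
    if species is not None:
        records = records[records["species"] == species]
        if records.empty:
            logger.warning("species filter %r matches no records: empty network", species)
    G = nx.Graph()
    if records.empty:
        return G
    attrs = records.drop_duplicates("individual_id").set_index("individual_id")
    for iid, row in attrs.iterrows():
        G.add_node(iid, species=row["species"], sex=row["sex"], age_class=row["age_class"])
    for (_roost, _date), colony in records.groupby(["roost_id", "date"]):
        ids = sorted(colony["individual_id"].unique())
        for a, b in combinations(ids, 2):
            if G.has_edge(a, b):
                G[a][b]["n_shared"] += 1
            else:
                G.add_edge(a, b, n_shared=1)
    return G


def filter_network(G: nx.Graph, records: pd.DataFrame) -> nx.Graph:
    """Apply the analysis inclusion rules.

    Individuals captured only once are excluded, then individuals with no
    remaining associations are excluded.  The order is fixed for
    reproducibility (it is observationally irrelevant).
    """
    counts = capture_counts(records)
    H = G.copy()
    once = [n for n in H.nodes if counts.get(n, 0) < 2]
    H.remove_nodes_from(once)
    isolated = [n for n in H.nodes if H.degree(n) == 0]
    H.remove_nodes_from(isolated)
    logger.info(
        "network filter: %d nodes in, %d removed (captured once), %d removed (no associations), %d retained",
        G.number_of_nodes(), len(once), len(isolated), H.number_of_nodes(),
    )
    H.graph["n_excluded_once_captured"] = len(once)
    H.graph["n_excluded_no_associations"] = len(isolated)
    return H


def subnetwork_by_sex(G: nx.Graph, sex: str) -> nx.Graph:
    """Induced subgraph on nodes of one sex ('M' or 'F')."""
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    nodes = [n for n, d in G.nodes(data=True) if d.get("sex") == sex]
    return G.subgraph(nodes).copy()


def write_edgelist_csv(G: nx.Graph, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["individual_a", "individual_b", "n_shared"])
        for a, b, d in sorted(G.edges(data=True)):
            w.writerow([a, b, d.get("n_shared", 1)])


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(G, path)
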
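"""Symbiosome compartment-graph connectivity statistics.

The symbiosome of *Anaeramoeba* is a membrane network of compartments, each
housing one symbiont, connected by tubular channels; some compartments also
open to the outside medium.  The network is modelled as a simple undirected
graph whose nodes are symbiont compartments (with a boolean external-contact
flag) and whose edges are symbiont–symbiont membrane connections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Tuple

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class ContactSummary:
    """Connectivity tallies of a compartment graph."""

    n_nodes: int
    n_edges: int
    n_components: int
    n_multi_components: int  # components with >= 2 symbionts
    largest_component_size: int
    n_singletons: int
    n_contacted: int  # degree >= 1
    pct_contacted: int  # rounded to nearest integer percent
    n_external: int  # external_contact flag set

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class CompartmentGraph:
    """Simple undirected graph of symbiont compartments.

    Invariants enforced at construction: no self-loops, no duplicate edges,
    every edge endpoint declared as a node.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[Tuple[str, str]],
        external: Iterable[str] = (),
    ):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        external = set(external)
        unknown_ext = external - set(g.nodes)
        if unknown_ext:
            raise ValueError(f"external flags for undeclared nodes: {sorted(unknown_ext)}")
        seen = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop at node {a}")
            if a not in g.nodes or b not in g.nodes:
                raise ValueError(f"edge ({a}, {b}) references undeclared node")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate edge ({a}, {b})")
            seen.add(key)
            g.add_edge(a, b)
        nx.set_node_attributes(
            g, {n: (n in external) for n in g.nodes}, "external_contact"
        )
        self._g = g

    @property
    def nodes(self) -> List[str]:
        return list(self._g.nodes)

    @property
    def edges(self) -> List[Tuple[str, str]]:
        return list(self._g.edges)

    def external_nodes(self) -> Set[str]:
        return {n for n, d in self._g.nodes(data="external_contact") if d}

    def degree(self, node: str) -> int:
        return self._g.degree[node]

    def components(self) -> List[Set[str]]:
        """Maximal connected node sets, largest first."""
        comps = [set(c) for c in nx.connected_components(self._g)]
        comps.sort(key=lambda c: (-len(c), sorted(c)))
        return comps

    def contact_summary(self) -> ContactSummary:
        comps = self.components()
        n_nodes = self._g.number_of_nodes()
        n_singletons = sum(1 for c in comps if len(c) == 1)
        n_contacted = sum(1 for n in self._g.nodes if self._g.degree[n] >= 1)
        pct = int(100 * n_contacted / n_nodes + 0.5) if n_nodes else 0
        return ContactSummary(
            n_nodes=n_nodes,
            n_edges=self._g.number_of_edges(),
            n_components=len(comps),
            n_multi_components=sum(1 for c in comps if len(c) >= 2),
            largest_component_size=len(comps[0]) if comps else 0,
            n_singletons=n_singletons,
            n_contacted=n_contacted,
            pct_contacted=pct,
            n_external=len(self.external_nodes()),
        )

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()


def read_graph(edges_path, nodes_path) -> CompartmentGraph:
    """Read an edge-list TSV (node_a, node_b) and a node-attribute TSV
    (node, external_contact in {0,1})."""
    ndf = pd.read_csv(nodes_path, sep="\t", dtype=str)
    if not {"node", "external_contact"}.issubset(ndf.columns):
        raise ValueError("node table must have columns node, external_contact")
    bad = ndf.loc[~ndf["external_contact"].isin(["0", "1"])]
    if len(bad):
        raise ValueError(f"external_contact must be 0/1; bad rows: {bad['node'].tolist()}")
    edf = pd.read_csv(edges_path, sep="\t", dtype=str)
    if not {"node_a", "node_b"}.issubset(edf.columns):
        raise ValueError("edge table must have columns node_a, node_b")
    return CompartmentGraph(
        nodes=ndf["node"].tolist(),
        edges=list(zip(edf["node_a"], edf["node_b"])),
        external=ndf.loc[ndf["external_contact"] == "1", "node"].tolist(),
    )


def write_graph(graph: CompartmentGraph, edges_path, nodes_path) -> None:
    ext = graph.external_nodes()
    pd.DataFrame(
        {"node": graph.nodes, "external_contact": [int(n in ext) for n in graph.nodes]}
    ).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(graph.edges, columns=["node_a", "node_b"]).to_csv(
        edges_path, sep="\t", index=False
    )


def write_graphml(graph: CompartmentGraph, path) -> None:
    nx.write_graphml(graph.to_networkx(), path)
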
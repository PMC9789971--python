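"""Post-processing of significant links into components, hubs and tables.

The significant links of the SVR-CLSM analysis form an undirected graph on
the parcellation's regions. The graph is segmented into connected components
(subnetworks with continuous links between nodes), and nodes disconnected
from strictly more than ``hub_threshold`` other regions (default 3) are
reported as hubs. The edge table carries per-link beta, p and the hemisphere
tags of both endpoints so interhemispheric disconnections are identifiable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import DataContractError
from .parcellation import Parcellation
from .svr import ClsmResult

DEFAULT_HUB_THRESHOLD = 3


def build_graph(result: ClsmResult, parcellation: Parcellation) -> nx.Graph:
    """Undirected graph of the Bonferroni-significant links.

    Nodes carry ``name`` and ``hemisphere`` attributes; edges carry ``beta``
    and ``p``. Only significant links become edges; self-loops cannot occur
    because links are ROI pairs with distinct nodes by construction.
    """
    if result.link_index is None:
        raise DataContractError("ClsmResult carries no link identities")
    g = nx.Graph()
    for (a, b), beta, p, sig in zip(
        result.link_index, result.beta, result.p_value, result.significant
    ):
        if not sig:
            continue
        for lab in (a, b):
            g.add_node(
                lab,
                name=parcellation.names[lab],
                hemisphere=parcellation.hemisphere[lab],
            )
        g.add_edge(a, b, beta=float(beta), p=float(p))
    return g


def components(graph: nx.Graph) -> list[set[int]]:
    """Connected components, ordered by edge count desc, size desc, then names."""
    comps = list(nx.connected_components(graph))

    def sort_key(nodes: set[int]):
        sub = graph.subgraph(nodes)
        names = sorted(graph.nodes[n].get("name", str(n)) for n in nodes)
        return (-sub.number_of_edges(), -len(nodes), names)

    return sorted(comps, key=sort_key)


def hubs(graph: nx.Graph, threshold: int = DEFAULT_HUB_THRESHOLD) -> list[tuple[int, int]]:
    """Nodes with degree strictly greater than ``threshold``.

    Returned as (node, degree), degree descending, ties by region name.
    Degrees count links within the significant graph only.
    """
    if threshold < 0:
        raise DataContractError("hub threshold must be >= 0")
    found = [
        (node, deg)
        for node, deg in graph.degree()
        if deg > threshold
    ]
    return sorted(
        found, key=lambda nd: (-nd[1], graph.nodes[nd[0]].get("name", str(nd[0])))
    )


@dataclass
class NetworkReport:
    """Components, hubs and the labelled edge table of the significant graph."""

    components: list[set[int]]
    hubs: list[tuple[int, int]]
    edge_table: pd.DataFrame
    hub_threshold: int

    def summary(self) -> dict:
        return {
            "n_significant_links": int(len(self.edge_table)),
            "n_components": len(self.components),
            "component_sizes": [len(c) for c in self.components],
            "hubs": [
                {"label": int(n), "degree": int(d)} for n, d in self.hubs
            ],
            "hub_threshold": self.hub_threshold,
        }

    def save(self, out_dir: str | Path, parcellation: Parcellation) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.edge_table.to_csv(out / "edges.csv", index=False)
        comp_rows = [
            {
                "component": i,
                "label": lab,
                "name": parcellation.names[lab],
                "hemisphere": parcellation.hemisphere[lab],
            }
            for i, comp in enumerate(self.components)
            for lab in sorted(comp)
        ]
        pd.DataFrame(
            comp_rows, columns=["component", "label", "name", "hemisphere"]
        ).to_csv(out / "components.csv", index=False)
        hub_rows = [
            {
                "label": lab,
                "name": parcellation.names[lab],
                "hemisphere": parcellation.hemisphere[lab],
                "degree": deg,
            }
            for lab, deg in self.hubs
        ]
        pd.DataFrame(hub_rows, columns=["label", "name", "hemisphere", "degree"]).to_csv(
            out / "hubs.csv", index=False
        )
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def make_report(
    result: ClsmResult,
    parcellation: Parcellation,
    hub_threshold: int = DEFAULT_HUB_THRESHOLD,
) -> NetworkReport:
    """Segment significant links into subnetworks and extract hubs."""
    graph = build_graph(result, parcellation)
    rows = []
    for a, b, data in sorted(
        graph.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))
    ):
        a, b = min(a, b), max(a, b)
        ha, hb = parcellation.hemisphere[a], parcellation.hemisphere[b]
        rows.append(
            {
                "roi_a": a,
                "roi_b": b,
                "name_a": parcellation.names[a],
                "name_b": parcellation.names[b],
                "hemisphere_a": ha,
                "hemisphere_b": hb,
                "interhemispheric": (ha != hb) and "midline" not in (ha, hb),
                "beta": data["beta"],
                "p": data["p"],
            }
        )
    edge_table = pd.DataFrame(
        rows,
        columns=[
            "roi_a", "roi_b", "name_a", "name_b", "hemisphere_a",
            "hemisphere_b", "interhemispheric", "beta", "p",
        ],
    )
    return NetworkReport(
        components=components(graph),
        hubs=hubs(graph, hub_threshold),
        edge_table=edge_table,
        hub_threshold=hub_threshold,
    )
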
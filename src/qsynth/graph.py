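"""Thresholded Pearson correlation graph over subscales and cascade ordering.

Nodes are the battery's subscales; an undirected edge joins two subscales
whose absolute pairwise-complete Pearson correlation reaches the threshold
(default 0.5, the usual moderate-correlation cut).  The questionnaire
generation order is derived greedily from graph coverage: starting from the
input questionnaire, repeatedly pick the questionnaire whose subscale nodes
are best covered by the already-selected questionnaires' nodes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .schema import QuestionnaireSchema

logger = logging.getLogger(__name__)

__all__ = [
    "SubscaleGraph",
    "pearson_matrix",
    "build_graph",
    "coverage",
    "covered_nodes",
    "cascade_order",
]


def pearson_matrix(scores: pd.DataFrame, min_records: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of subscale scores.

    Pairs with fewer than ``min_records`` complete observations, and pairs
    involving a constant column, yield NaN (and later generate no edge).
    """
    if isinstance(scores, np.ndarray):
        scores = pd.DataFrame(scores)
    corr = scores.corr(method="pearson", min_periods=min_records)
    n_missing = int(corr.isna().sum().sum()) - int(np.isnan(np.diag(corr)).sum())
    if n_missing:
        logger.warning("pearson_matrix: %d subscale pairs have undefined correlation "
                       "(constant column or < %d shared records)", n_missing // 2, min_records)
    np.fill_diagonal(corr.values, 1.0)
    return corr


class SubscaleGraph:
    """Undirected graph of subscales with |r| >= tau edges."""

    def __init__(self, g: nx.Graph, schema: QuestionnaireSchema, tau: float):
        self.g = g
        self.schema = schema
        self.tau = tau

    @property
    def nodes(self) -> list[str]:
        return list(self.g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.g.edges)

    def nodes_of(self, questionnaire: str) -> list[str]:
        q = self.schema.questionnaire(questionnaire).name
        return [n for n, d in self.g.nodes(data=True) if d["questionnaire"] == q]

    def degree_table(self) -> pd.DataFrame:
        rows = [
            {
                "subscale": n,
                "questionnaire": d["questionnaire"],
                "subject": d["subject"],
                "degree": self.g.degree[n],
            }
            for n, d in self.g.nodes(data=True)
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "r": d["weight"]}
            for a, b, d in self.g.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "r"])

    def to_edgelist_csv(self, path: str | Path) -> None:
        self.edge_table().to_csv(path, index=False)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.g, path)

    def subject_graph(self) -> nx.Graph:
        """Aggregate nodes by subject area (edge if any member pair is linked)."""
        sg = nx.Graph()
        for _, d in self.g.nodes(data=True):
            sg.add_node(d["subject"])
        for a, b in self.g.edges:
            sa = self.g.nodes[a]["subject"]
            sb = self.g.nodes[b]["subject"]
            if sa != sb:
                sg.add_edge(sa, sb)
        return sg


def build_graph(
    corr: pd.DataFrame,
    schema: QuestionnaireSchema,
    tau: float = 0.5,
) -> SubscaleGraph:
    """Threshold the correlation matrix into a subscale graph.

    Every schema subscale is a node (isolated if nothing correlates); an edge
    {i, j} exists iff |corr(i, j)| >= tau.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"threshold tau must be in (0, 1], got {tau}")
    subs = schema.subscales
    names = [s.name for s in subs]
    corr = corr.reindex(index=names, columns=names)
    a = corr.to_numpy(dtype=float)
    if not np.allclose(a, a.T, equal_nan=True):
        raise ValueError("correlation matrix is not symmetric")
    g = nx.Graph()
    for s in subs:
        g.add_node(s.name, questionnaire=s.questionnaire, subject=s.subject)
    absr = np.abs(a)
    ii, jj = np.where(np.triu(absr >= tau, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(names[i], names[j], weight=float(a[i, j]))
    logger.info("subscale graph: %d nodes, %d edges at tau=%.2f",
                g.number_of_nodes(), g.number_of_edges(), tau)
    return SubscaleGraph(g, schema, tau)


def covered_nodes(graph: SubscaleGraph, from_tests, to_test: str) -> list[str]:
    """Nodes of ``to_test`` adjacent to at least one node of any questionnaire
    in ``from_tests``."""
    from_names = {graph.schema.questionnaire(t).name for t in from_tests}
    to_name = graph.schema.questionnaire(to_test).name
    if to_name in from_names:
        raise ValueError(f"{to_test!r} cannot be both source and target")
    source = {n for n, d in graph.g.nodes(data=True) if d["questionnaire"] in from_names}
    out = []
    for n in graph.nodes_of(to_name):
        if any(nb in source for nb in graph.g.neighbors(n)):
            out.append(n)
    return out


def coverage(graph: SubscaleGraph, from_tests, to_test: str) -> float:
    """Fraction of ``to_test``'s subscale nodes touched by ``from_tests``."""
    total = graph.nodes_of(to_test)
    if not total:
        raise ValueError(f"questionnaire {to_test!r} has no subscale nodes")
    return len(covered_nodes(graph, from_tests, to_test)) / len(total)


def cascade_order(graph: SubscaleGraph, start: str = "SF-36") -> list[str]:
    """Greedy questionnaire ordering by graph coverage.

    Starting from ``start``, repeatedly append the questionnaire j that
    maximises coverage(selected -> j); ties broken by (1) more covered nodes,
    (2) fewer own nodes, (3) name.  Isolated questionnaires (coverage 0)
    therefore go last.
    """
    schema = graph.schema
    start_name = schema.questionnaire(start).name
    selected = [start_name]
    remaining = [q.name for q in schema.questionnaires if q.name != start_name]
    while remaining:
        ranked = []
        for j in remaining:
            cov_nodes = covered_nodes(graph, selected, j)
            own = len(graph.nodes_of(j))
            ranked.append((len(cov_nodes) / own, len(cov_nodes), -own, j))
        ranked.sort(key=lambda t: (-t[0], -t[1], -t[2], t[3]))
        logger.info("cascade_order: selected=%s, candidates=%s", selected,
                    [(j, round(c, 3), k) for c, k, _, j in ranked])
        best = ranked[0][3]
        selected.append(best)
        remaining.remove(best)
    return selected
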
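"""Alignment and rewiring comparison of two co-association networks.

Edges are matched by unordered OTU pair (weights retained but ignored for
membership), giving common / unique-to-A / unique-to-B sets.  Per-node
rewiring follows the DyNet idea: a node's incident positive edges in each
network are written as |r|-weight vectors over the union neighbourhood,
normalized to unit length, and the rewiring score D_n is the mean squared
Euclidean distance of the two vectors to their centroid — 0 for identical
neighbourhoods, 0.5 for disjoint ones of equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "NetworkDiff",
    "diff_edges",
    "rewiring_scores",
    "classify_module_membership",
]


def _edge_key(u, v):
    return (u, v) if u <= v else (v, u)


@dataclass
class NetworkDiff:
    common: set
    unique_a: set
    unique_b: set
    weights_a: dict = field(default_factory=dict)
    weights_b: dict = field(default_factory=dict)

    def provenance(self) -> pd.DataFrame:
        rows = [(u, v, "common") for u, v in sorted(self.common)]
        rows += [(u, v, "unique_a") for u, v in sorted(self.unique_a)]
        rows += [(u, v, "unique_b") for u, v in sorted(self.unique_b)]
        df = pd.DataFrame(rows, columns=["source", "target", "provenance"])
        df["weight_a"] = [self.weights_a.get(_edge_key(u, v)) for u, v in zip(df.source, df.target)]
        df["weight_b"] = [self.weights_b.get(_edge_key(u, v)) for u, v in zip(df.source, df.target)]
        return df


def diff_edges(graph_a: nx.Graph, graph_b: nx.Graph) -> NetworkDiff:
    """Common and unique edge sets of two graphs over comparable node labels."""
    ea = {_edge_key(u, v) for u, v in graph_a.edges()}
    eb = {_edge_key(u, v) for u, v in graph_b.edges()}
    wa = {_edge_key(u, v): d.get("weight") for u, v, d in graph_a.edges(data=True)}
    wb = {_edge_key(u, v): d.get("weight") for u, v, d in graph_b.edges(data=True)}
    return NetworkDiff(common=ea & eb, unique_a=ea - eb, unique_b=eb - ea,
                       weights_a=wa, weights_b=wb)


def _incidence_vector(G: nx.Graph, node, neighbourhood: list) -> np.ndarray:
    v = np.zeros(len(neighbourhood))
    if node in G:
        for i, m in enumerate(neighbourhood):
            if G.has_edge(node, m):
                w = G[node][m].get("weight", 1.0)
                if w > 0:  # positive co-associations only
                    v[i] = abs(w)
    return v


def rewiring_scores(graph_a: nx.Graph, graph_b: nx.Graph) -> pd.DataFrame:
    """Per-node rewiring between two networks (positive edges, |r| weights).

    Columns: ``d_n`` (centroid score), ``d_n_degree_corrected`` (divided by
    the union-neighbourhood size) and ``flag``.  Nodes present in only one
    network get the maximal score (flagged ``only_in_one``); nodes isolated
    in both get 0 (flagged ``isolated``).
    """
    nodes = sorted(set(graph_a) | set(graph_b))
    if not set(graph_a) & set(graph_b):
        raise ValueError("graphs share no nodes")
    rows = []
    for n in nodes:
        nbhd = sorted(set(graph_a[n]) if n in graph_a else set())
        nbhd = sorted(set(nbhd) | (set(graph_b[n]) if n in graph_b else set()))
        va = _incidence_vector(graph_a, n, nbhd)
        vb = _incidence_vector(graph_b, n, nbhd)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        flag = ""
        if na == 0 and nb == 0:
            d = 0.0
            flag = "isolated"
        elif na == 0 or nb == 0:
            d = 0.5  # one unit vector vs the zero vector: maximal centroid score
            flag = "only_in_one" if (n not in graph_a or n not in graph_b) else "isolated_in_one"
        else:
            va, vb = va / na, vb / nb
            # mean squared distance of the two unit vectors to their centroid
            d = float(np.sum((va - vb) ** 2)) / 4.0
        size = max(len(nbhd), 1)
        rows.append({"node": n, "d_n": d, "d_n_degree_corrected": d / size, "flag": flag})
    return pd.DataFrame(rows).set_index("node")


def classify_module_membership(modules_a: list[set], modules_b: list[set]) -> pd.DataFrame:
    """Best-Jaccard matching of module partitions with shared/gained/lost OTUs.

    Modules are matched by maximum-weight bipartite assignment on pairwise
    Jaccard similarity; each matched pair reports shared, A-only and B-only
    members.  Unmatched modules appear with an empty counterpart.
    """
    if not modules_a and not modules_b:
        return pd.DataFrame(
            columns=["module_a", "module_b", "jaccard", "shared", "only_a", "only_b"]
        )
    J = np.zeros((max(len(modules_a), 1), max(len(modules_b), 1)))
    for i, ma in enumerate(modules_a):
        for j, mb in enumerate(modules_b):
            union = ma | mb
            J[i, j] = len(ma & mb) / len(union) if union else 0.0
    ri, ci = linear_sum_assignment(-J)
    rows = []
    matched_a, matched_b = set(), set()
    for i, j in zip(ri, ci):
        if i < len(modules_a) and j < len(modules_b):
            ma, mb = modules_a[i], modules_b[j]
            rows.append({
                "module_a": i, "module_b": j, "jaccard": float(J[i, j]),
                "shared": sorted(ma & mb), "only_a": sorted(ma - mb),
                "only_b": sorted(mb - ma),
            })
            matched_a.add(i); matched_b.add(j)
    for i, ma in enumerate(modules_a):
        if i not in matched_a:
            rows.append({"module_a": i, "module_b": None, "jaccard": 0.0,
                         "shared": [], "only_a": sorted(ma), "only_b": []})
    for j, mb in enumerate(modules_b):
        if j not in matched_b:
            rows.append({"module_a": None, "module_b": j, "jaccard": 0.0,
                         "shared": [], "only_a": [], "only_b": sorted(mb)})
    return pd.DataFrame(rows)
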
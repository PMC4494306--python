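"""Signed sociograms and welfare-relevant network metrics.

Graphs are plain :class:`networkx.Graph` objects. An undirected edge joins a
dyad when at least one *direction* of the directed SR matrix passed the
significance threshold; the edge weight is the larger of the two directed
residual weights and a ``direction`` attribute records whether the
relationship is one-way or two-way. Every individual is a node, including
isolates — group-level density and the farness convention depend on it.

Metrics follow the small-group sociogram tradition:

degree
    number of incident edges (unweighted, undirected).
betweenness
    unnormalized Freeman betweenness over unordered pairs, with fractional
    credit when several geodesics tie.
farness
    sum of geodesic distances to all other nodes. Disconnected graphs need
    a finite convention for unreachable pairs: each contributes a distance
    equal to the node count ``n`` by default (``n - 1`` behind a flag).
    Closeness is the reciprocal of farness.
cutpoints
    articulation nodes whose removal disconnects part of the network.
blocks
    biconnected components: the maximal subgroups with no internal cutpoint.

All metrics are computed on the unweighted undirected projection; SR weights
are carried on the edges for display and export only.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

import networkx as nx
import pandas as pd

from .association import SignedAssociation

__all__ = [
    "build_graph",
    "density",
    "degree",
    "betweenness",
    "farness",
    "closeness",
    "cutpoints",
    "blocks",
    "node_table",
    "export_graph",
    "import_graph",
    "graph_from_weight_matrix",
]

EXPORT_FORMATS = ("graphml", "edgelist", "dot")


def build_graph(assoc: SignedAssociation, sign: str = "positive", node_attrs: dict | None = None) -> nx.Graph:
    """Sociogram of one sign from a signed association structure.

    Parameters
    ----------
    assoc
        Output of :func:`proxnet.association.associate`.
    sign
        ``"positive"`` (attraction) or ``"negative"`` (avoidance); selects
        which sign-split weight matrix supplies the edges.
    node_attrs
        Optional per-node attribute mapping (e.g. class labels such as
        mare/foal, sex, age) copied onto the nodes.

    Each dyad with at least one significant direction becomes one undirected
    edge with ``weight`` = max of the two directed weights, ``direction``
    "one-way"/"two-way", and ``arrows`` naming the passing direction(s).
    """
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    w = assoc.positive if sign == "positive" else assoc.negative
    ids = assoc.individuals
    g = nx.Graph(sign=sign, threshold=float(assoc.threshold))
    g.add_nodes_from(ids)
    if node_attrs:
        nx.set_node_attributes(g, {k: dict(v) if isinstance(v, dict) else {"label": v} for k, v in node_attrs.items()})
    size = len(ids)
    for i in range(size):
        for j in range(i + 1, size):
            wij, wji = float(w[i, j]), float(w[j, i])
            if wij <= 0 and wji <= 0:
                continue
            arrows = []
            if wij > 0:
                arrows.append(f"{ids[i]}->{ids[j]}")
            if wji > 0:
                arrows.append(f"{ids[j]}->{ids[i]}")
            g.add_edge(
                ids[i],
                ids[j],
                weight=max(wij, wji),
                direction="two-way" if len(arrows) == 2 else "one-way",
                arrows=";".join(arrows),
            )
    return g


def density(g: nx.Graph) -> float:
    """Fraction of possible dyads joined by an edge, ``m / (n(n-1)/2)``."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density needs at least two nodes")
    return g.number_of_edges() / (n * (n - 1) / 2)


def degree(g: nx.Graph) -> dict:
    """Undirected incident-edge count per node."""
    return dict(g.degree())


def betweenness(g: nx.Graph) -> dict:
    """Unnormalized Freeman betweenness (unordered pairs, fractional ties)."""
    return nx.betweenness_centrality(g, normalized=False, weight=None)


def farness(g: nx.Graph, unreachable: str = "n") -> dict:
    """Sum of geodesic distances from each node to all others.

    ``unreachable`` sets the distance charged per unreachable pair:
    ``"n"`` (node count, the default) or ``"n-1"``.
    """
    n = g.number_of_nodes()
    if unreachable == "n":
        penalty = n
    elif unreachable == "n-1":
        penalty = n - 1
    else:
        raise ValueError("unreachable must be 'n' or 'n-1'")
    out = {}
    for v in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, v)
        out[v] = float(sum(lengths.values()) + (n - len(lengths)) * penalty)
    return out


def closeness(g: nx.Graph, unreachable: str = "n") -> dict:
    """Reciprocal farness (infinite for a single-node graph)."""
    return {v: (1.0 / f if f > 0 else math.inf) for v, f in farness(g, unreachable).items()}


def cutpoints(g: nx.Graph) -> dict:
    """0/1 per node: 1 iff removing the node disconnects its component."""
    arts = set(nx.articulation_points(g))
    return {v: int(v in arts) for v in g.nodes}


def blocks(g: nx.Graph) -> list:
    """Biconnected components as sorted node lists, deterministically ordered.

    Only components containing at least one edge form blocks; isolated nodes
    belong to none. Cutpoints belong to every block they delimit.
    """
    comps = [sorted(c) for c in nx.biconnected_components(g)]
    return sorted(comps, key=lambda c: (c[0], len(c), c))


def node_table(g: nx.Graph, unreachable: str = "n") -> pd.DataFrame:
    """Per-node metric table plus an ``Average`` row.

    Columns: degree, betweenness, farness, cutpoint, and one 0/1 membership
    column per block. The averages of the 0/1 columns are proportions.
    """
    ids = sorted(g.nodes)
    deg, btw, far, cut = degree(g), betweenness(g), farness(g, unreachable), cutpoints(g)
    blist = blocks(g)
    data = {
        "degree": [deg[v] for v in ids],
        "betweenness": [btw[v] for v in ids],
        "farness": [far[v] for v in ids],
        "cutpoint": [cut[v] for v in ids],
    }
    for k, blk in enumerate(blist, start=1):
        members = set(blk)
        data[f"block_{k}"] = [int(v in members) for v in ids]
    table = pd.DataFrame(data, index=pd.Index(ids, name="id"))
    table.loc["Average"] = table.mean(axis=0)
    return table


def graph_from_weight_matrix(weights: pd.DataFrame, sign: str = "positive", threshold: float = 0.0) -> nx.Graph:
    """Sociogram from an already sign-split non-negative weight matrix.

    Used by the CLI stages, which exchange labeled CSV matrices. Entries are
    directed weights; a dyad gets an edge when either direction is > 0.
    """
    ids = list(weights.index)
    if list(weights.columns) != ids:
        raise ValueError("weight matrix must have identical row and column labels")
    w = weights.to_numpy(dtype=float)
    g = nx.Graph(sign=sign, threshold=float(threshold))
    g.add_nodes_from(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            wij, wji = w[i, j], w[j, i]
            if wij <= 0 and wji <= 0:
                continue
            arrows = [f"{ids[i]}->{ids[j]}"] * int(wij > 0) + [f"{ids[j]}->{ids[i]}"] * int(wji > 0)
            g.add_edge(
                ids[i], ids[j],
                weight=max(wij, wji),
                direction="two-way" if len(arrows) == 2 else "one-way",
                arrows=";".join(arrows),
            )
    return g


def export_graph(g: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write a sociogram to GraphML, edge-list CSV, or DOT.

    GraphML and the edge-list CSV round-trip through :func:`import_graph`
    (the edge list carries isolated nodes as rows with an empty target).
    DOT is write-only, for rendering with graphviz.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight", "direction", "arrows"])
            for u, v, attrs in sorted(g.edges(data=True)):
                writer.writerow([u, v, repr(attrs.get("weight", 1.0)), attrs.get("direction", ""), attrs.get("arrows", "")])
            for v in sorted(g.nodes):
                if g.degree(v) == 0:
                    writer.writerow([v, "", "", "", ""])
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write(f'graph "{g.graph.get("sign", "network")}" {{\n')
            for v in sorted(g.nodes):
                fh.write(f'  "{v}";\n')
            for u, v, attrs in sorted(g.edges(data=True)):
                fh.write(f'  "{u}" -- "{v}" [weight={attrs.get("weight", 1.0):.4f}];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")


def import_graph(path, fmt: str = "graphml") -> nx.Graph:
    """Re-read a graph written by :func:`export_graph` (graphml/edgelist)."""
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "edgelist":
        g = nx.Graph()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                if row["target"] == "":
                    g.add_node(row["source"])
                else:
                    g.add_edge(
                        row["source"],
                        row["target"],
                        weight=float(row["weight"]),
                        direction=row["direction"],
                        arrows=row["arrows"],
                    )
        return g
    raise ValueError(f"unknown import format {fmt!r}")
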
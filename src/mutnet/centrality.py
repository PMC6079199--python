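"""Node centralities and shortest-path-length matrices for metabolite graphs.

Six per-metabolite network parameters are computed: betweenness centrality,
closeness centrality, degree centrality, in-degree, out-degree, and core
number.  Conventions (which matter on directed, not-strongly-connected
graphs):

* betweenness is normalised by (n-1)(n-2); source/target pairs with no
  connecting path are skipped;
* closeness uses **incoming** distances, C(v) = (n-1) / sum_u d(u, v), with
  the Wasserman–Faust reachable-set scaling (r-1)/(n-1) on graphs that are
  not strongly connected (r = number of nodes that can reach v, plus v);
  nodes nothing can reach get 0;
* degree centrality is (in-degree + out-degree)/(n-1), counting distinct
  neighbours per direction;
* core number is computed on the undirected projection with total degree
  (the k-core picture is an undirected one).

Unreachable ordered pairs in path-length matrices are NaN, a marker that
downstream analyses must exclude — never a sentinel integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .reaction_net import MetaboliteNetwork

__all__ = [
    "CentralityTable",
    "PathLengthMatrix",
    "betweenness",
    "closeness",
    "degree_centrality",
    "in_out_degrees",
    "core_number",
    "shortest_paths",
    "centrality_table",
]

#: column order of the per-metabolite parameter table
CENTRALITY_COLUMNS = (
    "betweenness",
    "closeness",
    "degree_centrality",
    "in_degree",
    "out_degree",
    "core_number",
)

CentralityTable = pd.DataFrame  # one row per metabolite, CENTRALITY_COLUMNS


@dataclass(frozen=True)
class PathLengthMatrix:
    """Square matrix of shortest path lengths (edge counts).

    ``values`` is indexed/columned by metabolite id; entry (v, u) is the
    length of the shortest path from v to u, NaN when u is unreachable
    from v.  ``directed`` records whether the entries are one-directional
    or the elementwise minimum of the two directions.
    """

    values: pd.DataFrame
    directed: bool

    def length(self, v: str, u: str) -> float:
        return float(self.values.at[v, u])


def betweenness(network: MetaboliteNetwork) -> dict[str, float]:
    """Normalised directed betweenness centrality, c_B(v) in [0, 1]."""
    g = network.graph
    if g.number_of_nodes() < 3:
        raise ValueError("betweenness normalisation requires at least 3 nodes")
    return dict(nx.betweenness_centrality(g, normalized=True))


def closeness(network: MetaboliteNetwork) -> dict[str, float]:
    """Closeness centrality on incoming distances with reachable-set scaling."""
    # networkx's closeness_centrality already uses incoming distance on
    # directed graphs; wf_improved applies the (r-1)/(n-1) scaling.
    return dict(nx.closeness_centrality(network.graph, wf_improved=True))


def in_out_degrees(network: MetaboliteNetwork) -> dict[str, tuple[int, int]]:
    """Per-node (in-degree, out-degree), counting distinct neighbours."""
    g = network.graph
    return {v: (g.in_degree(v), g.out_degree(v)) for v in g.nodes}


def degree_centrality(network: MetaboliteNetwork) -> dict[str, float]:
    """C_D(v) = (in-degree + out-degree) / (n - 1)."""
    g = network.graph
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("degree centrality requires at least 2 nodes")
    return {v: (g.in_degree(v) + g.out_degree(v)) / (n - 1) for v in g.nodes}


def core_number(network: MetaboliteNetwork) -> dict[str, int]:
    """Core number k(v) by degree peeling on the undirected projection."""
    und = nx.Graph(network.graph.to_undirected())
    und.remove_edges_from(nx.selfloop_edges(und))
    return dict(nx.core_number(und))


def shortest_paths(network: MetaboliteNetwork, mode: str = "directed") -> PathLengthMatrix:
    """All-pairs shortest path lengths as a PathLengthMatrix.

    ``mode="directed"`` gives BFS edge counts along edge direction;
    ``mode="undirected"`` gives the elementwise minimum of d(i, j) and
    d(j, i) (the shorter of the two directed paths), still NaN when neither
    direction has a path.
    """
    if mode not in {"directed", "undirected"}:
        raise ValueError(f"mode must be 'directed' or 'undirected', got {mode!r}")
    g = network.graph
    nodes = sorted(g.nodes)
    mat = pd.DataFrame(np.nan, index=nodes, columns=nodes)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            mat.at[src, dst] = float(d)
    if mode == "undirected":
        vals = mat.to_numpy()
        mat = pd.DataFrame(
            np.fmin(vals, vals.T), index=nodes, columns=nodes  # fmin ignores one-sided NaN
        )
    return PathLengthMatrix(values=mat, directed=(mode == "directed"))


def centrality_table(network: MetaboliteNetwork) -> CentralityTable:
    """The six per-metabolite network parameters as one DataFrame."""
    bet = betweenness(network)
    clo = closeness(network)
    deg = degree_centrality(network)
    io = in_out_degrees(network)
    core = core_number(network)
    nodes = sorted(network.graph.nodes)
    return pd.DataFrame(
        {
            "betweenness": [bet[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
            "degree_centrality": [deg[v] for v in nodes],
            "in_degree": [io[v][0] for v in nodes],
            "out_degree": [io[v][1] for v in nodes],
            "core_number": [core[v] for v in nodes],
        },
        index=pd.Index(nodes, name="metabolite"),
    )
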
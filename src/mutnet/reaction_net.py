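"""Directed metabolite networks from reaction tables.

A metabolic network is represented as a simple directed graph whose nodes are
metabolites and whose edges connect the substrates of a reaction to its
products.  Ubiquitous cofactor-like "currency" metabolites (ATP, water, NADH,
...) are removed before edges are created, because including them collapses
almost every shortest path to one or two steps and destroys the biological
meaning of path length.  Reversible reactions contribute a pair of
antiparallel edges; stoichiometry is ignored (topology only).

The module also supports growing the subnetwork reachable from a set of seed
metabolites, extracting the great strong component, diffing two networks by
their supporting reaction sets, and Pajek / edge-list TSV interchange.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionRecord",
    "MetaboliteNetwork",
    "NetworkDiff",
    "GreatStrongComponent",
    "ReactionParseError",
    "parse_reactions",
    "default_currency_metabolites",
    "build_network",
    "expand_from_seeds",
    "great_strong_component",
    "diff_networks",
    "write_pajek",
    "read_pajek",
    "write_edgelist_tsv",
    "read_edgelist_tsv",
]

#: accepted spellings of the reversibility flag, by dialect
_REVERSIBLE_TOKENS = {"1", "r", "true", "rev"}
_IRREVERSIBLE_TOKENS = {"0", "i", "false", "irrev"}


class ReactionParseError(ValueError):
    """Raised for malformed reaction-table rows; message names the line."""


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: substrates -> products, optionally reversible."""

    reaction_id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    reversible: bool

    def __post_init__(self) -> None:
        if not self.substrates:
            raise ValueError(f"reaction {self.reaction_id}: empty substrate list")
        if not self.products:
            raise ValueError(f"reaction {self.reaction_id}: empty product list")

    @property
    def self_loop_candidate(self) -> bool:
        """True when some metabolite appears on both sides of the reaction."""
        return bool(set(self.substrates) & set(self.products))


@dataclass
class MetaboliteNetwork:
    """Simple directed metabolite graph with reaction-id edge annotations.

    ``graph`` is an :class:`networkx.DiGraph`; each edge carries a
    ``reactions`` attribute, the sorted tuple of reaction ids supporting it.
    """

    graph: nx.DiGraph
    currency_removed: list[str] = field(default_factory=list)
    seed_metabolites: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def directed_edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    @property
    def reaction_ids(self) -> set[str]:
        """All reaction ids supporting at least one edge."""
        out: set[str] = set()
        for _, _, data in self.graph.edges(data=True):
            out.update(data.get("reactions", ()))
        return out

    def edge_reactions(self, u: str, v: str) -> tuple[str, ...]:
        return tuple(self.graph.edges[u, v]["reactions"])


@dataclass(frozen=True)
class NetworkDiff:
    """Symmetric difference of the reaction support of two networks."""

    reactions_only_in_a: tuple[str, ...]
    reactions_only_in_b: tuple[str, ...]
    congruence_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.congruence_fraction <= 1.0:
            raise ValueError("congruence_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GreatStrongComponent:
    """Largest strongly connected component, with focal-metabolite report."""

    members: frozenset[str]
    focal_inside: tuple[str, ...]
    focal_outside: tuple[str, ...]


def parse_reactions(path: str | Path) -> list[ReactionRecord]:
    """Parse a 4-column reaction TSV.

    Columns: reaction id, semicolon-delimited substrates, semicolon-delimited
    products, reversibility flag (``0``/``1`` or ``I``/``R`` dialects).
    Lines starting with ``#`` are comments; a header row whose flag column is
    not a recognised token is skipped.
    """
    path = Path(path)
    records: list[ReactionRecord] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ReactionParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            rid, subs_s, prods_s, flag_s = (f.strip() for f in fields)
            flag = flag_s.lower()
            if flag in _REVERSIBLE_TOKENS:
                reversible = True
            elif flag in _IRREVERSIBLE_TOKENS:
                reversible = False
            elif lineno == 1:
                continue  # header row
            else:
                raise ReactionParseError(
                    f"{path}:{lineno}: unrecognised reversibility flag {flag_s!r}"
                )
            subs = tuple(s.strip() for s in subs_s.split(";") if s.strip())
            prods = tuple(p.strip() for p in prods_s.split(";") if p.strip())
            if not subs or not prods:
                raise ReactionParseError(
                    f"{path}:{lineno}: reaction {rid!r} has an empty substrate or product list"
                )
            records.append(ReactionRecord(rid, subs, prods, reversible))
    return records


def default_currency_metabolites() -> list[str]:
    """Packaged default currency-metabolite list (user-overridable config).

    The canonical criteria for currency metabolites are compound-specific and
    the exact list depends on the reaction database in use, so this default is
    a reconstruction of the usual ubiquitous cofactors; pass an explicit list
    to :func:`build_network` to override it.
    """
    text = resources.files("mutnet.data").joinpath("currency_metabolites.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def build_network(
    reactions: Iterable[ReactionRecord],
    currency: Iterable[str],
) -> MetaboliteNetwork:
    """Build the directed metabolite graph after currency removal.

    Every (substrate, product) pair of a reaction with neither member in
    ``currency`` contributes an edge; reversible reactions also contribute
    the antiparallel edge.  Self-loops are dropped (centralities are defined
    on simple graphs).  Parallel support from multiple reactions is merged
    into one edge annotated with all supporting reaction ids.  A reaction
    whose substrates or products are all currency metabolites contributes no
    edges and is logged.
    """
    currency_set = set(currency)
    g = nx.DiGraph()
    for rec in reactions:
        subs = [s for s in rec.substrates if s not in currency_set]
        prods = [p for p in rec.products if p not in currency_set]
        if not subs or not prods:
            logger.info(
                "reaction %s contributes no edges (all substrates or products are currency)",
                rec.reaction_id,
            )
            continue
        g.add_nodes_from(subs)
        g.add_nodes_from(prods)
        pairs = [(s, p) for s in subs for p in prods]
        if rec.reversible:
            pairs += [(p, s) for s in subs for p in prods]
        for u, v in pairs:
            if u == v:
                continue  # self-loop dropped
            if g.has_edge(u, v):
                existing = set(g.edges[u, v]["reactions"])
                existing.add(rec.reaction_id)
                g.edges[u, v]["reactions"] = tuple(sorted(existing))
            else:
                g.add_edge(u, v, reactions=(rec.reaction_id,))
    return MetaboliteNetwork(graph=g, currency_removed=sorted(currency_set))


def expand_from_seeds(
    network: MetaboliteNetwork, seeds: Sequence[str]
) -> MetaboliteNetwork:
    """Grow the subnetwork reachable from seed metabolites.

    Breadth-first closure following edges in both directions from every seed
    (reactions are followed forward to products and backward to substrates
    until they loop back or reach an endpoint).  Connected subnetworks that
    contain no seed are excluded.
    """
    missing = [s for s in seeds if s not in network.graph]
    if missing:
        raise KeyError(f"seed metabolites absent from network: {sorted(missing)}")
    undirected = network.graph.to_undirected(as_view=True)
    keep: set[str] = set()
    for seed in seeds:
        if seed in keep:
            continue
        keep.update(nx.node_connected_component(undirected, seed))
    sub = network.graph.subgraph(keep).copy()
    return MetaboliteNetwork(
        graph=sub,
        currency_removed=list(network.currency_removed),
        seed_metabolites=list(dict.fromkeys(seeds)),
    )


def great_strong_component(
    network: MetaboliteNetwork, focal: Sequence[str] | None = None
) -> GreatStrongComponent:
    """Largest strongly connected component of the network.

    Ties on size are broken deterministically by the lexicographically
    smallest sorted member tuple.  ``focal`` metabolites are partitioned into
    those inside and outside the component (the outside ones are excluded
    from downstream path-length analyses).
    """
    if network.graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    comps = [frozenset(c) for c in nx.strongly_connected_components(network.graph)]
    best = min(comps, key=lambda c: (-len(c), tuple(sorted(c))))
    focal = list(focal or [])
    inside = tuple(m for m in focal if m in best)
    outside = tuple(m for m in focal if m not in best)
    return GreatStrongComponent(members=best, focal_inside=inside, focal_outside=outside)


def diff_networks(a: MetaboliteNetwork, b: MetaboliteNetwork) -> NetworkDiff:
    """Compare two networks by supporting reaction ids.

    ``congruence_fraction`` is |shared| / |union| (1.0 when both are empty).
    """
    ra, rb = a.reaction_ids, b.reaction_ids
    union = ra | rb
    shared = ra & rb
    frac = 1.0 if not union else len(shared) / len(union)
    return NetworkDiff(
        reactions_only_in_a=tuple(sorted(ra - rb)),
        reactions_only_in_b=tuple(sorted(rb - ra)),
        congruence_fraction=frac,
    )


# ---------------------------------------------------------------------------
# interchange formats
# ---------------------------------------------------------------------------

def write_pajek(network: MetaboliteNetwork, path: str | Path) -> None:
    """Write the graph in Pajek .net format (*Vertices / *Arcs, 1-based).

    Reaction annotations are serialised as a pipe-joined edge attribute so a
    write -> read round trip preserves them.
    """
    g = nx.DiGraph()
    g.add_nodes_from(network.graph.nodes)
    for u, v, data in network.graph.edges(data=True):
        g.add_edge(u, v, reactions="|".join(data.get("reactions", ())))
    nx.write_pajek(g, str(path))


def read_pajek(path: str | Path) -> MetaboliteNetwork:
    """Read a Pajek .net file as a MetaboliteNetwork.

    Pajek readers return multigraphs; parallel arcs are collapsed and any
    reaction annotations are merged, matching the simple-graph contract.
    """
    multi = nx.read_pajek(str(path))
    g = nx.DiGraph()
    g.add_nodes_from(multi.nodes)
    for u, v, data in multi.edges(data=True):
        rxns = set(data.get("reactions", "").split("|")) - {""}
        if g.has_edge(u, v):
            rxns |= set(g.edges[u, v]["reactions"])
        g.add_edge(u, v, reactions=tuple(sorted(rxns)))
    return MetaboliteNetwork(graph=g)


def write_edgelist_tsv(
    network: MetaboliteNetwork, path: str | Path, header_comment: str | None = None
) -> None:
    """Write edges as a 3-column TSV: substrate, product, reaction ids."""
    with Path(path).open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("substrate\tproduct\treactions\n")
        for u, v, data in sorted(network.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{';'.join(data.get('reactions', ()))}\n")


def read_edgelist_tsv(path: str | Path) -> MetaboliteNetwork:
    """Read a network written by :func:`write_edgelist_tsv`."""
    g = nx.DiGraph()
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("substrate\t") or not line.strip():
                continue
            u, v, rxns = line.rstrip("\n").split("\t")
            g.add_edge(u, v, reactions=tuple(r for r in rxns.split(";") if r))
    return MetaboliteNetwork(graph=g)
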
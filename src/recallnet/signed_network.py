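"""Signed undirected social networks and their triplet census.

A :class:`SignedNetwork` is an undirected graph over named characters in
which every tie carries a valence: liking (+1) or disliking (-1).  The
triplet census counts connected triplets (2-paths) and closed connected
triplets (2-paths embedded in triangles); the ratio of the two is the
triadic-closure probability used by the recall model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .exceptions import InvalidNetworkError, ParseError

__all__ = [
    "Edge",
    "SignedNetwork",
    "TripletCensus",
    "normalize_edge",
    "density",
    "triplet_census",
    "incident_edges",
    "components",
    "read_signed_edgelist",
    "write_signed_edgelist",
    "write_graphml",
]

Edge = tuple[str, str]

#: accepted spellings of the two valences in edge-list files
VALENCE_ALIASES: Mapping[str, int] = {
    "+1": 1,
    "1": 1,
    "like": 1,
    "-1": -1,
    "dislike": -1,
}


def normalize_edge(u: str, v: str) -> Edge:
    """Return the unordered pair (u, v) with the lexicographically smaller endpoint first."""
    return (u, v) if u <= v else (v, u)


@dataclass
class SignedNetwork:
    """Undirected signed graph over opaque string node identifiers.

    Invariants: no self-loops, no multi-edges, every edge has exactly one
    valence in {+1, -1}.  Edges are stored normalized (smaller endpoint
    first).  ``labels`` is optional per-edge metadata (e.g. kin terms) with
    no structural meaning.
    """

    nodes: set[str] = field(default_factory=set)
    valence: dict[Edge, int] = field(default_factory=dict)
    labels: dict[Edge, str] = field(default_factory=dict)

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Iterable[str] = (),
    ) -> "SignedNetwork":
        """Build a network from ``(u, v, valence[, label])`` tuples.

        ``nodes`` may add isolated nodes beyond the edge endpoints.
        """
        net = cls(nodes=set(nodes))
        for item in edges:
            u, v, val = item[0], item[1], item[2]
            label = item[3] if len(item) > 3 else None
            net.add_edge(u, v, val, label)
        return net

    def add_node(self, node: str) -> None:
        self.nodes.add(node)

    def add_edge(self, u: str, v: str, valence: int, label: str | None = None) -> None:
        if u == v:
            raise InvalidNetworkError(f"self-loop on node {u!r}")
        if valence not in (1, -1):
            raise InvalidNetworkError(f"valence must be +1 or -1, got {valence!r}")
        e = normalize_edge(u, v)
        if e in self.valence:
            raise InvalidNetworkError(f"duplicate edge {e}")
        self.nodes.update(e)
        self.valence[e] = valence
        if label is not None:
            self.labels[e] = label

    # -- queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.valence)

    @property
    def edges(self) -> set[Edge]:
        return set(self.valence)

    def has_edge(self, u: str, v: str) -> bool:
        return normalize_edge(u, v) in self.valence

    def valence_of(self, u: str, v: str) -> int:
        return self.valence[normalize_edge(u, v)]

    def degree(self, node: str) -> int:
        return sum(1 for e in self.valence if node in e)

    def neighbors(self, node: str) -> set[str]:
        out: set[str] = set()
        for a, b in self.valence:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out

    def node_pairs(self) -> Iterator[Edge]:
        """All unordered node pairs, adjacent or not, in lexicographic order."""
        ordered = sorted(self.nodes)
        for i, u in enumerate(ordered):
            for v in ordered[i + 1 :]:
                yield (u, v)

    def copy(self) -> "SignedNetwork":
        return SignedNetwork(set(self.nodes), dict(self.valence), dict(self.labels))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for (u, v), val in self.valence.items():
            g.add_edge(u, v, valence=val)
            if (u, v) in self.labels:
                g.edges[u, v]["label"] = self.labels[(u, v)]
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.valence == other.valence
            and self.labels == other.labels
        )


@dataclass(frozen=True)
class TripletCensus:
    """Counts of connected triplets (``t``) and closed connected triplets (``t_closed``).

    A connected triplet is a 2-path; a triangle contributes three connected
    triplets, all closed.  Hence ``t_closed`` equals three times the
    triangle count and ``t_closed / t`` is the global clustering
    coefficient.
    """

    t: int
    t_closed: int

    def __post_init__(self) -> None:
        if not (0 <= self.t_closed <= self.t):
            raise InvalidNetworkError(
                f"census must satisfy 0 <= t_closed <= t, got t={self.t}, t_closed={self.t_closed}"
            )

    @property
    def n_triangles(self) -> int:
        return self.t_closed // 3


def density(net: SignedNetwork) -> float:
    """Observed ties divided by mathematically possible ties, |E| / (n(n-1)/2)."""
    n = net.n_nodes
    if n < 2:
        raise InvalidNetworkError(f"density requires at least 2 nodes, got {n}")
    return net.n_edges / (n * (n - 1) / 2)


def triplet_census(net: SignedNetwork) -> TripletCensus:
    """Count connected and closed connected triplets.

    ``t`` is the number of 2-paths, sum over nodes of C(deg, 2);
    ``t_closed`` is 3 times the number of triangles.
    """
    g = net.to_networkx()
    t = sum(d * (d - 1) // 2 for _, d in g.degree())
    n_triangles = sum(nx.triangles(g).values()) // 3
    return TripletCensus(t=t, t_closed=3 * n_triangles)


def incident_edges(net: SignedNetwork, characters: Iterable[str]) -> set[Edge]:
    """Union of ties having at least one endpoint in ``characters``."""
    chars = set(characters)
    unknown = chars - net.nodes
    if unknown:
        raise KeyError(f"unknown character(s): {sorted(unknown)}")
    return {e for e in net.valence if e[0] in chars or e[1] in chars}


def components(net: SignedNetwork) -> list[set[str]]:
    """Connected components, sorted by decreasing size then smallest member."""
    comps = [set(c) for c in nx.connected_components(net.to_networkx())]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


# -- I/O ---------------------------------------------------------------

_HEADER = ["source", "target", "valence", "label"]


def read_signed_edgelist(path: str | Path) -> SignedNetwork:
    """Read a tab-separated signed edge list.

    Expected header: ``source  target  valence  label``; valence tokens may
    be ``+1``/``-1``/``1``/``like``/``dislike``; the label column may be
    empty.  A leading ``# nodes:`` comment, if present, lists isolated
    nodes.  Malformed lines raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    net = SignedNetwork()
    with path.open() as fh:
        lines = fh.read().splitlines()
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("# nodes:"):
            for node in line[len("# nodes:") :].strip().split():
                if node:
                    net.add_node(node)
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            if [f.strip() for f in fields[:3]] != _HEADER[:3]:
                raise ParseError(f"{path}:{lineno}: expected header {_HEADER!r}")
            header_seen = True
            continue
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected at least 3 tab-separated fields")
        u, v, tok = fields[0].strip(), fields[1].strip(), fields[2].strip()
        label = fields[3].strip() if len(fields) > 3 and fields[3].strip() else None
        if not u or not v:
            raise ParseError(f"{path}:{lineno}: empty node identifier")
        if tok not in VALENCE_ALIASES:
            raise ParseError(f"{path}:{lineno}: unknown valence token {tok!r}")
        if u == v:
            raise ParseError(f"{path}:{lineno}: self-loop on {u!r}")
        if net.has_edge(u, v):
            raise ParseError(f"{path}:{lineno}: duplicate edge ({u!r}, {v!r})")
        net.add_edge(u, v, VALENCE_ALIASES[tok], label)
    if not header_seen:
        raise ParseError(f"{path}:1: missing header line")
    return net


def write_signed_edgelist(net: SignedNetwork, path: str | Path) -> None:
    """Write a network as a TSV edge list; round-trips losslessly.

    Edges are emitted in lexicographic order with the smaller endpoint
    first, so output is canonical for equal networks.
    """
    path = Path(path)
    isolated = sorted(net.nodes - {n for e in net.valence for n in e})
    with path.open("w") as fh:
        if isolated:
            fh.write("# nodes: " + " ".join(isolated) + "\n")
        fh.write("\t".join(_HEADER) + "\n")
        for u, v in sorted(net.valence):
            val = net.valence[(u, v)]
            label = net.labels.get((u, v), "")
            fh.write(f"{u}\t{v}\t{val:+d}\t{label}\n")


def write_graphml(net: SignedNetwork, path: str | Path) -> None:
    """Export to GraphML with a ``valence`` edge attribute, for visualization."""
    nx.write_graphml(net.to_networkx(), str(path))
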
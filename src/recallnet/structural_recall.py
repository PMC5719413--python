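"""Stochastic model of recall of tie existence.

Recall starts from exact memory of every tie incident to a small set of
seed characters, then sweeps once over all still-unconnected character
pairs in random order.  A pair that would complete at least one triangle
in the recalled-so-far graph gains a tie with the triadic-closure
probability P_Triangle = T_Closed / T of the *target* network; any other
pair gains a tie with a small background probability derived from the
target's density.  The pass ends when every pair has been considered
once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import UndefinedProbabilityError
from .signed_network import Edge, SignedNetwork, incident_edges, triplet_census

__all__ = [
    "StructuralParams",
    "RecalledNetwork",
    "p_triangle",
    "p_background",
    "simulate_structural_recall",
]

logger = logging.getLogger(__name__)

_warned_clamps: set[tuple] = set()  # avoid repeating the clamp warning per replicate


@dataclass(frozen=True)
class StructuralParams:
    """Parameters of the structural recall pass.

    ``p_triangle`` / ``p_background`` override the formula-derived
    probabilities when given explicitly.  ``t_closed_override`` replaces
    the target's closed-triplet count in both formulas (robustness
    sweeps).  ``census_mode`` selects how T_Closed is counted: "triplets"
    (three closed triplets per triangle, so P_Triangle is the global
    clustering coefficient) or "triangles" (one per triangle).
    ``background_mode`` selects the background denominator: "literal"
    ((n(n-1)/2)*T) or "subtractive" (n(n-1)/2 - T).  ``closure_against``
    selects the graph against which triangle completion is judged:
    "recalled" (the evolving recalled graph) or "seed_only".
    """

    p_triangle: float | None = None
    p_background: float | None = None
    t_closed_override: int | None = None
    census_mode: str = "triplets"
    background_mode: str = "literal"
    closure_against: str = "recalled"

    def __post_init__(self) -> None:
        for name in ("p_triangle", "p_background"):
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.census_mode not in ("triplets", "triangles"):
            raise ValueError(f"unknown census_mode {self.census_mode!r}")
        if self.background_mode not in ("literal", "subtractive"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")
        if self.closure_against not in ("recalled", "seed_only"):
            raise ValueError(f"unknown closure_against {self.closure_against!r}")


@dataclass
class RecalledNetwork:
    """One replicate's recalled network.

    ``seed_edges`` are the initially (exactly) recalled ties and are always
    a subset of ``edges``.  ``addition_order`` lists the heuristically
    added ties in the order the pass added them, which is the state needed
    to replay valence assignment with matching closure context.  ``valence``
    is filled by the affective pass.
    """

    edges: set[Edge]
    seed_edges: set[Edge]
    valence: dict[Edge, int] | None = None
    addition_order: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seed_edges <= self.edges:
            raise ValueError("seed_edges must be a subset of edges")
        if self.valence is not None and set(self.valence) != self.edges:
            raise ValueError("valence map must cover exactly the recalled edges")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _effective_t_closed(target: SignedNetwork, params: StructuralParams) -> tuple[int, int]:
    """Return (T, T_Closed) under the configured census mode and override."""
    census = triplet_census(target)
    t = census.t
    t_closed = census.t_closed if params.census_mode == "triplets" else census.n_triangles
    if params.t_closed_override is not None:
        if not (0 <= params.t_closed_override <= t):
            raise ValueError(
                f"t_closed_override must lie in [0, {t}], got {params.t_closed_override}"
            )
        t_closed = params.t_closed_override
    return t, t_closed


def p_triangle(target: SignedNetwork, params: StructuralParams | None = None) -> float:
    """Triadic-closure probability P_Triangle = T_Closed / T of the target."""
    params = params or StructuralParams()
    if params.p_triangle is not None:
        return params.p_triangle
    t, t_closed = _effective_t_closed(target, params)
    if t == 0:
        raise UndefinedProbabilityError(
            "target has no connected triplets; P_Triangle is undefined"
        )
    return t_closed / t


def p_background(target: SignedNetwork, params: StructuralParams | None = None) -> float:
    """Background tie probability P = (|E| - T_Closed) / denominator.

    The denominator is (n(n-1)/2)*T in "literal" mode and n(n-1)/2 - T in
    "subtractive" mode.  The result is clamped into [0, 1] with a logged
    warning, since T_Closed can exceed |E|.
    """
    params = params or StructuralParams()
    if params.p_background is not None:
        return params.p_background
    t, t_closed = _effective_t_closed(target, params)
    n = target.n_nodes
    pairs = n * (n - 1) / 2
    if params.background_mode == "literal":
        denom = pairs * t
    else:
        denom = pairs - t
    if denom <= 0:
        raise UndefinedProbabilityError(
            f"background probability denominator is {denom}; undefined"
        )
    raw = (target.n_edges - t_closed) / denom
    clamped = min(1.0, max(0.0, raw))
    key = (target.n_edges, t_closed, params.background_mode, n)
    if clamped != raw and key not in _warned_clamps:
        _warned_clamps.add(key)
        logger.warning(
            "background probability %.4f clamped to %.1f "
            "(|E|=%d, T_Closed=%d, mode=%s)",
            raw,
            clamped,
            target.n_edges,
            t_closed,
            params.background_mode,
        )
    return clamped


def simulate_structural_recall(
    target: SignedNetwork,
    seed_characters: set[str],
    params: StructuralParams | None = None,
    rng: np.random.Generator | None = None,
) -> RecalledNetwork:
    """Run one replicate of the structural recall pass.

    All target ties incident to ``seed_characters`` are recalled exactly and
    flagged as seed edges.  Every node pair still unconnected after seeding
    is then visited exactly once in an order drawn from ``rng``; a visited
    pair completing at least one triangle in the current recalled graph
    gains a tie with probability P_Triangle, otherwise with the background
    probability.  One probability draw per pair.  Fully reproducible given
    ``rng``.
    """
    params = params or StructuralParams()
    rng = rng if rng is not None else np.random.default_rng()
    seeds = incident_edges(target, seed_characters)  # raises KeyError on unknowns

    pt = p_triangle(target, params) if params.p_triangle is None else params.p_triangle
    pb = (
        p_background(target, params)
        if params.p_background is None
        else params.p_background
    )

    adjacency: dict[str, set[str]] = {node: set() for node in target.nodes}
    for u, v in seeds:
        adjacency[u].add(v)
        adjacency[v].add(u)
    if params.closure_against == "seed_only":
        closure_adj = {node: set(nbrs) for node, nbrs in adjacency.items()}
    else:
        closure_adj = adjacency

    pending = [pair for pair in target.node_pairs() if pair not in seeds]
    order = rng.permutation(len(pending))

    edges = set(seeds)
    added: list[Edge] = []
    for idx in order:
        u, v = pending[idx]
        closes = bool(closure_adj[u] & closure_adj[v])
        p = pt if closes else pb
        if p > 0 and rng.random() < p:
            edges.add((u, v))
            added.append((u, v))
            adjacency[u].add(v)
            adjacency[v].add(u)
    return RecalledNetwork(edges=edges, seed_edges=set(seeds), addition_order=added)
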
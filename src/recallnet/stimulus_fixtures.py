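"""Stimulus-network fixtures: generation, validation and balance census.

The experimental stimulus is a signed network of 15 characters and 23
undirected ties split over two disconnected components, with 15 positive
and 8 negative ties.  Seven characters have printed degree constraints and
every multi-character seed-set tie count in the printed catalogue is
exactly additive, which forces each co-listed pair of characters to be
non-adjacent.  Together with the printed totals this pins the topology
down almost completely: the four character pairs that are never co-listed
(Lewis-Peter, Lewis-Catherine, Peter-Catherine, Alyssa-James) must all be
ties, exactly one tie joins two unconstrained characters
(Henry-Elizabeth), and the remaining structure is forced up to which
filler characters play which role.  The generator builds that topology
constructively, with the RNG controlling the genuinely free choices, and
the canonical fixture is frozen from a fixed seed as a packaged TSV.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import networkx as nx
import yaml

from .exceptions import GenerationError
from .signed_network import (
    Edge,
    SignedNetwork,
    components,
    normalize_edge,
    read_signed_edgelist,
)

__all__ = [
    "TABLE1_ROWS",
    "FixtureSpec",
    "BalanceReport",
    "default_fixture_spec",
    "generate_fixture",
    "validate_fixture",
    "balance_report",
    "canonical_fixture",
    "CANONICAL_SEED",
]

#: Printed catalogue of tested seed character sets with the total number of
#: ties incident to them, in table order.
TABLE1_ROWS: list[tuple[tuple[str, ...], int]] = [
    (("Isabelle",), 2),
    (("Victoria",), 3),
    (("James",), 3),
    (("Alyssa",), 4),
    (("Catherine",), 4),
    (("Lewis",), 5),
    (("Peter",), 5),
    (("James", "Isabelle"), 5),
    (("Alyssa", "Isabelle"), 6),
    (("James", "Victoria"), 6),
    (("Catherine", "Isabelle"), 6),
    (("Peter", "Isabelle"), 7),
    (("Alyssa", "Victoria"), 7),
    (("Catherine", "Victoria"), 7),
    (("Lewis", "Isabelle"), 7),
    (("Catherine", "James"), 7),
    (("Lewis", "Victoria"), 8),
    (("Peter", "Victoria"), 8),
    (("Lewis", "James"), 8),
    (("Peter", "James"), 8),
    (("Catherine", "Alyssa"), 8),
    (("Lewis", "Alyssa"), 9),
    (("Peter", "Alyssa"), 9),
    (("Catherine", "James", "Isabelle"), 9),
    (("Peter", "James", "Isabelle"), 10),
    (("Catherine", "James", "Victoria"), 10),
    (("Lewis", "James", "Isabelle"), 10),
    (("Catherine", "Alyssa", "Isabelle"), 10),
    (("Peter", "Alyssa", "Isabelle"), 11),
    (("Lewis", "James", "Victoria"), 11),
    (("Lewis", "Alyssa", "Isabelle"), 11),
    (("Peter", "James", "Victoria"), 11),
    (("Catherine", "Alyssa", "Victoria"), 11),
    (("Lewis", "Alyssa", "Victoria"), 12),
    (("Peter", "Alyssa", "Victoria"), 12),
]

#: Characters whose degree is fixed by the seed-set catalogue.
CONSTRAINED_DEGREES: dict[str, int] = {
    "Isabelle": 2,
    "Victoria": 3,
    "James": 3,
    "Alyssa": 4,
    "Catherine": 4,
    "Lewis": 5,
    "Peter": 5,
}

#: Named characters outside the catalogue.
OTHER_NAMED: tuple[str, ...] = ("Henry", "Elizabeth", "Anne")

#: Fixed filler names for the five characters the vignette leaves unnamed,
#: kept deterministic so fixtures are reproducible.
FILLER_NAMES: tuple[str, ...] = ("Grace", "Margaret", "Oliver", "Samuel", "Thomas")

#: Ties among named characters that the vignette examples make recoverable:
#: Henry, Elizabeth and James are mutually tied (a closed connected triplet).
REQUIRED_EDGES: frozenset[Edge] = frozenset(
    {
        normalize_edge("Henry", "Elizabeth"),
        normalize_edge("Henry", "James"),
        normalize_edge("Elizabeth", "James"),
    }
)

#: Seed used to freeze the packaged canonical fixture.
CANONICAL_SEED = 2017


def _colisted_pairs() -> frozenset[Edge]:
    """Character pairs co-listed in a catalogue row; additivity of the printed
    counts requires each such pair to be non-adjacent."""
    pairs: set[Edge] = set()
    for chars, _ in TABLE1_ROWS:
        for u, v in itertools.combinations(chars, 2):
            pairs.add(normalize_edge(u, v))
    return frozenset(pairs)


@dataclass
class FixtureSpec:
    """Constraint set a stimulus network must satisfy."""

    n_nodes: int = 15
    n_edges: int = 23
    n_positive: int = 15
    n_negative: int = 8
    n_components: int = 2
    component_sizes: tuple[int, int] = (8, 7)
    characters: tuple[str, ...] = ()
    degree_constraints: dict[str, int] = field(default_factory=dict)
    nonadjacency_constraints: frozenset[Edge] = frozenset()
    required_edges: frozenset[Edge] = frozenset()
    hub_assignment: dict[str, int] = field(default_factory=dict)
    condition: str = "balanced"
    rng_seed: int = CANONICAL_SEED

    def __post_init__(self) -> None:
        if self.n_positive + self.n_negative != self.n_edges:
            raise ValueError("n_positive + n_negative must equal n_edges")
        if sum(self.component_sizes) != self.n_nodes:
            raise ValueError("component_sizes must sum to n_nodes")
        if self.condition not in ("balanced", "imbalanced"):
            raise ValueError(f"unknown condition {self.condition!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["component_sizes"] = list(self.component_sizes)
        d["characters"] = list(self.characters)
        d["nonadjacency_constraints"] = sorted(list(e) for e in self.nonadjacency_constraints)
        d["required_edges"] = sorted(list(e) for e in self.required_edges)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["component_sizes"] = tuple(d["component_sizes"])
        d["characters"] = tuple(d["characters"])
        d["nonadjacency_constraints"] = frozenset(
            normalize_edge(*e) for e in d["nonadjacency_constraints"]
        )
        d["required_edges"] = frozenset(normalize_edge(*e) for e in d["required_edges"])
        return cls(**d)


@dataclass(frozen=True)
class BalanceReport:
    """Triangles classified by the sign product of their three valences."""

    n_triangles: int
    n_balanced_triangles: int
    n_imbalanced_triangles: int

    def __post_init__(self) -> None:
        if self.n_balanced_triangles + self.n_imbalanced_triangles != self.n_triangles:
            raise ValueError("balanced + imbalanced must equal total triangles")


def default_fixture_spec(condition: str) -> FixtureSpec:
    """The canonical stimulus constraints for one valence condition."""
    if condition not in ("balanced", "imbalanced"):
        raise ValueError(f"unknown condition {condition!r}")
    nonadj = set(_colisted_pairs())
    # Anne's recoverable non-ties: she is not tied to Elizabeth, and the
    # catalogue's additivity leaves no room for an Anne-Henry tie either.
    nonadj.add(normalize_edge("Anne", "Elizabeth"))
    nonadj.add(normalize_edge("Anne", "Henry"))
    characters = tuple(
        sorted(CONSTRAINED_DEGREES) + list(OTHER_NAMED) + list(FILLER_NAMES)
    )
    return FixtureSpec(
        characters=characters,
        degree_constraints=dict(CONSTRAINED_DEGREES),
        nonadjacency_constraints=frozenset(nonadj),
        required_edges=REQUIRED_EDGES,
        hub_assignment={"Lewis": 0, "Alyssa": 1},
        condition=condition,
        rng_seed=CANONICAL_SEED,
    )


# -- triangle helpers --------------------------------------------------


def _triangles(net: SignedNetwork) -> list[tuple[str, str, str]]:
    g = net.to_networkx()
    return [tuple(sorted(t)) for t in nx.enumerate_all_cliques(g) if len(t) == 3]


def _sign_product(net: SignedNetwork, tri: tuple[str, str, str]) -> int:
    a, b, c = tri
    return net.valence_of(a, b) * net.valence_of(b, c) * net.valence_of(a, c)


def balance_report(net: SignedNetwork) -> BalanceReport:
    """Classify every triangle as balanced (positive sign product) or not."""
    tris = _triangles(net)
    n_bal = sum(1 for t in tris if _sign_product(net, t) > 0)
    return BalanceReport(
        n_triangles=len(tris),
        n_balanced_triangles=n_bal,
        n_imbalanced_triangles=len(tris) - n_bal,
    )


# -- generation --------------------------------------------------------


def _canonical_topology(spec: FixtureSpec, rng: np.random.Generator) -> list[Edge]:
    """Build the (essentially forced) canonical 23-edge topology.

    Free choices, drawn from ``rng``: which three fillers join Lewis's
    component, which two of those tie to Isabelle, and which two to
    Catherine.
    """
    fillers = sorted(
        set(spec.characters) - set(spec.degree_constraints) - set(OTHER_NAMED)
    )
    if len(fillers) != 5:
        raise GenerationError(
            f"canonical build needs exactly 5 filler characters, got {len(fillers)}"
        )
    fa = sorted(rng.choice(fillers, size=spec.component_sizes[0] - 5, replace=False))
    fb = sorted(set(fillers) - set(fa))
    edges: list[Edge] = []
    # Lewis's component: the three mutually-tied high-degree characters plus
    # Victoria and Isabelle, whose ties may only go to fillers.
    for u, v in itertools.combinations(("Lewis", "Peter", "Catherine"), 2):
        edges.append(normalize_edge(u, v))
    for f in fa:
        edges.append(normalize_edge("Lewis", f))
        edges.append(normalize_edge("Peter", f))
        edges.append(normalize_edge("Victoria", f))
    for f in rng.choice(fa, size=2, replace=False):
        edges.append(normalize_edge("Isabelle", f))
    for f in rng.choice(fa, size=2, replace=False):
        edges.append(normalize_edge("Catherine", f))
    # Alyssa's component: the Henry-Elizabeth-James triangle, Alyssa tied to
    # James, Anne and the two remaining fillers.
    edges.extend(sorted(REQUIRED_EDGES))
    edges.append(normalize_edge("Alyssa", "James"))
    edges.append(normalize_edge("Alyssa", "Anne"))
    for f in fb:
        edges.append(normalize_edge("Alyssa", f))
    if len(edges) != spec.n_edges or len(set(edges)) != spec.n_edges:
        raise GenerationError(
            f"canonical topology produced {len(set(edges))} edges, expected {spec.n_edges}"
        )
    return edges


def _balanced_valences(
    edges: list[Edge],
    comps: list[set[str]],
    n_negative: int,
    rng: np.random.Generator,
) -> dict[Edge, int]:
    """Find a valence map with exactly ``n_negative`` negative ties such that
    every triangle has a positive sign product.

    Uses the structural-balance characterisation: 2-colour each component
    and make exactly the cross-colour ties negative; every triangle then
    has an even number of negative ties.  Enumerates colourings per
    component and picks a combination with the required negative total.
    """
    per_comp: list[dict[int, list[frozenset[str]]]] = []
    for comp in comps:
        nodes = sorted(comp)
        anchor, rest = nodes[0], nodes[1:]
        comp_edges = [e for e in edges if e[0] in comp]
        by_count: dict[int, list[frozenset[str]]] = {}
        for r in range(len(rest) + 1):
            for group in itertools.combinations(rest, r):
                side = frozenset(group)  # anchor stays on the other side
                cross = sum(1 for u, v in comp_edges if (u in side) != (v in side))
                by_count.setdefault(cross, []).append(side)
        per_comp.append(by_count)
    # all ways to split the negative budget across components
    choices: list[tuple[int, ...]] = []
    counts = [sorted(bc) for bc in per_comp]
    for combo in itertools.product(*counts):
        if sum(combo) == n_negative:
            choices.append(combo)
    if not choices:
        raise GenerationError(
            f"no balanced valence layout with exactly {n_negative} negative ties"
        )
    combo = choices[rng.integers(len(choices))]
    valence: dict[Edge, int] = {}
    for comp, by_count, cross_n in zip(comps, per_comp, combo):
        options = by_count[cross_n]
        side = options[rng.integers(len(options))]
        for e in edges:
            if e[0] in comp:
                u, v = e
                valence[e] = -1 if (u in side) != (v in side) else 1
    return valence


def _imbalance_valences(
    net_edges: list[Edge],
    valence: dict[Edge, int],
    tris: list[tuple[str, str, str]],
    rng: np.random.Generator,
    max_iter: int = 400,
) -> dict[Edge, int]:
    """Greedy sign swaps (one +1 with one -1, preserving counts) maximising
    the number of imbalanced triangles, starting from a balanced layout."""

    def n_imbalanced(val: dict[Edge, int]) -> int:
        count = 0
        for a, b, c in tris:
            p = (
                val[normalize_edge(a, b)]
                * val[normalize_edge(b, c)]
                * val[normalize_edge(a, c)]
            )
            if p < 0:
                count += 1
        return count

    current = dict(valence)
    score = n_imbalanced(current)
    for _ in range(max_iter):
        pos = [e for e in net_edges if current[e] > 0]
        neg = [e for e in net_edges if current[e] < 0]
        p = pos[rng.integers(len(pos))]
        q = neg[rng.integers(len(neg))]
        trial = dict(current)
        trial[p], trial[q] = -1, 1
        trial_score = n_imbalanced(trial)
        if trial_score > score:
            current, score = trial, trial_score
    if score < 1:
        raise GenerationError("could not produce any imbalanced triangle")
    return current


def generate_fixture(spec: FixtureSpec) -> SignedNetwork:
    """Generate a stimulus network satisfying every field of ``spec``.

    Deterministic given ``spec.rng_seed``.  Specs carrying the canonical
    degree-constraint catalogue are built constructively (the topology is
    forced up to a few choices); unconstrained specs fall back to bounded
    random retries.  Raises :class:`GenerationError` naming the violated
    constraint on failure.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if spec.degree_constraints:
        if spec.degree_constraints != CONSTRAINED_DEGREES:
            raise GenerationError(
                "degree-constrained generation supports the canonical catalogue only; "
                f"got {spec.degree_constraints}"
            )
        edges = _canonical_topology(spec, rng)
        net = _valence_and_build(edges, spec, rng)
        violations = validate_fixture(net, spec)
        if violations:
            raise GenerationError("; ".join(violations))
        return net
    return _random_fixture(spec, rng)


def _valence_and_build(
    edges: list[Edge], spec: FixtureSpec, rng: np.random.Generator
) -> SignedNetwork:
    structure = SignedNetwork.from_edges((u, v, 1) for u, v in edges)
    comps = components(structure)
    valence = _balanced_valences(edges, comps, spec.n_negative, rng)
    if spec.condition == "imbalanced":
        tris = _triangles(structure)
        valence = _imbalance_valences(edges, valence, tris, rng)
    return SignedNetwork.from_edges((u, v, valence[(u, v)]) for u, v in edges)


def _random_fixture(
    spec: FixtureSpec, rng: np.random.Generator, max_tries: int = 200
) -> SignedNetwork:
    """Bounded random search for specs without degree constraints."""
    names = list(spec.characters) or [f"C{i:02d}" for i in range(spec.n_nodes)]
    if len(names) != spec.n_nodes:
        raise GenerationError(
            f"{len(names)} characters listed but n_nodes={spec.n_nodes}"
        )
    last = "exhausted retries"
    for _ in range(max_tries):
        perm = list(rng.permutation(names))
        # honour hub component assignments
        ok = True
        bounds = np.cumsum((0,) + tuple(spec.component_sizes))
        for hub, comp_idx in spec.hub_assignment.items():
            pos = perm.index(hub)
            lo, hi = bounds[comp_idx], bounds[comp_idx + 1]
            if not (lo <= pos < hi):
                target = int(rng.integers(lo, hi))
                perm[pos], perm[target] = perm[target], perm[pos]
        groups = [
            perm[bounds[i] : bounds[i + 1]] for i in range(len(spec.component_sizes))
        ]
        # split the edge budget, each component at least a spanning tree
        sizes = [len(g) for g in groups]
        spare = spec.n_edges - sum(s - 1 for s in sizes)
        if spare < 0:
            raise GenerationError("n_edges too small for connected components")
        extra = rng.multinomial(spare, np.ones(len(sizes)) / len(sizes))
        edges: list[Edge] = []
        feasible = True
        for grp, n_extra, size in zip(groups, extra, sizes):
            m = size - 1 + int(n_extra)
            if m > size * (size - 1) // 2:
                feasible = False
                break
            g = nx.gnm_random_graph(size, m, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                feasible = False
                break
            mapping = dict(enumerate(grp))
            edges.extend(normalize_edge(mapping[u], mapping[v]) for u, v in g.edges)
        if not feasible:
            last = "component construction failed"
            continue
        if any(e in spec.nonadjacency_constraints for e in edges):
            last = "nonadjacency constraint violated"
            continue
        if not spec.required_edges <= set(edges):
            last = "required edge missing"
            continue
        try:
            net = _valence_and_build(edges, spec, rng)
        except GenerationError as exc:
            last = str(exc)
            continue
        violations = validate_fixture(net, spec)
        if not violations:
            return net
        last = violations[0]
    raise GenerationError(f"fixture generation failed after {max_tries} tries: {last}")


# -- validation --------------------------------------------------------


def validate_fixture(net: SignedNetwork, spec: FixtureSpec) -> list[str]:
    """Check every spec constraint; return a violation message per failure."""
    v: list[str] = []
    if net.n_nodes != spec.n_nodes:
        v.append(f"n_nodes: expected {spec.n_nodes}, observed {net.n_nodes}")
    if spec.characters and net.nodes != set(spec.characters):
        v.append("characters: node set differs from spec characters")
    if net.n_edges != spec.n_edges:
        v.append(f"n_edges: expected {spec.n_edges}, observed {net.n_edges}")
    n_pos = sum(1 for val in net.valence.values() if val > 0)
    n_neg = net.n_edges - n_pos
    if n_pos != spec.n_positive:
        v.append(f"n_positive: expected {spec.n_positive}, observed {n_pos}")
    if n_neg != spec.n_negative:
        v.append(f"n_negative: expected {spec.n_negative}, observed {n_neg}")
    comps = components(net)
    if len(comps) != spec.n_components:
        v.append(f"n_components: expected {spec.n_components}, observed {len(comps)}")
    observed_sizes = tuple(sorted((len(c) for c in comps), reverse=True))
    expected_sizes = tuple(sorted(spec.component_sizes, reverse=True))
    if observed_sizes != expected_sizes:
        v.append(
            f"component_sizes: expected {expected_sizes}, observed {observed_sizes}"
        )
    for hub, idx in spec.hub_assignment.items():
        if hub not in net.nodes:
            v.append(f"hub_assignment: {hub} not in network")
        elif idx >= len(comps) or hub not in comps[idx]:
            v.append(f"hub_assignment: {hub} not in component {idx}")
    for name, deg in spec.degree_constraints.items():
        if name not in net.nodes:
            v.append(f"degree: {name} not in network")
        elif net.degree(name) != deg:
            v.append(f"degree: {name} expected {deg}, observed {net.degree(name)}")
    for e in sorted(spec.nonadjacency_constraints):
        if e in net.valence:
            v.append(f"nonadjacency: forbidden tie {e} present")
    for e in sorted(spec.required_edges):
        if e not in net.valence:
            v.append(f"required_edge: tie {e} absent")
    report = balance_report(net)
    if spec.condition == "balanced" and report.n_imbalanced_triangles != 0:
        v.append(
            f"balance: condition=balanced but {report.n_imbalanced_triangles} "
            "imbalanced triangle(s)"
        )
    if spec.condition == "imbalanced" and report.n_imbalanced_triangles < 1:
        v.append("balance: condition=imbalanced but no imbalanced triangle")
    return v


# -- packaged canonical fixtures ---------------------------------------


def canonical_fixture(condition: str = "balanced") -> SignedNetwork:
    """Load the frozen canonical stimulus network for one condition."""
    if condition not in ("balanced", "imbalanced"):
        raise ValueError(f"unknown condition {condition!r}")
    ref = resources.files("recallnet").joinpath(f"data/canonical_{condition}.tsv")
    with resources.as_file(ref) as path:
        return read_signed_edgelist(path)
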
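"""Valence assignment for recalled ties.

Seed ties start from exact affect memory, except that a fraction ``x`` of
them is remembered with a randomly chosen valence (the redraw may
accidentally match the truth).  Each heuristically added tie takes its
valence from the triadic-balance rule: the sign of the (mean) sign
product of the open triplets it closes in the recalled graph at the
moment of addition, falling back to a positive valence — the positivity
bias — when it closes none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import RecallnetError
from .signed_network import Edge, SignedNetwork, normalize_edge
from .structural_recall import RecalledNetwork, StructuralParams, simulate_structural_recall

__all__ = [
    "AffectParams",
    "corrupt_seed_valences",
    "valence_for_new_tie",
    "simulate_affective_recall",
    "simulate_recall",
]


@dataclass(frozen=True)
class AffectParams:
    """Parameters of the affective pass.

    ``x`` is the fraction of seed ties whose valence is redrawn uniformly
    at random (default 0.30, the model's operating point).
    ``zero_tiebreak`` resolves an exact-zero mean sign product over
    multiple closed triplets: "positive" (default, consistent with the
    positivity bias), "negative", or "random".
    """

    x: float = 0.30
    zero_tiebreak: str = "positive"

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0):
            raise ValueError(f"x must lie in [0, 1], got {self.x}")
        if self.zero_tiebreak not in ("positive", "negative", "random"):
            raise ValueError(f"unknown zero_tiebreak {self.zero_tiebreak!r}")


def corrupt_seed_valences(
    true_valences: dict[Edge, int],
    params: AffectParams | None = None,
    rng: np.random.Generator | None = None,
) -> dict[Edge, int]:
    """Redraw the valences of round(x * |seed|) seed ties uniformly at random.

    The corrupted subset is chosen uniformly without replacement; each
    chosen tie's valence is drawn uniformly from {+1, -1} independent of
    the truth, so about half the redraws remain accidentally correct.
    Rounding is half-up.  Reproducible given ``rng``.
    """
    params = params or AffectParams()
    rng = rng if rng is not None else np.random.default_rng()
    edges = sorted(true_valences)
    k = math.floor(params.x * len(edges) + 0.5)
    out = dict(true_valences)
    if k > 0:
        chosen = rng.choice(len(edges), size=k, replace=False)
        for i in chosen:
            out[edges[i]] = 1 if rng.random() < 0.5 else -1
    return out


def valence_for_new_tie(
    valences: dict[Edge, int],
    pair: Edge,
    params: AffectParams | None = None,
    rng: np.random.Generator | None = None,
) -> int:
    """Valence for a tie being added to a recalled graph with ``valences``.

    If the pair closes exactly one open triplet the valence is the sign
    product of the triplet's two existing valences; over several triplets
    it is the sign of the mean of the sign products, with an exact-zero
    mean resolved by the tiebreak; with no closed triplet it is +1.
    """
    params = params or AffectParams()
    u, v = pair
    adjacency: dict[str, set[str]] = {}
    for a, b in valences:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    common = adjacency.get(u, set()) & adjacency.get(v, set())
    if not common:
        return 1  # positivity bias
    products = [
        valences[normalize_edge(u, w)] * valences[normalize_edge(v, w)] for w in common
    ]
    mean = sum(products) / len(products)
    if mean > 0:
        return 1
    if mean < 0:
        return -1
    if params.zero_tiebreak == "positive":
        return 1
    if params.zero_tiebreak == "negative":
        return -1
    rng = rng if rng is not None else np.random.default_rng()
    return 1 if rng.random() < 0.5 else -1


def simulate_affective_recall(
    target: SignedNetwork,
    structural_result: RecalledNetwork,
    params: AffectParams | None = None,
    rng: np.random.Generator | None = None,
) -> RecalledNetwork:
    """Assign valences to a structural recall result.

    Seed ties get corrupted exact memory; heuristic ties are valenced by
    replaying the structural pass's addition order, so each tie sees the
    same recalled-graph state (seed ties plus earlier additions) as when
    its existence was decided.  The edge set is never altered.
    """
    params = params or AffectParams()
    rng = rng if rng is not None else np.random.default_rng()
    missing = [e for e in structural_result.seed_edges if e not in target.valence]
    if missing:
        raise RecallnetError(
            f"seed edges absent from target (not a result for this target): {missing[:3]}"
        )
    truth = {e: target.valence[e] for e in sorted(structural_result.seed_edges)}
    valences = corrupt_seed_valences(truth, params, rng)
    for pair in structural_result.addition_order:
        valences[pair] = valence_for_new_tie(valences, pair, params, rng)
    return RecalledNetwork(
        edges=set(structural_result.edges),
        seed_edges=set(structural_result.seed_edges),
        valence=valences,
        addition_order=list(structural_result.addition_order),
    )


def simulate_recall(
    target: SignedNetwork,
    seed_characters: set[str],
    structural_params: StructuralParams | None = None,
    affect_params: AffectParams | None = None,
    rng: np.random.Generator | None = None,
) -> RecalledNetwork:
    """One full replicate: structural pass followed by the affective pass."""
    rng = rng if rng is not None else np.random.default_rng()
    structural = simulate_structural_recall(target, seed_characters, structural_params, rng)
    return simulate_affective_recall(target, structural, affect_params, rng)
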
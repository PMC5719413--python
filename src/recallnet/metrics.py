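"""Scoring of recalled networks against their targets.

precision  = correctly recalled ties / recalled ties
coverage   = correctly recalled ties / ties in the target
quality    = correctly recalled valences / correctly recalled ties
delta      = |model mean - experimental mean| / experimental SD

Undefined ratios (empty recall, zero correct ties) are reported as
missing (None), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

from .signed_network import SignedNetwork
from .structural_recall import RecalledNetwork

__all__ = ["MetricSummary", "score_structure", "score_quality", "score", "delta"]


@dataclass(frozen=True)
class MetricSummary:
    """Per-replicate scores; fractions are None when undefined."""

    precision: float | None
    coverage: float
    quality: float | None
    n_recalled: int
    n_correct: int


def score_structure(target: SignedNetwork, recalled: RecalledNetwork) -> MetricSummary:
    """Precision and coverage of a recalled edge set (quality left missing)."""
    correct = recalled.edges & target.edges
    n_recalled = len(recalled.edges)
    precision = len(correct) / n_recalled if n_recalled > 0 else None
    coverage = len(correct) / target.n_edges
    return MetricSummary(
        precision=precision,
        coverage=coverage,
        quality=None,
        n_recalled=n_recalled,
        n_correct=len(correct),
    )


def score_quality(target: SignedNetwork, recalled: RecalledNetwork) -> float | None:
    """Correct valences over correctly recalled ties; spurious ties are ignored."""
    if recalled.valence is None:
        raise ValueError("recalled network carries no valences")
    correct = recalled.edges & target.edges
    if not correct:
        return None
    n_good = sum(1 for e in correct if recalled.valence[e] == target.valence[e])
    return n_good / len(correct)


def score(target: SignedNetwork, recalled: RecalledNetwork) -> MetricSummary:
    """Full per-replicate summary: precision, coverage and (if valenced) quality."""
    base = score_structure(target, recalled)
    quality = score_quality(target, recalled) if recalled.valence is not None else None
    return MetricSummary(
        precision=base.precision,
        coverage=base.coverage,
        quality=quality,
        n_recalled=base.n_recalled,
        n_correct=base.n_correct,
    )


def delta(model_mean: float, exp_mean: float, exp_sd: float) -> float:
    """Distance between model and experimental means in experimental SDs.

    delta < 1 means the model mean lies within one experimental standard
    deviation of the experimental mean.
    """
    if exp_sd <= 0:
        raise ValueError(f"exp_sd must be positive, got {exp_sd}")
    return abs(model_mean - exp_mean) / exp_sd
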
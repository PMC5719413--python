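"""Sweep designs: seed-set catalogue sweep, T_Closed robustness sweep, x sweep.

Each sweep runs many independent replicates of the structural + affective
recall simulation against a target fixture and aggregates precision,
coverage and quality into a table of means and standard deviations — the
machine-readable analogue of the bar-panel figures.  Replicate RNG
streams are derived counter-style from a master seed, keyed by
(sweep id, unit index, replicate index), so results are reproducible,
batches can be split or parallelized without changing any number, and
the two valence conditions share common random numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .affective_recall import AffectParams, simulate_recall
from .exceptions import RecallnetError
from .metrics import delta, score
from .signed_network import SignedNetwork, incident_edges, triplet_census
from .stimulus_fixtures import TABLE1_ROWS
from .structural_recall import StructuralParams

__all__ = [
    "table1_seed_sets",
    "SweepConfig",
    "SweepTable",
    "collect_replicates",
    "run_seed_sweep",
    "run_tclosed_sweep",
    "run_x_sweep",
    "report",
]

_SWEEP_IDS = {"seeds": 0, "tclosed": 1, "x": 2}
_METRICS = ("precision", "coverage", "quality")

#: default seed characters for the robustness sweeps: one high-degree
#: character in each component
DEFAULT_ROBUSTNESS_SEEDS: tuple[str, ...] = ("Lewis", "Alyssa")


def table1_seed_sets() -> list[tuple[tuple[str, ...], int]]:
    """The 35 catalogued seed character sets with their incident tie counts,
    in table order."""
    return [(tuple(chars), count) for chars, count in TABLE1_ROWS]


@dataclass
class SweepConfig:
    """Configuration shared by the three sweep designs.

    ``targets`` maps condition name (e.g. "balanced") to its target
    network.  ``seed_sets`` defaults to the full 35-row catalogue for the
    seed sweep; the robustness sweeps use its first entry (default
    Lewis + Alyssa).  Grids default to the robustness ranges: T_Closed
    from 0 to T in quarters, x from 0 to 1 in steps of 0.05.
    """

    targets: dict[str, SignedNetwork]
    seed_sets: list[tuple[tuple[str, ...], int | None]] = field(
        default_factory=lambda: [(chars, count) for chars, count in TABLE1_ROWS]
    )
    replicates: int = 1000
    replicate_offset: int = 0
    structural: StructuralParams = field(default_factory=StructuralParams)
    affect: AffectParams = field(default_factory=AffectParams)
    t_closed_grid: tuple[int, ...] | None = None
    x_grid: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(21))
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.seed_sets:
            raise ValueError("seed_sets must be a non-empty collection")
        if not self.targets:
            raise ValueError("at least one target condition is required")


@dataclass
class SweepTable:
    """Aggregated sweep results, one row per (unit, condition)."""

    frame: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SweepTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SweepTable":
        return cls(pd.read_csv(path))


def _replicate_rng(master_seed: int, sweep_id: int, unit_idx: int, rep: int) -> np.random.Generator:
    seq = np.random.SeedSequence(master_seed, spawn_key=(sweep_id, unit_idx, rep))
    return np.random.default_rng(seq)


def collect_replicates(
    target: SignedNetwork,
    seed_characters: Sequence[str],
    structural: StructuralParams,
    affect: AffectParams,
    master_seed: int,
    sweep_id: int,
    unit_idx: int,
    replicates: int,
    replicate_offset: int = 0,
) -> pd.DataFrame:
    """Per-replicate metric rows for one sweep unit.

    Replicate ``r`` always uses the stream keyed by (sweep_id, unit_idx,
    replicate_offset + r), so split batches pool to the identical result.
    """
    rows = []
    for r in range(replicates):
        rep = replicate_offset + r
        rng = _replicate_rng(master_seed, sweep_id, unit_idx, rep)
        recalled = simulate_recall(target, set(seed_characters), structural, affect, rng)
        m = score(target, recalled)
        rows.append(
            {
                "replicate": rep,
                "precision": np.nan if m.precision is None else m.precision,
                "coverage": m.coverage,
                "quality": np.nan if m.quality is None else m.quality,
                "n_recalled": m.n_recalled,
                "n_correct": m.n_correct,
            }
        )
    return pd.DataFrame(rows)


def _aggregate(per_rep: pd.DataFrame) -> dict[str, float]:
    out: dict[str, float] = {}
    for metric in _METRICS:
        values = per_rep[metric].dropna()
        out[f"{metric}_mean"] = float(values.mean()) if len(values) else np.nan
        out[f"{metric}_sd"] = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        out[f"{metric}_n"] = int(len(values))
    out["n_undefined"] = int(per_rep[list(_METRICS)].isna().any(axis=1).sum())
    return out


def _seed_label(chars: Sequence[str]) -> str:
    return " + ".join(chars)


def _check_seed_set(
    target: SignedNetwork, chars: Sequence[str], expected: int | None
) -> None:
    if expected is None:
        return
    observed = len(incident_edges(target, chars))
    if observed != expected:
        raise RecallnetError(
            f"fixture/seed mismatch: {_seed_label(chars)} has {observed} incident "
            f"ties, catalogue expects {expected}"
        )


def run_seed_sweep(config: SweepConfig) -> SweepTable:
    """Replicated recall for every seed set in the catalogue, per condition."""
    rows = []
    for condition, target in sorted(config.targets.items()):
        for unit_idx, (chars, expected) in enumerate(config.seed_sets):
            _check_seed_set(target, chars, expected)
            per_rep = collect_replicates(
                target,
                chars,
                config.structural,
                config.affect,
                config.master_seed,
                _SWEEP_IDS["seeds"],
                unit_idx,
                config.replicates,
                config.replicate_offset,
            )
            row = {
                "sweep": "seeds",
                "condition": condition,
                "seed_set": _seed_label(chars),
                "value": np.nan,
                "replicates": config.replicates,
            }
            row.update(_aggregate(per_rep))
            rows.append(row)
    return SweepTable(pd.DataFrame(rows))


def _robustness_seeds(config: SweepConfig) -> tuple[tuple[str, ...], int | None]:
    chars, expected = config.seed_sets[0]
    return tuple(chars), expected


def run_tclosed_sweep(config: SweepConfig) -> SweepTable:
    """Vary the closed-triplet count used by both model probabilities,
    holding the seed set fixed (default Lewis + Alyssa)."""
    rows = []
    for condition, target in sorted(config.targets.items()):
        census = triplet_census(target)
        grid = config.t_closed_grid
        if grid is None:
            grid = tuple(int(round(census.t * f)) for f in (0.0, 0.25, 0.5, 0.75, 1.0))
        chars, expected = _robustness_seeds(config)
        _check_seed_set(target, chars, expected)
        for unit_idx, override in enumerate(grid):
            if not (0 <= override <= census.t):
                raise ValueError(
                    f"t_closed override {override} outside [0, {census.t}]"
                )
            structural = replace(config.structural, t_closed_override=int(override))
            per_rep = collect_replicates(
                target,
                chars,
                structural,
                config.affect,
                config.master_seed,
                _SWEEP_IDS["tclosed"],
                unit_idx,
                config.replicates,
                config.replicate_offset,
            )
            row = {
                "sweep": "tclosed",
                "condition": condition,
                "seed_set": _seed_label(chars),
                "value": float(override),
                "replicates": config.replicates,
            }
            row.update(_aggregate(per_rep))
            rows.append(row)
    return SweepTable(pd.DataFrame(rows))


def run_x_sweep(config: SweepConfig) -> SweepTable:
    """Vary the seed-valence corruption fraction x, holding the seed set
    fixed; run on every configured condition."""
    rows = []
    for condition, target in sorted(config.targets.items()):
        chars, expected = _robustness_seeds(config)
        _check_seed_set(target, chars, expected)
        for unit_idx, x in enumerate(config.x_grid):
            affect = replace(config.affect, x=float(x))
            per_rep = collect_replicates(
                target,
                chars,
                config.structural,
                affect,
                config.master_seed,
                _SWEEP_IDS["x"],
                unit_idx,
                config.replicates,
                config.replicate_offset,
            )
            row = {
                "sweep": "x",
                "condition": condition,
                "seed_set": _seed_label(chars),
                "value": float(x),
                "replicates": config.replicates,
            }
            row.update(_aggregate(per_rep))
            rows.append(row)
    return SweepTable(pd.DataFrame(rows))


def report(
    table: SweepTable,
    out_dir: str | Path,
    experimental: Mapping[str, tuple[float, float]] | None = None,
    plot: bool = False,
) -> list[Path]:
    """Write a sweep table as CSV + JSON, with optional delta columns and plots.

    ``experimental`` maps a metric name to its experimentally derived
    (mean, SD); when supplied, a ``delta_<metric>`` column is added
    row-wise.  ``plot=True`` additionally writes one bar panel per metric
    (mean with SD error bars, one bar per table row).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = table.frame.copy()
    if experimental:
        for metric, (exp_mean, exp_sd) in experimental.items():
            if metric not in _METRICS:
                raise ValueError(f"unknown metric {metric!r}")
            frame[f"delta_{metric}"] = [
                delta(m, exp_mean, exp_sd) if np.isfinite(m) else np.nan
                for m in frame[f"{metric}_mean"]
            ]
    written: list[Path] = []
    csv_path = out_dir / "sweep.csv"
    frame.to_csv(csv_path, index=False)
    written.append(csv_path)
    json_path = out_dir / "sweep.json"
    json_path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
    written.append(json_path)
    if plot:
        written.extend(_plot_panels(frame, out_dir))
    return written


def _plot_panels(frame: pd.DataFrame, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    labels = [
        f"{row.seed_set}" + (f" ({row.value:g})" if np.isfinite(row.value) else "")
        for row in frame.itertuples()
    ]
    for metric in _METRICS:
        means = frame[f"{metric}_mean"]
        sds = frame[f"{metric}_sd"]
        if means.isna().all():
            continue
        fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(frame)), 4))
        ax.bar(range(len(frame)), means, yerr=sds, capsize=2)
        ax.set_xticks(range(len(frame)))
        ax.set_xticklabels(labels, rotation=90, fontsize=6)
        ax.set_ylabel(metric)
        ax.set_ylim(0, 1.05)
        fig.tight_layout()
        path = out_dir / f"sweep_{metric}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
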
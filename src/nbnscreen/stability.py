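"""Reporter-stability screen: EGFP:mCherry ratios and stability classes.

Each cell carrying a recombined variant construct co-translates an EGFP-tagged
variant protein and free mCherry, so the per-cell EGFP:mCherry ratio measures
variant protein abundance independent of expression noise.  Recombined cells
are gated as mCherry-positive / BFP-negative; the per-variant central ratio is
the geometric mean of per-cell ratios (flow intensities are approximately
log-normal), and the variant's fold change is its ratio relative to the
wild-type ratio measured in the same replicate.

Stability classes are bins of the reduction r = 1 - fold_change:

==============  ==================
complete loss   r >= 0.9
partial loss    0.5 <= r < 0.9
mild loss       0.2 <= r < 0.5
WT-like         r < 0.2
==============  ==================

Bins are left-closed on r, so a fold change of exactly 0.1 is a complete
loss (a 10-fold EGFP reduction counts as >= 90% reduction).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DomainError,
    GatingError,
    InsufficientEventsError,
)

__all__ = [
    "StabilityClass",
    "StabilitySummary",
    "GateConfig",
    "gate_recombined",
    "summarize_ratio",
    "classify_stability",
    "summarize_stability",
    "read_flow_csv",
]

EVENT_COLUMNS = ("egfp", "mcherry", "bfp")

#: Default minimum number of gated events required to summarize a ratio.
DEFAULT_MIN_EVENTS = 500


class StabilityClass(str, Enum):
    COMPLETE_LOSS = "complete_loss"
    PARTIAL_LOSS = "partial_loss"
    MILD_LOSS = "mild_loss"
    WT_LIKE = "wt_like"


@dataclass(frozen=True)
class GateConfig:
    """Recombination gate: keep events with mcherry > mcherry_min and bfp < bfp_max.

    Defaults are in the synthetic units of the flow generator, where
    non-recombined cells carry BFP around 1000 and background BFP/mCherry sit
    near 10; real instruments need instrument-specific values.
    """

    mcherry_min: float = 50.0
    bfp_max: float = 100.0
    min_events: int = DEFAULT_MIN_EVENTS

    def __post_init__(self) -> None:
        if self.mcherry_min < 0 or self.bfp_max < 0:
            raise ConfigError("gate thresholds must be >= 0")
        if self.min_events < 1:
            raise ConfigError("min_events must be >= 1")


@dataclass(frozen=True)
class StabilitySummary:
    """Per-variant stability result across replicates."""

    variant_id: str
    n_events_gated: int
    ratio: float  # geometric mean of per-replicate central ratios
    fold_change: float  # mean over replicates of ratio / WT ratio
    reduction: float  # 1 - fold_change
    stability_class: StabilityClass


def read_flow_csv(path: str | Path) -> pd.DataFrame:
    """Read a flow-event CSV with columns egfp, mcherry, bfp.

    Long-format files may add ``variant_id`` and ``replicate`` columns to hold
    several variant-replicate acquisitions in one file.
    """
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing flow column(s) {missing}")
    return df


def gate_recombined(
    events: pd.DataFrame, mcherry_min: float, bfp_max: float
) -> pd.DataFrame:
    """Gate to successfully recombined (mCherry-positive, BFP-negative) cells.

    Raises
    ------
    GatingError
        If no event passes the gate; the downstream ratio would be undefined.
    """
    if mcherry_min < 0 or bfp_max < 0:
        raise DomainError("gate thresholds must be >= 0")
    gated = events[(events["mcherry"] > mcherry_min) & (events["bfp"] < bfp_max)]
    if len(gated) == 0:
        raise GatingError("no recombined cells pass the mCherry+/BFP- gate")
    return gated


def summarize_ratio(
    gated: pd.DataFrame, min_events: int = DEFAULT_MIN_EVENTS
) -> float:
    """Geometric mean of per-cell EGFP:mCherry ratios over gated events.

    The geometric mean is scale-equivariant: multiplying every EGFP intensity
    by a detector gain c multiplies the ratio by c, so fold changes against a
    wild-type acquired at the same gain are gain-invariant.
    """
    if len(gated) < min_events:
        raise InsufficientEventsError(
            f"{len(gated)} gated events < required {min_events}"
        )
    mcherry = gated["mcherry"].to_numpy(dtype=float)
    egfp = gated["egfp"].to_numpy(dtype=float)
    if np.any(mcherry <= 0):
        raise DomainError("mcherry intensity must be > 0 after gating")
    # Geometric mean via mean of logs; egfp may be 0 (fully unstable protein),
    # driving the geometric mean to 0, which is the honest answer.
    if np.any(egfp < 0):
        raise DomainError("negative egfp intensity")
    if np.any(egfp == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(egfp) - np.log(mcherry))))


def classify_stability(fold_change: float) -> StabilityClass:
    """Bin a fold change (variant ratio / WT ratio) into a stability class."""
    if fold_change < 0 or not np.isfinite(fold_change):
        raise DomainError(f"fold change must be finite and >= 0, got {fold_change}")
    # thresholds on fold change directly (fc <= 0.1 <=> reduction >= 90%);
    # comparing 1 - fc would misplace exact boundaries through round-off
    if fold_change <= 0.1:
        return StabilityClass.COMPLETE_LOSS
    if fold_change <= 0.5:
        return StabilityClass.PARTIAL_LOSS
    if fold_change <= 0.8:
        return StabilityClass.MILD_LOSS
    return StabilityClass.WT_LIKE


def _per_replicate_ratios(
    events: pd.DataFrame, gate: GateConfig
) -> tuple[dict[object, float], int]:
    """Gate and summarize each replicate; returns ratios keyed by replicate."""
    ratios: dict[object, float] = {}
    n_gated = 0
    for rep, sub in events.groupby("replicate", sort=True):
        gated = gate_recombined(sub, gate.mcherry_min, gate.bfp_max)
        n_gated += len(gated)
        ratios[rep] = summarize_ratio(gated, gate.min_events)
    return ratios, n_gated


def summarize_stability(
    events: pd.DataFrame,
    wt_id: str = "WT",
    gate: GateConfig = GateConfig(),
) -> list[StabilitySummary]:
    """Full stability pipeline on a long-format event table.

    ``events`` must carry columns ``variant_id, replicate, egfp, mcherry,
    bfp`` and include wild-type acquisitions under ``wt_id``.  For each
    variant, the fold change is computed per replicate against that
    replicate's wild-type ratio (falling back to the geometric mean of all
    wild-type replicates when a replicate has no matching wild type) and then
    averaged arithmetically across replicates.
    """
    for col in ("variant_id", "replicate", *EVENT_COLUMNS):
        if col not in events.columns:
            raise ConfigError(f"event table missing column {col!r}")
    wt_events = events[events["variant_id"] == wt_id]
    if len(wt_events) == 0:
        raise ConfigError(f"no wild-type events under variant_id {wt_id!r}")
    wt_ratios, _ = _per_replicate_ratios(wt_events, gate)
    wt_pooled = float(np.exp(np.mean(np.log(list(wt_ratios.values())))))

    out: list[StabilitySummary] = []
    for vid, sub in events.groupby("variant_id", sort=True):
        if vid == wt_id:
            continue
        ratios, n_gated = _per_replicate_ratios(sub, gate)
        fcs = [
            ratio / wt_ratios.get(rep, wt_pooled) for rep, ratio in ratios.items()
        ]
        fc = float(np.mean(fcs))
        log_ratios = [r for r in ratios.values() if r > 0]
        central = (
            float(np.exp(np.mean(np.log(log_ratios)))) if len(log_ratios) == len(ratios) else 0.0
        )
        out.append(
            StabilitySummary(
                variant_id=str(vid),
                n_events_gated=n_gated,
                ratio=central,
                fold_change=fc,
                reduction=1.0 - fc,
                stability_class=classify_stability(fc),
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[StabilitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": s.variant_id,
                "n_events_gated": s.n_events_gated,
                "ratio": s.ratio,
                "fold_change": s.fold_change,
                "reduction": s.reduction,
                "stability_class": s.stability_class.value,
            }
            for s in summaries
        ]
    )
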
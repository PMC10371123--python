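"""Synthetic flow-cytometry, barcode-screen, and cohort generators.

Every pipeline stage can be exercised without the study's raw data: the
generators emit exactly the event tables, count matrices, and stratum counts
the quantification modules consume, with known ground truth and seeded,
bitwise-reproducible randomness.

Models
------
* **Flow events.**  mCherry intensity is log-normal; EGFP is
  ``stability_factor x mcherry x`` log-normal noise, so the per-cell
  EGFP:mCherry ratio is log-normal around the stability factor.  A fraction of
  events are non-recombined contaminants carrying high BFP and background
  EGFP, which the mCherry+/BFP- gate must remove.
* **Barcode screen.**  Cells grow exponentially at rate ``g = ln 2 /
  doubling_time``; drug exposure kills proportionally to a variant's
  sensitivity ``s_v``, so a barcode's expected abundance evolves as
  ``initial_skew x exp((g - s_v * kill_rate) * t)``.  Reads are multinomial at
  fixed depth per sample, making frequencies compositional: depleting variants
  raise the fold change of neutral ones above 1, exactly as in the assay.
* **Cohort.**  Control carriers are binomial at the stratum's carrier
  frequency ``p0_k``; case carriers are binomial at the logistic-transformed
  frequency ``p1_k = theta * p0_k / (1 - p0_k + theta * p0_k)``, so ``theta``
  is the per-stratum carrier odds ratio the burden module estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .burden import StratumCounts
from .errors import ConfigError
from .mmc import BarcodeCountTable

__all__ = [
    "FlowSimConfig",
    "ScreenSimConfig",
    "CohortSimConfig",
    "SimulationConfig",
    "generate_flow_events",
    "generate_stability_dataset",
    "generate_barcode_screen",
    "expected_fold_change",
    "sensitivities_for_targets",
    "generate_cohort",
]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class FlowSimConfig:
    """Flow-event generator parameters (intensities in arbitrary units).

    ``n_events`` defaults to 4000 cells per acquisition, the scale of one
    screened variant histogram.  ``wt_mcherry_log_mean``/``log_sd`` set the
    log-normal mCherry distribution; ``ratio_noise_log_sd`` is the per-cell
    log-normal spread of the EGFP:mCherry ratio around the stability factor;
    ``bfp_contamination_fraction`` of events are non-recombined (high BFP,
    background EGFP).
    """

    n_events: int = 4000
    wt_mcherry_log_mean: float = math.log(1000.0)
    log_sd: float = 0.5
    ratio_noise_log_sd: float = 0.25
    bfp_contamination_fraction: float = 0.10
    bfp_background_log_mean: float = math.log(10.0)
    bfp_contaminant_log_mean: float = math.log(1000.0)
    egfp_background_log_mean: float = math.log(5.0)

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ConfigError("n_events must be >= 1")
        if self.log_sd < 0 or self.ratio_noise_log_sd < 0:
            raise ConfigError("log-scale spreads must be >= 0")
        if not 0.0 <= self.bfp_contamination_fraction < 1.0:
            raise ConfigError("bfp_contamination_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ScreenSimConfig:
    """Barcode-screen generator parameters.

    ``read_depth`` reads per sample (default 1e6, sequencing-run scale);
    ``doubling_time_h`` untreated doubling time in hours; ``drug_kill_rate``
    per-hour death rate per unit sensitivity, defaulting to ``ln 2 / 24`` so a
    sensitivity of 1 exactly cancels growth; ``barcodes_per_variant`` fixed at
    3 by library design; ``skew_alpha`` is the symmetric-Dirichlet
    concentration of the initial barcode skew (larger = more even);
    ``n_replicates`` independent cultures.
    """

    read_depth: int = 1_000_000
    doubling_time_h: float = 24.0
    drug_kill_rate: float = math.log(2.0) / 24.0
    barcodes_per_variant: int = 3
    skew_alpha: float = 50.0
    n_replicates: int = 3
    days: tuple[int, ...] = (0, 10, 14)

    def __post_init__(self) -> None:
        if self.read_depth < 1:
            raise ConfigError("read_depth must be >= 1")
        if self.doubling_time_h <= 0 or self.drug_kill_rate < 0:
            raise ConfigError("kinetic rates must be positive")
        if self.skew_alpha <= 0:
            raise ConfigError("skew_alpha must be > 0")

    @property
    def growth_rate(self) -> float:
        return math.log(2.0) / self.doubling_time_h


@dataclass(frozen=True)
class CohortSimConfig:
    """Stratified cohort generator parameters.

    Defaults emulate a 4,183-case cohort against 118,479 summary-count
    controls split over three ancestry strata (55/25/20%), each with a 0.2%
    control carrier frequency, and a carrier odds ratio ``theta`` of 1.77.
    """

    strata: tuple[tuple[str, int, int, float], ...] = (
        ("EUR", 2301, 65163, 0.002),
        ("AMR", 1046, 29620, 0.002),
        ("AFR", 836, 23696, 0.002),
    )
    theta: float = 1.77

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ConfigError("theta must be > 0")
        for sid, n1, n0, p0 in self.strata:
            if n1 < 1 or n0 < 1:
                raise ConfigError(f"{sid}: stratum sizes must be >= 1")
            if not 0.0 < p0 < 1.0:
                raise ConfigError(f"{sid}: p0 must be in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of all generator parameters plus the master seed."""

    seed: int = 0
    flow: FlowSimConfig = field(default_factory=FlowSimConfig)
    screen: ScreenSimConfig = field(default_factory=ScreenSimConfig)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)


# ---------------------------------------------------------------------------
# Flow cytometry


def generate_flow_events(
    cfg: FlowSimConfig, stability_factor: float, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Simulate one variant-replicate acquisition.

    Returns a shuffled DataFrame with columns ``egfp, mcherry, bfp``.
    ``stability_factor`` is the true EGFP:mCherry ratio relative to wild type
    (1 = wild-type-like, 0 = no detectable protein).
    """
    if stability_factor < 0:
        raise ConfigError("stability_factor must be >= 0")
    rng = np.random.default_rng(seed)
    n = cfg.n_events
    mcherry = rng.lognormal(cfg.wt_mcherry_log_mean, cfg.log_sd, size=n)
    noise = rng.lognormal(0.0, cfg.ratio_noise_log_sd, size=n)
    egfp = stability_factor * mcherry * noise
    bfp = rng.lognormal(cfg.bfp_background_log_mean, cfg.log_sd, size=n)
    n_contam = int(round(cfg.bfp_contamination_fraction * n))
    if n_contam:
        idx = rng.choice(n, size=n_contam, replace=False)
        bfp[idx] = rng.lognormal(cfg.bfp_contaminant_log_mean, cfg.log_sd, n_contam)
        # non-recombined cells express no EGFP fusion, only autofluorescence
        egfp[idx] = rng.lognormal(cfg.egfp_background_log_mean, cfg.log_sd, n_contam)
    df = pd.DataFrame({"egfp": egfp, "mcherry": mcherry, "bfp": bfp})
    return df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)


def generate_stability_dataset(
    factors: Mapping[str, float],
    cfg: FlowSimConfig = FlowSimConfig(),
    n_replicates: int = 3,
    seed: int = 0,
    wt_id: str = "WT",
) -> pd.DataFrame:
    """Long-format multi-variant, multi-replicate flow dataset.

    ``factors`` maps variant_id -> true stability factor; a wild-type series
    (factor 1) is added under ``wt_id`` if absent.  Columns: ``variant_id,
    replicate, egfp, mcherry, bfp``.
    """
    rng = np.random.default_rng(seed)
    all_factors = dict(factors)
    all_factors.setdefault(wt_id, 1.0)
    frames = []
    for vid in sorted(all_factors):
        for rep in range(1, n_replicates + 1):
            ev = generate_flow_events(cfg, all_factors[vid], rng.integers(2**31))
            ev.insert(0, "replicate", rep)
            ev.insert(0, "variant_id", vid)
            frames.append(ev)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Barcode screen


def _abundance(
    cfg: ScreenSimConfig, weights: np.ndarray, s_per_barcode: np.ndarray, day: int
) -> np.ndarray:
    t = day * HOURS_PER_DAY
    rate = cfg.growth_rate - s_per_barcode * cfg.drug_kill_rate
    return weights * np.exp(rate * t)


def generate_barcode_screen(
    sensitivities: Mapping[str, float],
    cfg: ScreenSimConfig = ScreenSimConfig(),
    seed: int = 0,
) -> BarcodeCountTable:
    """Simulate a pooled depletion screen with known per-variant sensitivity.

    Each variant gets ``cfg.barcodes_per_variant`` barcodes with
    Dirichlet-skewed initial weights per replicate; counts per sample are one
    multinomial draw of ``read_depth`` reads from the renormalized expected
    abundances, so column totals equal the read depth exactly.
    """
    if not sensitivities:
        raise ConfigError("need at least one variant")
    if any(s < 0 for s in sensitivities.values()):
        raise ConfigError("sensitivities must be >= 0")
    rng = np.random.default_rng(seed)
    variants = sorted(sensitivities)
    barcodes = [
        f"{vid}_bc{i}" for vid in variants for i in range(1, cfg.barcodes_per_variant + 1)
    ]
    s_bc = np.repeat([sensitivities[v] for v in variants], cfg.barcodes_per_variant)
    bmap = pd.Series(
        np.repeat(variants, cfg.barcodes_per_variant), index=pd.Index(barcodes, name="barcode_id"),
        name="variant_id",
    )
    counts = {}
    sheet_rows = []
    for rep in range(1, cfg.n_replicates + 1):
        weights = rng.dirichlet(np.full(len(barcodes), cfg.skew_alpha))
        for day in cfg.days:
            sample_id = f"rep{rep}_day{day}"
            expected = _abundance(cfg, weights, s_bc, day)
            probs = expected / expected.sum()
            counts[sample_id] = rng.multinomial(cfg.read_depth, probs)
            sheet_rows.append(
                {"sample_id": sample_id, "replicate": rep, "timepoint": f"day{day}"}
            )
    counts_df = pd.DataFrame(counts, index=pd.Index(barcodes, name="barcode_id"))
    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    return BarcodeCountTable(counts=counts_df, sample_sheet=sheet, barcode_map=bmap)


def expected_fold_change(
    sensitivities: Mapping[str, float],
    cfg: ScreenSimConfig = ScreenSimConfig(),
    day: int = 14,
) -> dict[str, float]:
    """Noise-free expected per-variant frequency fold change at ``day``.

    Closed form under even initial weights: with ``e_v = s_v * kill_rate * t``
    the fold change is ``exp(-e_v)`` renormalized by the library mean, since
    the shared growth rate cancels in the composition.
    """
    t = day * HOURS_PER_DAY
    x = {v: math.exp(-s * cfg.drug_kill_rate * t) for v, s in sensitivities.items()}
    z = sum(x.values()) / len(x)
    return {v: xv / z for v, xv in x.items()}


def sensitivities_for_targets(
    targets: Mapping[str, float | None],
    cfg: ScreenSimConfig = ScreenSimConfig(),
    day: int = 14,
) -> dict[str, float]:
    """Invert :func:`expected_fold_change`: sensitivities hitting target
    fold changes.

    ``targets`` maps variant_id -> desired expected fold change at ``day``,
    with ``None`` marking neutral members (sensitivity 0) whose fold change
    is implied by compositional renormalization.  Requires at least one
    neutral member and feasible (<= the neutral fold change) targets.
    """
    neutral = [v for v, f in targets.items() if f is None]
    depleted = {v: f for v, f in targets.items() if f is not None}
    if not neutral:
        raise ConfigError("need at least one neutral member (target None)")
    n_total = len(targets)
    f_sum = sum(depleted.values())
    if f_sum >= n_total:
        raise ConfigError("targets infeasible: depleted fold changes too large")
    z = len(neutral) / (n_total - f_sum)
    t = day * HOURS_PER_DAY
    out: dict[str, float] = {v: 0.0 for v in neutral}
    for v, f in depleted.items():
        x = f * z
        if x > 1.0:
            raise ConfigError(
                f"{v}: target {f} exceeds the neutral fold change {1 / z:.3f}"
            )
        out[v] = -math.log(x) / (cfg.drug_kill_rate * t)
    return out


# ---------------------------------------------------------------------------
# Cohort


def generate_cohort(
    cfg: CohortSimConfig = CohortSimConfig(), seed: int = 0
) -> list[StratumCounts]:
    """Simulate stratified carrier counts with carrier odds ratio ``theta``."""
    rng = np.random.default_rng(seed)
    out = []
    for sid, n1, n0, p0 in cfg.strata:
        p1 = cfg.theta * p0 / (1.0 - p0 + cfg.theta * p0)
        out.append(
            StratumCounts(
                stratum_id=sid,
                case_carriers=int(rng.binomial(n1, p1)),
                case_total=n1,
                control_carriers=int(rng.binomial(n0, p0)),
                control_total=n0,
            )
        )
    return out
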
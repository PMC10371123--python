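"""Mitomycin-C barcode-depletion screen: frequencies, fold changes, classes.

Variants are pooled in one library, each represented by three barcodes, and
grown under 20 nM mitomycin C (MMC).  Cells expressing a damaging variant lose
DNA-damage signaling, die faster, and their barcodes deplete.  Barcode counts
per sample are normalized to the sample's total mapped reads (frequencies are
compositional: each sample column sums to 1, so depletion of one variant
raises the others); depletion is the fold change of barcode frequency at a
treated timepoint relative to the same replicate's day-0 sample.

A variant's score at a timepoint is the arithmetic mean of its nine
barcode-by-replicate fold changes (3 barcodes x 3 replicates).  Sensitivity
classes follow the day-14 mean fold change: high < 0.75, moderate in
[0.75, 1] (both ends closed), WT-like > 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, PairingError, SampleError

__all__ = [
    "MMCClass",
    "MMCSummary",
    "BarcodeCountTable",
    "normalize_counts",
    "variant_fold_change",
    "classify_mmc",
    "summarize_mmc",
]

TIMEPOINTS = ("day0", "day10", "day14")

#: Pseudocount added to every raw count before normalization so that a fully
#: depleted barcode still has a defined (small, positive) frequency.
DEFAULT_PSEUDOCOUNT = 0.5


class MMCClass(str, Enum):
    HIGH = "high"
    MODERATE = "moderate"
    WT_LIKE = "wt_like"


@dataclass(frozen=True)
class MMCSummary:
    """Per-variant MMC-sensitivity result (class assigned from day 14)."""

    variant_id: str
    fold_change_day10: float
    fold_change_day14: float
    mmc_class: MMCClass


@dataclass
class BarcodeCountTable:
    """Barcode x sample count matrix with its sample sheet and barcode map.

    ``counts``: non-negative integer DataFrame, rows indexed by barcode_id,
    columns by sample_id.  ``sample_sheet``: DataFrame indexed by sample_id
    with columns ``replicate`` (1..R) and ``timepoint`` (day0/day10/day14).
    ``barcode_map``: Series mapping barcode_id -> variant_id (three barcodes
    per variant by library design; the table only requires >= 1).
    """

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    barcode_map: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ConfigError("barcode counts must be >= 0")
        unmapped = self.counts.index.difference(self.barcode_map.index)
        if len(unmapped) > 0:
            raise ConfigError(f"barcodes without a variant mapping: {list(unmapped)[:5]}")
        for col in ("replicate", "timepoint"):
            if col not in self.sample_sheet.columns:
                raise ConfigError(f"sample sheet missing column {col!r}")
        missing = self.counts.columns.difference(self.sample_sheet.index)
        if len(missing) > 0:
            raise ConfigError(f"samples without sheet entries: {list(missing)[:5]}")
        bad_tp = set(self.sample_sheet["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ConfigError(f"unknown timepoint(s) {sorted(bad_tp)}")
        # every (replicate, timepoint) pair must be present exactly once
        sheet = self.sample_sheet.loc[self.counts.columns]
        pairs = sheet.groupby(["replicate", "timepoint"]).size()
        if (pairs > 1).any():
            dup = pairs[pairs > 1].index.tolist()
            raise ConfigError(f"duplicate (replicate, timepoint) samples: {dup}")

    @property
    def replicates(self) -> list:
        return sorted(self.sample_sheet["replicate"].unique())

    def sample_for(self, replicate, timepoint: str) -> str:
        sheet = self.sample_sheet
        hit = sheet[(sheet["replicate"] == replicate) & (sheet["timepoint"] == timepoint)]
        if len(hit) == 0:
            raise PairingError(
                f"no sample for replicate {replicate!r} at {timepoint}"
            )
        return str(hit.index[0])

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        sample_sheet_path: str | Path,
        barcode_map_path: str | Path,
    ) -> "BarcodeCountTable":
        """Load the three-file TSV dialect (counts, sample sheet, barcode map)."""
        counts = pd.read_csv(counts_path, sep="\t", index_col="barcode_id")
        sheet = pd.read_csv(sample_sheet_path, sep="\t", index_col="sample_id")
        bmap = pd.read_csv(barcode_map_path, sep="\t", index_col="barcode_id")[
            "variant_id"
        ]
        return cls(counts=counts, sample_sheet=sheet, barcode_map=bmap)

    def to_tsv(self, counts_path, sample_sheet_path, barcode_map_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="barcode_id")
        self.sample_sheet.to_csv(sample_sheet_path, sep="\t", index_label="sample_id")
        self.barcode_map.rename("variant_id").to_csv(
            barcode_map_path, sep="\t", index_label="barcode_id"
        )


def normalize_counts(
    table: BarcodeCountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Barcode frequencies per sample: (count + pseudocount) / column total.

    Each sample column of the result sums to 1.  Raises
    :class:`SampleError` naming the sample if any column has zero raw reads.
    """
    if pseudocount < 0:
        raise ConfigError("pseudocount must be >= 0")
    totals = table.counts.sum(axis=0)
    dead = totals[totals <= 0]
    if len(dead) > 0:
        raise SampleError(f"sample(s) with zero total reads: {list(dead.index)}")
    padded = table.counts.astype(float) + pseudocount
    return padded / padded.sum(axis=0)


def variant_fold_change(
    freqs: pd.DataFrame,
    table: BarcodeCountTable,
    timepoint: str,
    *,
    detail: bool = False,
):
    """Mean per-variant fold change of barcode frequency vs day 0.

    For each barcode and replicate, fc = freq(timepoint) / freq(day0); the
    per-variant value is the arithmetic mean over its barcodes x replicates
    (nine measurements in the standard 3x3 design).  With ``detail=True``
    also returns the per-(barcode, replicate) fold-change DataFrame.
    """
    if timepoint not in ("day10", "day14"):
        raise ConfigError(f"timepoint must be day10 or day14, got {timepoint!r}")
    cols = {}
    for rep in table.replicates:
        treated = table.sample_for(rep, timepoint)
        baseline = table.sample_for(rep, "day0")
        cols[rep] = freqs[treated] / freqs[baseline]
    fc = pd.DataFrame(cols)  # rows: barcode, cols: replicate
    long = (
        fc.stack().rename("fc").rename_axis(["barcode_id", "replicate"]).reset_index()
    )
    long["variant_id"] = long["barcode_id"].map(table.barcode_map)
    per_variant = long.groupby("variant_id")["fc"].mean()
    if detail:
        return per_variant, fc
    return per_variant


def classify_mmc(mean_fc: float) -> MMCClass:
    """Bin a day-14 mean fold change into an MMC-sensitivity class."""
    if mean_fc < 0 or not np.isfinite(mean_fc):
        raise DomainError(f"fold change must be finite and >= 0, got {mean_fc}")
    if mean_fc < 0.75:
        return MMCClass.HIGH
    if mean_fc <= 1.0:
        return MMCClass.MODERATE
    return MMCClass.WT_LIKE


def summarize_mmc(
    table: BarcodeCountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> tuple[list[MMCSummary], pd.DataFrame]:
    """Full depletion pipeline: normalize, fold changes, classes, barcode QC.

    Returns per-variant summaries (classified on day 14; day 10 reported for
    trend) and a QC table with each variant's min/max per-barcode-replicate
    fold change at day 14 — a large spread flags a discordant barcode.
    """
    freqs = normalize_counts(table, pseudocount)
    fc10 = variant_fold_change(freqs, table, "day10")
    fc14, detail14 = variant_fold_change(freqs, table, "day14", detail=True)
    summaries = [
        MMCSummary(
            variant_id=str(vid),
            fold_change_day10=float(fc10[vid]),
            fold_change_day14=float(fc14[vid]),
            mmc_class=classify_mmc(float(fc14[vid])),
        )
        for vid in fc14.index
    ]
    per_bc = (
        detail14.stack()
        .rename("fc")
        .rename_axis(["barcode_id", "replicate"])
        .reset_index()
    )
    per_bc["variant_id"] = per_bc["barcode_id"].map(table.barcode_map)
    qc = per_bc.groupby("variant_id")["fc"].agg(["min", "max", "count"])
    return summaries, qc


def summaries_to_frame(summaries: Sequence[MMCSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": s.variant_id,
                "fold_change_day10": s.fold_change_day10,
                "fold_change_day14": s.fold_change_day14,
                "mmc_class": s.mmc_class.value,
            }
            for s in summaries
        ]
    )
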
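"""Combined pathogenicity calls from the two functional screens.

The final call integrates the protein-stability class and the MMC-sensitivity
class through a deterministic decision table:

* **pathogenic** — complete loss of protein stability AND high MMC
  sensitivity (both assays show loss of function);
* **likely benign** — WT-like or mild loss of stability AND WT-like MMC
  tolerance (neither assay shows functional impact);
* **likely pathogenic** — every other combination (partial loss of stability
  and/or moderate MMC sensitivity, or discordant assays).

The table is total over all 4 x 3 class pairs and monotone: worsening either
assay class never improves the final call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError, VariantTableError
from .mmc import MMCClass
from .stability import StabilityClass

__all__ = [
    "FinalCall",
    "PathogenicityCall",
    "classify_variant",
    "classify_table",
    "correlate_screens",
]


from enum import Enum


class FinalCall(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    LIKELY_BENIGN = "likely_benign"


@dataclass(frozen=True)
class PathogenicityCall:
    variant_id: str
    stability_class: StabilityClass
    mmc_class: MMCClass
    final_call: FinalCall

    def is_plp(self) -> bool:
        """Pathogenic or likely pathogenic."""
        return self.final_call in (FinalCall.PATHOGENIC, FinalCall.LIKELY_PATHOGENIC)


def classify_variant(
    stability_class: StabilityClass, mmc_class: MMCClass
) -> FinalCall:
    """Apply the decision table to one (stability, MMC) class pair."""
    stability_class = StabilityClass(stability_class)
    mmc_class = MMCClass(mmc_class)
    if (
        stability_class is StabilityClass.COMPLETE_LOSS
        and mmc_class is MMCClass.HIGH
    ):
        return FinalCall.PATHOGENIC
    if (
        stability_class in (StabilityClass.WT_LIKE, StabilityClass.MILD_LOSS)
        and mmc_class is MMCClass.WT_LIKE
    ):
        return FinalCall.LIKELY_BENIGN
    return FinalCall.LIKELY_PATHOGENIC


def classify_table(
    rows: Iterable[tuple[str, StabilityClass | str, MMCClass | str]],
) -> tuple[list[PathogenicityCall], Counter]:
    """Classify many variants; returns calls and a tally by final call.

    ``rows`` are (variant_id, stability_class, mmc_class) triples; classes may
    be enum members or their string values.  Duplicate variant ids are
    rejected.
    """
    calls: list[PathogenicityCall] = []
    seen: set[str] = set()
    for vid, stab, mmc in rows:
        if vid in seen:
            raise VariantTableError(f"duplicate variant_id {vid!r}")
        seen.add(vid)
        stab = StabilityClass(stab)
        mmc = MMCClass(mmc)
        calls.append(
            PathogenicityCall(
                variant_id=vid,
                stability_class=stab,
                mmc_class=mmc,
                final_call=classify_variant(stab, mmc),
            )
        )
    tally = Counter(c.final_call for c in calls)
    for fc in FinalCall:  # report zeros explicitly
        tally.setdefault(fc, 0)
    return calls, tally


def correlate_screens(
    stability_fcs: Sequence[float], mmc_fcs: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between paired per-variant fold changes.

    Returns (r, two-sided p) from the t transform with n - 2 degrees of
    freedom.  Requires >= 3 paired finite values and non-zero variance in
    both vectors.
    """
    x = np.asarray(stability_fcs, dtype=float)
    y = np.asarray(mmc_fcs, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise UndefinedStatisticError("need >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise UndefinedStatisticError("non-finite values in screen fold changes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
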
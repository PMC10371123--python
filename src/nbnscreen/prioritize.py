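"""Rare-variant prioritization filters and carrier summaries.

The putative-damaging filter keeps variants that are rare (allele fraction
strictly below ``af_max``) and either protein-truncating (frameshift or stop
gain) or missense with CADD strictly above ``cadd_min``.  A separate REVEL
filter re-prioritizes missense variants with REVEL strictly above
``revel_min``; truncating variants have no REVEL score and never pass it.

Carrier counting sums per-variant case counts, which assumes carrier sets are
disjoint across variants (each study individual carries exactly one listed
variant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .catalog import DEFAULT_DOMAIN_MAP, DomainMap, VariantClass, VariantRecord
from .errors import ConfigError

__all__ = [
    "FilterConfig",
    "filter_damaging",
    "filter_revel",
    "count_carriers",
    "summarize_by_class_and_region",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the prioritization filters.

    ``af_max``: keep variants with population allele fraction < af_max
    (default 1e-3, combining-cohorts rarity rule; af = 0, i.e. absent from
    the reference population, passes).
    ``cadd_min``: missense variants must have CADD > cadd_min (default 20,
    roughly the top 1% predicted-damaging).
    ``revel_min``: the REVEL re-prioritization keeps missense variants with
    REVEL > revel_min (default 0.45).
    """

    af_max: float = 1e-3
    cadd_min: float = 20.0
    revel_min: float = 0.45

    def __post_init__(self) -> None:
        if not 0.0 < self.af_max <= 1.0:
            raise ConfigError(f"af_max must be in (0, 1], got {self.af_max}")
        if self.cadd_min < 0:
            raise ConfigError(f"cadd_min must be >= 0, got {self.cadd_min}")
        if not 0.0 <= self.revel_min <= 1.0:
            raise ConfigError(f"revel_min must be in [0, 1], got {self.revel_min}")


def filter_damaging(
    records: Iterable[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> list[VariantRecord]:
    """Keep rare truncating variants and rare high-CADD missense variants.

    Retains a record iff ``af < af_max`` and (the class is truncating, or the
    class is missense with ``cadd > cadd_min``).  Input order is preserved;
    the filter is idempotent.
    """
    return [
        r
        for r in records
        if r.af < cfg.af_max
        and (r.vclass.is_truncating() or (r.vclass is VariantClass.MISSENSE and r.cadd > cfg.cadd_min))
    ]


def filter_revel(
    records: Iterable[VariantRecord], cfg: FilterConfig = FilterConfig()
) -> list[VariantRecord]:
    """Keep missense variants whose REVEL score strictly exceeds the threshold."""
    return [
        r
        for r in records
        if r.vclass is VariantClass.MISSENSE
        and r.revel is not None
        and r.revel > cfg.revel_min
    ]


def count_carriers(records: Iterable[VariantRecord]) -> int:
    """Total case carriers, summing per-variant counts (disjoint carrier sets)."""
    return sum(r.case_count for r in records)


def summarize_by_class_and_region(
    records: Sequence[VariantRecord], domain_map: DomainMap = DEFAULT_DOMAIN_MAP
) -> dict:
    """Tally distinct variants, N-terminal membership, and carriers by class.

    Returns a JSON-ready dict with overall counts, per-class breakdowns, and
    the number of variants and carriers mapping to the N-terminal
    FHA/BRCT-repeat region of the domain map.
    """
    by_class: dict[str, dict[str, int]] = {
        c.value: {"n_variants": 0, "n_nterminal": 0, "n_carriers": 0}
        for c in VariantClass
    }
    n_nterm = carriers_nterm = 0
    for r in records:
        in_nterm = r.residue <= domain_map.nterminal_boundary
        slot = by_class[r.vclass.value]
        slot["n_variants"] += 1
        slot["n_carriers"] += r.case_count
        if in_nterm:
            slot["n_nterminal"] += 1
            n_nterm += 1
            carriers_nterm += r.case_count
    truncating = (
        by_class[VariantClass.FRAMESHIFT.value],
        by_class[VariantClass.STOP_GAIN.value],
    )
    return {
        "n_variants": len(records),
        "n_carriers": count_carriers(records),
        "n_truncating_variants": sum(s["n_variants"] for s in truncating),
        "n_truncating_carriers": sum(s["n_carriers"] for s in truncating),
        "n_nterminal_variants": n_nterm,
        "n_nterminal_carriers": carriers_nterm,
        "by_class": by_class,
    }
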
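"""Exact stratified carrier-burden testing against summary-count controls.

Cases and controls are compared as carrier / non-carrier 2x2 tables within
ancestry strata.  Conditioning on all margins of each stratum's table, the
case-carrier count a_k follows a (central, under the null of no association)
hypergeometric law, and the summed count S = sum_k a_k has as its null
distribution the convolution of the K hypergeometric mass functions.  The
exact Cochran–Mantel–Haenszel (CMH) p-value is two-sided by the
minimum-likelihood convention: the total probability of all values s with
P(S = s) <= P(S = S_obs), with a 1 + 1e-7 relative guard against
floating-point ties.  For a single stratum this reduces exactly to Fisher's
exact test.

The accompanying effect estimate is the Mantel–Haenszel common odds ratio,
optionally with Haldane–Anscombe 0.5 corrections for strata with zero cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import DEFAULT_DOMAIN_MAP, DomainMap, VariantRecord
from .errors import ConfigError, UndefinedStatisticError

__all__ = [
    "StratumCounts",
    "BurdenResult",
    "null_pmf_of_sum",
    "cmh_exact_test",
    "mantel_haenszel_or",
    "region_burden",
    "nterminal_predicate",
    "whole_gene",
    "load_strata_tsv",
]


@dataclass(frozen=True)
class StratumCounts:
    """Carrier counts for one ancestry stratum.

    ``case_carriers``/``case_total`` count individuals carrying at least one
    qualifying variant among cases; ``control_carriers``/``control_total``
    are the summary counts of the reference cohort, treated as carrier counts
    of distinct individuals.
    """

    stratum_id: str
    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int

    def __post_init__(self) -> None:
        if self.case_total < 1 or self.control_total < 1:
            raise ConfigError(f"{self.stratum_id}: totals must be >= 1")
        if not 0 <= self.case_carriers <= self.case_total:
            raise ConfigError(
                f"{self.stratum_id}: case_carriers outside [0, case_total]"
            )
        if not 0 <= self.control_carriers <= self.control_total:
            raise ConfigError(
                f"{self.stratum_id}: control_carriers outside [0, control_total]"
            )

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(a, b, c, d): case carriers, control carriers, case non-carriers,
        control non-carriers."""
        a, b = self.case_carriers, self.control_carriers
        return a, b, self.case_total - a, self.control_total - b


@dataclass(frozen=True)
class BurdenResult:
    """Outcome of an exact stratified carrier-burden test."""

    p_two_sided: float
    or_mh: float
    per_stratum_or: tuple[float, ...]
    s_obs: int
    method: str = "exact-cmh"

    def to_dict(self) -> dict:
        return {
            "p": self.p_two_sided,
            "or_mh": self.or_mh,
            "S_obs": self.s_obs,
            "per_stratum": list(self.per_stratum_or),
            "method": self.method,
        }


def _stratum_pmf(s: StratumCounts) -> tuple[int, np.ndarray]:
    """Support offset and pmf of a_k conditional on all margins.

    Returns ``(lo, pmf)`` where the support is ``lo .. lo + len(pmf) - 1``.
    A stratum whose margins force a_k contributes a point mass.
    """
    m1 = s.case_carriers + s.control_carriers  # carrier margin
    n = s.case_total + s.control_total
    lo = max(0, m1 - s.control_total)
    hi = min(m1, s.case_total)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, m1, s.case_total)
    # guard against tiny negative round-off and renormalize
    pmf = np.clip(pmf, 0.0, None)
    pmf /= pmf.sum()
    return lo, pmf


def null_pmf_of_sum(strata: Sequence[StratumCounts]) -> tuple[int, np.ndarray]:
    """Null pmf of S = sum of case-carrier counts, all margins fixed.

    Convolution of the per-stratum hypergeometric pmfs; returns the support
    offset (value of S at index 0) and the probability array, which sums to 1.
    """
    if len(strata) == 0:
        raise ConfigError("need at least one stratum")
    lo_total = 0
    pmf = np.array([1.0])
    for s in strata:
        lo, p = _stratum_pmf(s)
        lo_total += lo
        pmf = np.convolve(pmf, p)
    return lo_total, pmf


def cmh_exact_test(strata: Sequence[StratumCounts]) -> BurdenResult:
    """Exact conditional CMH test of carrier burden across strata.

    Two-sided p-value by the minimum-likelihood convention on the convolved
    hypergeometric null of S = sum of case-carrier counts; for K = 1 this is
    Fisher's exact test.  The Mantel–Haenszel odds ratio (Haldane-corrected
    when a zero cell would otherwise make it undefined) accompanies the
    p-value, together with per-stratum odds ratios.
    """
    lo, pmf = null_pmf_of_sum(strata)
    s_obs = sum(s.case_carriers for s in strata)
    idx = s_obs - lo
    if not 0 <= idx < len(pmf):  # impossible under the fixed margins
        raise ConfigError("observed count outside the conditional support")
    p_obs = pmf[idx]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    p = min(1.0, max(p, float(np.finfo(float).tiny)))
    try:
        or_mh = mantel_haenszel_or(strata)
    except UndefinedStatisticError:
        or_mh = mantel_haenszel_or(strata, haldane=True)
    return BurdenResult(
        p_two_sided=p,
        or_mh=or_mh,
        per_stratum_or=tuple(_per_stratum_or(s) for s in strata),
        s_obs=s_obs,
    )


def _per_stratum_or(s: StratumCounts) -> float:
    a, b, c, d = s.cells
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def mantel_haenszel_or(
    strata: Sequence[StratumCounts], haldane: bool = False
) -> float:
    """Mantel–Haenszel common odds ratio across strata.

    OR = sum_k(a_k d_k / N_k) / sum_k(b_k c_k / N_k).  With ``haldane``, 0.5
    is added to all four cells of any stratum containing a zero cell; without
    it, a zero denominator raises :class:`UndefinedStatisticError`.
    """
    if len(strata) == 0:
        raise ConfigError("need at least one stratum")
    num = den = 0.0
    for s in strata:
        a, b, c, d = (float(x) for x in s.cells)
        if haldane and 0.0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        n = a + b + c + d
        num += a * d / n
        den += b * c / n
    if den == 0.0:
        raise UndefinedStatisticError(
            "Mantel-Haenszel denominator is 0; use haldane=True"
        )
    return num / den


# ---------------------------------------------------------------------------
# Region-restricted burden


def nterminal_predicate(
    domain_map: DomainMap = DEFAULT_DOMAIN_MAP,
) -> Callable[[int], bool]:
    """Predicate selecting residues in the N-terminal FHA/BRCT-repeat region."""
    boundary = domain_map.nterminal_boundary
    return lambda residue: residue <= boundary


def whole_gene(residue: int) -> bool:
    """Predicate selecting every residue (gene-based test)."""
    return True


def region_burden(
    records: Iterable[VariantRecord],
    region: Callable[[int], bool],
    control_strata: Sequence[StratumCounts],
    case_carriers_by_stratum: dict[str, int] | None = None,
) -> BurdenResult:
    """Carrier-burden test restricted to variants in a protein region.

    Case carriers are recomputed as the sum of ``case_count`` over records
    whose residue satisfies ``region``; the caller supplies control strata
    already restricted to the same region.  With a single stratum the regional
    case-carrier total replaces that stratum's ``case_carriers``; with several
    strata a ``case_carriers_by_stratum`` mapping (stratum_id -> regional case
    carriers) is required, since variant records carry no ancestry.
    """
    total = sum(r.case_count for r in records if region(r.residue))
    if case_carriers_by_stratum is None:
        if len(control_strata) != 1:
            raise ConfigError(
                "multiple strata require case_carriers_by_stratum; per-record "
                "ancestry is not part of the variant table"
            )
        strata = [
            StratumCounts(
                stratum_id=control_strata[0].stratum_id,
                case_carriers=total,
                case_total=control_strata[0].case_total,
                control_carriers=control_strata[0].control_carriers,
                control_total=control_strata[0].control_total,
            )
        ]
    else:
        if sum(case_carriers_by_stratum.values()) != total:
            raise ConfigError(
                "case_carriers_by_stratum does not sum to the regional carrier total"
            )
        strata = [
            StratumCounts(
                stratum_id=s.stratum_id,
                case_carriers=case_carriers_by_stratum[s.stratum_id],
                case_total=s.case_total,
                control_carriers=s.control_carriers,
                control_total=s.control_total,
            )
            for s in control_strata
        ]
    return cmh_exact_test(strata)


def load_strata_tsv(path: str | Path) -> list[StratumCounts]:
    """Load a strata TSV: stratum_id, case_carriers, case_total,
    control_carriers, control_total."""
    df = pd.read_csv(path, sep="\t")
    required = [
        "stratum_id",
        "case_carriers",
        "case_total",
        "control_carriers",
        "control_total",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing column(s) {missing}")
    return [
        StratumCounts(
            stratum_id=str(row["stratum_id"]),
            case_carriers=int(row["case_carriers"]),
            case_total=int(row["case_total"]),
            control_carriers=int(row["control_carriers"]),
            control_total=int(row["control_total"]),
        )
        for _, row in df.iterrows()
    ]
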
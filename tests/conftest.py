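import itertools

import numpy as np
import pytest
from scipy import stats

from nbnscreen import datasets
from nbnscreen.burden import StratumCounts


@pytest.fixture(scope="session")
def ball_records():
    return datasets.load_ball_variants()


@pytest.fixture(scope="session")
def ball_classes():
    return datasets.load_ball_screen_classes()


def enumerate_cmh_pvalue(strata: list[StratumCounts]) -> float:
    """Brute-force oracle for the exact stratified test.

    Enumerates every joint configuration (a_1, ..., a_K) compatible with the
    fixed margins, accumulates the pmf of S = sum a_k as a product of
    hypergeometric point masses, and applies the minimum-likelihood two-sided
    rule. Independent of the convolution implementation under test.
    """
    supports, pmfs = [], []
    for s in strata:
        m1 = s.case_carriers + s.control_carriers
        lo = max(0, m1 - s.control_total)
        hi = min(m1, s.case_total)
        supp = list(range(lo, hi + 1))
        supports.append(supp)
        pmfs.append(
            {
                a: stats.hypergeom.pmf(
                    a, s.case_total + s.control_total, m1, s.case_total
                )
                for a in supp
            }
        )
    dist: dict[int, float] = {}
    for combo in itertools.product(*supports):
        prob = 1.0
        for a, pmf in zip(combo, pmfs):
            prob *= pmf[a]
        dist[sum(combo)] = dist.get(sum(combo), 0.0) + prob
    s_obs = sum(s.case_carriers for s in strata)
    p_obs = dist[s_obs]
    return sum(p for p in dist.values() if p <= p_obs * (1 + 1e-7))


def random_stratum(rng: np.random.Generator, max_total: int = 15) -> StratumCounts:
    n1 = int(rng.integers(1, max_total + 1))
    n0 = int(rng.integers(1, max_total + 1))
    return StratumCounts(
        stratum_id=f"s{rng.integers(1e6)}",
        case_carriers=int(rng.integers(0, n1 + 1)),
        case_total=n1,
        control_carriers=int(rng.integers(0, n0 + 1)),
        control_total=n0,
    )
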
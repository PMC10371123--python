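import numpy as np
import pytest
from scipy import stats

from conftest import enumerate_cmh_pvalue, random_stratum
from nbnscreen.burden import (
    StratumCounts,
    cmh_exact_test,
    load_strata_tsv,
    mantel_haenszel_or,
    nterminal_predicate,
    null_pmf_of_sum,
    region_burden,
    whole_gene,
)
from nbnscreen.errors import ConfigError, UndefinedStatisticError


class TestSingleStratumReducesToFisher:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_fisher_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            s = random_stratum(rng, max_total=30)
            a, b, c, d = s.cells
            _, p_fisher = stats.fisher_exact([[a, b], [c, d]])
            p_cmh = cmh_exact_test([s]).p_two_sided
            assert p_cmh == pytest.approx(p_fisher, rel=1e-9, abs=1e-12)

    def test_printed_cohort_marginals(self):
        """Whole-cohort 2x2: 50/4183 cases vs 208/118479 controls."""
        s = StratumCounts("all", 50, 4183, 208, 118_479)
        result = cmh_exact_test([s])
        _, p_fisher = stats.fisher_exact([[50, 208], [4133, 118_271]])
        assert result.p_two_sided == pytest.approx(p_fisher, rel=1e-9)
        assert result.s_obs == 50


class TestExactCMHAgainstEnumeration:
    def test_two_strata_worked_example(self):
        strata = [
            StratumCounts("s1", 3, 10, 1, 10),
            StratumCounts("s2", 2, 8, 2, 12),
        ]
        assert cmh_exact_test(strata).p_two_sided == pytest.approx(
            enumerate_cmh_pvalue(strata), rel=1e-9
        )

    @pytest.mark.parametrize("n_strata", [2, 3])
    def test_random_small_tables(self, n_strata):
        rng = np.random.default_rng(n_strata)
        for _ in range(25):
            strata = [random_stratum(rng) for _ in range(n_strata)]
            assert cmh_exact_test(strata).p_two_sided == pytest.approx(
                enumerate_cmh_pvalue(strata), rel=1e-9
            )

    def test_point_mass_null_gives_p_one(self):
        # margins force a = n1 in both strata (all controls are carriers too)
        strata = [
            StratumCounts("s1", 5, 5, 10, 10),
            StratumCounts("s2", 3, 3, 7, 7),
        ]
        assert cmh_exact_test(strata).p_two_sided == 1.0

    def test_empty_strata_rejected(self):
        with pytest.raises(ConfigError):
            cmh_exact_test([])


class TestNullPmfProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_pmf_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        strata = [random_stratum(rng, max_total=50) for _ in range(rng.integers(1, 6))]
        _, pmf = null_pmf_of_sum(strata)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_stratum_order_invariance(self):
        rng = np.random.default_rng(42)
        strata = [random_stratum(rng) for _ in range(4)]
        p_fwd = cmh_exact_test(strata).p_two_sided
        p_rev = cmh_exact_test(strata[::-1]).p_two_sided
        assert p_fwd == pytest.approx(p_rev, rel=1e-12)


class TestMantelHaenszelOR:
    def test_crude_whole_cohort_odds_ratio(self):
        s = StratumCounts("all", 50, 4183, 208, 118_479)
        assert mantel_haenszel_or([s]) == pytest.approx(
            (50 * 118_271) / (208 * 4133), rel=1e-12
        )

    def test_equal_proportions_give_unity(self):
        strata = [
            StratumCounts("s1", 10, 100, 100, 1000),
            StratumCounts("s2", 5, 50, 20, 200),
        ]
        assert mantel_haenszel_or(strata) == pytest.approx(1.0)

    def test_haldane_correction_yields_finite_positive(self):
        s = StratumCounts("s", 0, 10, 5, 100)
        with pytest.raises(UndefinedStatisticError):
            mantel_haenszel_or([StratumCounts("s", 0, 10, 0, 100)])
        assert mantel_haenszel_or([s], haldane=False) == 0.0
        assert mantel_haenszel_or([StratumCounts("s", 0, 10, 0, 100)], haldane=True) > 0

    def test_matches_statsmodels_pooled_estimate(self):
        sm_contingency = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(7)
        strata = [random_stratum(rng, max_total=40) for _ in range(3)]
        # statsmodels wants [[a, b], [c, d]] per stratum, shape (2, 2, K)
        tables = np.stack(
            [np.array(s.cells).reshape(2, 2) for s in strata], axis=-1
        )
        st_table = sm_contingency.StratifiedTable(tables.astype(float))
        ours = mantel_haenszel_or(strata)
        assert ours == pytest.approx(st_table.oddsratio_pooled, rel=1e-9)


class TestRegionBurden:
    def test_nterminal_plp_case_carriers(self, ball_records, ball_classes):
        """13 of 14 P/LP variants lie in the N-terminal FHA/BRCT region."""
        plp_ids = set(
            ball_classes.loc[
                ball_classes["reported_call"] != "likely_benign", "variant_id"
            ]
        )
        plp_records = [r for r in ball_records if r.variant_id in plp_ids]
        assert len(plp_records) == 14
        pred = nterminal_predicate()
        in_region = [r for r in plp_records if pred(r.residue)]
        assert len(in_region) == 13
        control = StratumCounts("all", 0, 4183, 150, 118_479)
        result = region_burden(plp_records, pred, [control])
        assert result.s_obs == sum(r.case_count for r in in_region)

    def test_whole_gene_predicate_matches_gene_test(self, ball_records):
        control = StratumCounts("all", 0, 4183, 208, 118_479)
        gene = region_burden(ball_records, whole_gene, [control])
        direct = cmh_exact_test(
            [StratumCounts("all", 50, 4183, 208, 118_479)]
        )
        assert gene.p_two_sided == direct.p_two_sided
        assert gene.s_obs == 50

    def test_empty_region_still_defined(self, ball_records):
        control = StratumCounts("all", 0, 4183, 208, 118_479)
        result = region_burden(ball_records, lambda r: False, [control])
        assert result.s_obs == 0
        assert 0 < result.p_two_sided <= 1

    def test_multi_stratum_requires_explicit_mapping(self, ball_records):
        strata = [
            StratumCounts("s1", 0, 2000, 100, 60_000),
            StratumCounts("s2", 0, 2183, 108, 58_479),
        ]
        with pytest.raises(ConfigError, match="case_carriers_by_stratum"):
            region_burden(ball_records, whole_gene, strata)
        result = region_burden(
            ball_records, whole_gene, strata,
            case_carriers_by_stratum={"s1": 30, "s2": 20},
        )
        assert result.s_obs == 50


def test_stratum_counts_validation():
    with pytest.raises(ConfigError):
        StratumCounts("bad", 5, 4, 0, 10)  # a > n1
    with pytest.raises(ConfigError):
        StratumCounts("bad", 0, 0, 0, 10)  # n1 < 1


def test_load_strata_tsv(tmp_path):
    p = tmp_path / "strata.tsv"
    p.write_text(
        "stratum_id\tcase_carriers\tcase_total\tcontrol_carriers\tcontrol_total\n"
        "EUR\t30\t2301\t130\t65163\n"
        "AMR\t20\t1046\t78\t29620\n"
    )
    strata = load_strata_tsv(p)
    assert [s.stratum_id for s in strata] == ["EUR", "AMR"]
    assert strata[0].case_carriers == 30
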
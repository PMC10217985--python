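"""Unit and property tests for the cohort domain model and genotype QC."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from sscpgx.cohort_model import (
    Cohort,
    ConsistencyError,
    EmptyDataError,
    GenotypeCall,
    GenotypeCounts,
    MissingGenotypeError,
    OutcomeFlags,
    OUTCOME_NAMES,
    PanelError,
    Subject,
    THERAPY_GROUPS,
    ValidationError,
    Variant,
    allele_frequencies,
    collapse_perfect_ld,
    apply_ld_collapse,
    derive_outcomes,
    dominant_code,
    fisher_exact_2xk,
    group_difference_test,
    hwe_chi_square,
    summarize_cohort,
)

FLAGS = OutcomeFlags(False, False, False, False, False)


def make_cohort(counts_by_rsid, panel=None, therapy="MTX"):
    """Tiny cohort from {rsid: [minor_allele_count or None, ...]}."""
    n = len(next(iter(counts_by_rsid.values())))
    panel = panel or [
        Variant(rsid, "GENE", "G", "A") for rsid in counts_by_rsid
    ]
    subjects = [
        Subject(f"P{i}", "female", 50.0 + i, therapy, FLAGS) for i in range(n)
    ]
    calls = {
        (f"P{i}", rsid): GenotypeCall(f"P{i}", rsid, c)
        for rsid, col in counts_by_rsid.items()
        for i, c in enumerate(col)
    }
    return Cohort(subjects, calls, panel)


def cohort_from_counts(n_major_hom, n_het, n_minor_hom):
    col = [0] * n_major_hom + [1] * n_het + [2] * n_minor_hom
    return make_cohort({"rs1": col})


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "counts, expected_minor",
        [((25, 50, 25), 0.5), ((100, 0, 0), 0.0), ((30, 10, 10), 0.30)],
    )
    def test_examples(self, counts, expected_minor):
        cohort = cohort_from_counts(*counts)
        freq = allele_frequencies(cohort, "rs1")
        assert freq.minor_freq == pytest.approx(expected_minor)
        assert freq.major_freq + freq.minor_freq == 1.0

    def test_missing_calls_excluded(self):
        cohort = make_cohort({"rs1": [0, 1, None, None]})
        freq = allele_frequencies(cohort, "rs1")
        assert freq.counts.total == 2
        assert freq.minor_freq == pytest.approx(0.25)

    def test_unknown_rsid_is_panel_error(self):
        with pytest.raises(PanelError):
            allele_frequencies(cohort_from_counts(5, 0, 0), "rs_nope")

    def test_all_missing_is_empty_data_error(self):
        cohort = make_cohort({"rs1": [None, None]})
        with pytest.raises(EmptyDataError):
            allele_frequencies(cohort, "rs1")

    def test_invariant_under_subject_permutation(self):
        rng = np.random.default_rng(0)
        col = list(rng.integers(0, 3, size=30))
        a = allele_frequencies(make_cohort({"rs1": col}), "rs1")
        b = allele_frequencies(make_cohort({"rs1": col[::-1]}), "rs1")
        assert a.minor_freq == b.minor_freq


class TestHWE:
    def test_exact_hwe_proportions_give_zero(self):
        res = hwe_chi_square(GenotypeCounts(25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_monomorphic_skips_zero_expectation_cells(self):
        res = hwe_chi_square(GenotypeCounts(100, 0, 0))
        assert res.chi2 == 0.0

    def test_textbook_disequilibrium_value(self):
        # counts (30,10,10): p̂=0.7, expected (24.5, 21, 4.5);
        # hand value 5.5²/24.5 + 11²/21 + 5.5²/4.5 = 13.71882…
        res = hwe_chi_square(GenotypeCounts(30, 10, 10))
        assert res.chi2 == pytest.approx(13.718820861678, rel=1e-9)
        assert res.df == 1
        assert res.p == pytest.approx(stats.chi2.sf(13.718820861678, 1))

    def test_empty_counts_error(self):
        with pytest.raises(EmptyDataError):
            hwe_chi_square(GenotypeCounts(0, 0, 0))

    @given(
        st.tuples(
            st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
        ).filter(lambda t: sum(t) > 0)
    )
    def test_statistic_nonnegative(self, counts):
        res = hwe_chi_square(GenotypeCounts(*counts))
        assert res.chi2 >= 0.0
        assert 0.0 <= res.p <= 1.0

    def test_nominal_rejection_rate_under_hwe(self):
        # 5,000 cohorts of n=102 drawn at HWE with minor freq 0.3 should
        # reject at alpha=0.05 in 5% ± 1% of replicates
        rng = np.random.default_rng(2024)
        q = 0.3
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
        draws = rng.multinomial(102, probs, size=5000)
        rejections = sum(
            hwe_chi_square(GenotypeCounts(*row)).p < 0.05 for row in draws
        )
        assert 0.04 <= rejections / 5000 <= 0.06


class TestDominantCode:
    @pytest.mark.parametrize("count, code", [(0, 0), (1, 1), (2, 1)])
    def test_carrier_coding(self, count, code):
        assert dominant_code(GenotypeCall("P1", "rs1", count)) == code

    def test_missing_call_signals(self):
        with pytest.raises(MissingGenotypeError):
            dominant_code(GenotypeCall("P1", "rs1", None))

    def test_coding_follows_function_not_frequency(self):
        # referent = normal-function allele; swapping the allele labels
        # (2 - count) flips every code
        counts = [0, 1, 2, 0, 2]
        codes = [dominant_code(GenotypeCall("P", "rs1", c)) for c in counts]
        swapped = [dominant_code(GenotypeCall("P", "rs1", 2 - c)) for c in counts]
        assert codes == [0, 1, 1, 0, 1]
        assert swapped == [1, 1, 0, 1, 0]


class TestPerfectLDCollapse:
    def test_concordant_pair_merges(self):
        cohort = make_cohort(
            {"rsA": [0, 1, 2, 0], "rsB": [0, 1, 1, 0]},
            panel=[Variant("rsA", "TPMT", "G", "A"), Variant("rsB", "TPMT", "A", "G")],
        )
        res = collapse_perfect_ld(cohort, "rsA", "rsB")
        assert res.concordant and res.marker_name == "TPMT*haplotype"
        merged, _ = apply_ld_collapse(cohort, "rsA", "rsB")
        assert merged.rsids == ["TPMT*haplotype"]
        assert merged.dominant_codes("TPMT*haplotype") == {
            "P0": 0, "P1": 1, "P2": 1, "P3": 0,
        }

    def test_single_discordant_subject_blocks_merge(self):
        cohort = make_cohort({"rsA": [0, 1], "rsB": [0, 0]})
        res = collapse_perfect_ld(cohort, "rsA", "rsB")
        assert not res.concordant and res.marker_name is None

    def test_verdict_is_symmetric(self):
        cohort = make_cohort({"rsA": [0, 1, 1], "rsB": [0, 1, 2]})
        assert (
            collapse_perfect_ld(cohort, "rsA", "rsB").concordant
            == collapse_perfect_ld(cohort, "rsB", "rsA").concordant
        )

    def test_vacuous_concordance_refuses_merge(self):
        cohort = make_cohort({"rsA": [0, None], "rsB": [None, 1]})
        with pytest.warns(UserWarning, match="merge refused"):
            res = collapse_perfect_ld(cohort, "rsA", "rsB")
        assert res.concordant and res.marker_name is None and res.n_overlap == 0

    def test_custom_marker_name(self):
        cohort = make_cohort({"rsA": [0, 1], "rsB": [0, 1]})
        res = collapse_perfect_ld(cohort, "rsA", "rsB", marker_name="TPMT*3A")
        assert res.marker_name == "TPMT*3A"


class TestDeriveOutcomes:
    BASE = {"pf": False, "kidney_insufficiency": False, "huv": False,
            "fvc_dlco_high": False}

    def test_rvsp_threshold_is_strict(self):
        assert not derive_outcomes({**self.BASE, "rvsp_mmHg": 35.0}).rvsp_high
        assert derive_outcomes({**self.BASE, "rvsp_mmHg": 36.0}).rvsp_high

    def test_fvc_dlco_ratio(self):
        base = {k: v for k, v in self.BASE.items() if k != "fvc_dlco_high"}
        flags = derive_outcomes(
            {**base, "rvsp_high": False, "fvc": 3.4, "dlco": 2.0}
        )
        assert flags.fvc_dlco_high  # 1.7 > 1.6

    def test_contradictory_flag_raises(self):
        with pytest.raises(ConsistencyError):
            derive_outcomes({**self.BASE, "rvsp_mmHg": 40.0, "rvsp_high": False})

    def test_zero_dlco_rejected(self):
        with pytest.raises(ValidationError):
            derive_outcomes(
                {**self.BASE, "rvsp_high": False, "fvc": 3.0, "dlco": 0.0}
            )

    def test_booleans_pass_through(self):
        flags = derive_outcomes(
            {"pf": True, "kidney_insufficiency": False, "huv": True,
             "rvsp_high": True, "fvc_dlco_high": False}
        )
        assert (flags.pf, flags.huv, flags.rvsp_high) == (True, True, True)


class TestSummarize:
    def test_margins_reproduced(self, margin_cohort):
        s = summarize_cohort(margin_cohort)
        assert s.total_n == 102
        assert [s.groups[g].n for g in THERAPY_GROUPS] == [16, 43, 3, 40]
        assert s.overall.outcome_counts["pf"] == 39
        assert s.groups["MTX"].outcome_pct["pf"] == pytest.approx(100 * 14 / 102)
        # group counts sum to whole-cohort totals for every outcome
        for o in OUTCOME_NAMES:
            assert (
                sum(s.groups[g].outcome_counts[o] for g in THERAPY_GROUPS)
                == s.overall.outcome_counts[o]
            )

    def test_interpolated_quartiles(self):
        cohort = make_cohort({"rs1": [0, 0, 0, 0]})
        object.__setattr__  # ages are 50,51,52,53 per make_cohort
        s = summarize_cohort(cohort)
        assert s.overall.age_q1 == pytest.approx(50.75)
        assert s.overall.age_q3 == pytest.approx(52.25)

    def test_single_group_cohort(self):
        cohort = make_cohort({"rs1": [0] * 10}, therapy="AZA")
        s = summarize_cohort(cohort)
        assert s.groups["AZA"].pct == 100.0
        assert s.groups["MTX"].n == 0

    def test_empty_cohort_rejected(self):
        with pytest.raises(EmptyDataError):
            summarize_cohort(Cohort([], {}, [Variant("rs1", "G1", "G", "A")]))


class TestGroupDifference:
    def test_homogeneous_2x2_gives_p_one(self):
        assert fisher_exact_2xk(np.array([[5, 5], [5, 5]])) == pytest.approx(1.0)

    def test_fisher_small_table_matches_enumeration_oracle(self):
        # independent scipy hypergeometric oracle, two-sided
        table = np.array([[1, 9], [11, 3]])
        p = fisher_exact_2xk(table)
        assert p == pytest.approx(stats.fisher_exact(table)[1], rel=1e-9)
        assert p == pytest.approx(0.0027595, abs=2e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_2x2_enumeration_agrees_with_scipy(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 15, size=(2, 2))
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            pytest.skip("degenerate margins")
        assert fisher_exact_2xk(table) == pytest.approx(
            stats.fisher_exact(table)[1], rel=1e-9
        )

    def test_method_selection(self, margin_cohort):
        s = summarize_cohort(margin_cohort)
        # sex: expected cells fall below 5 in the small AZA+MTX arm
        assert group_difference_test(s, "sex").method == "fisher-exact"
        res = group_difference_test(s, "pf")
        assert res.method == "fisher-exact"  # AZA+MTX column expectation < 5
        assert 0.0 <= res.p <= 1.0

    def test_chi_square_path_when_expectations_large(self):
        from sscpgx.synthetic_data import margins_cohort

        cohort = margins_cohort(
            group_sizes={"AZA": 50, "MTX": 50, "AZA+MTX": 50, "Other": 50},
            n_women={"AZA": 25, "MTX": 30, "AZA+MTX": 20, "Other": 25},
            outcome_counts={
                o: {"AZA": 20, "MTX": 25, "AZA+MTX": 15, "Other": 20}
                for o in OUTCOME_NAMES
            },
        )
        res = group_difference_test(summarize_cohort(cohort), "pf")
        assert res.method == "chi-square"

    def test_degenerate_zero_margin_flagged(self):
        from sscpgx.synthetic_data import margins_cohort

        cohort = margins_cohort(
            group_sizes={"AZA": 10, "MTX": 10, "AZA+MTX": 0, "Other": 10},
            n_women={"AZA": 5, "MTX": 5, "Other": 5},
            outcome_counts={o: {} for o in OUTCOME_NAMES},
        )
        res = group_difference_test(summarize_cohort(cohort), "pf")
        assert res.method == "degenerate" and res.p == 1.0 and res.note
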
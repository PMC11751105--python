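"""Three-pool signature classification and the sibling-ratio tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from selfseg.segregation import (
    CLASSIFICATIONS,
    FilterThresholds,
    PooledVariant,
    classify_segregation,
    classify_table,
    expected_pool_frequency,
    filter_candidates,
    sibling_pool_test,
    sibling_ratio_test,
)


def make_variant(mut, sib, wt, vid="v1"):
    """Variant from three (alt, depth) pairs."""
    return PooledVariant(
        variant_id=vid, contig="c", pos=1, ref_allele="A", alt_allele="G",
        counts={"mutant": mut, "sibling": sib, "wt": wt},
    )


def enumeration_pvalue(alt, depth, p0):
    """Independent oracle: sum the probabilities of all outcomes no more
    likely than the observed one."""
    pmf = stats.binom.pmf(np.arange(depth + 1), depth, p0)
    return min(1.0, pmf[pmf <= pmf[alt] * (1 + 1e-7)].sum())


class TestExpectedPoolFrequency:
    def test_recessive_signature_fixed_points(self):
        assert expected_pool_frequency("mutant") == 1.0
        assert expected_pool_frequency("wt") == 0.0
        assert expected_pool_frequency("sibling") == pytest.approx(1.0 / 3.0)

    def test_wt_allele_twice_as_abundant_in_siblings(self):
        f = expected_pool_frequency("sibling")
        assert (1 - f) / f == pytest.approx(2.0)

    def test_unknown_pool_rejected(self):
        with pytest.raises(ValueError):
            expected_pool_frequency("parents")


class TestSiblingRatioTest:
    def test_observation_equal_to_expectation_has_pvalue_one(self):
        p, consistent = sibling_ratio_test(33, 99, 1.0 / 3.0)
        assert p == pytest.approx(1.0)
        assert consistent

    def test_all_mutant_reads_are_firmly_rejected(self):
        p, consistent = sibling_ratio_test(99, 99, 1.0 / 3.0)
        assert p < 1e-15
        assert not consistent

    def test_thirty_eight_percent_is_consistent_with_one_third(self):
        p, consistent = sibling_ratio_test(38, 100, 1.0 / 3.0, alpha=0.05)
        assert consistent
        assert p > 0.05

    def test_zero_depth_signals_low_depth(self):
        with pytest.raises(ValueError, match="low_depth"):
            sibling_ratio_test(0, 0)

    @pytest.mark.parametrize("depth", [7, 23, 50, 61])
    def test_pvalue_matches_enumeration_oracle(self, depth):
        for alt in range(depth + 1):
            p, _ = sibling_ratio_test(alt, depth, 1.0 / 3.0)
            assert p == pytest.approx(enumeration_pvalue(alt, depth, 1.0 / 3.0),
                                      abs=1e-12)


class TestSiblingPoolTest:
    def test_converges_to_read_level_test_for_huge_pools(self):
        p_pool, _ = sibling_pool_test(38, 100, pool_size=20_000)
        p_read, _ = sibling_ratio_test(38, 100)
        assert p_pool == pytest.approx(p_read, abs=0.02)

    def test_small_pools_tolerate_more_spread_than_the_read_level_test(self):
        # 48/100 is rejected if reads are the only noise, but is an
        # unremarkable draw for a pool of 12 embryos
        p_read, consistent_read = sibling_ratio_test(48, 100)
        p_pool, consistent_pool = sibling_pool_test(48, 100, pool_size=12)
        assert not consistent_read
        assert consistent_pool
        assert p_pool > p_read

    def test_fixed_variant_still_firmly_rejected(self):
        p, consistent = sibling_pool_test(100, 100, pool_size=12)
        assert p < 1e-20
        assert not consistent

    def test_null_pmf_is_a_distribution(self):
        from selfseg.segregation import _compound_null_pmf

        pmf = _compound_null_pmf(80, 12, 1.0 / 3.0)
        assert pmf.sum() == pytest.approx(1.0)
        assert (pmf >= 0).all()


class TestClassification:
    def test_published_signature_is_a_candidate(self):
        v = make_variant((100, 100), (38, 100), (0, 100))
        call = classify_segregation(v)
        assert call.classification == "candidate"
        assert call.observed_frequencies["sibling"] == pytest.approx(0.38)

    def test_line_fixed_differences_are_phenotype_uninformative(self):
        v = make_variant((100, 100), (100, 100), (100, 100))
        assert classify_segregation(v).classification == "strain_fixed"

    def test_wrong_sibling_ratio_is_rejected(self):
        v = make_variant((100, 100), (95, 100), (0, 100))
        assert classify_segregation(v).classification == "sibling_ratio_inconsistent"

    def test_wt_presence_disqualifies(self):
        v = make_variant((100, 100), (38, 100), (30, 100))
        assert classify_segregation(v).classification == "wt_contaminated"

    def test_shallow_pools_are_flagged_not_classified(self):
        v = make_variant((5, 5), (2, 5), (0, 100))
        assert classify_segregation(v).classification == "low_depth"

    def test_swapping_mutant_and_wt_pools_breaks_the_signature(self):
        v = make_variant((100, 100), (38, 100), (0, 100))
        swapped = make_variant((0, 100), (38, 100), (100, 100))
        assert classify_segregation(v).classification == "candidate"
        assert classify_segregation(swapped).classification == "wt_contaminated"

    @given(
        counts=st.lists(
            st.tuples(*(st.integers(0, 60) for _ in range(6))),
            min_size=1, max_size=20,
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_every_variant_gets_exactly_one_class_and_table_matches_scalar(
        self, counts
    ):
        rows = []
        variants = []
        for i, (a1, d1, a2, d2, a3, d3) in enumerate(counts):
            mut = (min(a1, d1), max(a1, d1, 1))
            sib = (min(a2, d2), max(a2, d2, 1))
            wt = (min(a3, d3), max(a3, d3, 1))
            variants.append(make_variant(mut, sib, wt, vid=f"v{i}"))
            rows.append(
                {"variant_id": f"v{i}", "mut_alt": mut[0], "mut_depth": mut[1],
                 "sib_alt": sib[0], "sib_depth": sib[1],
                 "wt_alt": wt[0], "wt_depth": wt[1]}
            )
        table = classify_table(pd.DataFrame(rows))
        for v, cls in zip(variants, table["classification"]):
            scalar = classify_segregation(v).classification
            assert scalar in CLASSIFICATIONS
            assert scalar == cls

    def test_tightening_thresholds_never_adds_candidates(self):
        rng = np.random.default_rng(4)
        n = 300
        table = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(n)],
                "mut_alt": rng.integers(0, 101, n),
                "mut_depth": 100,
                "sib_alt": rng.integers(0, 101, n),
                "sib_depth": 100,
                "wt_alt": rng.integers(0, 11, n),
                "wt_depth": 100,
            }
        )
        loose = FilterThresholds(min_mutant_freq=0.9, max_wt_freq=0.08)
        tight_mut = FilterThresholds(min_mutant_freq=0.98, max_wt_freq=0.08)
        tight_wt = FilterThresholds(min_mutant_freq=0.9, max_wt_freq=0.02)

        def candidates(t):
            calls = classify_table(table, t)
            return set(calls.loc[calls["classification"] == "candidate",
                                 "variant_id"])

        assert candidates(tight_mut) <= candidates(loose)
        assert candidates(tight_wt) <= candidates(loose)


class TestFilterCandidates:
    def test_planted_causal_among_candidates(self, small_dataset):
        t = FilterThresholds(
            sibling_pool_size=small_dataset.config.n_sibling_embryos
        )
        result = filter_candidates(small_dataset.variants, t)
        assert small_dataset.causal_variant_id in {
            c.variant_id for c in result.candidates
        }
        assert result.funnel["total"] == len(small_dataset.variants)
        assert sum(
            result.funnel[c] for c in CLASSIFICATIONS
        ) == result.funnel["total"]

    def test_everything_in_wt_means_no_candidates(self):
        table = pd.DataFrame(
            {
                "variant_id": ["a", "b"],
                "mut_alt": [100, 100], "mut_depth": [100, 100],
                "sib_alt": [40, 30], "sib_depth": [100, 100],
                "wt_alt": [100, 100], "wt_depth": [100, 100],
            }
        )
        assert filter_candidates(table).candidates == []

    def test_empty_table_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            result = filter_candidates(pd.DataFrame())
        assert result.candidates == []
        assert result.funnel["total"] == 0


class TestThresholdValidation:
    def test_inverted_frequency_bounds_rejected(self):
        with pytest.raises(ValueError):
            FilterThresholds(min_mutant_freq=0.1, max_wt_freq=0.5)

    def test_sibling_expectation_must_sit_between_the_bounds(self):
        with pytest.raises(ValueError):
            FilterThresholds(sibling_expected_freq=0.99)

    def test_variant_count_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_variant((5, 3), (0, 10), (0, 10))
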
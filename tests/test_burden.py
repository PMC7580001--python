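"""Unit and property tests for the exact Poisson-binomial burden test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helpers
from domainburden.burden import (
    DomainFamilyStats,
    GeneDomainProfile,
    domain_hit_probability,
    family_test,
    poisson_binomial_logpmf,
    poisson_binomial_pmf,
    poisson_binomial_tail,
    span_union_length,
    tally_all_families,
    tally_family,
)
from domainburden.records import DomainInstance, VariantClass


def _inst(gene, L, start, end, acc="FAMX"):
    return DomainInstance(gene=gene, protein_length=L, family_acc=acc,
                          family_name=acc.lower(), start=start, end=end,
                          e_value=1e-9)


class TestDomainHitProbability:
    def test_direct_ratio(self):
        assert domain_hit_probability([_inst("G", 300, 41, 100)]) == pytest.approx(0.2)

    def test_overlapping_instances_union(self):
        # [10,40] U [30,70] has length 61 in a 122-aa protein
        p = domain_hit_probability([_inst("G", 122, 10, 40), _inst("G", 122, 30, 70)])
        assert p == pytest.approx(61 / 122) == pytest.approx(0.5)

    def test_whole_protein_domain(self):
        assert domain_hit_probability([_inst("G", 80, 1, 80)]) == 1.0

    def test_empty_instances_error(self):
        with pytest.raises(ValueError):
            domain_hit_probability([])

    def test_union_of_disjoint_spans(self):
        assert span_union_length([(1, 10), (21, 30)]) == 20
        assert span_union_length([(1, 10), (11, 20)]) == 20  # adjacent merge


class TestPmf:
    def test_single_fair_trial(self):
        assert poisson_binomial_pmf([0.5]) == pytest.approx([0.5, 0.5])

    def test_three_trial_enumeration(self):
        pmf = poisson_binomial_pmf([0.1, 0.2, 0.3])
        assert pmf == pytest.approx([0.504, 0.398, 0.092, 0.006], abs=1e-14)

    @pytest.mark.parametrize("n,p", [(10, 0.2), (40, 0.5), (100, 0.01)])
    def test_equal_p_matches_binomial(self, n, p):
        from scipy.stats import binom

        pmf = poisson_binomial_pmf(np.full(n, p))
        np.testing.assert_allclose(pmf, binom.pmf(np.arange(n + 1), n, p),
                                   atol=1e-12, rtol=1e-9)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            poisson_binomial_pmf([0.5, 1.2])
        with pytest.raises(ValueError):
            poisson_binomial_pmf([-0.1])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=0, max_size=12))
    def test_matches_enumeration_and_normalises(self, probs):
        pmf = poisson_binomial_pmf(probs)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(pmf, helpers.enum_pmf(probs), atol=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.001, 0.999), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_reorder_invariance(self, probs, rnd):
        shuffled = list(probs)
        rnd.shuffle(shuffled)
        np.testing.assert_allclose(
            poisson_binomial_pmf(probs), poisson_binomial_pmf(shuffled), atol=1e-12
        )

    def test_normalisation_large_random_vector(self):
        rng = np.random.default_rng(0)
        p = rng.random(5000)
        assert poisson_binomial_pmf(p).sum() == pytest.approx(1.0, abs=1e-10)

    def test_logspace_agrees_with_linear(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 0.3, 50)
        lp = poisson_binomial_logpmf(p)
        np.testing.assert_allclose(np.exp(lp), poisson_binomial_pmf(p), rtol=1e-10)


class TestTail:
    def test_all_zero_probs(self):
        assert poisson_binomial_tail([0.0, 0.0], 0) == 1.0
        assert poisson_binomial_tail([0.0, 0.0], 1) == 0.0

    def test_enumeration_inclusive_and_strict(self):
        assert poisson_binomial_tail([0.1, 0.2, 0.3], 2) == pytest.approx(0.098)
        assert poisson_binomial_tail([0.1, 0.2, 0.3], 2, inclusive=False) == (
            pytest.approx(0.006)
        )

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            poisson_binomial_tail([0.5], 2)

    def test_strict_equals_inclusive_shifted(self):
        rng = np.random.default_rng(3)
        p = rng.random(20)
        for k in range(1, 21):
            assert poisson_binomial_tail(p, k) == pytest.approx(
                poisson_binomial_tail(p, k - 1, inclusive=False), rel=1e-12
            )

    def test_monotone_in_k(self):
        rng = np.random.default_rng(4)
        p = rng.random(30)
        tails = [poisson_binomial_tail(p, k) for k in range(31)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_deep_tail_matches_exact_integer_dp(self):
        rng = np.random.default_rng(5)
        p = helpers.quantize_probs(rng.uniform(0, 0.05, 60))
        for k in (20, 30, 40):
            exact = helpers.exact_tail(p, k)
            got = poisson_binomial_tail(p, k)
            assert got == pytest.approx(float(exact), rel=1e-9)

    def test_log_tail_below_double_underflow(self):
        # tail so small the linear DP underflows: log-space answer survives
        p = np.full(500, 1e-4)
        logt = poisson_binomial_tail(p, 400, return_log=True)
        assert logt < -1000
        assert np.isfinite(logt)

    def test_monte_carlo_agreement(self):
        # mirrors a permutation check: 1e6 draws, tail above 1e-4
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 0.3, 25)
        draws = (rng.random((10**6, p.size)) < p).sum(axis=1)
        k = int(np.percentile(draws, 99.9))
        mc = float((draws >= k).mean())
        se = np.sqrt(mc * (1 - mc) / 10**6)
        assert abs(poisson_binomial_tail(p, k) - mc) < 3 * se


class TestTally:
    def test_boundary_convention_and_counts(self, toy_mutations, toy_domains):
        st_ = tally_family(toy_mutations, toy_domains, "FAMX", cohort_size=5)
        by_gene = {p.gene: p for p in st_.member_profiles}
        assert (by_gene["GA"].n, by_gene["GA"].k) == (3, 2)  # pos 40 in, 41 out
        assert (by_gene["GB"].n, by_gene["GB"].k) == (2, 0)  # pos 50 = start-1
        assert (by_gene["GC"].n, by_gene["GC"].k) == (1, 1)
        assert st_.n_obs == 3
        assert st_.genomes_hit == 2  # P1, P2
        # conservation: in + out = total eligible trials
        assert sum(p.n for p in st_.member_profiles) == 6

    def test_unknown_family_errors(self, toy_mutations, toy_domains):
        with pytest.raises(KeyError):
            tally_family(toy_mutations, toy_domains, "NOPE")

    def test_zero_hits_family(self, toy_mutations, toy_domains):
        st_ = tally_family(toy_mutations, toy_domains, "FAMY")
        # GD's only mutation at 120 is inside [101,160]
        assert st_.n_obs == 1
        mut2 = toy_mutations.copy()
        mut2.loc[mut2["gene"] == "GD", "protein_pos"] = 50
        st2 = tally_family(mut2, toy_domains, "FAMY")
        assert st2.n_obs == 0

    def test_tally_all_matches_per_family(self, toy_mutations, toy_domains):
        all_stats = {s.family_acc: s for s in
                     tally_all_families(toy_mutations, toy_domains, cohort_size=5)}
        for acc in ("FAMX", "FAMY"):
            one = tally_family(toy_mutations, toy_domains, acc, cohort_size=5)
            assert all_stats[acc].n_obs == one.n_obs
            assert all_stats[acc].genomes_hit == one.genomes_hit
            assert {(p.gene, p.n, p.k) for p in all_stats[acc].member_profiles} == {
                (p.gene, p.n, p.k) for p in one.member_profiles
            }

    def test_eligible_classes_must_be_nonempty(self, toy_mutations, toy_domains):
        with pytest.raises(ValueError):
            tally_family(toy_mutations, toy_domains, "FAMX", eligible_classes=set())


class TestFamilyTest:
    def test_single_gene_binomial_oracle(self):
        from scipy.stats import binom

        st_ = DomainFamilyStats(
            family_acc="F", family_name="f",
            member_profiles=[GeneDomainProfile("G", 100, 20, n=10, k=2)],
            n_obs=2,
        )
        family_test(st_)
        assert st_.p_value == pytest.approx(float(binom.sf(1, 10, 0.2)))
        assert st_.p_value == pytest.approx(0.6242, abs=5e-5)

    def test_zero_observed_gives_one(self):
        st_ = DomainFamilyStats(
            family_acc="F", family_name="f",
            member_profiles=[GeneDomainProfile("G", 100, 20, n=5, k=0)],
            n_obs=0,
        )
        assert family_test(st_).p_value == 1.0

    def test_zero_trials_gives_one(self):
        st_ = DomainFamilyStats(family_acc="F", family_name="f")
        assert family_test(st_).p_value == 1.0

    def test_two_gene_enumeration_oracle(self):
        probs = [0.5, 0.5, 0.5, 0.1, 0.1]
        expected = helpers.enum_pmf(probs)[4:].sum()
        st_ = DomainFamilyStats(
            family_acc="F", family_name="f",
            member_profiles=[
                GeneDomainProfile("G1", 10, 5, n=3, k=3),
                GeneDomainProfile("G2", 10, 1, n=2, k=1),
            ],
            n_obs=4,
        )
        assert family_test(st_).p_value == pytest.approx(float(expected), rel=1e-12)
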
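"""High-coverage caller: ML calls, LRTs, refinement, allele counts."""

import math

import numpy as np
import pytest
from scipy.stats import chi2

from quartetcall import hgc
from quartetcall.error_model import ml_error_rate as generic_eps
from quartetcall.simulate import simulate_individuals


class TestErrorRate:
    @pytest.mark.parametrize(
        "q,G,expected",
        [
            ((9, 1, 0, 0), "AA", 0.1),
            ((5, 5, 0, 0), "AC", 0.0),
            ((4, 4, 1, 1), "AC", 1.5 * 0.2),
            ((1, 9, 0, 0), "AA", 0.75),  # clamped
        ],
    )
    def test_closed_forms(self, q, G, expected):
        assert hgc.ml_error_rate(q, G) == pytest.approx(expected, abs=1e-12)

    def test_matches_generic_profile_maximizer(self, rng):
        for _ in range(300):
            q = rng.integers(0, 25, 4)
            if q.sum() == 0:
                continue
            for G in ("AA", "CC", "AC", "GT", "AG"):
                assert hgc.ml_error_rate(q, G) == pytest.approx(generic_eps(q, G), abs=1e-9)


class TestCallIndividual:
    def test_clean_homozygote(self):
        call = hgc.call_individual([10, 0, 0, 0])
        assert call.call == "AA"
        assert call.eps_call == 0.0

    def test_minimum_coverage_gate(self):
        assert hgc.call_individual([5, 0, 0, 0]).reason == "low_coverage"
        assert hgc.call_individual([5, 0, 0, 0], min_cov=5).call == "AA"
        assert hgc.call_individual([0, 0, 0, 0]).reason == "zero_coverage"

    def test_balanced_reads_called_heterozygous(self):
        call = hgc.call_individual([3, 3, 0, 0], min_cov=1)
        assert call.call == "AC"
        # LL(AC) = 6 ln(1/2) strictly beats LL(AA) at its own eps
        assert call.ll_profile["AC"][1] == pytest.approx(6 * math.log(0.5))
        assert call.ll_profile["AC"][1] > call.ll_profile["AA"][1]

    def test_candidates_restricted_to_observed_nucleotides(self):
        call = hgc.call_individual([6, 2, 0, 0], min_cov=1)
        assert set(call.ll_profile) == {"AA", "AC", "CC"}

    def test_single_discordant_read_boundary_at_coverage_six(self):
        """A lone second nucleotide is an allele up to n=5, an error from n=6."""
        assert hgc.call_individual([4, 1, 0, 0], min_cov=1).call == "AC"
        assert hgc.call_individual([5, 1, 0, 0], min_cov=1).call == "AA"

    def test_double_discordant_read_boundary_at_coverage_eleven(self):
        assert hgc.call_individual([8, 2, 0, 0], min_cov=1).call == "AC"
        assert hgc.call_individual([9, 2, 0, 0], min_cov=1).call == "AA"

    def test_perfect_calls_without_errors(self, rng):
        """eps = 0 data with both alleles seen at least twice is called
        perfectly (a lone 1-of-10 minority read is rightly attributed to
        error by ML, the same mechanism as the coverage-6 boundary)."""
        for G, truth in (("AA", "AA"), ("AC", "AC")):
            qs = simulate_individuals(G, 10, 0.0, rng)
            for q in qs[:200]:
                if len(set(G)) == 2 and (q[0] < 2 or q[1] < 2):
                    continue
                assert hgc.call_individual(q).call == truth


class TestSiteTests:
    def test_all_major_homozygotes_not_polymorphic(self):
        calls = [hgc.call_individual([20, 0, 0, 0]) for _ in range(5)]
        assert not hgc.test_site_polymorphism(calls, "A")

    def test_worked_lrt_equals_ten_ln_three(self):
        calls = [hgc.call_individual([5, 5, 0, 0], min_cov=1)]
        assert hgc.test_site_polymorphism(calls, "A", alpha=0.05)
        assert calls[0].lrt_vs_mm == pytest.approx(10 * math.log(3), rel=1e-12)
        assert calls[0].lrt_vs_mm > chi2.isf(0.05, 1)

    def test_lrt_nonnegative_random_quartets(self, rng):
        for _ in range(200):
            q = rng.integers(0, 15, 4)
            if q.sum() < 6:
                continue
            c = hgc.call_individual(q)
            if c.call is None:
                continue
            hgc.test_site_polymorphism([c], "A")
            assert c.lrt_vs_mm is None or c.lrt_vs_mm >= 0

    def test_het_refinement(self):
        assert hgc.refine_heterozygote([50, 50, 0, 0], "AC")
        assert not hgc.refine_heterozygote([6, 1, 0, 0], "AC")
        with pytest.raises(ValueError):
            hgc.refine_heterozygote([5, 5, 0, 0], "AA")

    def test_allele_counting_with_refinement(self):
        # confirmed het CC/AC individuals against M=A
        calls = [
            hgc.call_individual([40, 40, 0, 0]),  # AC, confirmed het
            hgc.call_individual([0, 60, 0, 0]),  # CC
            hgc.call_individual([60, 0, 0, 0]),  # AA (MM)
        ]
        assert hgc.test_site_polymorphism(calls, "A")
        assert hgc.count_alleles(calls, "A") == 2
        # an unconfirmed het contributes only its abundant allele
        weak = [hgc.call_individual([12, 2, 0, 0], min_cov=1)]
        hgc.test_site_polymorphism(weak, "C")
        if weak[0].call == "AC" and weak[0].significant:
            assert hgc.count_alleles(weak, "C") <= 2

    def test_monomorphic_site_reports_one_allele(self, rng):
        quartets = simulate_individuals("AA", 20, 0.005, rng)[:30]
        res = hgc.call_site(quartets)
        assert res.M == "A"
        assert res.n_alleles in (1, 2)  # rare error-driven false positive
        if not res.polymorphic:
            assert res.n_alleles == 1


class TestVectorizedCaller:
    def test_matches_scalar_on_random_quartets(self, rng):
        qs = rng.integers(0, 12, size=(400, 4))
        batch = hgc.call_quartets(qs, min_cov=3)
        for q, b in zip(qs, batch):
            ref = hgc.call_individual(q, min_cov=3)
            assert b == (ref.call or "")

    def test_homozygote_accuracy_dips_then_recovers(self, rng):
        """Fixed-coverage accuracy: valley below 6, then approaches 1."""
        rates = {}
        for cov in (2, 5, 6, 10, 30):
            qs = simulate_individuals("AA", cov, 0.01, rng, n_reps=4000)
            calls = hgc.call_quartets(qs, min_cov=1)
            rates[cov] = (calls == "AA").mean()
        # valley below 6 (lone errors absorbed as alleles), near-perfect after
        assert rates[5] < rates[2]
        assert rates[5] < rates[6]
        assert min(rates[6], rates[10], rates[30]) > 0.99

    def test_heterozygote_accuracy_dips_at_six_and_eleven(self, rng):
        rates = {}
        for cov in (5, 6, 10, 11, 30):
            qs = simulate_individuals("AC", cov, 0.01, rng, n_reps=4000)
            calls = hgc.call_quartets(qs, min_cov=1)
            rates[cov] = (calls == "AC").mean()
        assert rates[6] < rates[5]
        assert rates[11] < rates[10]
        assert rates[30] > 0.99
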
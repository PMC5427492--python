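"""Bayesian low-coverage caller: posteriors, no-call rules, population calls."""

import math

import numpy as np
import pytest

from quartetcall import bgc, gfe
from quartetcall.error_model import read_prob
from quartetcall.hgc import call_quartets
from quartetcall.simulate import simulate_biallelic_sites


def _priors(gamma, eps, M="A", m="C"):
    return gfe.SitePriors(M, m, np.asarray(gamma, float), eps, 0.0, 0.0, 100.0, 1e-9)


def test_degenerate_prior_forces_major_homozygote():
    pr = _priors([1.0, 0.0, 0.0], 0.01)
    call = bgc.posterior_call([1, 0, 0, 0], pr)
    assert call.call == "AA"
    assert np.exp(call.log_post[0]) == pytest.approx(1.0)
    # even a quartet full of minor reads cannot escape a degenerate prior
    assert bgc.posterior_call([0, 5, 0, 0], pr).call == "AA"


def test_zero_coverage_never_called():
    call = bgc.posterior_call([0, 0, 0, 0], _priors([0.25, 0.5, 0.25], 0.01))
    assert call.call is None
    assert call.reason == "zero_coverage"


def test_posterior_matches_brute_force_enumeration():
    """Independent arithmetic oracle: three numerators computed by hand."""
    gamma = [0.25, 0.5, 0.25]
    eps = 0.01
    q = [2, 1, 0, 0]  # M=A, m=C
    pr = _priors(gamma, eps)
    numerators = []
    for G in ["AA", "AC", "CC"]:
        like = read_prob("A", G, eps) ** 2 * read_prob("C", G, eps)
        numerators.append(gamma[["AA", "AC", "CC"].index(G)] * like)
    post = np.array(numerators) / sum(numerators)
    call = bgc.posterior_call(q, pr)
    assert call.call == "AC"
    assert np.exp(call.log_post) == pytest.approx(post, rel=1e-10)


def test_posterior_normalizes(rng):
    pr = _priors([0.5, 0.3, 0.2], 0.02, M="G", m="T")
    for _ in range(20):
        q = rng.integers(0, 8, 4)
        if q.sum() == 0:
            continue
        call = bgc.posterior_call(q, pr)
        assert np.exp(call.log_post).sum() == pytest.approx(1.0, abs=1e-12)


def test_flat_prior_reduces_to_ml_call(rng):
    """With gamma = (1/3, 1/3, 1/3) the posterior call is the pure ML call."""
    pr = _priors([1 / 3, 1 / 3, 1 / 3], 0.01)
    for _ in range(50):
        q = np.zeros(4, dtype=int)
        q[:2] = rng.integers(0, 10, 2)
        if q.sum() == 0:
            continue
        call = bgc.posterior_call(q, pr)
        lls = [
            sum(c * math.log(read_prob(x, G, 0.01)) for c, x in zip(q, "ACGT") if c)
            for G in ["AA", "AC", "CC"]
        ]
        best = ["AA", "AC", "CC"][int(np.argmax(lls))]
        if call.call is not None:
            assert call.call == best


def test_increasing_het_prior_never_flips_away_from_het():
    q = [3, 2, 0, 0]
    seen_het = False
    for g2 in np.linspace(0.01, 0.98, 25):
        rest = (1 - g2) / 2
        call = bgc.posterior_call(q, _priors([rest, g2, rest], 0.01))
        if seen_het:
            assert call.call == "AC"
        seen_het = seen_het or (call.call == "AC")
    assert seen_het


def test_monomorphic_sites_yield_all_no_calls(rng):
    sim = simulate_biallelic_sites(30, 20, 1.0, 0.0, 5.0, 0.002, rng)
    batch = gfe.estimate_priors_batch(sim.quartets)
    calls, poly = bgc.call_population(sim.quartets, batch, alpha=0.05)
    assert poly.sum() <= 1  # type-I errors only
    assert (calls[~poly] == "").all()


def test_population_calls_match_scalar_path(rng):
    sim = simulate_biallelic_sites(40, 30, 0.49, 0.09, 3.0, 0.01, rng)
    batch = gfe.estimate_priors_batch(sim.quartets)
    calls, poly = bgc.call_population(sim.quartets, batch, alpha=0.05, chunk=7)
    for s in range(sim.n_sites):
        pr = batch[s]
        for i in range(sim.n_individuals):
            if not poly[s]:
                assert calls[s, i] == ""
                continue
            ref = bgc.posterior_call(sim.quartets[s, i], pr)
            assert calls[s, i] == (ref.call or "")


def test_accuracy_among_called_improves_with_coverage(rng):
    from quartetcall.evaluate import score_calls

    rates = []
    for mu in (3.0, 10.0):
        sim = simulate_biallelic_sites(250, 100, 0.49, 0.09, mu, 0.01, rng)
        batch = gfe.estimate_priors_batch(sim.quartets)
        calls, _ = bgc.call_population(sim.quartets, batch)
        rates.append(score_calls(calls, sim.truth).correct_among_called)
    assert rates[1] > rates[0]


def test_bgc_beats_prior_free_calling_at_low_coverage(rng):
    """Population priors add accuracy over per-individual ML at mean 3x."""
    from quartetcall.evaluate import score_calls

    sim = simulate_biallelic_sites(250, 100, 0.81, 0.01, 3.0, 0.01, rng)
    batch = gfe.estimate_priors_batch(sim.quartets)
    calls, _ = bgc.call_population(sim.quartets, batch)
    ml_calls = call_quartets(sim.quartets, min_cov=1)
    bayes = score_calls(calls, sim.truth).correct_among_called
    ml = score_calls(ml_calls, sim.truth).correct_among_called
    assert bayes > ml
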
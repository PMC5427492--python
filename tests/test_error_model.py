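"""Read-probability model and profile-ML error rates."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from quartetcall import error_model as em

ALL_GENOTYPES = (
    em.enumerate_genotypes("ACGT", 2)
    + em.enumerate_genotypes("ACGT", 3)
    + em.enumerate_genotypes("ACGT", 4)
)


@pytest.mark.parametrize(
    "x,G,eps,expected",
    [
        # diploid major/minor table at several error rates
        ("A", "AA", 0.01, 0.99),
        ("C", "AA", 0.01, 0.01 / 3),
        ("A", "AC", 0.01, 0.5 * 0.99 + 0.5 * 0.01 / 3),
        ("C", "AC", 0.3, 0.5 * 0.7 + 0.5 * 0.1),
        ("G", "AC", 0.3, 0.1),
        ("C", "CC", 0.0, 1.0),
        # polyploid instances of the (k/m) rule
        ("A", "ACC", 0.09, 1 / 3 - 0.01),  # 1/3 - eps/9
        ("C", "ACC", 0.09, 2 / 3 - 0.05),  # 2/3 - 5 eps/9
        ("A", "ACCC", 0.5, 0.25),  # eps-free tetraploid singleton
        ("A", "AAAA", 0.0, 1.0),
        ("A", "AACG", 0.3, 0.5 - 0.1),
    ],
)
def test_read_prob_matches_known_cells(x, G, eps, expected):
    assert em.read_prob(x, G, eps) == pytest.approx(expected, abs=1e-12)


@given(
    G=st.sampled_from(ALL_GENOTYPES),
    eps=st.floats(0.0, em.MAX_ERROR_RATE),
)
def test_read_probs_normalize(G, eps):
    """The four read probabilities sum to one for every genotype and eps."""
    p = em.read_probs(G, eps)
    assert np.all(p >= -1e-15)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


@given(
    x=st.sampled_from("ACGT"),
    eps=st.floats(0.0, em.MAX_ERROR_RATE),
    ploidy=st.sampled_from([2, 3, 4]),
    data=st.data(),
)
def test_read_prob_depends_only_on_multiplicity(x, eps, ploidy, data):
    """Exchangeability: P(x|G) is a function of x's copy number only."""
    k = data.draw(st.integers(0, ploidy))
    others = data.draw(
        st.lists(st.sampled_from([c for c in "ACGT" if c != x]), min_size=ploidy - k, max_size=ploidy - k)
    )
    G = em.genotype([x] * k + others)
    expected = (k / ploidy) * (1 - eps) + ((ploidy - k) / ploidy) * (eps / 3)
    assert em.read_prob(x, G, eps) == pytest.approx(expected, abs=1e-12)


def test_quartet_log_likelihood_examples():
    assert em.quartet_log_likelihood([5, 0, 0, 0], "AA", 0.0) == 0.0
    assert em.quartet_log_likelihood([0, 0, 0, 0], "ACG"[:2], 0.3) == 0.0
    # heterozygote with balanced reads: 6 * ln(1/2 - eps/3)
    got = em.quartet_log_likelihood([3, 3, 0, 0], "AC", 0.01)
    assert got == pytest.approx(6 * math.log(0.5 - 0.01 / 3), rel=1e-12)
    assert got == pytest.approx(-4.1990, abs=5e-4)
    # positive count against zero probability -> -inf
    assert em.quartet_log_likelihood([1, 1, 0, 0], "AA", 0.0) == -np.inf


@pytest.mark.parametrize(
    "q,G,expected",
    [
        ((9, 1, 0, 0), "AA", 0.1),  # homozygote: (n - nA)/n
        ((5, 5, 0, 0), "AC", 0.0),
        ((4, 4, 1, 1), "AC", 0.3),  # heterozygote: (3/2) n_err/n
        ((9, 1, 0, 0), "AAA", 0.1),
        ((3, 6, 1, 0), "ACC", (129 - math.sqrt(13041)) / 100),  # quadratic root
        ((3, 3, 3, 1), "ACG", 0.3),  # 3 * nT/n
        ((6, 2, 2, 1), "AACG", 1.5 * 1 / 7),  # (3/2) nT/(nA+nT)
        ((2, 6, 1, 1), "ACCC", (9 / 8) * 2 / 8),  # (9/8)(nG+nT)/(nC+nG+nT)
        ((4, 4, 1, 1), "AACC", 0.3),  # (3/2) n_err/n
        ((3, 2, 2, 1), "ACGT", 0.0),  # all probabilities eps-free
        ((1, 9, 0, 0), "AA", em.MAX_ERROR_RATE),  # clamped at uniform limit
    ],
)
def test_ml_error_rate_closed_forms(q, G, expected):
    """The generic profile maximizer reproduces every printed closed form."""
    assert em.ml_error_rate(q, G) == pytest.approx(expected, abs=1e-10)


@pytest.mark.parametrize("G", ["AA", "AC", "AAA", "AAC", "ACC", "ACG", "AAAA", "AAAC", "AACC", "AACG", "ACGT"])
def test_ml_error_rate_beats_grid(G, rng):
    """eps_hat attains at least the best log-likelihood on a 1e-5 grid."""
    n_q = 1000
    quartets = rng.integers(0, 30, size=(n_q, 4)).astype(float)
    quartets = quartets[quartets.sum(axis=1) > 0]
    grid = np.linspace(1e-5, em.MAX_ERROR_RATE, 75000)
    m = len(G)
    k = np.array([G.count(x) for x in "ACGT"], dtype=float)
    probs = (k[:, None] / m) * (1 - grid) + ((m - k[:, None]) / m) * (grid / 3)  # (4, T)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(probs > 0, np.log(np.maximum(probs, 1e-300)), -np.inf)
        grid_ll = quartets @ logp  # (n_q, T); rows with -inf only when count>0 & p==0
    grid_best = np.nanmax(np.where(np.isfinite(grid_ll), grid_ll, -np.inf), axis=1)
    for q, gbest in zip(quartets, grid_best):
        e = em.ml_error_rate(q, G)
        assert 0.0 <= e <= em.MAX_ERROR_RATE
        assert em.quartet_log_likelihood(q, G, e) >= gbest - 1e-9


def test_enumerate_genotypes_counts():
    assert len(em.enumerate_genotypes("ACGT", 2)) == 10
    assert len(em.enumerate_genotypes("ACG", 2)) == 6
    assert len(em.enumerate_genotypes("ACGT", 3)) == 20
    assert len(em.enumerate_genotypes("ACGT", 4)) == 35
    assert em.enumerate_genotypes("CA", 2) == ["AA", "AC", "CC"]
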
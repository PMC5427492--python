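"""Canonical simulation benchmarks for the callers.

Each function runs one published-style evaluation regime end to end —
simulate, estimate, call, score — and returns the headline quantities.  The
regimes are the study conditions themselves (N = 100 individuals, error rate
0.01, 10,000 sites at full scale); ``n_sites`` is exposed so test suites can
run reduced replicates.
"""

from __future__ import annotations

import numpy as np

from . import bgc, gfe, hgc
from .evaluate import allele_freq_bias, score_calls
from .simulate import simulate_biallelic_sites, simulate_triallelic_sites

N_INDIVIDUALS = 100
ERROR_RATE = 0.01
FULL_SITES = 10_000

#: Table-style biallelic regimes: gamma1, gamma3 given minor-allele
#: frequency q and inbreeding extreme.
BIALLELIC_REGIMES = {
    ("hwe", 0.1): (0.81, 0.01),
    ("hwe", 0.3): (0.49, 0.09),
    ("min_f", 0.1): (0.80, 0.00),
    ("min_f", 0.3): (0.40, 0.00),
    ("max_f", 0.1): (0.90, 0.10),
    ("max_f", 0.3): (0.70, 0.30),
}


def run_biallelic_bgc(
    regime: str,
    q: float,
    mean_cov: float = 3.0,
    n_sites: int = FULL_SITES,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
) -> dict:
    """Simulate a biallelic regime, run GFE priors + BGC, score the calls."""
    gamma1, gamma3 = BIALLELIC_REGIMES[(regime, q)]
    sim = simulate_biallelic_sites(
        n_sites, N_INDIVIDUALS, gamma1, gamma3, mean_cov, ERROR_RATE, rng
    )
    priors = gfe.estimate_priors_batch(sim.quartets)
    calls, polymorphic = bgc.call_population(sim.quartets, priors, alpha=alpha, min_cov=1)
    score = score_calls(calls, sim.truth)
    qhat_mean, qhat_2sem = allele_freq_bias(priors.qhat)
    return {
        "qhat_mean": qhat_mean,
        "qhat_2sem": qhat_2sem,
        "correct_among_individuals": score.correct_among_individuals,
        "correct_among_called": score.correct_among_called,
        "no_call_fraction": score.no_call_fraction,
        "polymorphic_fraction": float(polymorphic.mean()),
        "n_sites": n_sites,
    }


def run_triallelic_hgc(
    mean_cov: float,
    n_sites: int = FULL_SITES,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Triallelic HWE regime (p, q, r = 0.7, 0.2, 0.1) with the HGC."""
    sim = simulate_triallelic_sites(
        n_sites, N_INDIVIDUALS, 0.7, 0.2, 0.1, mean_cov, ERROR_RATE, rng
    )
    calls = hgc.call_quartets(sim.quartets, min_cov=1)
    score = score_calls(calls, sim.truth)
    return {
        "correct_among_individuals": score.correct_among_individuals,
        "correct_among_called": score.correct_among_called,
        "n_sites": n_sites,
    }


def run_triallelic_bgc(
    mean_cov: float = 20.0,
    n_sites: int = FULL_SITES,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
) -> dict:
    """The biallelic Bayesian caller applied to triallelic data.

    The genotype-frequency estimator keeps the two most abundant
    nucleotides; genotypes carrying the rarest allele cannot be called
    correctly, which is the documented cost of the biallelic assumption.
    """
    sim = simulate_triallelic_sites(
        n_sites, N_INDIVIDUALS, 0.7, 0.2, 0.1, mean_cov, ERROR_RATE, rng
    )
    priors = gfe.estimate_priors_batch(sim.quartets)
    calls, _ = bgc.call_population(sim.quartets, priors, alpha=alpha, min_cov=1)
    score = score_calls(calls, sim.truth)
    return {
        "correct_among_individuals": score.correct_among_individuals,
        "correct_among_called": score.correct_among_called,
        "n_sites": n_sites,
    }
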
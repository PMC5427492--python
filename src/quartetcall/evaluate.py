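"""Scoring genotype calls against recorded truth.

Two accuracy definitions are used throughout:

* correct-call rate among individuals: per site, the fraction of all N
  individuals whose call equals the truth, with missing (no-call)
  individuals counted incorrect;
* correct-call rate among called genotypes: per site, the fraction correct
  among individuals that received a call (sites with no calls contribute
  nothing to this rate).

Both are averaged over sites; uncertainty is reported as twice the standard
error of that per-site mean ("mean +/- 2 SEM", the replicate unit being the
site).  Polymorphism- and allele-count-detection performance is summarized
as false-positive and false-negative rates over sites, and the sampling
floor on the false-negative rate at minor-allele frequency q with N diploid
individuals is q^(2N) + (1-q)^(2N) — the probability that only one allele is
present in the sample at all, which no caller can beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CallScore:
    """Accuracy summary of a call matrix against truth."""

    correct_among_individuals: float
    sem2_among_individuals: float
    correct_among_called: float
    sem2_among_called: float
    no_call_fraction: float
    n_sites: int
    n_sites_with_calls: int


def _mean_2sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return float("nan"), float("nan")
    mean = float(x.mean())
    if x.size == 1:
        return mean, 0.0
    sem = float(x.std(ddof=1) / np.sqrt(x.size))
    return mean, 2.0 * sem


def score_calls(calls: np.ndarray, truth: np.ndarray) -> CallScore:
    """Score an (S, N) call matrix ('' = no-call) against (S, N) truth."""
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.shape != truth.shape:
        raise ValueError(f"shape mismatch: calls {calls.shape} vs truth {truth.shape}")
    called = calls != ""
    correct = called & (calls == truth)
    per_site_ind = correct.mean(axis=1)
    mean_ind, sem2_ind = _mean_2sem(per_site_ind)
    n_called = called.sum(axis=1)
    has_calls = n_called > 0
    with np.errstate(invalid="ignore"):
        per_site_called = correct.sum(axis=1)[has_calls] / n_called[has_calls]
    mean_called, sem2_called = _mean_2sem(per_site_called)
    return CallScore(
        correct_among_individuals=mean_ind,
        sem2_among_individuals=sem2_ind,
        correct_among_called=mean_called,
        sem2_among_called=sem2_called,
        no_call_fraction=float(1.0 - called.mean()),
        n_sites=calls.shape[0],
        n_sites_with_calls=int(has_calls.sum()),
    )


def polymorphism_power(declared: np.ndarray, truly_polymorphic: np.ndarray) -> tuple[float, float]:
    """(false-positive rate, false-negative rate) of polymorphism detection.

    ``declared``: per-site boolean, site declared polymorphic.
    ``truly_polymorphic``: per-site boolean truth.
    FP = fraction of truly monomorphic sites declared polymorphic;
    FN = fraction of truly polymorphic sites not declared.  A rate whose
    denominator is empty is NaN.
    """
    declared = np.asarray(declared, dtype=bool)
    truth = np.asarray(truly_polymorphic, dtype=bool)
    if declared.shape != truth.shape:
        raise ValueError("shape mismatch between declared and truth")
    mono = ~truth
    fp = float(declared[mono].mean()) if mono.any() else float("nan")
    fn = float((~declared[truth]).mean()) if truth.any() else float("nan")
    return fp, fn


def allele_count_power(
    n_alleles_called: np.ndarray, n_alleles_true: np.ndarray, k: int = 3
) -> tuple[float, float]:
    """FP/FN rates for detecting sites with >= k alleles."""
    called = np.asarray(n_alleles_called) >= k
    truth = np.asarray(n_alleles_true) >= k
    return polymorphism_power(called, truth)


def fn_floor(q: float, N: int) -> float:
    """Sampling floor of the polymorphism-detection false-negative rate.

    Probability that a sample of N diploid individuals (2N chromosomes)
    carries only one of the two alleles: q^(2N) + (1-q)^(2N).
    """
    return q ** (2 * N) + (1.0 - q) ** (2 * N)


def allele_freq_bias(qhat: np.ndarray) -> tuple[float, float]:
    """Mean and 2-SEM of per-site minor-allele-frequency estimates."""
    return _mean_2sem(np.asarray(qhat, dtype=float))
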
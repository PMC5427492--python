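"""Nucleotide-read probability model shared by all genotype callers.

A sequenced read at a site is drawn from one chromosome of the individual's
genotype, chosen uniformly, and is miscalled with probability ``eps`` (the
per-read, per-site sequencing error rate), landing on each of the other three
nucleotides with probability ``eps/3``.  For a genotype ``G`` of ploidy ``m``
that carries ``k`` copies of nucleotide ``x``, the probability of observing an
``x`` read is therefore::

    P(x | G, eps) = (k/m) * (1 - eps) + ((m - k)/m) * (eps/3)

which is linear in ``eps``.  The diploid specialization is the classic
major/minor table (1 - eps for a matching homozygote read, 1/2 - eps/3 for a
heterozygote allele read, eps/3 for an error read); the triploid and
tetraploid callers use the same rule with m = 3 and 4.

Likelihoods of a read quartet (the counts of A, C, G, T reads) are multinomial
with the coefficient dropped: every likelihood-ratio statistic and posterior
computed downstream is invariant to it, so dropping it is exact.

Genotypes are represented as sorted strings over "ACGT" whose length is the
ploidy, e.g. ``"AC"``, ``"ACC"``, ``"AACG"``.
"""

from __future__ import annotations

from itertools import combinations_with_replacement
from typing import Iterable, Sequence

import numpy as np
from scipy.special import xlogy

NUCLEOTIDES = "ACGT"
NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

#: Largest admissible error rate: at eps = 3/4 every nucleotide is read with
#: probability 1/4 regardless of the genotype.
MAX_ERROR_RATE = 0.75


def genotype(alleles: Iterable[str]) -> str:
    """Normalize a collection of alleles into a canonical genotype string."""
    g = "".join(sorted(alleles))
    if not 2 <= len(g) <= 4:
        raise ValueError(f"ploidy must be 2, 3 or 4, got genotype {g!r}")
    if any(a not in NUCLEOTIDES for a in g):
        raise ValueError(f"invalid allele in genotype {g!r}")
    return g


def enumerate_genotypes(nucleotides: Sequence[str], ploidy: int) -> list[str]:
    """All genotype multisets of size ``ploidy`` over the given nucleotides."""
    nucs = sorted(set(nucleotides))
    return ["".join(c) for c in combinations_with_replacement(nucs, ploidy)]


def _check_eps(eps: float) -> None:
    if not 0.0 <= eps <= MAX_ERROR_RATE:
        raise ValueError(f"error rate must lie in [0, 3/4], got {eps}")


def read_prob(x: str, G: str, eps: float) -> float:
    """P(read = x | genotype G, error rate eps) under the (k/m) rule."""
    _check_eps(eps)
    m = len(G)
    k = G.count(x)
    return (k / m) * (1.0 - eps) + ((m - k) / m) * (eps / 3.0)


def read_probs(G: str, eps: float) -> np.ndarray:
    """Probabilities of the four nucleotide reads, in A, C, G, T order."""
    _check_eps(eps)
    m = len(G)
    k = np.array([G.count(x) for x in NUCLEOTIDES], dtype=float)
    return (k / m) * (1.0 - eps) + ((m - k) / m) * (eps / 3.0)


def quartet_log_likelihood(q: Sequence[float], G: str, eps: float) -> float:
    """Multinomial log-likelihood of a read quartet (coefficient dropped).

    Returns sum_x n_x * ln P(x | G, eps), with the conventions
    0 * ln 0 = 0 (a zero count never contributes) and ln 0 = -inf when a
    positive count meets a zero probability.  An all-zero quartet has
    log-likelihood 0 for every genotype.
    """
    q = np.asarray(q, dtype=float)
    return float(xlogy(q, read_probs(G, eps)).sum())


def ml_error_rate(q: Sequence[float], G: str) -> float:
    """Exact profile-ML error rate for a genotype given a read quartet.

    The log-likelihood is a sum of c_k * ln(a_k + b_k * eps) terms over the
    multiplicity classes k present in the quartet, with a_k = k/m and
    b_k = 1/3 - 4k/(3m); it is concave on [0, 3/4].  The stationarity
    condition is a polynomial of degree at most 3 in eps, solved exactly;
    the maximizer is picked among its admissible real roots and the interval
    endpoints.  This subsumes the familiar closed forms: (n - n_match)/n for
    homozygotes, (3/2) n_err / n for balanced heterozygotes, the quadratic
    root for unbalanced triploid heterozygotes, and so on.
    """
    q = np.asarray(q, dtype=float)
    if q.sum() == 0:
        return 0.0
    m = len(G)
    # group observed read categories by allele multiplicity in G
    groups: dict[int, float] = {}
    for x, cnt in zip(NUCLEOTIDES, q):
        if cnt > 0:
            k = G.count(x)
            groups[k] = groups.get(k, 0.0) + float(cnt)
    terms = []
    for k, c in groups.items():
        a = k / m
        b = 1.0 / 3.0 - 4.0 * k / (3.0 * m)
        if b != 0.0:  # b == 0 categories (k = m/4) carry no information on eps
            terms.append((a, b, c))
    if not terms:
        return 0.0
    # derivative numerator: sum_i c_i b_i * prod_{j != i} (b_j eps + a_j)
    factors = [np.poly1d([b, a]) for a, b, _ in terms]
    numer = np.poly1d([0.0])
    for i, (_, b, c) in enumerate(terms):
        piece = np.poly1d([c * b])
        for j, f in enumerate(factors):
            if j != i:
                piece = piece * f
        numer = numer + piece
    candidates = [0.0, MAX_ERROR_RATE]
    if numer.order >= 1 or numer[0] != 0.0:
        for r in np.atleast_1d(numer.r):
            if abs(r.imag) < 1e-9 and 0.0 < r.real < MAX_ERROR_RATE:
                candidates.append(float(r.real))
    lls = [quartet_log_likelihood(q, G, e) for e in candidates]
    return candidates[int(np.argmax(lls))]


def profile_log_likelihood(q: Sequence[float], G: str) -> tuple[float, float]:
    """(eps_hat, log-likelihood at eps_hat) for a genotype and quartet."""
    eps = ml_error_rate(q, G)
    return eps, quartet_log_likelihood(q, G, eps)
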
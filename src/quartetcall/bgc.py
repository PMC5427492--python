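"""Bayesian genotype caller (BGC) for low-coverage diploid data.

For an individual with read quartet q at a site with estimated priors
(gamma_hat, eps_hat) over {MM, Mm, mm}, the posterior mass of genotype g is

    post_g = gamma_g * prod_x P_g(x | eps_hat)^(n_x) / (normalizing sum)

and the call is the arg-max genotype.  Reads of nucleotides other than M and
m contribute through the error categories (probability eps/3 under every
genotype); they are not masked.  Genotypes are only called at sites that the
population-level likelihood-ratio test declares significantly polymorphic —
calling at apparently monomorphic sites would mostly reproduce errors.

No-calls: individuals with coverage below ``min_cov`` (default 1, so in
particular zero-coverage individuals are never called), and individuals
whose top two posteriors tie within tolerance.  This caller is biallelic by
construction: a true third allele at a site is folded into the error
categories, which is the documented cost of the biallelic assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp, xlogy

from .error_model import NUC_INDEX, NUCLEOTIDES
from .gfe import PriorsBatch, SitePriors, test_polymorphism

DEFAULT_TIE_TOL = 1e-9


@dataclass
class DiploidCall:
    """Posterior genotype call for one individual at one site."""

    call: str | None  # sorted nucleotide pair, e.g. "AC"; None = no-call
    log_post: np.ndarray  # (3,) log posterior masses for MM, Mm, mm
    reason: str | None = None  # no-call reason


def _genotype_labels(M: str, m: str) -> list[str]:
    return ["".join(sorted(M + M)), "".join(sorted(M + m)), "".join(sorted(m + m))]


def _log_read_prob_matrix(M_idx: np.ndarray, m_idx: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """(S, 3, 4) matrix of ln P_g(x | eps) per site, genotype, nucleotide."""
    S = len(eps)
    e = eps[:, None]
    probs = np.empty((S, 3, 4))
    probs[:, 0, :] = e / 3.0
    probs[:, 1, :] = e / 3.0
    probs[:, 2, :] = e / 3.0
    rows = np.arange(S)
    probs[rows, 0, M_idx] = 1.0 - eps
    probs[rows, 1, M_idx] = 0.5 - eps / 3.0
    probs[rows, 1, m_idx] = 0.5 - eps / 3.0
    probs[rows, 2, m_idx] = 1.0 - eps
    with np.errstate(divide="ignore"):
        return np.log(probs)


def posterior_call(
    q: Sequence[int] | np.ndarray,
    priors: SitePriors,
    min_cov: int = 1,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> DiploidCall:
    """Posterior genotype call for one individual (Bayes over MM/Mm/mm)."""
    gamma = np.asarray(priors.gamma, dtype=float)
    if not (np.all(gamma >= -1e-9) and abs(gamma.sum() - 1.0) < 1e-6):
        raise ValueError("genotype-frequency priors must lie on the simplex")
    arr = np.asarray(getattr(q, "counts", q), dtype=float)
    n = arr.sum()
    if n == 0:
        return DiploidCall(None, np.full(3, np.nan), reason="zero_coverage")
    if n < min_cov:
        return DiploidCall(None, np.full(3, np.nan), reason="low_coverage")
    M_idx = np.array([NUC_INDEX[priors.M]])
    m_idx = np.array([NUC_INDEX[priors.m]])
    logP = _log_read_prob_matrix(M_idx, m_idx, np.array([priors.eps]))[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.array([xlogy(arr, np.exp(logP[g])).sum() for g in range(3)])
        lognum = np.where(gamma > 0, np.log(np.maximum(gamma, 1e-300)) + ll, -np.inf)
    logZ = logsumexp(lognum)
    log_post = lognum - logZ
    order = np.argsort(log_post)
    if log_post[order[2]] - log_post[order[1]] <= tie_tol:
        return DiploidCall(None, log_post, reason="tie")
    labels = _genotype_labels(priors.M, priors.m)
    return DiploidCall(labels[order[2]], log_post, reason=None)


def call_population(
    quartets: np.ndarray,
    priors: PriorsBatch,
    alpha: float = 0.05,
    min_cov: int = 1,
    tie_tol: float = DEFAULT_TIE_TOL,
    chunk: int = 2048,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior calls for an (S, N, 4) stack of sites.

    Returns ``(calls, polymorphic)``: calls is an (S, N) array of sorted
    genotype strings ('' = no-call); sites failing the polymorphism test at
    ``alpha`` are entirely no-call and flagged False in ``polymorphic``.
    """
    quartets = np.asarray(quartets, dtype=float)
    S, N, _ = quartets.shape
    if len(priors) != S:
        raise ValueError(f"priors for {len(priors)} sites but {S} sites of data")
    polymorphic = np.isfinite(priors.p_poly) & (priors.p_poly < alpha)
    calls = np.full((S, N), "", dtype="<U2")

    # per-site genotype labels in A,C,G,T space
    nucs = np.array(list(NUCLEOTIDES))
    pair_idx = np.stack([priors.M_idx, priors.m_idx], axis=1)
    labels = np.empty((S, 3), dtype="<U2")
    Mc, mc = nucs[priors.M_idx], nucs[priors.m_idx]
    labels[:, 0] = np.char.add(Mc, Mc)
    het = np.where(pair_idx[:, 0] < pair_idx[:, 1], np.char.add(Mc, mc), np.char.add(mc, Mc))
    labels[:, 1] = het
    labels[:, 2] = np.char.add(mc, mc)

    with np.errstate(divide="ignore"):
        lgamma = np.where(priors.gamma > 0, np.log(np.maximum(priors.gamma, 1e-300)), -np.inf)
    for start in range(0, S, chunk):
        sl = slice(start, min(start + chunk, S))
        logP = _log_read_prob_matrix(priors.M_idx[sl], priors.m_idx[sl], priors.eps[sl])
        q = quartets[sl]  # (s, N, 4)
        ll = xlogy(q[:, :, None, :], np.exp(logP)[:, None, :, :]).sum(axis=3)
        lognum = ll + lgamma[sl][:, None, :]
        srt = np.sort(lognum, axis=2)
        arg = np.argmax(lognum, axis=2)
        n = q.sum(axis=2)
        ok = (
            (n >= max(min_cov, 1))
            & (srt[:, :, 2] - srt[:, :, 1] > tie_tol)
            & polymorphic[sl][:, None]
        )
        chunk_calls = np.take_along_axis(labels[sl], arg, axis=1)
        calls[sl] = np.where(ok, chunk_calls, "")
    return calls, polymorphic
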
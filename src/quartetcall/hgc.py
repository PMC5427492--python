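"""Prior-free high-coverage diploid genotype caller (HGC).

Each individual is called independently: the candidate genotypes are all
diploid multisets over the nucleotides observed in the individual's read
quartet, each candidate is scored at its own maximum-likelihood error rate,
and the call is the likelihood maximizer (ties -> no-call).  The profile-ML
error rates have closed forms:

    homozygote XX:    eps_hat = (n - n_X) / n
    heterozygote XY:  eps_hat = (3/2) * (n - n_X - n_Y) / n

both clamped to [0, 3/4] (at eps = 3/4 all reads are equiprobable, the
model's uniform limit).

Site-level statistics mirror the population view: with M the most abundant
nucleotide pooled over the sample, each non-MM called genotype is tested
against MM by LRT = 2(LL1 - LL0) ~ chi2(1), each hypothesis at its own ML
error rate; the site is declared polymorphic if at least one such test is
significant.  A significant heterozygote is additionally tested against the
homozygote of the individual's more abundant allele; if not confirmed it is
treated as that homozygote for allele counting (the reported call is left as
the ML genotype).  The number of alleles at a site is the number of distinct
nucleotides in the union of {M} and the significant (refinement-adjusted)
genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import xlogy
from scipy.stats import chi2

from .error_model import (
    MAX_ERROR_RATE,
    NUC_INDEX,
    NUCLEOTIDES,
    enumerate_genotypes,
    quartet_log_likelihood,
)

DEFAULT_MIN_COV = 6
DEFAULT_TIE_TOL = 1e-9


@dataclass
class HgcCall:
    """ML genotype call for one individual, with its likelihood profile."""

    quartet: np.ndarray
    call: str | None
    eps_call: float | None
    ll_profile: dict[str, tuple[float, float]]  # genotype -> (eps_hat, ll)
    reason: str | None = None
    lrt_vs_mm: float | None = None
    significant: bool | None = None
    het_confirmed: bool | None = None


@dataclass
class HgcSiteResult:
    """Site-level summary over a population sample."""

    M: str
    calls: list[HgcCall]
    polymorphic: bool
    n_alleles: int
    alpha: float = 0.05
    counted_nucleotides: set[str] = field(default_factory=set)


def ml_error_rate(q: Sequence[int] | np.ndarray, G: str) -> float:
    """Closed-form profile-ML error rate for a diploid genotype."""
    arr = np.asarray(getattr(q, "counts", q), dtype=float)
    n = arr.sum()
    if n == 0:
        return 0.0
    if len(G) != 2:
        raise ValueError(f"diploid genotype expected, got {G!r}")
    a, b = G[0], G[1]
    if a == b:
        e = (n - arr[NUC_INDEX[a]]) / n
    else:
        e = 1.5 * (n - arr[NUC_INDEX[a]] - arr[NUC_INDEX[b]]) / n
    return float(np.clip(e, 0.0, MAX_ERROR_RATE))


def genotype_profile(q: Sequence[int] | np.ndarray) -> dict[str, tuple[float, float]]:
    """(eps_hat, log-likelihood) for every candidate over observed nucleotides."""
    arr = np.asarray(getattr(q, "counts", q), dtype=float)
    observed = [x for x in NUCLEOTIDES if arr[NUC_INDEX[x]] > 0]
    profile = {}
    for G in enumerate_genotypes(observed, 2):
        eps = ml_error_rate(arr, G)
        profile[G] = (eps, quartet_log_likelihood(arr, G, eps))
    return profile


def call_individual(
    q: Sequence[int] | np.ndarray,
    min_cov: int = DEFAULT_MIN_COV,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> HgcCall:
    """ML genotype call for one individual's read quartet."""
    arr = np.asarray(getattr(q, "counts", q), dtype=float)
    n = arr.sum()
    if n == 0:
        return HgcCall(arr, None, None, {}, reason="zero_coverage")
    if n < min_cov:
        return HgcCall(arr, None, None, {}, reason="low_coverage")
    profile = genotype_profile(arr)
    ranked = sorted(profile.items(), key=lambda kv: kv[1][1], reverse=True)
    if len(ranked) > 1 and ranked[0][1][1] - ranked[1][1][1] <= tie_tol:
        return HgcCall(arr, None, None, profile, reason="tie")
    G, (eps, _) = ranked[0]
    return HgcCall(arr, G, eps, profile)


def _mm_loglik(q: np.ndarray, M: str) -> float:
    """Profile log-likelihood of the population-major homozygote."""
    eps = ml_error_rate(q, M + M)
    return quartet_log_likelihood(q, M + M, eps)


def test_site_polymorphism(
    calls: Sequence[HgcCall], M: str, alpha: float = 0.05
) -> bool:
    """Reject monomorphism if any non-MM call beats MM by the chi2(1) LRT.

    Annotates each call with its ``lrt_vs_mm`` and ``significant`` flags.
    """
    crit = chi2.isf(alpha, df=1)
    mm = "".join(sorted(M + M))
    any_sig = False
    for c in calls:
        if c.call is None or c.call == mm:
            c.lrt_vs_mm = None if c.call is None else 0.0
            c.significant = False
            continue
        ll1 = c.ll_profile[c.call][1]
        ll0 = _mm_loglik(c.quartet, M)
        c.lrt_vs_mm = max(2.0 * (ll1 - ll0), 0.0)
        c.significant = c.lrt_vs_mm > crit
        any_sig = any_sig or c.significant
    return any_sig


def refine_heterozygote(
    q: Sequence[int] | np.ndarray, call: str, alpha: float = 0.05
) -> bool:
    """Confirm a called heterozygote against the more-abundant homozygote.

    True iff 2 * [LL(het) - LL(homozygote of the individual's more abundant
    allele)] exceeds the chi2(1) critical value at ``alpha``.
    """
    arr = np.asarray(getattr(q, "counts", q), dtype=float)
    if len(set(call)) != 2:
        raise ValueError("refinement applies to heterozygous calls only")
    a, b = call[0], call[1]
    top = a if arr[NUC_INDEX[a]] >= arr[NUC_INDEX[b]] else b
    e_het = ml_error_rate(arr, call)
    ll_het = quartet_log_likelihood(arr, call, e_het)
    e_hom = ml_error_rate(arr, top + top)
    ll_hom = quartet_log_likelihood(arr, top + top, e_hom)
    lrt = max(2.0 * (ll_het - ll_hom), 0.0)
    return lrt > chi2.isf(alpha, df=1)


def count_alleles(calls: Sequence[HgcCall], M: str, alpha: float = 0.05) -> int:
    """Number of alleles: nucleotides of M plus significant genotypes.

    Unconfirmed heterozygotes are counted as the homozygote of their more
    abundant allele; the reported individual call itself is not changed.
    """
    nucs = {M}
    mm = "".join(sorted(M + M))
    for c in calls:
        if c.call is None or c.call == mm or not c.significant:
            continue
        if len(set(c.call)) == 2:
            c.het_confirmed = refine_heterozygote(c.quartet, c.call, alpha)
            if c.het_confirmed:
                nucs.update(c.call)
            else:
                a, b = c.call[0], c.call[1]
                arr = c.quartet
                nucs.add(a if arr[NUC_INDEX[a]] >= arr[NUC_INDEX[b]] else b)
        else:
            nucs.add(c.call[0])
    return len(nucs)


def call_site(
    quartets: np.ndarray,
    alpha: float = 0.05,
    min_cov: int = DEFAULT_MIN_COV,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> HgcSiteResult:
    """Call every individual at a site and run the site-level tests."""
    quartets = np.asarray(quartets, dtype=float)
    pooled = quartets.sum(axis=0)
    if pooled.sum() == 0:
        return HgcSiteResult(M="N", calls=[], polymorphic=False, n_alleles=0, alpha=alpha)
    M = NUCLEOTIDES[int(np.argsort(-pooled, kind="stable")[0])]
    calls = [call_individual(q, min_cov=min_cov, tie_tol=tie_tol) for q in quartets]
    polymorphic = test_site_polymorphism(calls, M, alpha)
    n_alleles = count_alleles(calls, M, alpha) if polymorphic else 1
    return HgcSiteResult(M=M, calls=calls, polymorphic=polymorphic, n_alleles=n_alleles, alpha=alpha)


# ---------------------------------------------------------------------------
# vectorized population calling (used for large simulation studies)

_CANDIDATES = enumerate_genotypes(NUCLEOTIDES, 2)  # all 10 diploid genotypes


def call_quartets(
    quartets: np.ndarray,
    min_cov: int = DEFAULT_MIN_COV,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> np.ndarray:
    """Vectorized ML calls for an (..., 4) array of read quartets.

    Returns an array of genotype strings with '' for no-call.  Agrees with
    :func:`call_individual` element-wise (checked by the test suite).
    """
    q = np.asarray(quartets, dtype=float)
    n = q.sum(axis=-1)
    lls = np.full(q.shape[:-1] + (len(_CANDIDATES),), -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        for gi, G in enumerate(_CANDIDATES):
            a, b = G[0], G[1]
            ia, ib = NUC_INDEX[a], NUC_INDEX[b]
            if a == b:
                match = q[..., ia]
                valid = match > 0
                e = np.where(n > 0, (n - match) / np.maximum(n, 1), 0.0)
                e = np.clip(e, 0.0, MAX_ERROR_RATE)
                ll = xlogy(match, 1.0 - e) + xlogy(n - match, e / 3.0)
            else:
                match = q[..., ia] + q[..., ib]
                valid = (q[..., ia] > 0) & (q[..., ib] > 0)
                e = np.where(n > 0, 1.5 * (n - match) / np.maximum(n, 1), 0.0)
                e = np.clip(e, 0.0, MAX_ERROR_RATE)
                ll = xlogy(match, 0.5 - e / 3.0) + xlogy(n - match, e / 3.0)
            lls[..., gi] = np.where(valid, ll, -np.inf)
    srt = np.sort(lls, axis=-1)
    best, second = srt[..., -1], srt[..., -2]
    arg = np.argmax(lls, axis=-1)
    with np.errstate(invalid="ignore"):
        gap = best - second  # inf - inf -> nan only where nothing is callable
    callable_ = (n >= max(min_cov, 1)) & np.isfinite(best) & (gap > tie_tol)
    cand = np.array(_CANDIDATES, dtype="<U2")
    return np.where(callable_, cand[arg], "")
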
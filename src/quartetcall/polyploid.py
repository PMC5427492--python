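"""Triploid (TRI) and tetraploid (TET) genotype callers.

These extend the prior-free high-coverage caller to genotype multisets of
size 3 and 4: candidates are all multisets over the nucleotides observed in
the individual's quartet, each scored at its own profile-ML error rate under
the (k/m) read model, and the likelihood maximizer is called (ties ->
no-call).  The same likelihood-ratio machinery applies: monomorphism is
tested against the homozygote of the population-major nucleotide, and
significant heterozygotes are confirmed against the homozygote of the
individual's most abundant allele, chi-square with 1 df in both cases.

Closed-form error-rate estimators exist for many genotype classes (for
example (n - n_match)/n for homozygotes, 3 n_err / n for a triploid
three-nucleotide heterozygote, the quadratic root for an unbalanced
triploid two-nucleotide heterozygote); ``poly_ml_error_rate`` returns the
exact profile maximizer for every class by solving the polynomial
stationarity condition of the concave log-likelihood, which reproduces each
closed form.  Accurate polyploid calling needs substantially higher coverage
than diploid calling (all chromosomes must be sampled, and allele dosage —
e.g. AAC vs ACC — is hard to resolve); the default minimum coverage matches
the diploid caller and no hard floor is imposed.

At ploidy 2 the machinery reduces exactly to the diploid HGC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .error_model import (
    NUC_INDEX,
    NUCLEOTIDES,
    enumerate_genotypes,
    ml_error_rate as _generic_ml_eps,
    profile_log_likelihood,
    quartet_log_likelihood,
)

DEFAULT_MIN_COV = 6
DEFAULT_TIE_TOL = 1e-9

_CLASS_LABELS = {1: "homozygote", 2: "2-nucleotide het", 3: "3-nucleotide het", 4: "4-nucleotide het"}


@dataclass
class PolyploidCall:
    """ML polyploid genotype call for one individual."""

    quartet: np.ndarray
    ploidy: int
    call: str | None
    eps_call: float | None
    ll_profile: dict[str, tuple[float, float]]
    reason: str | None = None
    lrt_vs_mm: float | None = None
    significant: bool | None = None
    het_confirmed: bool | None = None

    @property
    def genotype_class(self) -> str | None:
        if self.call is None:
            return None
        return _CLASS_LABELS[len(set(self.call))]


def poly_ml_error_rate(q: Sequence[int] | np.ndarray, G: str) -> float:
    """Exact profile-ML error rate for any genotype of ploidy 2, 3 or 4."""
    return _generic_ml_eps(np.asarray(getattr(q, "counts", q), dtype=float), G)


def call_polyploid(
    q: Sequence[int] | np.ndarray,
    ploidy: int,
    min_cov: int = DEFAULT_MIN_COV,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> PolyploidCall:
    """ML genotype call over all multisets of observed nucleotides."""
    if ploidy not in (2, 3, 4):
        raise ValueError("ploidy must be 2, 3 or 4")
    arr = np.asarray(getattr(q, "counts", q), dtype=float)
    n = arr.sum()
    if n == 0:
        return PolyploidCall(arr, ploidy, None, None, {}, reason="zero_coverage")
    if n < min_cov:
        return PolyploidCall(arr, ploidy, None, None, {}, reason="low_coverage")
    observed = [x for x in NUCLEOTIDES if arr[NUC_INDEX[x]] > 0]
    profile = {}
    for G in enumerate_genotypes(observed, ploidy):
        profile[G] = profile_log_likelihood(arr, G)
    ranked = sorted(profile.items(), key=lambda kv: kv[1][1], reverse=True)
    if len(ranked) > 1 and ranked[0][1][1] - ranked[1][1][1] <= tie_tol:
        return PolyploidCall(arr, ploidy, None, None, profile, reason="tie")
    G, (eps, _) = ranked[0]
    return PolyploidCall(arr, ploidy, G, eps, profile)


def _hom_loglik(q: np.ndarray, x: str, ploidy: int) -> float:
    G = x * ploidy
    return quartet_log_likelihood(q, G, _generic_ml_eps(q, G))


def test_site_polymorphism(
    calls: Sequence[PolyploidCall], M: str, alpha: float = 0.05
) -> bool:
    """Reject monomorphism if any non-M-homozygote call beats it, chi2(1)."""
    crit = chi2.isf(alpha, df=1)
    any_sig = False
    for c in calls:
        mm = M * c.ploidy
        if c.call is None or c.call == mm:
            c.lrt_vs_mm = None if c.call is None else 0.0
            c.significant = False
            continue
        ll1 = c.ll_profile[c.call][1]
        ll0 = _hom_loglik(c.quartet, M, c.ploidy)
        c.lrt_vs_mm = max(2.0 * (ll1 - ll0), 0.0)
        c.significant = c.lrt_vs_mm > crit
        any_sig = any_sig or c.significant
    return any_sig


def refine_heterozygote(
    q: Sequence[int] | np.ndarray, call: str, ploidy: int, alpha: float = 0.05
) -> bool:
    """Confirm a heterozygous call against its most-abundant-allele homozygote."""
    arr = np.asarray(getattr(q, "counts", q), dtype=float)
    alleles = sorted(set(call))
    if len(alleles) < 2:
        raise ValueError("refinement applies to heterozygous calls only")
    top = max(alleles, key=lambda x: (arr[NUC_INDEX[x]], -NUC_INDEX[x]))
    ll_het = quartet_log_likelihood(arr, call, _generic_ml_eps(arr, call))
    ll_hom = _hom_loglik(arr, top, ploidy)
    lrt = max(2.0 * (ll_het - ll_hom), 0.0)
    return lrt > chi2.isf(alpha, df=1)


def count_alleles(calls: Sequence[PolyploidCall], M: str, alpha: float = 0.05) -> int:
    """Allele count from the union of M and significant genotypes."""
    nucs = {M}
    for c in calls:
        if c.call is None or not c.significant:
            continue
        if len(set(c.call)) >= 2:
            c.het_confirmed = refine_heterozygote(c.quartet, c.call, c.ploidy, alpha)
            if c.het_confirmed:
                nucs.update(c.call)
            else:
                arr = c.quartet
                alleles = sorted(set(c.call))
                nucs.add(max(alleles, key=lambda x: (arr[NUC_INDEX[x]], -NUC_INDEX[x])))
        else:
            nucs.add(c.call[0])
    return len(nucs)


@dataclass
class PolyploidSiteResult:
    M: str
    calls: list[PolyploidCall]
    polymorphic: bool
    n_alleles: int
    alpha: float = 0.05


def call_site(
    quartets: np.ndarray,
    ploidy: int,
    alpha: float = 0.05,
    min_cov: int = DEFAULT_MIN_COV,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> PolyploidSiteResult:
    """Call every individual at a site and run the site-level tests."""
    quartets = np.asarray(quartets, dtype=float)
    pooled = quartets.sum(axis=0)
    if pooled.sum() == 0:
        return PolyploidSiteResult("N", [], False, 0, alpha)
    M = NUCLEOTIDES[int(np.argsort(-pooled, kind="stable")[0])]
    calls = [call_polyploid(q, ploidy, min_cov=min_cov, tie_tol=tie_tol) for q in quartets]
    polymorphic = test_site_polymorphism(calls, M, alpha)
    n_alleles = count_alleles(calls, M, alpha) if polymorphic else 1
    return PolyploidSiteResult(M, calls, polymorphic, n_alleles, alpha)
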
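"""Population-level ML estimation of genotype frequencies and error rate.

At each site the two most abundant nucleotides pooled over the population are
the candidate major (M) and minor (m) alleles.  The per-site model is a
three-component finite mixture over the diploid genotypes MM, Mm, mm with
mixing weights (genotype frequencies) gamma = (gamma1, gamma2, gamma3) on the
simplex and a shared error rate eps:

    ln L(gamma, eps) = sum_i ln sum_g gamma_g * L_i(g, eps)

where L_i(g, eps) is the (coefficient-free) multinomial likelihood of
individual i's read quartet, collapsed to the three categories
(M reads, m reads, other reads).  Reads that are neither M nor m are kept as
error categories, never discarded.  No mating-system assumption is made:
gamma is free on the simplex, so any inbreeding coefficient (including
negative f, i.e. heterozygote excess) is representable.

The maximum is found by EM over genotype memberships.  Both M-steps are
exact: the weight update is the responsibility mean and the error-rate update
solves a quadratic stationarity condition in closed form.  Three starting
points guard against local optima.  The minor-allele frequency estimate is
q_hat = gamma3_hat + gamma2_hat / 2 — obtained without calling genotypes,
which is what keeps it unbiased at low coverage.

Polymorphism is tested per site by a likelihood-ratio test against the null
of monomorphism (the site fixed for M: gamma1 = 1, eps free, whose ML is the
closed-form homozygote fit), with the statistic referred to a chi-square
distribution with 2 degrees of freedom (gamma2, gamma3 freed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, xlogy
from scipy.stats import chi2

from .error_model import MAX_ERROR_RATE, NUCLEOTIDES
from .quartet_io import SiteRecord

_EM_TOL = 1e-10
_EM_MAX_ITER = 1000


@dataclass
class SitePriors:
    """Site-level ML estimates used as Bayes priors by the low-coverage caller."""

    M: str
    m: str
    gamma: np.ndarray  # (3,) frequencies of MM, Mm, mm
    eps: float
    ll_full: float
    ll_null: float
    lrt_poly: float
    p_poly: float
    converged: bool = True

    @property
    def qhat(self) -> float:
        """Minor-allele frequency estimate gamma3 + gamma2/2."""
        return float(self.gamma[2] + self.gamma[1] / 2.0)


class PriorsBatch:
    """Vectorized per-site priors for a stack of sites (arrays of length S)."""

    def __init__(self, M_idx, m_idx, gamma, eps, ll_full, ll_null, lrt_poly, p_poly, converged):
        self.M_idx = M_idx
        self.m_idx = m_idx
        self.gamma = gamma
        self.eps = eps
        self.ll_full = ll_full
        self.ll_null = ll_null
        self.lrt_poly = lrt_poly
        self.p_poly = p_poly
        self.converged = converged

    def __len__(self) -> int:
        return len(self.eps)

    @property
    def qhat(self) -> np.ndarray:
        return self.gamma[:, 2] + self.gamma[:, 1] / 2.0

    def __getitem__(self, i: int) -> SitePriors:
        return SitePriors(
            M=NUCLEOTIDES[self.M_idx[i]],
            m=NUCLEOTIDES[self.m_idx[i]],
            gamma=self.gamma[i].copy(),
            eps=float(self.eps[i]),
            ll_full=float(self.ll_full[i]),
            ll_null=float(self.ll_null[i]),
            lrt_poly=float(self.lrt_poly[i]),
            p_poly=float(self.p_poly[i]),
            converged=bool(self.converged[i]),
        )


def identify_major_minor(site: SiteRecord | np.ndarray) -> tuple[str, str]:
    """Major and minor nucleotides: largest and second-largest pooled counts.

    Ties break alphabetically (A < C < G < T); with fewer than two observed
    nucleotides the minor is the alphabetically first unobserved one.
    """
    arr = site.as_array() if isinstance(site, SiteRecord) else np.asarray(site)
    pooled = arr.reshape(-1, 4).sum(axis=0)
    if pooled.sum() == 0:
        raise ValueError("zero total coverage at site; skip it")
    order = np.argsort(-pooled, kind="stable")  # stable: ties stay alphabetical
    return NUCLEOTIDES[order[0]], NUCLEOTIDES[order[1]]


def _major_minor_batch(quartets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pooled = quartets.sum(axis=1)  # (S, 4)
    order = np.argsort(-pooled, axis=1, kind="stable")
    return order[:, 0], order[:, 1]


def _collapse_counts(quartets: np.ndarray, M_idx: np.ndarray, m_idx: np.ndarray) -> np.ndarray:
    """(S, N, 4) quartets -> (S, N, 3) counts of (M reads, m reads, other)."""
    S, N, _ = quartets.shape
    cM = np.take_along_axis(quartets, M_idx[:, None, None], axis=2)[:, :, 0]
    cm = np.take_along_axis(quartets, m_idx[:, None, None], axis=2)[:, :, 0]
    ce = quartets.sum(axis=2) - cM - cm
    return np.stack([cM, cm, ce], axis=2).astype(float)


def _genotype_loglik(c3: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """(S, N, 3) collapsed counts, (S,) eps -> (S, N, 3) log L_i(g, eps)."""
    cM, cm, ce = c3[..., 0], c3[..., 1], c3[..., 2]
    e = eps[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll1 = xlogy(cM, 1.0 - e) + xlogy(cm + ce, e / 3.0)
        ll2 = xlogy(cM + cm, 0.5 - e / 3.0) + xlogy(ce, e / 3.0)
        ll3 = xlogy(cm, 1.0 - e) + xlogy(cM + ce, e / 3.0)
    return np.stack([ll1, ll2, ll3], axis=2)


def _mixture_loglik(c3: np.ndarray, gamma: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Per-site mixture log-likelihood, summed over individuals: (S,)."""
    llg = _genotype_loglik(c3, eps)  # (S, N, 3)
    with np.errstate(divide="ignore"):
        lg = np.log(gamma)[:, None, :]
    return logsumexp(llg + lg, axis=2).sum(axis=1)


def _eps_mstep(w_hom: np.ndarray, w_het: np.ndarray, w_err: np.ndarray) -> np.ndarray:
    """Exact error-rate M-step.

    Maximizes w_hom*ln(1-e) + w_het*ln(1/2 - e/3) + w_err*ln(e/3); the
    stationarity condition is
    T e^2 - (5/2 w_err + 3/2 w_hom + w_het) e + 3/2 w_err = 0 with
    T = w_hom + w_het + w_err; the smaller root is the maximizer.
    """
    T = w_hom + w_het + w_err
    b = 2.5 * w_err + 1.5 * w_hom + w_het
    c = 1.5 * w_err
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = np.sqrt(np.maximum(b * b - 4.0 * T * c, 0.0))
        e = np.where(T > 0, (b - disc) / (2.0 * T), 0.0)
    return np.clip(e, 0.0, MAX_ERROR_RATE)


def _run_em(c3: np.ndarray, gamma0: np.ndarray, eps0: np.ndarray):
    """EM on a batch of sites; returns (gamma, eps, ll, converged)."""
    S = c3.shape[0]
    gamma = gamma0.copy()
    eps = eps0.copy()
    ll = _mixture_loglik(c3, gamma, eps)
    converged = np.zeros(S, dtype=bool)
    active = np.arange(S)
    for _ in range(_EM_MAX_ITER):
        if active.size == 0:
            break
        ca = c3[active]
        ga = gamma[active]
        ea = eps[active]
        llg = _genotype_loglik(ca, ea)
        with np.errstate(divide="ignore"):
            lognum = llg + np.log(ga)[:, None, :]
        logZ = logsumexp(lognum, axis=2, keepdims=True)
        with np.errstate(invalid="ignore"):
            r = np.exp(lognum - logZ)  # (s, N, 3) responsibilities
        # zero-coverage individuals have uniform-in-prior responsibilities
        # already (ll_g = 0 for all g), which leaves the fixed point intact.
        r = np.where(np.isfinite(logZ), r, ga[:, None, :])
        gamma_new = r.mean(axis=1)
        cM, cm, ce = ca[..., 0], ca[..., 1], ca[..., 2]
        w_hom = (r[..., 0] * cM + r[..., 2] * cm).sum(axis=1)
        w_het = (r[..., 1] * (cM + cm)).sum(axis=1)
        w_err = (
            r[..., 0] * (cm + ce) + r[..., 1] * ce + r[..., 2] * (cM + ce)
        ).sum(axis=1)
        eps_new = _eps_mstep(w_hom, w_het, w_err)
        ll_new = _mixture_loglik(ca, gamma_new, eps_new)
        done = np.abs(ll_new - ll[active]) < _EM_TOL
        gamma[active] = gamma_new
        eps[active] = eps_new
        ll[active] = ll_new
        converged[active[done]] = True
        active = active[~done]
    return gamma, eps, ll, converged


def _null_fit(c3: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Monomorphic null (site fixed for M, eps free): closed-form ML.

    eps0_hat = (non-M reads)/(total reads); returns (eps0, ll0) per site.
    """
    cM = c3[..., 0].sum(axis=1)
    cother = (c3[..., 1] + c3[..., 2]).sum(axis=1)
    tot = cM + cother
    with np.errstate(divide="ignore", invalid="ignore"):
        eps0 = np.where(tot > 0, cother / tot, 0.0)
    eps0 = np.clip(eps0, 0.0, MAX_ERROR_RATE)
    ll0 = xlogy(cM, 1.0 - eps0) + xlogy(cother, eps0 / 3.0)
    return eps0, ll0


def _initial_points(c3: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Three EM starting points per site."""
    S, N, _ = c3.shape
    cM, cm = c3[..., 0], c3[..., 1]
    n = c3.sum(axis=2)
    covered = n > 0
    # 1. naive genotype proportions from per-individual majority reads
    is_het = (cM > 0) & (cm > 0)
    is_mm = (cm > 0) & (cM == 0)
    denom = np.maximum(covered.sum(axis=1), 1)
    g2 = (is_het & covered).sum(axis=1) / denom
    g3 = (is_mm & covered).sum(axis=1) / denom
    naive = np.stack([1.0 - g2 - g3, g2, g3], axis=1)
    # 2. Hardy-Weinberg from the pooled minor-read fraction
    tot_al = np.maximum((cM + cm).sum(axis=1), 1.0)
    qr = cm.sum(axis=1) / tot_al
    hwe = np.stack([(1 - qr) ** 2, 2 * qr * (1 - qr), qr**2], axis=1)
    # 3. near-monomorphic corner
    mono = np.tile(np.array([0.98, 0.015, 0.005]), (S, 1))
    inits = []
    for g in (naive, hwe, mono):
        g = np.clip(g, 1e-6, None)
        g = g / g.sum(axis=1, keepdims=True)
        inits.append((g, np.full(S, 0.005)))
    return inits


def estimate_priors_batch(quartets: np.ndarray) -> PriorsBatch:
    """ML genotype-frequency/error-rate estimation for a stack of sites.

    ``quartets`` is an (S, N, 4) array of read counts.  Sites with zero total
    coverage get gamma = (1, 0, 0), eps = 0 and an undefined (NaN) test.
    """
    quartets = np.asarray(quartets)
    if quartets.ndim != 3 or quartets.shape[2] != 4:
        raise ValueError("quartets must have shape (S, N, 4)")
    S = quartets.shape[0]
    M_idx, m_idx = _major_minor_batch(quartets)
    c3 = _collapse_counts(quartets, M_idx, m_idx)

    best_g = np.tile(np.array([1.0, 0.0, 0.0]), (S, 1))
    best_e = np.zeros(S)
    best_ll = np.full(S, -np.inf)
    best_conv = np.ones(S, dtype=bool)
    for g0, e0 in _initial_points(c3):
        g, e, ll, conv = _run_em(c3, g0, e0)
        better = ll > best_ll
        best_g[better] = g[better]
        best_e[better] = e[better]
        best_conv[better] = conv[better]
        best_ll[better] = ll[better]

    eps0, ll0 = _null_fit(c3)
    lrt = np.maximum(2.0 * (best_ll - ll0), 0.0)
    p = chi2.sf(lrt, df=2)

    empty = quartets.sum(axis=(1, 2)) == 0
    if empty.any():
        best_g[empty] = np.array([1.0, 0.0, 0.0])
        best_e[empty] = 0.0
        best_ll[empty] = 0.0
        lrt[empty] = 0.0
        p[empty] = np.nan
    return PriorsBatch(M_idx, m_idx, best_g, best_e, best_ll, ll0, lrt, p, best_conv)


def estimate_site_priors(site: SiteRecord | np.ndarray) -> SitePriors:
    """Per-site convenience wrapper around :func:`estimate_priors_batch`."""
    arr = site.as_array() if isinstance(site, SiteRecord) else np.asarray(site)
    batch = estimate_priors_batch(arr[None, :, :])
    return batch[0]


def test_polymorphism(priors: SitePriors, alpha: float = 0.05) -> bool:
    """True iff the site is significantly polymorphic at level ``alpha``."""
    return bool(np.isfinite(priors.p_poly) and priors.p_poly < alpha)
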
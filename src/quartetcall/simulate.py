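"""Synthetic read-quartet data with recorded truth.

The generative model matches the probabilistic model the callers assume:
each individual's genotype is drawn from its population frequency, the
depth of coverage is Poisson with mean ``mu`` (or fixed), each read picks a
chromosome of the genotype uniformly, and is miscalled with probability
``eps`` to one of the other three nucleotides uniformly.  Conditional on
genotype and coverage, a quartet is therefore Multinomial(n, P(. | G, eps))
with the same (k/m) read probabilities the callers use.

Population modes:

* biallelic diploid: genotype frequencies (gamma1, gamma2, gamma3) over
  (MM, Mm, mm) with fixed allele identities M = A, m = C by default (callers
  must not care which nucleotides play the roles — tested by permutation);
* triallelic diploid: allele frequencies (p, q, r) on three nucleotides
  under Hardy-Weinberg equilibrium (six genotypes);
* single individual: an explicit genotype of any ploidy at fixed coverage.

One seeded generator drives a run; sites and individuals are consumed in a
fixed order, so a seed reproduces quartets and truth exactly.  Coverage is
not truncated: zero-coverage individuals occur and are the callers'
missing-data case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .error_model import NUCLEOTIDES, read_probs
from .quartet_io import ReadQuartet, SiteRecord


@dataclass
class SimResult:
    """Simulated quartets with recorded truth."""

    quartets: np.ndarray  # (S, N, 4) int64 read counts
    truth: np.ndarray  # (S, N) genotype strings (sorted multisets)
    genotype_freqs: np.ndarray  # population frequencies used
    genotype_labels: list[str]
    params: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.quartets.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.quartets.shape[1]

    def to_site_records(self, seq_id: str = "sim") -> list[SiteRecord]:
        out = []
        for s in range(self.n_sites):
            qs = [ReadQuartet(*map(int, self.quartets[s, i])) for i in range(self.n_individuals)]
            out.append(SiteRecord(seq_id=seq_id, pos=s + 1, ref="N", quartets=qs))
        return out


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _draw_quartets(
    genotype_idx: np.ndarray,
    coverage: np.ndarray,
    genotypes: list[str],
    eps: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial quartets grouped by genotype class (fixed group order)."""
    quartets = np.zeros(genotype_idx.shape + (4,), dtype=np.int64)
    for gi, G in enumerate(genotypes):
        mask = genotype_idx == gi
        if not mask.any():
            continue
        p = read_probs(G, eps)
        quartets[mask] = rng.multinomial(coverage[mask], p)
    return quartets


def simulate_biallelic_sites(
    n_sites: int,
    n_individuals: int,
    gamma1: float,
    gamma3: float,
    mean_cov: float,
    error_rate: float,
    rng: np.random.Generator | int | None = None,
    major: str = "A",
    minor: str = "C",
    fixed_cov: int | None = None,
) -> SimResult:
    """Biallelic diploid population sites with genotype frequencies gamma."""
    gamma2 = 1.0 - gamma1 - gamma3
    if gamma2 < -1e-12 or gamma1 < 0 or gamma3 < 0:
        raise ValueError("genotype frequencies must lie on the simplex")
    gamma2 = max(gamma2, 0.0)
    rng = _as_rng(rng)
    genotypes = ["".join(sorted(major + major)), "".join(sorted(major + minor)), "".join(sorted(minor + minor))]
    freqs = np.array([gamma1, gamma2, gamma3])
    gidx = rng.choice(3, size=(n_sites, n_individuals), p=freqs)
    if fixed_cov is not None:
        cov = np.full((n_sites, n_individuals), int(fixed_cov), dtype=np.int64)
    else:
        cov = rng.poisson(mean_cov, size=(n_sites, n_individuals))
    quartets = _draw_quartets(gidx, cov, genotypes, error_rate, rng)
    truth = np.array(genotypes, dtype="<U4")[gidx]
    return SimResult(
        quartets,
        truth,
        freqs,
        genotypes,
        params=dict(
            mode="biallelic",
            gamma=(gamma1, gamma2, gamma3),
            mean_cov=mean_cov,
            fixed_cov=fixed_cov,
            error_rate=error_rate,
            alleles=(major, minor),
        ),
    )


def simulate_triallelic_sites(
    n_sites: int,
    n_individuals: int,
    p: float,
    q: float,
    r: float,
    mean_cov: float,
    error_rate: float,
    rng: np.random.Generator | int | None = None,
    alleles: tuple[str, str, str] = ("A", "C", "G"),
    fixed_cov: int | None = None,
) -> SimResult:
    """Triallelic diploid sites under HWE with allele frequencies (p, q, r)."""
    if abs(p + q + r - 1.0) > 1e-9 or min(p, q, r) < 0:
        raise ValueError("allele frequencies must sum to 1 and be non-negative")
    rng = _as_rng(rng)
    a1, a2, a3 = alleles
    genotypes = [
        "".join(sorted(a1 + a1)),
        "".join(sorted(a1 + a2)),
        "".join(sorted(a1 + a3)),
        "".join(sorted(a2 + a2)),
        "".join(sorted(a2 + a3)),
        "".join(sorted(a3 + a3)),
    ]
    freqs = np.array([p * p, 2 * p * q, 2 * p * r, q * q, 2 * q * r, r * r])
    gidx = rng.choice(6, size=(n_sites, n_individuals), p=freqs)
    if fixed_cov is not None:
        cov = np.full((n_sites, n_individuals), int(fixed_cov), dtype=np.int64)
    else:
        cov = rng.poisson(mean_cov, size=(n_sites, n_individuals))
    quartets = _draw_quartets(gidx, cov, genotypes, error_rate, rng)
    truth = np.array(genotypes, dtype="<U4")[gidx]
    return SimResult(
        quartets,
        truth,
        freqs,
        genotypes,
        params=dict(
            mode="triallelic",
            allele_freqs=(p, q, r),
            mean_cov=mean_cov,
            fixed_cov=fixed_cov,
            error_rate=error_rate,
            alleles=alleles,
        ),
    )


def simulate_individual(
    genotype: str,
    coverage: int,
    error_rate: float,
    rng: np.random.Generator | int | None = None,
) -> ReadQuartet:
    """A single quartet: ``coverage`` reads drawn from one genotype."""
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    rng = _as_rng(rng)
    counts = rng.multinomial(int(coverage), read_probs(genotype, error_rate))
    return ReadQuartet(*map(int, counts))


def simulate_individuals(
    genotype: str,
    coverage: int,
    error_rate: float,
    rng: np.random.Generator | int | None = None,
    n_reps: int = 1000,
) -> np.ndarray:
    """(n_reps, 4) quartets from one genotype at fixed coverage."""
    rng = _as_rng(rng)
    return rng.multinomial(int(coverage), read_probs(genotype, error_rate), size=n_reps)
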
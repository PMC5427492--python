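"""Population read-quartet ("pro") file I/O, site filters and call tables.

Dialect
-------
A pro file is a tab-separated text file with one header line::

    #seq	pos	ref	q_1	...	q_N

followed by one line per site: sequence name, 1-based position, reference
nucleotide (or ``N`` when unknown), then one quartet per individual written
as ``nA,nC,nG,nT`` in fixed A, C, G, T order.  Individual order is fixed
across sites.

Site filters
------------
Population-genomic practice excludes sites whose total (population) coverage
is far from the mean, which flags collapsed repeats and dropped regions: a
site is kept iff its population coverage lies within
``[lo_frac * mean, hi_frac * mean]`` (inclusive on both ends; defaults 0.5
and 1.5).  Individuals with coverage below ``min_ind_cov`` (default 6) are
flagged uncallable for the prior-free callers but the site is retained.
A post-hoc filter on the mean per-individual error-rate estimate of called
genotypes (> 0.01 suggests mismapping) is provided as a helper to apply
after high-coverage calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .error_model import NUCLEOTIDES


class ProFileError(ValueError):
    """Malformed pro-file content; the message names the offending line."""


@dataclass(frozen=True)
class ReadQuartet:
    """Read counts of A, C, G, T for one individual at one site."""

    nA: int
    nC: int
    nG: int
    nT: int

    def __post_init__(self) -> None:
        for c in self.counts:
            if c < 0:
                raise ValueError(f"negative read count in quartet {self.counts}")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.nA, self.nC, self.nG, self.nT)

    @property
    def n(self) -> int:
        """Depth of coverage: total reads."""
        return sum(self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass
class SiteRecord:
    """One genomic site: identifier plus one read quartet per individual."""

    seq_id: str
    pos: int
    ref: str
    quartets: list[ReadQuartet]

    @property
    def n_individuals(self) -> int:
        return len(self.quartets)

    @property
    def pop_coverage(self) -> int:
        return sum(q.n for q in self.quartets)

    def as_array(self) -> np.ndarray:
        """(N, 4) array of read counts."""
        return np.asarray([q.counts for q in self.quartets], dtype=np.int64)


@dataclass
class SiteFilterConfig:
    """Site-level filter thresholds."""

    min_ind_cov: int = 6
    pop_cov_lo_frac: float = 0.5
    pop_cov_hi_frac: float = 1.5
    max_mean_error: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.pop_cov_lo_frac < self.pop_cov_hi_frac:
            raise ValueError("require 0 <= lo_frac < hi_frac")
        if self.min_ind_cov < 1:
            raise ValueError("min_ind_cov must be >= 1")


@dataclass
class SiteFilterMask:
    """Outcome of filtering one site."""

    kept: bool
    reason: str | None
    #: per-individual flag: True where coverage < min_ind_cov (uncallable for
    #: the prior-free callers; the individual's data are retained).
    uncallable: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


def _parse_quartet(token: str, lineno: int) -> ReadQuartet:
    parts = token.split(",")
    if len(parts) != 4:
        raise ProFileError(f"line {lineno}: quartet {token!r} does not have 4 fields")
    try:
        counts = [int(p) for p in parts]
    except ValueError as exc:
        raise ProFileError(f"line {lineno}: non-integer count in {token!r}") from exc
    if any(c < 0 for c in counts):
        raise ProFileError(f"line {lineno}: negative count in {token!r}")
    return ReadQuartet(*counts)


def read_pro_file(path: str | Path, N: int) -> Iterator[SiteRecord]:
    """Yield SiteRecords from a pro file declaring ``N`` individuals."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + N:
                raise ProFileError(
                    f"line {lineno}: expected {3 + N} fields "
                    f"(seq, pos, ref, {N} quartets), got {len(fields)}"
                )
            seq_id, pos_s, ref = fields[:3]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ProFileError(f"line {lineno}: bad position {pos_s!r}") from exc
            quartets = [_parse_quartet(tok, lineno) for tok in fields[3:]]
            yield SiteRecord(seq_id=seq_id, pos=pos, ref=ref, quartets=quartets)


def write_pro_file(path: str | Path, sites: Iterable[SiteRecord]) -> None:
    """Write SiteRecords in the pro dialect (exact count round-trip)."""
    sites = list(sites)
    n = sites[0].n_individuals if sites else 0
    with open(path, "w") as fh:
        header = ["#seq", "pos", "ref"] + [f"q_{i + 1}" for i in range(n)]
        fh.write("\t".join(header) + "\n")
        for s in sites:
            toks = [s.seq_id, str(s.pos), s.ref]
            toks += [",".join(str(c) for c in q.counts) for q in s.quartets]
            fh.write("\t".join(toks) + "\n")


def apply_site_filters(
    sites: Sequence[SiteRecord],
    cfg: SiteFilterConfig | None = None,
    mean_pop_cov: float | None = None,
) -> tuple[list[SiteRecord], list[SiteFilterMask]]:
    """Apply population-coverage bounds; flag low-coverage individuals.

    ``mean_pop_cov`` defaults to the mean population coverage of the input
    sites (a first pass).  Bounds are inclusive on both ends.  Filtering is
    per-site, hence order-independent and idempotent given the same mean.
    """
    cfg = cfg or SiteFilterConfig()
    sites = list(sites)
    if not sites:
        return [], []
    if mean_pop_cov is None:
        mean_pop_cov = float(np.mean([s.pop_coverage for s in sites]))
    if mean_pop_cov <= 0:
        raise ValueError("mean population coverage must be positive")
    lo = cfg.pop_cov_lo_frac * mean_pop_cov
    hi = cfg.pop_cov_hi_frac * mean_pop_cov
    kept: list[SiteRecord] = []
    masks: list[SiteFilterMask] = []
    for s in sites:
        cov = s.pop_coverage
        uncallable = np.array([q.n < cfg.min_ind_cov for q in s.quartets])
        if cov < lo:
            masks.append(SiteFilterMask(False, "pop_coverage_below", uncallable))
        elif cov > hi:
            masks.append(SiteFilterMask(False, "pop_coverage_above", uncallable))
        else:
            masks.append(SiteFilterMask(True, None, uncallable))
            kept.append(s)
    return kept, masks


def mean_error_filter(eps_by_individual: Sequence[float], max_mean_error: float = 0.01) -> bool:
    """True iff the site passes the mean called-genotype error-rate filter.

    Applied after high-coverage calling, using the per-individual error-rate
    estimates of the called genotypes; a mean above ``max_mean_error``
    indicates likely mismapping and the site should be excluded.
    """
    eps = [e for e in eps_by_individual if e is not None and np.isfinite(e)]
    if not eps:
        return True
    return float(np.mean(eps)) <= max_mean_error


def format_genotype(call: str | None) -> str:
    """Render a genotype multiset as 'A/C' style, or './.' for no-call."""
    if not call:
        return "./."
    return "/".join(call)


def calls_table(
    site_meta: pd.DataFrame,
    calls: np.ndarray,
) -> pd.DataFrame:
    """Assemble a genotype-call table.

    ``site_meta`` carries site-level columns (seq_id, pos, ref and optionally
    M, m, lrt, p_value, n_alleles); ``calls`` is an (S, N) array of genotype
    strings ('' for no-call).  Per-individual columns are named ind_1..ind_N.
    """
    calls = np.asarray(calls)
    n_ind = calls.shape[1]
    out = site_meta.reset_index(drop=True).copy()
    rendered = np.frompyfunc(format_genotype, 1, 1)(calls)
    for j in range(n_ind):
        out[f"ind_{j + 1}"] = rendered[:, j]
    return out


def write_calls_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)
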
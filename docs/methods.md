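# Methods

## The read model

All callers share one probability model for a sequenced base at a site.  A
read is drawn from one chromosome of the individual's genotype, chosen
uniformly, and is miscalled with probability ε (the per-read, per-site error
rate), landing on each of the three other nucleotides with probability ε/3.
For a genotype `G` of ploidy m carrying k copies of nucleotide x,

    P(x | G, ε) = (k/m)(1 − ε) + ((m − k)/m)(ε/3),

linear in ε, summing to 1 over the four nucleotides for every G and every
ε ∈ [0, 3/4].  At ε = 3/4 all four reads are equiprobable, which is the
model's uniform limit and the upper bound enforced everywhere.  The diploid
specialization is the familiar major/minor table: 1 − ε for a matching
homozygote read, 1/2 − ε/3 for either allele of a heterozygote, ε/3 for an
error read.

A read quartet (nA, nC, nG, nT) is multinomial given genotype, coverage and
ε.  The multinomial coefficient is dropped in every likelihood: all
posteriors and likelihood-ratio statistics are invariant to it, so this is
exact rather than an approximation.  Likelihoods are evaluated in log space
with the conventions 0·ln 0 = 0 and ln 0 = −∞ (via `scipy.special.xlogy`),
so degenerate inputs (zero quartets, ε = 0 with error reads) behave
correctly without special cases.

## Profile-ML error rates

Each candidate genotype is scored at its own maximizing ε.  The
log-likelihood is a sum of terms c·ln(a + bε) grouped by allele multiplicity
k (a = k/m, b = 1/3 − 4k/(3m)), hence concave on [0, 3/4]; categories with
k = m/4 are ε-free and drop out.  The stationarity condition is a polynomial
of degree ≤ 3, solved exactly (`numpy.roots`), and the maximizer is chosen
among admissible real roots and the interval endpoints.  This one solver
reproduces every familiar closed form — (n − n_match)/n for homozygotes,
(3/2)·n_err/n for balanced heterozygotes, 3·n_err/n for the triploid
three-nucleotide heterozygote, the quadratic root for unbalanced triploid
heterozygotes, (3/2)·nT/(nA+nT)-type tetraploid forms — which the test suite
cross-checks against those formulas and against dense grid maximization.
If every observed category is ε-free (e.g. a four-nucleotide tetraploid
heterozygote) the likelihood is flat in ε and the estimate is reported as 0.

## Population genotype-frequency estimation (the Bayes priors)

At each site the two most abundant nucleotides pooled over the sample are
the candidate major/minor alleles M and m (ties broken alphabetically; with
fewer than two observed nucleotides, m is the alphabetically first
unobserved one and its frequency is estimated near zero).  The site model is
a three-component mixture over {MM, Mm, mm} with free weights γ on the
simplex — no mating-system assumption, so heterozygote excess (negative
inbreeding coefficient f) is representable — and a shared ε.  Reads that are
neither M nor m stay in the likelihood as error categories.

The ML fit uses EM over genotype memberships.  Both M-steps are exact: the
weight update is the responsibility mean, and the ε update maximizes a
three-group objective w_hom·ln(1−ε) + w_het·ln(1/2−ε/3) + w_err·ln(ε/3)
whose stationarity condition is the quadratic
Tε² − (5/2·w_err + 3/2·w_hom + w_het)ε + 3/2·w_err = 0 (T = total weighted
reads), solved in closed form (smaller root).  Because the M-steps are exact
and each iteration increases the likelihood, no separate quasi-Newton polish
is applied.  Convergence is declared when successive site log-likelihoods
change by < 1e-10, capped at 1,000 iterations; sites at the cap are flagged
`converged=False` but their (still interior) estimates are reported — in
practice these are boundary-crawling sites with γ̂3 → 0.  Three starting
points guard against local optima: naive per-individual majority-read
genotype proportions, Hardy–Weinberg frequencies from the pooled minor-read
fraction, and a near-monomorphic corner.  The EM is vectorized across sites
(arrays shaped sites × individuals), with converged sites dropping out of
the iteration, which is what makes the 10,000-site benchmark regimes cheap.

The minor-allele frequency estimate is q̂ = γ̂3 + γ̂2/2 — obtained without
calling genotypes, which is why it stays unbiased at 3× coverage where
call-and-count estimators are biased.

Polymorphism is tested per site by a likelihood-ratio test against
monomorphism (site fixed for M, ε free; the null ML is the closed-form
pooled homozygote fit), with 2(lnL_full − lnL_null) referred to χ² with 2 df
(γ2 and γ3 freed).  The null lies on the simplex boundary, so the χ²
reference is conservative; the measured type-I error under a monomorphic
simulation is well below the nominal level, which is the intended direction
for a variant screen.

## The Bayesian caller (low coverage)

Given site priors (γ̂, ε̂), an individual's posterior genotype mass is
γ̂_g multiplied by its quartet likelihood, normalized over the three
genotypes; the call is the arg-max.  No-calls: zero coverage (the likelihood
is flat), coverage below `min_cov` (default 1), top-two posteriors within
1e-9 (floating-point tie), and all individuals at sites failing the
polymorphism test at level α (default 0.05).  With flat priors the call
reduces to the pure ML call, a property the tests assert.  The caller is
biallelic by construction; at a site with a genuine third allele those reads
are treated as errors and individuals carrying the third allele are called
wrong — the benchmark reproduces this as an accuracy ceiling near
1 − (2pr + 2qr + r²) ≈ 0.81 on the standard triallelic regime.

## The prior-free caller (high coverage) and polyploid extensions

Candidates are all genotype multisets (size = ploidy) over the nucleotides
observed in the individual's quartet; each is scored at its own profile-ML
ε; the maximizer is called, ties → no-call, and coverage below `min_cov`
(default 6, the value that keeps false heterozygote→homozygote calls low) →
no-call.  Site-level statistics: with M the pooled most abundant nucleotide,
each non-M-homozygote call is tested against the M homozygote by
LRT = 2(LL1 − LL0) ~ χ²(1), each hypothesis at its own ML ε (a standard
profile-likelihood LRT; whether the original implementation profiled ε under
the null the same way is not documented, so this choice is normative here).
The site is polymorphic if any individual test rejects; no multiplicity
correction is applied across individuals (one rejection suffices) or across
sites (α is exposed).  Significant heterozygotes are confirmed against the
homozygote of the individual's most abundant allele (ties alphabetical)
with another χ²(1) LRT; unconfirmed heterozygotes count as that homozygote
for allele counting, while the reported call remains the ML genotype.  The
allele count is the number of distinct nucleotides in {M} plus the
significant, refinement-adjusted genotypes.

These rules produce characteristic, exactly derivable decision boundaries
that the tests assert by direct likelihood comparison: a lone discordant
read is part of the genotype up to coverage 5 and a sequencing error from
coverage 6 (diploid), a discordant pair flips at coverage 11, and the
triploid caller absorbs a lone discordant read up to coverage 8.  They
appear as accuracy dips at those coverages in fixed-coverage sweeps.

Polyploid calling (ploidy 3 and 4) uses the identical machinery over larger
candidate sets; at ploidy 2 it reduces exactly to the diploid caller
(regression-tested).  Allele dosage (AAC vs ACC) is identifiable only
through read ratios, so polyploid accuracy approaches 1 much more slowly in
coverage than diploid accuracy; the default `min_cov` stays at 6 with no
hard floor, but realistic use needs far deeper data.

## The simulator

The generator draws genotypes i.i.d. per individual per site from their
population frequencies (free γ for biallelic sites; Hardy–Weinberg products
of (p, q, r) over three fixed nucleotides for triallelic sites), coverage
from Poisson(μ) without truncation (zero-coverage individuals are the
missing-data case) or at a fixed depth, and reads multinomially from the
same (k/m)·(1 − ε) model the callers assume.  One seeded
`numpy.random.Generator` drives a run with a fixed consumption order, so a
seed reproduces quartets and truth exactly.  Biallelic allele identities
default to M=A, m=C; callers are identity-invariant (tested by permuting
nucleotide columns).

Because generator and callers share the read model, the benchmarks measure
statistical performance under the model's own assumptions.  Real data add
mapping artifacts, base-quality variation, allelic mapping bias, indels and
duplicated regions, none of which are simulated; the site filters
(population coverage within [0.5, 1.5]× the mean, per-individual minimum
coverage, post-hoc mean error-rate ≤ 0.01) exist precisely to blunt those
real-data failure modes and are exercised on synthetic data only.  Passing
benchmarks therefore demonstrate correctness of the estimators, not
robustness to mapping error.

## Scoring conventions

Correct-call rate among individuals counts no-calls (including zero-coverage
individuals) as incorrect; the rate among called genotypes conditions on a
call being made.  Both are per-site fractions averaged over sites, with
uncertainty reported as twice the standard error of that mean across sites
(the site is the replicate unit).  Polymorphism/triallele detection is
summarized as false-positive and false-negative rates over sites; the
sampling floor q^(2N) + (1 − q)^(2N) — the chance that a sample of N diploid
individuals contains only one allele — bounds any caller's false-negative
rate from below and is exposed as a closed form.

## Benchmark scales and defaults

The canonical regimes (module `benchmarks`) use N = 100 individuals,
ε = 0.01, Poisson coverage, and 10,000 sites at full scale — the conditions
behind the package's headline numbers; the test suite runs them at 2,000
sites, scaling tolerances by √5.  Defaults elsewhere: α = 0.05 for every
LRT; tie tolerance 1e-9 in log space; `min_cov` 1 for the Bayesian caller
(any read is informative once priors exist) and 6 for the prior-free
callers; EM tolerance 1e-10.

## Known limitations

* The Bayesian caller is strictly biallelic; use the high-coverage caller
  first to flag sites with more alleles.
* Priors for polyploid calling are not implemented (candidate genotype
  spaces grow quickly; per-individual ML is used instead).
* Error rates are assumed uniform across the three wrong nucleotides and
  shared across individuals at a site; strand- or context-specific error
  structure is not modeled.
* Ploidy above 4 is out of scope.
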
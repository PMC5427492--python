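"""High-coverage workflow: per-individual ML calls without population priors,
likelihood-ratio polymorphism detection, and allele counting at a site with
three alleles.
"""

import numpy as np

from quartetcall import hgc
from quartetcall.simulate import simulate_individuals

rng = np.random.default_rng(7)

# One individual: a read quartet with 12 A and 3 C reads at 15x.
call = hgc.call_individual([12, 3, 0, 0])
print(f"quartet (12,3,0,0): call={call.call}, eps_hat={call.eps_call:.4f}")
for G, (eps, ll) in sorted(call.ll_profile.items(), key=lambda kv: -kv[1][1]):
    print(f"   {G}: eps_hat={eps:.4f}  lnL={ll:.3f}")

# The same evidence at low coverage is ambiguous: a lone discordant read is
# an allele up to coverage 5 and a sequencing error from coverage 6 on.
print("(4,1,0,0) ->", hgc.call_individual([4, 1, 0, 0], min_cov=1).call)
print("(5,1,0,0) ->", hgc.call_individual([5, 1, 0, 0], min_cov=1).call)

# A population sample at a triallelic site: 30x coverage, 1% error.
quartets = np.vstack([
    simulate_individuals("AA", 30, 0.01, rng, n_reps=10),
    simulate_individuals("AC", 30, 0.01, rng, n_reps=5),
    simulate_individuals("AG", 30, 0.01, rng, n_reps=3),
    simulate_individuals("CG", 30, 0.01, rng, n_reps=2),
])
site = hgc.call_site(quartets, alpha=0.05, min_cov=6)
print(f"\npopulation site: major={site.M}, polymorphic={site.polymorphic}, "
      f"alleles detected={site.n_alleles}")
# n_alleles counts nucleotides in significant genotypes only, so sequencing
# errors do not inflate the allele count.
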
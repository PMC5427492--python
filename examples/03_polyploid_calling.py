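"""Triploid and tetraploid calling, and why polyploids need more coverage:
allele dosage (AAC vs ACC) is only resolvable from read ratios.
"""

import numpy as np

from quartetcall import polyploid as pp
from quartetcall.simulate import simulate_individuals

rng = np.random.default_rng(3)

# Dosage from read ratios at 30x: 20:10 favors AAC, 10:20 favors ACC.
for q in ([20, 10, 0, 0], [10, 20, 0, 0], [10, 10, 10, 0]):
    call = pp.call_polyploid(q, ploidy=3)
    print(f"triploid {tuple(q)} -> {call.call} ({call.genotype_class}), "
          f"eps_hat={call.eps_call:.4f}")

for q in ([20, 20, 1, 1], [30, 10, 0, 0]):
    call = pp.call_polyploid(q, ploidy=4)
    print(f"tetraploid {tuple(q)} -> {call.call} ({call.genotype_class}), "
          f"eps_hat={call.eps_call:.4f}")

# A perfectly balanced four-nucleotide quartet is a genuine no-call: at the
# error-rate bound 3/4 the read distribution is uniform for every genotype,
# so several candidates tie in likelihood.
print("tetraploid (15,15,15,15) ->", pp.call_polyploid([15, 15, 15, 15], 4).reason)

# Correct-call rate vs coverage for a two-nucleotide triploid heterozygote:
# distinguishing AAC from ACC needs many reads, so accuracy climbs slowly.
print("\ncoverage  correct-call rate (true genotype AAC)")
for cov in (10, 20, 50, 100):
    qs = simulate_individuals("AAC", cov, 0.01, rng, n_reps=400)
    correct = np.mean([pp.call_polyploid(q, 3).call == "AAC" for q in qs])
    print(f"{cov:>8}  {correct:.3f}")
# Much higher coverage is needed than for diploid calls: at 10-20x a large
# fraction of dosage calls is still wrong, which is the central practical
# caveat for polyploid genotyping.
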
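"""Effective population sizes of the age-structured scenarios.

Tracks a neutral biallelic variant (mu=0, b=0, 50/50 start) and converts
the measured per-step coalescence rate into an effective size via the
genealogical generation time.  The unrestricted pool behaves like
N/(2 - p_death) (between the Moran N/2 and Wright-Fisher N limits); the
'1' scenario collapses to the newborn cohort, Ne = N * p_death.
"""

import numpy as np

from agedrift import ALL, SimParams, estimate_ne, moran_reference_ne

N = 20_000
print(f"N = {N}; Moran reference N/2 = {moran_reference_ne(N):.0f}")
for c_thresh, p_death, expected in ((ALL, 0.1, N / 1.9), (1, 0.1, N * 0.1),
                                    (1, 0.02, N * 0.02)):
    params = SimParams(N=N, mu=0.0, p_death=p_death, c_thresh=c_thresh)
    est = estimate_ne(params, n_replicates=1200, rng=np.random.default_rng(5))
    print(f"scenario {est.scenario:>3}, p_death={p_death}: "
          f"Ne = {est.ne:7.0f} +- {est.se:.0f}   (closed-form {expected:.0f}) "
          f"[{est.method}]")
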
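"""Rejection-probability experiment over a constellation grid.

For each (b, p_death, c_thresh) constellation, simulates independent
populations, samples them, applies the Ewens-Watterson test, and
tabulates the fraction rejected.  The unbiased Wright-Fisher row sits
near the significance level; the age-constrained row is rejected far
more often despite unbiased copying.
"""

import numpy as np

from agedrift import rejection_experiment

grid = [
    {"b": 0.0, "p_death": 1.0, "c_thresh": "ALL"},   # Wright-Fisher null
    {"b": 0.0, "p_death": 0.02, "c_thresh": 1},      # strong age constraint
]
table = rejection_experiment("ewens", grid, n_reps=40, sample_sizes=[1000],
                             rng=np.random.default_rng(7),
                             N=10_000, mu=5e-4, alpha=0.05)
cols = ["b", "p_death", "c_thresh", "sample_size",
        "rejection_fraction", "ci_low", "ci_high"]
print(table[cols].to_string(index=False))
print("\nc_thresh -1 denotes the unrestricted pool; the age-constrained "
      "constellation is rejected well above the 5% level.")
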
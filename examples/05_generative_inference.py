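"""Generative inference: classify samples as unbiased vs biased copying.

Trains per-sample-size random forests on diversity profiles simulated
from the parameter prior (b ~ N(0, 1e-3) with a point mass at 0,
mu ~ U(1e-5, 1e-3), p_death ~ U(0.02, 0.1), c_thresh ~ U{1..a_max}), then
classifies fresh samples from known generating processes.  Desk scale
(N=1000, 300 examples) keeps the run short; study-scale inference uses
N=1e5 and 10,000 examples.
"""

import numpy as np

from agedrift import (PriorSpec, SimParams, build_training_set, classify,
                      diversity_profile, run_to_steady_state, sample_variants,
                      train_classifier)

rng = np.random.default_rng(6)
training = build_training_set(PriorSpec(), n_examples=300, sample_size=500,
                              N=1000, rng=rng)
bundle = train_classifier(training, T=200, rng=rng)
print(f"held-out accuracy (n=500): {bundle.heldout_accuracy[500]:.2f}")

for label, b in (("unbiased", 0.0), ("conformist", 2e-3),
                 ("anti-conformist", -2e-3)):
    params = SimParams(N=1000, mu=5e-4, p_death=0.05, c_thresh=10, b=b)
    pop, _ = run_to_steady_state(params, rng)
    prof = diversity_profile(sample_variants(pop, 500, rng))
    pred, vote = classify(bundle, prof)
    print(f"true process {label:>15} (b={b:+.0e}): classified '{pred}' "
          f"({vote:.0%} of trees voted biased)")
print("At this reduced scale the anti-conformist excess of rare variants "
      "is the easiest signature to detect; conformity mostly accelerates "
      "fixation, which low-innovation unbiased runs mimic.")
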
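"""Frequency-table Wright-Fisher dynamics (the no-age-structure limit).

Equivalent in law to the agent model with ``p_death = 1`` and an
unrestricted copy pool, but a generation costs O(number of types) instead
of O(N): the N offspring types are drawn jointly (multinomial) from the
adoption distribution over the parent generation's frequency table, and
innovations enter as fresh singleton types.
"""

from __future__ import annotations

import math

import numpy as np

from .core import (ParameterError, VariantFrequencyTable, as_rng)
from .ewens import feller_counts

__all__ = ["wf_generation", "run_wright_fisher"]


def wf_generation(counts: np.ndarray, next_label: int, labels: np.ndarray,
                  N: int, mu: float, b: float, rng):
    """One Wright-Fisher generation on a frequency table.

    Returns (labels, counts, next_label).
    """
    w = (counts / N) ** (1.0 + b)
    probs = w / w.sum()
    n_innov = rng.binomial(N, mu) if mu > 0 else 0
    offspring = rng.multinomial(N - n_innov, probs)
    keep = offspring > 0
    new_labels = np.concatenate([labels[keep],
                                 next_label + np.arange(n_innov, dtype=np.int64)])
    new_counts = np.concatenate([offspring[keep],
                                 np.ones(n_innov, dtype=np.int64)])
    return new_labels, new_counts, next_label + n_innov


def run_wright_fisher(N: int, mu: float, b: float = 0.0, rng=None,
                      n_generations: int | None = None,
                      initial_counts=None,
                      record_richness: bool = False):
    """Run WF infinite-alleles dynamics; return the final frequency table.

    With ``n_generations=None`` and ``mu > 0`` the run length is an
    automatic burn-in of five relaxation times (1/(2*mu + 1/N)
    generations) from an ESF-distributed start; with ``mu = 0`` the chain
    is run to absorption (a single surviving type) unless
    ``n_generations`` caps it.

    ``initial_counts`` (any positive-integer vector summing to N)
    overrides the default start.  If ``record_richness`` is true, also
    return the per-recorded-generation richness trajectory.
    """
    N = int(N)
    if N < 2:
        raise ParameterError(f"N must be >= 2, got {N}")
    if not (0.0 <= mu <= 1.0):
        raise ParameterError(f"mu must be in [0, 1], got {mu}")
    if b <= -1.0:
        raise ParameterError(f"b must be > -1, got {b}")
    rng = as_rng(rng)

    if initial_counts is not None:
        counts = np.asarray(initial_counts, dtype=np.int64)
        if counts.min() < 1 or counts.sum() != N:
            raise ParameterError("initial_counts must be positive and sum to N")
    elif mu > 0:
        counts = np.asarray(feller_counts(N, 2.0 * N * mu, rng), dtype=np.int64)
    else:
        counts = np.array([N], dtype=np.int64)
    labels = np.arange(counts.size, dtype=np.int64)
    next_label = int(counts.size)

    if n_generations is None:
        if mu > 0:
            n_generations = max(200, int(math.ceil(5.0 / (2.0 * mu + 1.0 / N))))
        else:
            n_generations = -1          # run to absorption

    richness = []
    g = 0
    while True:
        if n_generations >= 0 and g >= n_generations:
            break
        if mu == 0.0 and counts.size == 1:
            break
        labels, counts, next_label = wf_generation(counts, next_label, labels,
                                                   N, mu, b, rng)
        g += 1
        if record_richness:
            richness.append(counts.size)

    table = VariantFrequencyTable(labels, counts)
    if record_richness:
        return table, np.asarray(richness)
    return table
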
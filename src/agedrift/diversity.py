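"""Hill numbers and diversity profiles.

The Hill number of order q,

    qD(p_1, ..., p_k) = (sum_i p_i^q)^(1/(1-q)),

is the effective number of equally abundant types at frequency-sensitivity
q: q=0 gives richness k, q->1 the exponential of Shannon entropy (the
continuous limit), q=2 the inverse Simpson concentration 1/sum p_i^2.
A diversity profile evaluates qD on a grid of q values (default 0 to 3 in
steps of 0.25, 13 points) and is the feature vector of the
generative-inference classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ParameterError, SampleConfiguration

__all__ = ["DEFAULT_Q_GRID", "hill_number", "diversity_profile", "DiversityProfile"]

#: q in [0, 3] with step 0.25.
DEFAULT_Q_GRID = tuple(np.round(np.arange(0, 3.01, 0.25), 2))

_Q1_TOL = 1e-9


def hill_number(freqs, q: float) -> float:
    """Hill number of order q for a normalized frequency vector."""
    p = np.asarray(freqs, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("freqs must be a non-empty 1-d vector")
    if p.min() <= 0:
        raise ParameterError("frequencies must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ParameterError(f"frequencies must sum to 1, got {p.sum()}")
    if q < 0:
        raise ParameterError(f"q must be >= 0, got {q}")
    if abs(q - 1.0) < _Q1_TOL:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p ** q).sum() ** (1.0 / (1.0 - q)))


@dataclass(frozen=True)
class DiversityProfile:
    """Hill numbers over a q-grid, computed from a sample of size n."""

    q_grid: tuple
    values: tuple
    n: int

    def __post_init__(self):
        if len(self.q_grid) != len(self.values):
            raise ParameterError("q_grid and values must have equal length")
        object.__setattr__(self, "q_grid", tuple(float(q) for q in self.q_grid))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def richness(self) -> int:
        return int(round(self.values[0]))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float64)

    def feature_names(self) -> list[str]:
        return [f"q{q:g}" for q in self.q_grid]


def diversity_profile(config: SampleConfiguration,
                      q_grid=DEFAULT_Q_GRID) -> DiversityProfile:
    """Diversity profile of a sample configuration on the q-grid.

    Profiles are computed from the raw sample relative frequencies (no
    small-sample bias correction); the q=0 entry equals the integer
    richness k exactly.
    """
    if not isinstance(config, SampleConfiguration):
        config = SampleConfiguration.from_counts(config)
    p = config.frequencies()
    values = []
    for q in q_grid:
        if q == 0:
            values.append(float(config.k))
        else:
            values.append(hill_number(p, float(q)))
    return DiversityProfile(tuple(q_grid), tuple(values), config.n)
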
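"""Domain types shared across the package.

The model is an age-structured infinite-alleles process: a fixed-size
population of ``N`` individuals, each carrying an age and an opaque variant
label.  Per time step every individual dies independently with probability
``p_death``; newborns replace the dead, keeping ``N`` constant, and adopt a
variant by copying a role model drawn from the *previous* step's population,
restricted to a maximum age ``c_thresh`` (``ALL`` = the whole previous
population).  With probability ``mu`` a newborn innovates, taking a label
never seen before.  ``b`` tilts copy probabilities by frequency:
``p_i \\propto (n_i/N_P)^(1+b)``; ``b = 0`` is unbiased (linear) copying.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import numpy as np

#: Sentinel for an unrestricted copy pool (the whole previous population).
ALL = "ALL"

CThresh = Union[int, str]


class ParameterError(ValueError):
    """Raised when model parameters violate their domain constraints."""


class EmptyPoolError(RuntimeError):
    """Raised when the copy pool contains no individuals in the age range."""


class SteadyStateError(RuntimeError):
    """Raised when a simulation fails to reach steady state within budget."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


def _validate_c_thresh(c_thresh: CThresh) -> CThresh:
    if isinstance(c_thresh, str):
        if c_thresh != ALL:
            raise ParameterError(f"c_thresh must be a positive int or 'ALL', got {c_thresh!r}")
        return ALL
    c = int(c_thresh)
    if c < 1:
        raise ParameterError(f"c_thresh must be >= 1, got {c}")
    return c


@dataclass(frozen=True)
class SimParams:
    """Parameters of the age-structured transmission model.

    Parameters
    ----------
    N : int
        Population size (constant over time), >= 2.
    mu : float
        Innovation probability per adoption event, in [0, 1].
    p_death : float
        Per-step death probability, in (0, 1].  ``p_death = 1`` with
        ``c_thresh = ALL`` is the Wright-Fisher limit.
    c_thresh : int or "ALL"
        Maximum age of role models.  Finite values restrict the pool to
        ages ``1..c_thresh`` of the previous step; ``ALL`` means the whole
        previous population (including its age-0 cohort).
    b : float
        Frequency-dependence strength; must exceed -1.  0 = unbiased.
    burn_in : int, optional
        Explicit burn-in length in steps; ``None`` selects an automatic,
        relaxation-time-based length.
    max_steps : int, optional
        Hard cap on total steps in ``run_to_steady_state``.
    seed : int, optional
        Convenience seed recorded with the parameters (operations accept an
        explicit RNG as well).
    """

    N: int
    mu: float
    p_death: float
    c_thresh: CThresh = ALL
    b: float = 0.0
    burn_in: int | None = None
    max_steps: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if int(self.N) < 2:
            raise ParameterError(f"N must be >= 2, got {self.N}")
        if not (0.0 <= self.mu <= 1.0):
            raise ParameterError(f"mu must be in [0, 1], got {self.mu}")
        if not (0.0 < self.p_death <= 1.0):
            raise ParameterError(f"p_death must be in (0, 1], got {self.p_death}")
        if self.b <= -1.0:
            raise ParameterError(f"b must be > -1 (exponent 1+b must stay positive), got {self.b}")
        object.__setattr__(self, "c_thresh", _validate_c_thresh(self.c_thresh))
        object.__setattr__(self, "N", int(self.N))

    @property
    def is_all_pool(self) -> bool:
        return self.c_thresh == ALL

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "mu": self.mu,
            "p_death": self.p_death,
            "c_thresh": self.c_thresh,
            "b": self.b,
            "burn_in": self.burn_in,
            "max_steps": self.max_steps,
            "seed": self.seed,
        }


@dataclass
class Population:
    """Population state at one time step: per-individual ages and variants."""

    ages: np.ndarray
    variants: np.ndarray
    next_label: int
    step_index: int = 0

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=np.int64)
        self.variants = np.asarray(self.variants, dtype=np.int64)
        if self.ages.shape != self.variants.shape or self.ages.ndim != 1:
            raise ParameterError("ages and variants must be 1-d arrays of equal length")
        if self.ages.size and self.ages.min() < 0:
            raise ParameterError("ages must be non-negative")
        if self.variants.size and self.variants.max() >= self.next_label:
            raise ParameterError("every variant label must be < next_label")

    @property
    def size(self) -> int:
        return self.ages.size

    @property
    def a_max(self) -> int:
        """Age of the oldest individual (derived, never cached)."""
        return int(self.ages.max())

    def frequency_table(self) -> "VariantFrequencyTable":
        return VariantFrequencyTable.from_variants(self.variants)

    def copy(self) -> "Population":
        return Population(self.ages.copy(), self.variants.copy(), self.next_label, self.step_index)


@dataclass(frozen=True)
class VariantFrequencyTable:
    """Abundance table of variants: labels with positive counts."""

    labels: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        counts = np.asarray(self.counts, dtype=np.int64)
        if labels.shape != counts.shape or labels.ndim != 1:
            raise ParameterError("labels and counts must be 1-d arrays of equal length")
        if counts.size == 0:
            raise EmptyPoolError("frequency table is empty")
        if counts.min() < 1:
            raise ParameterError("all counts must be >= 1")
        if np.unique(labels).size != labels.size:
            raise ParameterError("duplicate variant labels in frequency table")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_variants(cls, variants: np.ndarray) -> "VariantFrequencyTable":
        variants = np.asarray(variants, dtype=np.int64)
        if variants.size == 0:
            raise EmptyPoolError("no individuals in the copy pool")
        labels, counts = np.unique(variants, return_counts=True)
        return cls(labels, counts)

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, int]) -> "VariantFrequencyTable":
        if not mapping:
            raise EmptyPoolError("no individuals in the copy pool")
        labels = np.fromiter(mapping.keys(), dtype=np.int64, count=len(mapping))
        counts = np.fromiter(mapping.values(), dtype=np.int64, count=len(mapping))
        return cls(labels, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return int(self.counts.size)

    def as_dict(self) -> dict[int, int]:
        return dict(zip(self.labels.tolist(), self.counts.tolist()))

    def to_configuration(self) -> "SampleConfiguration":
        return SampleConfiguration.from_counts(self.counts)


@dataclass(frozen=True)
class AdoptionDistribution:
    """Per-variant adoption probabilities plus the innovation mass mu."""

    labels: np.ndarray
    probs: np.ndarray
    innovation_mass: float

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        probs = np.asarray(self.probs, dtype=np.float64)
        if labels.shape != probs.shape:
            raise ParameterError("labels and probs must have equal length")
        if probs.size and (probs.min() < -1e-15 or probs.max() > 1 + 1e-12):
            raise ParameterError("probabilities must lie in [0, 1]")
        total = float(probs.sum()) + float(self.innovation_mass)
        if abs(total - 1.0) > 1e-12:
            raise ParameterError(f"probabilities + innovation_mass must sum to 1, got {total}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "probs", probs)

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.labels.tolist(), self.probs.tolist()))


@dataclass(frozen=True)
class SampleConfiguration:
    """Unordered abundance multiset (n_1 >= ... >= n_k) of a sample.

    Canonical form sorts counts non-increasingly; the identity of variant
    labels is deliberately discarded (multiset semantics).
    """

    counts: tuple

    def __post_init__(self):
        counts = tuple(int(c) for c in self.counts)
        if len(counts) == 0:
            raise ParameterError("a sample configuration must contain at least one type")
        if any(c < 1 for c in counts):
            raise ParameterError("all configuration counts must be >= 1")
        if any(counts[i] < counts[i + 1] for i in range(len(counts) - 1)):
            raise ParameterError("configuration counts must be sorted non-increasingly; "
                                 "use SampleConfiguration.from_counts to canonicalize")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_counts(cls, counts: Iterable[int]) -> "SampleConfiguration":
        return cls(tuple(sorted((int(c) for c in counts), reverse=True)))

    @classmethod
    def from_variants(cls, variants: np.ndarray) -> "SampleConfiguration":
        _, counts = np.unique(np.asarray(variants), return_counts=True)
        return cls.from_counts(counts)

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def k(self) -> int:
        return len(self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    def frequencies(self) -> np.ndarray:
        arr = self.as_array().astype(np.float64)
        return arr / arr.sum()


def as_rng(rng: Union[np.random.Generator, int, None]) -> np.random.Generator:
    """Coerce a seed or Generator to a Generator (None -> unseeded)."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def child_seed(rng: np.random.Generator) -> int:
    """Derive an integer seed below 2**31 for a subordinate RNG stream."""
    return int(rng.integers(0, 2**31 - 1))
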
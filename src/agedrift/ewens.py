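"""Ewens sampling formula machinery and the Slatkin exact neutrality test.

Under neutrality, conditional on sample size ``n`` and number of types
``k``, the probability of an ordered configuration ``(n_1, ..., n_k)`` is

    P(n_1, ..., n_k | n, k) = n! / (|S_n^k| * k! * n_1 * ... * n_k)

with ``|S_n^k|`` the unsigned Stirling number of the first kind.  The
Slatkin exact test computes the two-tailed tail probability ``P_E``: the
total probability of all configurations no more probable than the observed
one.  For small ``n`` we enumerate integer partitions exhaustively; for
large ``n`` the tail probability is estimated by Monte Carlo over
configurations drawn from the conditional law given ``k``.

The conditional sampler uses the Feller coupling of the ESF: for a sample
of size ``n`` and concentration ``theta``, independent Bernoulli "closure"
indicators with success probability ``theta / (theta + m - 1)`` (``m`` the
number of items still unassigned) partition ``1..n`` into segments whose
lengths are ESF(theta)-distributed type counts.  Because ``k`` is
sufficient for ``theta``, rejection on the observed ``k`` yields the exact
conditional law for any ``theta``; ``theta`` is tuned only to maximize the
acceptance rate (``E[K] = k``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from .core import ParameterError, SampleConfiguration, as_rng

__all__ = [
    "log_stirling_unsigned",
    "esf_log_prob",
    "esf_log_prob_unordered",
    "enumerate_configs",
    "expected_num_types",
    "theta_for_expected_types",
    "feller_counts",
    "sample_config_given_k",
    "ewens_watterson_test",
    "EwensTestResult",
]

# Relative log-space tolerance for the "equal or less than" tie rule.
_TIE_RTOL = 1e-9

# Guard on exhaustive enumeration (partition counts explode beyond this).
N_ENUM_MAX = 60


# ---------------------------------------------------------------------------
# Stirling numbers (log space)

class _StirlingTable:
    """Row-cached table of log |S_n^k| built from the triangular recurrence

    |S_{n+1}^k| = n * |S_n^k| + |S_n^{k-1}|.
    """

    def __init__(self):
        # rows[n][k-1] = log |S_n^k|, k = 1..n
        self._rows = [None, np.array([0.0])]

    def row(self, n: int) -> np.ndarray:
        while len(self._rows) <= n:
            m = len(self._rows) - 1          # last computed n
            prev = self._rows[m]
            nxt = np.empty(m + 1)
            with np.errstate(divide="ignore"):
                # k = 1..m: m*|S_m^k| + |S_m^{k-1}|
                shifted = np.concatenate(([-np.inf], prev[:-1]))
                nxt[:-1] = np.logaddexp(math.log(m) + prev, shifted)
            nxt[-1] = 0.0                    # |S_{m+1}^{m+1}| = 1
            self._rows.append(nxt)
        return self._rows[n]


_TABLE = _StirlingTable()


def log_stirling_unsigned(n: int, k: int) -> float:
    """Natural log of the unsigned Stirling number of the first kind |S_n^k|."""
    n, k = int(n), int(k)
    if n < 1 or k < 1 or k > n:
        raise ParameterError(f"require 1 <= k <= n, got n={n}, k={k}")
    return float(_TABLE.row(n)[k - 1])


# ---------------------------------------------------------------------------
# ESF probabilities

def esf_log_prob(config: SampleConfiguration) -> float:
    """Log probability of an *ordered* k-tuple configuration given (n, k)."""
    counts = config.as_array()
    n, k = config.n, config.k
    return (gammaln(n + 1) - log_stirling_unsigned(n, k)
            - gammaln(k + 1) - float(np.log(counts).sum()))


def _log_orderings(config: SampleConfiguration) -> float:
    """Log number of distinct ordered k-tuples of an unordered multiset."""
    _, mult = np.unique(config.as_array(), return_counts=True)
    return float(gammaln(config.k + 1) - gammaln(mult + 1).sum())


def esf_log_prob_unordered(config: SampleConfiguration) -> float:
    """Log probability of the unordered multiset (ordered prob x #orderings)."""
    return esf_log_prob(config) + _log_orderings(config)


def _log_stat_from_lengths(lengths: np.ndarray) -> float:
    """Ranking statistic of the exact test: -log of the unordered
    configuration probability up to the (n, k)-constant normalizer,

        s = sum_i log n_i + sum_j log a_j!,

    where a_j is the number of types with exactly j copies.  Larger s
    means a less probable partition (P_unordered = n!/|S_n^k| * e^{-s}).
    """
    _, mult = np.unique(lengths, return_counts=True)
    return float(np.log(lengths).sum() + gammaln(mult + 1).sum())


def _partitions_exact(n: int, k: int, max_part: int) -> Iterator[tuple]:
    """Partitions of n into exactly k parts, each <= max_part, non-increasing."""
    if k == 1:
        if 1 <= n <= max_part:
            yield (n,)
        return
    # first (largest) part needs at least ceil(n/k)
    lo = -(-n // k)
    for first in range(min(n - k + 1, max_part), lo - 1, -1):
        for rest in _partitions_exact(n - first, k - 1, first):
            yield (first,) + rest


def enumerate_configs(n: int, k: int) -> list[SampleConfiguration]:
    """All partitions of n into exactly k positive parts (canonical form)."""
    n, k = int(n), int(k)
    if n < 1 or k < 1 or k > n:
        raise ParameterError(f"require 1 <= k <= n, got n={n}, k={k}")
    if n > N_ENUM_MAX:
        raise ParameterError(
            f"exhaustive enumeration is guarded at n <= {N_ENUM_MAX} "
            f"(got n={n}); use the Monte-Carlo tail probability instead")
    return [SampleConfiguration(p) for p in _partitions_exact(n, k, n)]


# ---------------------------------------------------------------------------
# Conditional sampling given k

def expected_num_types(n: int, theta: float) -> float:
    """E[K] under ESF(theta) for sample size n: sum_i theta/(theta+i)."""
    i = np.arange(n, dtype=np.float64)
    return float((theta / (theta + i)).sum())


def theta_for_expected_types(n: int, k: int) -> float:
    """Solve E[K] = k for theta (acceptance-rate tuning only)."""
    if k <= 1:
        return 1e-9
    if k >= n:
        return 1e9
    return float(brentq(lambda th: expected_num_types(n, th) - k, 1e-9, 1e9,
                        xtol=1e-12, rtol=1e-10))


def feller_counts(n: int, theta: float, rng) -> np.ndarray:
    """One ESF(theta) configuration of sample size n (unsorted counts)."""
    rng = as_rng(rng)
    m = np.arange(n, 0, -1, dtype=np.float64)      # items remaining
    p_close = theta / (theta + m - 1.0)
    close = rng.random(n) < p_close
    close[-1] = True
    pos = np.flatnonzero(close)
    return np.diff(np.concatenate(([-1], pos)))


def _feller_batch_stats(n: int, k: int, theta: float, n_target: int,
                        rng: np.random.Generator,
                        collect_configs: bool = False,
                        max_batches: int = 2000):
    """Draw conditioned configurations; return sum-log-counts statistics.

    Vectorized over a batch of Feller sequences; rows with exactly k
    closures are accepted.  Returns (stats, configs-or-None).
    """
    m = np.arange(n, 0, -1, dtype=np.float64)
    p_close = theta / (theta + m - 1.0)
    stats = np.empty(n_target)
    configs = [] if collect_configs else None
    got = 0
    proposed = 0
    batch = max(32, 2 * n_target)
    batch_cap = max(256, 4_000_000 // max(n, 1))
    for _ in range(max_batches):
        batch = min(batch, batch_cap)
        u = rng.random((batch, n)) < p_close
        u[:, -1] = True
        kk = u.sum(axis=1)
        proposed += batch
        rows = np.flatnonzero(kk == k)
        for r in rows:
            pos = np.flatnonzero(u[r])
            lengths = np.diff(np.concatenate(([-1], pos)))
            stats[got] = _log_stat_from_lengths(lengths)
            if collect_configs:
                configs.append(SampleConfiguration.from_counts(lengths))
            got += 1
            if got == n_target:
                return stats, configs
        # adapt the batch size to the observed acceptance rate
        acc = (got + 1) / proposed
        batch = int(1.5 * (n_target - got) / acc) + 32
    raise RuntimeError(
        f"conditioned sampler failed to reach {n_target} acceptances "
        f"(n={n}, k={k}); acceptance rate too low")


def sample_config_given_k(n: int, k: int, rng) -> SampleConfiguration:
    """One configuration from the ESF conditioned on (n, k)."""
    n, k = int(n), int(k)
    if not (1 <= k <= n):
        raise ParameterError(f"require 1 <= k <= n, got n={n}, k={k}")
    if k == n:
        return SampleConfiguration.from_counts([1] * k)
    if k == 1:
        return SampleConfiguration.from_counts([n])
    rng = as_rng(rng)
    theta = theta_for_expected_types(n, k)
    _, configs = _feller_batch_stats(n, k, theta, 1, rng, collect_configs=True)
    return configs[0]


# ---------------------------------------------------------------------------
# The Slatkin exact test

@dataclass(frozen=True)
class EwensTestResult:
    """Outcome of the two-tailed Ewens-Watterson/Slatkin neutrality test.

    ``p_value`` is Slatkin's tail probability P_E (total null mass of
    configurations no more probable than the observed one); ``p_upper``
    is the complementary tie-inclusive tail (mass of configurations at
    least as probable).  P_E is uniform under the null, so the two-tailed
    test at level alpha rejects when either tail is <= alpha/2: a tiny
    P_E flags an improbably *even* configuration (e.g. negative frequency
    dependence), a tiny upper tail an improbably *skewed* one (positive
    frequency dependence, or the accumulation signature of strong age
    constraints).  Both tails count ties, so each is conservative and a
    monomorphic sample (a single possible configuration) never rejects.
    """

    p_value: float
    n: int
    k: int
    method: str                 # "exhaustive" | "monte_carlo"
    mc_samples: int = 0         # 0 for the exhaustive path
    p_upper: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 and 0.0 <= self.p_upper <= 1.0):
            raise ParameterError(f"tail probabilities must be in [0, 1], "
                                 f"got {self.p_value}, {self.p_upper}")

    def reject(self, alpha: float = 0.05) -> bool:
        """Two-tailed decision at significance level alpha."""
        return self.p_value <= alpha / 2 or self.p_upper <= alpha / 2

    def to_dict(self) -> dict:
        return {"p_value": self.p_value, "p_upper": self.p_upper,
                "n": self.n, "k": self.k,
                "method": self.method, "mc_samples": self.mc_samples}


def _exact_tail_probabilities(observed: SampleConfiguration) -> tuple[float, float]:
    """(P_E, upper tail) by exhaustive enumeration of partitions (small n).

    Both the tie rule and the summed masses use the unordered partition
    probability (the probability of actually observing the multiset),
    which is Slatkin's exact-test statistic.
    """
    n, k = observed.n, observed.k
    stat_obs = _log_stat_from_lengths(observed.as_array())
    tol = _TIE_RTOL * max(1.0, abs(stat_obs))
    log_low, log_high = [], []
    for cfg in enumerate_configs(n, k):
        stat = _log_stat_from_lengths(cfg.as_array())
        mass = esf_log_prob_unordered(cfg)
        if stat >= stat_obs - tol:          # no more probable (ties count)
            log_low.append(mass)
        if stat <= stat_obs + tol:          # at least as probable
            log_high.append(mass)
    p_low = float(min(1.0, math.exp(logsumexp(log_low))))
    p_high = float(min(1.0, math.exp(logsumexp(log_high))))
    return p_low, p_high


def ewens_watterson_test(observed, mc_samples: int = 100_000, rng=None,
                         force_monte_carlo: bool = False) -> EwensTestResult:
    """Two-tailed Slatkin exact test of neutrality for a sample configuration.

    Parameters
    ----------
    observed : SampleConfiguration or iterable of counts
        The observed variant-abundance multiset.
    mc_samples : int
        Number of conditioned Monte-Carlo configurations when enumeration
        is intractable (n > 60).  Add-one smoothing keeps the p-value
        strictly positive.
    rng : Generator or int, optional
        Randomness source for the Monte-Carlo path.
    force_monte_carlo : bool
        Use the Monte-Carlo path even when enumeration is tractable
        (used for cross-validation of the two paths).
    """
    if not isinstance(observed, SampleConfiguration):
        observed = SampleConfiguration.from_counts(observed)
    n, k = observed.n, observed.k
    if k == 1 or k == n:
        # single possible configuration given (n, k); both tails saturate
        return EwensTestResult(1.0, n, k, "exhaustive", 0, p_upper=1.0)
    if n <= N_ENUM_MAX and not force_monte_carlo:
        p_low, p_high = _exact_tail_probabilities(observed)
        return EwensTestResult(p_low, n, k, "exhaustive", 0, p_upper=p_high)

    if mc_samples < 1000:
        warnings.warn(f"mc_samples={mc_samples} is small; the Monte-Carlo "
                      "tail probability will be noisy", stacklevel=2)
    rng = as_rng(rng)
    theta = theta_for_expected_types(n, k)
    stats, _ = _feller_batch_stats(n, k, theta, int(mc_samples), rng)
    stat_obs = _log_stat_from_lengths(observed.as_array())
    # larger statistic <=> less probable partition; ties count in both tails
    tol = _TIE_RTOL * max(1.0, abs(stat_obs))
    m = int(mc_samples)
    p_low = (int((stats >= stat_obs - tol).sum()) + 1) / (m + 1)
    p_high = (int((stats <= stat_obs + tol).sum()) + 1) / (m + 1)
    return EwensTestResult(float(p_low), n, k, "monte_carlo", m,
                           p_upper=float(p_high))
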
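"""Forward-time agent-based simulator of the age-structured model.

Two implementations coexist deliberately:

* :func:`step` is the readable numpy reference implementation of one time
  step, used directly in small-scale work and as the semantic oracle in the
  test suite.
* :func:`run_to_steady_state` drives the compiled O(deaths)-per-step kernel
  in :mod:`agedrift._kernels` for long runs; the two are cross-checked
  distributionally in the tests.

The Wright-Fisher limit (``p_death = 1``, ``c_thresh = ALL``) is also
available as an efficient frequency-table implementation in
:mod:`agedrift.wright_fisher`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import (ALL, AdoptionDistribution, CThresh, EmptyPoolError,
                   ParameterError, Population, SampleConfiguration,
                   SimParams, SteadyStateError, VariantFrequencyTable,
                   as_rng, child_seed)
from .ewens import feller_counts

__all__ = [
    "init_population", "copy_pool", "adoption_distribution", "step",
    "run_to_steady_state", "sample_variants", "sample_from_table",
    "ne_guess", "SteadyStateDiagnostics",
]


def _age_cap(p_death: float) -> int:
    return max(1, int(round(20.0 / p_death)))


def init_population(params: SimParams, rng) -> Population:
    """Monomorphic population with stationary-geometric ages.

    Every individual carries variant label 0; ages are i.i.d. geometric
    with success probability ``p_death`` (the stationary age profile of the
    constant-size death-replacement process), capped at ``20 / p_death``.
    """
    rng = as_rng(rng)
    ages = np.minimum(rng.geometric(params.p_death, size=params.N) - 1,
                      _age_cap(params.p_death))
    variants = np.zeros(params.N, dtype=np.int64)
    return Population(ages=ages, variants=variants, next_label=1, step_index=0)


def _stationary_population(params: SimParams, rng) -> Population:
    """Approximate-steady-state start: ESF-distributed variant counts at
    theta = 2 * Ne_guess * mu, stationary geometric ages."""
    rng = as_rng(rng)
    pop = init_population(params, rng)
    if params.mu > 0:
        theta = 2.0 * ne_guess(params) * params.mu
        counts = feller_counts(params.N, theta, rng)
        labels = np.repeat(np.arange(counts.size, dtype=np.int64), counts)
        rng.shuffle(labels)
        pop.variants = labels
        pop.next_label = int(counts.size)
    return pop


def copy_pool(prev: Population, c_thresh: CThresh) -> VariantFrequencyTable:
    """Abundance table of the copy pool drawn from the previous step.

    Pool membership is decided by age *at the moment of copying*, i.e.
    after the previous population has aged by one step: a role model of
    age ``a`` in [1, c_thresh] was of stored age ``a - 1`` in ``prev``.
    Hence ``c_thresh = 1`` is exactly the previous step's newborn cohort
    (the most recently transmitted variants), and ``ALL`` is the whole
    previous population.  With this convention the '1' scenario is a
    per-step Wright-Fisher chain over the N * p_death newborns, matching
    the model's effective sizes, and the Wright-Fisher limit
    (p_death = 1) works for any c_thresh without special cases.
    """
    if c_thresh == ALL:
        variants = prev.variants
    else:
        c = int(c_thresh)
        if c < 1:
            raise ParameterError(f"c_thresh must be >= 1 or ALL, got {c_thresh}")
        mask = prev.ages <= c - 1
        variants = prev.variants[mask]
    if variants.size == 0:
        raise EmptyPoolError(
            f"copy pool is empty: no role model of age <= {c_thresh} "
            "was present in the previous step")
    return VariantFrequencyTable.from_variants(variants)


def adoption_distribution(pool: VariantFrequencyTable, b: float,
                          mu: float) -> AdoptionDistribution:
    """Adoption probabilities p_i = (n_i/N_P)^(1+b) / sum_j (...) * (1-mu).

    ``b = 0`` reduces exactly to linear (unbiased) copying
    p_i = n_i/N_P * (1-mu); the remaining mass ``mu`` is innovation.
    """
    if b <= -1.0:
        raise ParameterError(f"b must be > -1, got {b}")
    if not (0.0 <= mu <= 1.0):
        raise ParameterError(f"mu must be in [0, 1], got {mu}")
    freqs = pool.counts / pool.total
    w = freqs ** (1.0 + b)
    probs = w / w.sum() * (1.0 - mu)
    return AdoptionDistribution(pool.labels, probs, mu)


def step(prev: Population, params: SimParams, rng) -> Population:
    """One time step of the age-structured model (reference implementation).

    Every individual dies independently with probability ``p_death``;
    survivors age by one; exactly as many newborns (age 0) enter as died.
    Newborn variants are drawn from the adoption distribution over the copy
    pool of the *previous* state — a snapshot unaffected by this step's
    deaths.
    """
    rng = as_rng(rng)
    N = prev.size
    dist = adoption_distribution(copy_pool(prev, params.c_thresh),
                                 params.b, params.mu)
    dies = rng.random(N) < params.p_death
    nd = int(dies.sum())

    ages = prev.ages + 1
    variants = prev.variants.copy()
    next_label = prev.next_label
    if nd:
        ages[dies] = 0
        u = rng.random(nd)
        cum = np.cumsum(dist.probs)       # sums to 1 - mu
        innovates = u >= cum[-1]
        n_innov = int(innovates.sum())
        newv = np.empty(nd, dtype=np.int64)
        newv[innovates] = next_label + np.arange(n_innov)
        next_label += n_innov
        newv[~innovates] = dist.labels[np.searchsorted(cum, u[~innovates],
                                                       side="right")]
        variants[dies] = newv
    return Population(ages=ages, variants=variants, next_label=next_label,
                      step_index=prev.step_index + 1)


def sample_variants(pop: Population, n: int, rng) -> SampleConfiguration:
    """Simple random sample without replacement of n individuals' variants."""
    n = int(n)
    if not (1 <= n <= pop.size):
        raise ParameterError(f"sample size must satisfy 1 <= n <= N={pop.size}, got {n}")
    rng = as_rng(rng)
    if n == pop.size:
        return SampleConfiguration.from_variants(pop.variants)
    idx = rng.choice(pop.size, size=n, replace=False)
    return SampleConfiguration.from_variants(pop.variants[idx])


def sample_from_table(table: VariantFrequencyTable, n: int, rng) -> SampleConfiguration:
    """Sample n items without replacement from an abundance table
    (multivariate hypergeometric); equivalent in law to sample_variants."""
    n = int(n)
    if not (1 <= n <= table.total):
        raise ParameterError(f"sample size must satisfy 1 <= n <= {table.total}, got {n}")
    rng = as_rng(rng)
    draws = rng.multivariate_hypergeometric(table.counts, n)
    return SampleConfiguration.from_counts(draws[draws > 0])


def ne_guess(params: SimParams) -> float:
    """Rough effective-size guess used to budget burn-in and seed the
    approximate-stationary start.

    The unconstrained (ALL) pool behaves like N/(2 - p_death); a finite age
    window behaves like the expected pool size N*(1-(1-p)^c) (the c most
    recent cohorts) when that is the binding constraint (N*p_death for the
    '1' scenario).
    """
    N, p = params.N, params.p_death
    ne_all = N / (2.0 - p)
    if params.is_all_pool:
        return ne_all
    c = int(params.c_thresh)
    pool = N * (1.0 - (1.0 - p) ** c)
    return max(2.0, min(ne_all, pool))


@dataclass
class SteadyStateDiagnostics:
    """Thinned trajectory of richness/heterozygosity plus burn-in metadata."""

    steps: np.ndarray
    richness: np.ndarray
    heterozygosity: np.ndarray
    burn_in_steps: int
    total_steps: int
    t_stat: float
    converged: bool
    extensions: int = 0


def _slope_tstat(x: np.ndarray, y: np.ndarray) -> float:
    """OLS slope t-statistic with a lag-1 autocorrelation (ESS) correction,
    so the |t| < 2 stationarity rule keeps roughly nominal size on an
    autocorrelated trajectory."""
    m = x.size
    if m < 8:
        return 0.0
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float((xc ** 2).sum())
    if sxx == 0:
        return 0.0
    beta = float((xc * yc).sum()) / sxx
    resid = yc - beta * xc
    dof = m - 2
    s2 = float((resid ** 2).sum()) / dof
    if s2 <= 0:
        return 0.0
    t = beta / math.sqrt(s2 / sxx)
    denom = float((resid ** 2).sum())
    if denom > 0:
        rho = float((resid[:-1] * resid[1:]).sum()) / denom
        rho = min(max(rho, 0.0), 0.98)
        t *= math.sqrt((1.0 - rho) / (1.0 + rho))
    return t


def default_burn_in(params: SimParams) -> int:
    """Automatic burn-in length in steps: two relaxation times of the
    summary statistics, 1/(2*mu + 1/Ne_guess) generations, with one
    generation = 1/p_death steps."""
    ne = ne_guess(params)
    tau_gens = 1.0 / (2.0 * params.mu + 1.0 / ne)
    return max(50, int(math.ceil(2.0 * tau_gens / params.p_death)))


def _kernel_state(pop: Population):
    birth = pop.step_index - pop.ages
    return birth.astype(np.int64), pop.variants.astype(np.int64)


def run_kernel_steps(pop: Population, params: SimParams, n_steps: int, rng,
                     rec_cadence: int | None = None):
    """Advance a population n_steps with the compiled kernel.

    Returns (population, (steps, richness, heterozygosity)) records.
    """
    rng = as_rng(rng)
    birth, variant = _kernel_state(pop)
    c = _kernels.C_ALL if params.is_all_pool else int(params.c_thresh)
    cadence = rec_cadence or max(1, n_steps // 100)
    try:
        next_label, nrec, rec_t, rec_k, rec_het = _kernels.run_agent_chunk(
            birth, variant, pop.next_label, pop.step_index, int(n_steps),
            float(params.mu), float(params.p_death), float(params.b), c,
            int(cadence), child_seed(rng))
    except ValueError as exc:                   # raised inside the kernel
        if "empty copy pool" in str(exc):
            raise EmptyPoolError(str(exc)) from None
        raise
    t_new = pop.step_index + int(n_steps)
    new_pop = Population(ages=t_new - birth, variants=variant,
                         next_label=int(next_label), step_index=t_new)
    return new_pop, (rec_t.copy(), rec_k.copy(), rec_het.copy())


def run_to_steady_state(params: SimParams, rng, init: str = "stationary",
                        t_threshold: float = 2.0):
    """Run the model to steady state; return (population, diagnostics).

    The burn-in budget is relaxation-time-based (see
    :func:`default_burn_in`); afterwards the slope of the richness
    trajectory over the last quarter of the run must be statistically
    indistinguishable from zero (|t| < ``t_threshold``, ESS-corrected).
    Failing runs are extended by 50% until ``params.max_steps`` is hit, at
    which point a :class:`~agedrift.core.SteadyStateError` carrying the
    diagnostics is raised.
    """
    rng = as_rng(rng if rng is not None else params.seed)
    if init == "stationary":
        pop = _stationary_population(params, rng)
    elif init == "monomorphic":
        pop = init_population(params, rng)
    else:
        raise ParameterError(f"unknown init mode {init!r}")

    if params.mu == 0.0 and np.unique(pop.variants).size == 1:
        # absorbing state: monomorphic without innovation stays monomorphic
        diag = SteadyStateDiagnostics(
            steps=np.array([0]), richness=np.array([1]),
            heterozygosity=np.array([0.0]), burn_in_steps=0, total_steps=0,
            t_stat=0.0, converged=True)
        return pop, diag

    burn = params.burn_in if params.burn_in is not None else default_burn_in(params)
    max_steps = params.max_steps if params.max_steps is not None else max(6 * burn, 300)
    cadence = max(1, burn // 200)

    all_t, all_k, all_h = [], [], []
    total = 0
    chunk = burn
    extensions = 0
    while True:
        pop, (rt, rk, rh) = run_kernel_steps(pop, params, chunk, rng,
                                             rec_cadence=cadence)
        all_t.append(rt); all_k.append(rk); all_h.append(rh)
        total += chunk
        ts = np.concatenate(all_t)
        ks = np.concatenate(all_k)
        tail = ts >= ts[-1] - max(1, total // 4)
        t_stat = _slope_tstat(ts[tail].astype(float), ks[tail].astype(float))
        if abs(t_stat) < t_threshold:
            diag = SteadyStateDiagnostics(
                steps=ts, richness=ks, heterozygosity=np.concatenate(all_h),
                burn_in_steps=burn, total_steps=total, t_stat=float(t_stat),
                converged=True, extensions=extensions)
            return pop, diag
        if total + burn // 2 > max_steps:
            diag = SteadyStateDiagnostics(
                steps=ts, richness=ks, heterozygosity=np.concatenate(all_h),
                burn_in_steps=burn, total_steps=total, t_stat=float(t_stat),
                converged=False, extensions=extensions)
            raise SteadyStateError(
                f"no steady state within {total} steps (|t|={abs(t_stat):.2f})",
                diagnostics=diag)
        chunk = burn // 2
        extensions += 1
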
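"""Rejection-probability experiments.

For a grid of fixed (b, p_death, c_thresh) constellations, simulate
independent populations to steady state, draw samples of the requested
sizes, apply either the Ewens-Watterson test (reject when P_E <= alpha) or
a trained classifier (reject when the sample is labeled biased), and
tabulate rejection fractions with binomial confidence intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .core import (ALL, ParameterError, SimParams, SteadyStateError, as_rng)
from .classifier import ClassifierBundle, classify_profiles
from .diversity import diversity_profile
from .ewens import ewens_watterson_test
from .simulate import run_to_steady_state, sample_variants, sample_from_table
from .wright_fisher import run_wright_fisher

__all__ = ["rejection_experiment", "simulate_samples"]

# Monte-Carlo draws per Ewens-Watterson test inside experiments: enough for
# alpha = 0.05 decisions (p-value SE ~ 0.003 near the threshold) at a
# fraction of the single-test default cost.
EXPERIMENT_MC_SAMPLES = 5_000


def _simulate_population(params: SimParams, rng, max_retries: int = 3):
    """One steady-state population; WF fast path when there is no age
    structure (p_death = 1, unrestricted pool, so the frequency-table
    dynamic is the same process)."""
    if params.p_death >= 1.0 and params.is_all_pool:
        return run_wright_fisher(params.N, params.mu, params.b, rng)
    for attempt in range(max_retries):
        try:
            pop, _ = run_to_steady_state(params, rng)
            return pop
        except SteadyStateError:
            if attempt == max_retries - 1:
                raise
    raise AssertionError("unreachable")


def simulate_samples(params: SimParams, sample_sizes, rng):
    """One population, sampled once per requested size.

    Returns {n: SampleConfiguration}.
    """
    pop = _simulate_population(params, rng)
    out = {}
    for n in sample_sizes:
        if hasattr(pop, "variants"):
            out[int(n)] = sample_variants(pop, int(n), rng)
        else:                        # frequency table from the WF fast path
            out[int(n)] = sample_from_table(pop, int(n), rng)
    return out


def rejection_experiment(mode: str, grid, n_reps: int, sample_sizes, rng,
                         N: int = 100_000, mu: float = 5e-4,
                         alpha: float = 0.05,
                         mc_samples: int = EXPERIMENT_MC_SAMPLES,
                         bundle: ClassifierBundle | None = None) -> pd.DataFrame:
    """Rejection fractions over a constellation grid.

    Parameters
    ----------
    mode : "ewens" or "ml"
    grid : iterable of dicts with keys b, p_death, c_thresh
        ``c_thresh`` may be an int, "ALL", or -1 (meaning ALL).
        ``p_death = 1`` with an unrestricted pool runs the Wright-Fisher
        fast path.  Per-constellation overrides of N and mu are honored.
    n_reps : int
        Independent populations per constellation (>= 20).
    sample_sizes : iterable of int
        Each population is sampled once per size.
    """
    if mode not in ("ewens", "ml"):
        raise ParameterError(f"mode must be 'ewens' or 'ml', got {mode!r}")
    if n_reps < 20:
        raise ParameterError(f"n_reps must be >= 20, got {n_reps}")
    if mode == "ml" and bundle is None:
        raise ParameterError("ml mode requires a trained ClassifierBundle")
    rng = as_rng(rng)
    sample_sizes = [int(n) for n in sample_sizes]

    rows = []
    for cell in grid:
        c = cell.get("c_thresh", ALL)
        if c == -1:
            c = ALL
        params = SimParams(N=int(cell.get("N", N)), mu=float(cell.get("mu", mu)),
                           p_death=float(cell["p_death"]), c_thresh=c,
                           b=float(cell.get("b", 0.0)))
        rejections = {n: 0 for n in sample_sizes}
        profiles = {n: [] for n in sample_sizes}
        for _ in range(int(n_reps)):
            samples = simulate_samples(params, sample_sizes, rng)
            for n, cfg in samples.items():
                if mode == "ewens":
                    res = ewens_watterson_test(cfg, mc_samples=mc_samples, rng=rng)
                    if res.reject(alpha):
                        rejections[n] += 1
                else:
                    profiles[n].append(diversity_profile(cfg))
        if mode == "ml":
            for n in sample_sizes:
                labels, _ = classify_profiles(bundle, profiles[n])
                rejections[n] = int((labels == "biased").sum())
        for n in sample_sizes:
            ci = binomtest(rejections[n], n_reps).proportion_ci(0.95)
            rows.append({
                "mode": mode, "b": params.b, "p_death": params.p_death,
                "c_thresh": -1 if params.is_all_pool else int(params.c_thresh),
                "N": params.N, "mu": params.mu, "sample_size": n,
                "n_reps": int(n_reps), "n_reject": rejections[n],
                "rejection_fraction": rejections[n] / n_reps,
                "ci_low": float(ci.low), "ci_high": float(ci.high),
            })
    return pd.DataFrame(rows)
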
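"""Variance effective population size of the age-structured model.

The effective size is defined by matching drift to an idealized
Wright-Fisher population on the genealogical time scale of the model:

    N_e = 1 / (lambda * T_gen),

where ``lambda`` is the per-step pairwise-coalescence rate (the decay rate
of expected heterozygosity in a neutral biallelic tracking experiment:
mu = 0, b = 0, two types started 50/50) and ``T_gen`` is the generation
time — one plus the mean age of a role model, in closed form from the
stationary geometric age profile.  This reproduces the model's limits
exactly: the Wright-Fisher case (p_death = 1) has T_gen = 1, lambda = 1/N,
hence N_e = N; the Moran limit p_death -> 1/N gives N/2; the unrestricted
'ALL' scenario gives N/(2 - p_death); and the '1' scenario — whose
reproducing lineage is a per-step Wright-Fisher chain over the N * p_death
newborns of the previous step — gives N * p_death.

Because deaths are exchangeable and only the ``c`` most recent cohorts can
be copied, the biallelic agent model aggregates exactly to ``c + 1``
bucket counts per replicate (the young cohorts plus one "too old to copy"
bucket; a single bucket for ALL), so ensembles of hundreds of replicates
advance in lockstep as small integer matrices.

``lambda`` is measured by one of two backends:

* ensemble heterozygosity decay (robust through fixation; used when the
  coalescent time 1/lambda is short enough to simulate through);
* window variance of the population frequency, E[(Δp)^2] = p0(1-p0)
  * lambda * W for windows of W steps (efficient for large N_e, where
  fixation is unreachable within any affordable horizon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (ALL, EmptyPoolError, ParameterError, SimParams, as_rng)

__all__ = ["NeEstimate", "estimate_ne", "moran_reference_ne", "generation_time"]


@dataclass(frozen=True)
class NeEstimate:
    """Variance-effective-size estimate with bootstrap standard error."""

    ne: float
    scenario: str           # "ALL", "1", or "c=<int>"
    p_death: float
    n_replicates: int
    se: float
    n_windows: int = 0
    method: str = ""

    def __post_init__(self):
        if self.ne <= 0 or self.se < 0:
            raise ParameterError("require ne > 0 and se >= 0")

    def to_dict(self) -> dict:
        return {"ne": self.ne, "scenario": self.scenario,
                "p_death": self.p_death, "n_replicates": self.n_replicates,
                "se": self.se, "n_windows": self.n_windows,
                "method": self.method}


def moran_reference_ne(N: int) -> float:
    """Moran-model comparison baseline N/2 (the p_death -> 1/N limit)."""
    if N < 2:
        raise ParameterError(f"N must be >= 2, got {N}")
    return N / 2.0


def generation_time(p_death: float, c_thresh) -> float:
    """Mean genealogical generation length in steps: 1 + E[stored age of a
    role model], under the stationary geometric age profile.

    ALL: 1 + (1-p)/p = 1/p.  c_thresh = 1: exactly 1 step (role models
    are the previous step's newborns).
    """
    p = float(p_death)
    q = 1.0 - p
    if c_thresh == ALL:
        return 1.0 / p
    c = int(c_thresh)
    if c < 1:
        raise ParameterError(f"c_thresh must be >= 1 or ALL, got {c_thresh}")
    if q == 0.0:
        return 1.0
    a = np.arange(c, dtype=np.float64)
    w = q ** a
    return 1.0 + float((a * w).sum() / w.sum())


def _scenario_name(params: SimParams) -> str:
    if params.is_all_pool:
        return "ALL"
    return "1" if int(params.c_thresh) == 1 else f"c={int(params.c_thresh)}"


def _ne_rough(params: SimParams) -> float:
    """Order-of-magnitude guess used only to budget the measurement."""
    N, p = params.N, params.p_death
    ne_all = N / (2.0 - p)
    if params.is_all_pool:
        return ne_all
    c = int(params.c_thresh)
    return max(2.0, min(ne_all, N * (1.0 - (1.0 - p) ** c)))


class _BiallelicEnsemble:
    """R lockstep replicates of the neutral biallelic model, aggregated to
    bucket counts (sizes, allele-1 counts) of shape (R, B)."""

    def __init__(self, params: SimParams, n_replicates: int, rng):
        self.N = params.N
        self.p = params.p_death
        self.c = 0 if params.is_all_pool else int(params.c_thresh)
        self.B = max(1, self.c + 1 if self.c else 1)
        self.R = int(n_replicates)
        self.rng = rng
        self.sizes = np.empty((self.R, self.B), dtype=np.int64)
        self.ones = np.empty((self.R, self.B), dtype=np.int64)
        self.reset(np.arange(self.R))

    def reset(self, rows) -> None:
        """(Re)initialize rows: stationary bucket sizes, 50/50 alleles."""
        rows = np.atleast_1d(rows)
        if rows.size == 0:
            return
        if self.B == 1:
            self.sizes[rows, 0] = self.N
        else:
            pmf = self.p * (1.0 - self.p) ** np.arange(self.B - 1)
            pmf = np.append(pmf, max(0.0, 1.0 - pmf.sum()))
            self.sizes[rows] = self.rng.multinomial(self.N, pmf, size=rows.size)
        # exchangeable 50/50 split: allocate the N//2 allele-1 carriers
        # across buckets jointly (multivariate hypergeometric)
        for r in rows:
            self.ones[r] = self.rng.multivariate_hypergeometric(
                self.sizes[r], self.N // 2)

    def freq(self) -> np.ndarray:
        return self.ones.sum(axis=1) / self.N

    def step(self) -> None:
        rng = self.rng
        sizes, ones = self.sizes, self.ones
        dead = rng.binomial(sizes, self.p)
        dead_ones = np.zeros_like(dead)
        m = dead > 0
        if m.any():
            dead_ones[m] = rng.hypergeometric(ones[m], sizes[m] - ones[m],
                                              dead[m])
        d = dead.sum(axis=1)
        surv = sizes - dead
        surv_ones = ones - dead_ones

        if self.c == 0:
            pool_n = sizes.sum(axis=1)
            pool_1 = ones.sum(axis=1)
        else:
            pool_n = sizes[:, :self.c].sum(axis=1)
            pool_1 = ones[:, :self.c].sum(axis=1)
        if (pool_n == 0).any():
            raise EmptyPoolError(
                f"copy pool is empty for c_thresh={self.c or 'ALL'}")
        born_1 = rng.binomial(d, pool_1 / pool_n)

        if self.B == 1:
            ones[:, 0] = surv_ones[:, 0] + born_1
        else:
            sizes[:, -1] = surv[:, -1] + surv[:, -2]
            ones[:, -1] = surv_ones[:, -1] + surv_ones[:, -2]
            if self.B > 2:
                sizes[:, 1:-1] = surv[:, :-2]
                ones[:, 1:-1] = surv_ones[:, :-2]
            sizes[:, 0] = d
            ones[:, 0] = born_1


def _lambda_decay(params: SimParams, n_replicates: int, horizon: int,
                  skip: int, fit_end: int, rng, n_bootstrap: int):
    """Per-step coalescence rate from ensemble heterozygosity decay.

    The slope of log E[H_t] is fitted over a *predetermined* early-decay
    window [skip, fit_end] (about one expected coalescent time), where
    the ensemble mean is well resolved; a data-dependent window would
    couple fit-range selection to noise and inflate the variance beyond
    the bootstrap's estimate.
    """
    ens = _BiallelicEnsemble(params, n_replicates, rng)
    cadence = max(1, (horizon - skip) // 150)
    rec_t, H = [], []
    for t in range(horizon + 1):
        if t >= skip and (t - skip) % cadence == 0:
            f = ens.freq()
            H.append(2.0 * f * (1.0 - f))
            rec_t.append(t)
        if t < horizon:
            ens.step()
    rec_t = np.asarray(rec_t, dtype=float)
    H = np.asarray(H)                      # (T_rec, R)
    window = rec_t <= fit_end

    def fit(h_mean):
        keep = window & (h_mean > 1e-8)
        x, y = rec_t[keep], np.log(h_mean[keep])
        if x.size < 3 or x[-1] == x[0]:
            return np.nan
        return -np.polyfit(x, y, 1)[0]

    lam = fit(H.mean(axis=1))
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, ens.R, ens.R)
        boots.append(fit(H[:, idx].mean(axis=1)))
    boots = np.asarray(boots)
    boots = boots[np.isfinite(boots)]
    se = float(np.std(boots, ddof=1)) if boots.size > 2 else np.nan
    return lam, se, ens.R


def _lambda_window(params: SimParams, n_windows: int, window: int,
                   rng, band, skip_windows: int, n_replicates: int = 32):
    """Per-step coalescence rate from window variance of the frequency."""
    ens = _BiallelicEnsemble(params, n_replicates, rng)
    skip = np.full(ens.R, skip_windows)
    F = []
    while len(F) < n_windows:
        p0 = ens.freq()
        out = (p0 < band[0]) | (p0 > band[1])
        if out.any():
            ens.reset(np.flatnonzero(out))
            skip[out] = skip_windows
            p0 = ens.freq()
        for _ in range(window):
            ens.step()
        p1 = ens.freq()
        usable = skip == 0
        F.extend(((p1 - p0) ** 2 / (p0 * (1.0 - p0)))[usable].tolist())
        skip[~usable] -= 1
    F = np.asarray(F[:n_windows])
    lam = F.mean() / window
    boot = rng.choice(F, size=(200, F.size), replace=True).mean(axis=1) / window
    return float(lam), float(np.std(boot, ddof=1)), len(F)


def estimate_ne(params: SimParams, n_replicates: int | None = None,
                horizon: int | None = None, rng=None,
                band: tuple[float, float] = (0.1, 0.9),
                n_bootstrap: int = 100) -> NeEstimate:
    """Estimate the variance effective size of an age-structured scenario.

    ``params`` must be neutral and innovation-free (mu = 0, b = 0); the
    measurement tracks two variant types started at 50/50.  The backend is
    chosen automatically: heterozygosity decay when the coalescent time is
    short enough to simulate through, window variance otherwise.
    """
    if params.mu != 0.0 or params.b != 0.0:
        raise ParameterError("estimate_ne requires mu = 0 and b = 0 "
                             "(neutral biallelic tracking)")
    rng = as_rng(rng if rng is not None else params.seed)
    p = params.p_death
    t_gen = generation_time(p, params.c_thresh)
    lam_guess = 1.0 / (_ne_rough(params) * t_gen)

    if 1.0 / lam_guess <= 60_000:
        reps = int(n_replicates) if n_replicates is not None else 800
        skip = int(round(4.0 / p))
        hor = int(horizon) if horizon is not None else skip + int(1.3 / lam_guess)
        fit_end = skip + int(1.2 / lam_guess)
        lam, lam_se, nw = _lambda_decay(params, reps, hor, skip, fit_end,
                                        rng, n_bootstrap)
        method = "het_decay"
    else:
        window = max(1, int(round(20.0 / p)))      # ~20 generations
        n_windows = int(n_replicates * 100) if n_replicates is not None else 4000
        lam, lam_se, nw = _lambda_window(params, n_windows, window, rng,
                                         band, skip_windows=2)
        method = "window_variance"

    if not np.isfinite(lam) or lam <= 0:
        raise RuntimeError("coalescence-rate measurement failed "
                           f"(lambda={lam}); increase replicates or horizon")
    ne = 1.0 / (lam * t_gen)
    se = ne * (lam_se / lam) if np.isfinite(lam_se) else 0.0
    return NeEstimate(ne=float(ne), scenario=_scenario_name(params),
                      p_death=p, n_replicates=nw,
                      se=float(se), n_windows=nw, method=method)
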
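"""Compiled inner loops for the age-structured simulator.

The kernel advances the population in-place using an O(deaths)-per-step
scheme:

* death indices come from geometric gap sampling of the Bernoulli death
  process;
* for unbiased copying (b = 0) role models are drawn uniformly: directly
  for the unrestricted (ALL) pool, by rejection against the age window
  for wide windows, or from a FIFO buffer of recent newborn entries for
  narrow windows (e.g. the '1' scenario), with per-entry staleness checks
  so each living pool member is drawn uniformly;
* frequency-dependent copying (b != 0) keeps exact pool variant counts
  incrementally — updated on every birth, death, and window expiry (the
  FIFO supplies the cohort that ages out) — so each step only iterates
  the present variant types to build the weighted adoption distribution.

State is stored as birth steps rather than ages (age = t - birth), which
makes aging free.  Pool ages are measured after aging: the window
``c_thresh`` covers stored ages ``0..c-1`` of the previous state, i.e.
the c most recent cohorts including the previous step's newborns.  These
loops are semantically equivalent to the readable
``agedrift.simulate.step``; the equivalence is checked distributionally
in the test suite.
"""

import numpy as np
from numba import njit

# c_thresh encoding for the kernel: -1 means the unrestricted (ALL) pool.
C_ALL = -1


@njit(cache=True)
def _pool_scan(birth, t, c, buf):
    """Collect the copy pool for window c at time t into buf; return count.

    A role model of age 1..c at the copying moment has stored age 0..c-1
    in the time-t state.
    """
    m = 0
    for i in range(birth.shape[0]):
        a = t - birth[i]
        if a <= c - 1:
            buf[m] = i
            m += 1
    return m


@njit(cache=True)
def _richness_het(variant):
    """(number of types, heterozygosity 1 - sum f_i^2) of a population."""
    sv = np.sort(variant)
    n = sv.shape[0]
    k = 0
    ss = 0.0
    run = 1
    for i in range(1, n):
        if sv[i] == sv[i - 1]:
            run += 1
        else:
            k += 1
            ss += (run / n) ** 2
            run = 1
    k += 1
    ss += (run / n) ** 2
    return k, 1.0 - ss


@njit(cache=True)
def run_agent_chunk(birth, variant, next_label, t0, n_steps,
                    mu, p_death, b, c, rec_cadence, seed):
    """Advance the population n_steps from time t0, mutating birth/variant.

    Returns (next_label, n_records, rec_step, rec_richness, rec_het).
    Records are taken every rec_cadence steps (and at the final step).
    """
    np.random.seed(seed)
    N = birth.shape[0]
    dead = np.empty(N, np.int64)
    newv = np.empty(N, np.int64)
    pool_buf = np.empty(N, np.int64)

    n_rec_max = n_steps // rec_cadence + 2
    rec_step = np.empty(n_rec_max, np.int64)
    rec_k = np.empty(n_rec_max, np.int64)
    rec_het = np.empty(n_rec_max, np.float64)
    nrec = 0

    biased = b != 0.0

    # --- FIFO of recent newborn entries -------------------------------
    # Used for uniform draws from narrow windows (b = 0) and to detect
    # cohorts aging out of the window for incremental counts (b != 0).
    use_fifo = False
    fcap = 0
    if c != C_ALL:
        acc_est = 1.0 - (1.0 - p_death) ** c
        if biased or acc_est < 0.25:
            use_fifo = True
            mean_d = N * p_death
            sd_d = (N * p_death * (1.0 - p_death)) ** 0.5
            fcap = int((c + 2) * (mean_d + 6.0 * sd_d) + N + 64)
    fifo_idx = np.empty(max(fcap, 1), np.int64)
    fifo_birth = np.empty(max(fcap, 1), np.int64)
    f_tail = 0
    f_head = 0          # total entries ever appended (head pointer)
    if use_fifo:
        # seed from current state: stored ages c-1..0, oldest first so
        # trimming stays monotone in birth step
        for a in range(c - 1, -1, -1):
            bs = t0 - a
            for i in range(N):
                if birth[i] == bs:
                    fifo_idx[f_head % fcap] = i
                    fifo_birth[f_head % fcap] = bs
                    f_head += 1

    # --- incremental pool counts for frequency-dependent copying ------
    # cnt is indexed by variant label; keys lists candidate labels (may
    # contain extinct ones, compacted lazily).
    cap = 0
    if biased:
        cap = int(next_label + n_steps * N * p_death * mu * 2.0 + 4096)
    cnt = np.zeros(max(cap, 1), np.int64)
    keys = np.empty(max(cap, 1), np.int64)
    cumw = np.empty(max(cap, 1), np.float64)
    dist_keys = np.empty(max(cap, 1), np.int64)
    nk = 0
    if biased:
        if c == C_ALL:
            for i in range(N):
                cnt[variant[i]] += 1
        else:
            for i in range(N):
                if t0 - birth[i] <= c - 1:
                    cnt[variant[i]] += 1
        # collect present labels by scanning the label space once
        for v in range(next_label):
            if v < cap and cnt[v] > 0:
                keys[nk] = v
                nk += 1

    max_tries = 200 + int(100.0 / max(p_death * (1.0 - p_death), 1e-3))

    for t in range(t0, t0 + n_steps):
        # -- deaths: Bernoulli(p_death) per individual via geometric gaps
        nd = 0
        if p_death >= 1.0:
            for i in range(N):
                dead[i] = i
            nd = N
        else:
            i = np.random.geometric(p_death) - 1
            while i < N:
                dead[nd] = i
                nd += 1
                i += np.random.geometric(p_death)

        if use_fifo:
            # expire entries older than the window (stored age > c-1);
            # for biased copying their variants leave the pool counts
            while f_tail < f_head and fifo_birth[f_tail % fcap] < t - (c - 1):
                if biased:
                    idx = fifo_idx[f_tail % fcap]
                    if birth[idx] == fifo_birth[f_tail % fcap]:
                        cnt[variant[idx]] -= 1
                f_tail += 1

        if nd > 0:
            if not biased:
                pool_m = -1      # lazily materialized on budget overflow
                for j in range(nd):
                    if mu > 0.0 and np.random.random() < mu:
                        newv[j] = next_label
                        next_label += 1
                    elif c == C_ALL:
                        newv[j] = variant[np.random.randint(0, N)]
                    elif pool_m >= 0:
                        newv[j] = variant[pool_buf[np.random.randint(0, pool_m)]]
                    elif use_fifo:
                        tries = 0
                        while True:
                            if f_head == f_tail:
                                raise ValueError("empty copy pool: no individual in the age range")
                            pos = f_tail + np.random.randint(0, f_head - f_tail)
                            idx = fifo_idx[pos % fcap]
                            fb = fifo_birth[pos % fcap]
                            if birth[idx] == fb:    # not stale
                                newv[j] = variant[idx]
                                break
                            tries += 1
                            if tries > max_tries:
                                pool_m = _pool_scan(birth, t, c, pool_buf)
                                if pool_m == 0:
                                    raise ValueError("empty copy pool: no individual in the age range")
                                newv[j] = variant[pool_buf[np.random.randint(0, pool_m)]]
                                break
                    else:
                        tries = 0
                        while True:
                            idx = np.random.randint(0, N)
                            if t - birth[idx] <= c - 1:
                                newv[j] = variant[idx]
                                break
                            tries += 1
                            if tries > max_tries:
                                pool_m = _pool_scan(birth, t, c, pool_buf)
                                if pool_m == 0:
                                    raise ValueError("empty copy pool: no individual in the age range")
                                newv[j] = variant[pool_buf[np.random.randint(0, pool_m)]]
                                break
            else:
                # weighted adoption over the pool's variant counts
                # (pre-death snapshot: cnt reflects the time-t window)
                m = 0
                tot = 0.0
                for q in range(nk):
                    v = keys[q]
                    if cnt[v] > 0:
                        tot += cnt[v] ** (1.0 + b)
                        cumw[m] = tot
                        dist_keys[m] = v
                        m += 1
                if m == 0:
                    raise ValueError("empty copy pool: no individual in the age range")
                if m < nk // 2:
                    # compact the candidate list
                    for q in range(m):
                        keys[q] = dist_keys[q]
                    nk = m
                for j in range(nd):
                    if mu > 0.0 and np.random.random() < mu:
                        if next_label >= cap:
                            raise ValueError("variant-label capacity exceeded; rerun in shorter chunks")
                        newv[j] = next_label
                        keys[nk] = next_label   # genuinely new label
                        nk += 1
                        next_label += 1
                    else:
                        r = np.random.random() * tot
                        pos = np.searchsorted(cumw[:m], r)
                        if pos >= m:
                            pos = m - 1
                        # copied labels are already in the candidate list
                        newv[j] = dist_keys[pos]

            # -- replacement: newborns take the dead slots at age 0
            for j in range(nd):
                slot = dead[j]
                if biased:
                    # the departing individual leaves the pool counts if
                    # it was inside the window (older ones already left)
                    if c == C_ALL or t - birth[slot] <= c - 1:
                        cnt[variant[slot]] -= 1
                    cnt[newv[j]] += 1
                variant[slot] = newv[j]
                birth[slot] = t + 1
            if use_fifo:
                if f_head - f_tail + nd > fcap:
                    # compact: drop stale entries (their index was reborn)
                    w = f_tail
                    for pos in range(f_tail, f_head):
                        idx = fifo_idx[pos % fcap]
                        if birth[idx] == fifo_birth[pos % fcap]:
                            fifo_idx[w % fcap] = idx
                            fifo_birth[w % fcap] = fifo_birth[pos % fcap]
                            w += 1
                    f_head = w
                for j in range(nd):
                    fifo_idx[f_head % fcap] = dead[j]
                    fifo_birth[f_head % fcap] = t + 1
                    f_head += 1

        if (t + 1 - t0) % rec_cadence == 0 or t == t0 + n_steps - 1:
            kk, het = _richness_het(variant)
            rec_step[nrec] = t + 1
            rec_k[nrec] = kk
            rec_het[nrec] = het
            nrec += 1

    return next_label, nrec, rec_step[:nrec], rec_k[:nrec], rec_het[:nrec]
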
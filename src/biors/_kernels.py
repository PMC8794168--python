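"""Compiled inner loops: windowed consensus scanning, whole-genome staircase
fitness, population mutation, and the (parallel) hill-climbing chains.

Everything here operates on uint8 code arrays (A,C,G,U -> 0..3) and the
position/value arrays produced by ``ConsensusSpec.encoded()`` /
``AlternativeConsensusSpec.encoded()``. Fitness modes are encoded as
MODE_SIMPLE=0, MODE_ALTERNATIVE=1, MODE_COMPETITIVE=2. Random draws use
numba's internal RNG; call :func:`seed_kernels` once per run.
"""

import numpy as np
from numba import njit

MODE_SIMPLE = 0
MODE_ALTERNATIVE = 1
MODE_COMPETITIVE = 2

_EMPTY_POS = np.empty(0, dtype=np.int64)
_EMPTY_VAL = np.empty(0, dtype=np.uint8)


@njit(cache=True)
def seed_kernels(seed):
    np.random.seed(seed)


@njit(cache=True)
def scan_simple(g, start, n_offsets, upos, uval, tpos, tpref, talt):
    """Best core placement in g[start:...] over offsets 0..n_offsets-1.

    Returns (fits, increment, offset); ties broken by smallest offset.
    """
    best_inc = -1
    best_off = -1
    for w in range(n_offsets):
        base = start + w
        inc = 0
        ok = True
        for j in range(upos.size):
            if g[base + upos[j]] != uval[j]:
                ok = False
                break
            inc += 1
        if not ok:
            continue
        for j in range(tpos.size):
            x = g[base + tpos[j]]
            if x == tpref[j]:
                inc += 1
            elif x != talt[j]:
                ok = False
                break
        if ok and inc > best_inc:
            best_inc = inc
            best_off = w
    if best_off < 0:
        return False, 0, -1
    return True, best_inc, best_off


@njit(cache=True)
def scan_alternative(g, start, n_offsets, upos, uval,
                     m1pos, m1val, m1alt, m2pos, m2val, m2alt):
    """As :func:`scan_simple` for the two-structure consensus.

    Returns (fits, increment, offset, s1, s2) for the best placement,
    where increment = max(s1, s2).
    """
    best_inc = -1
    best_off = -1
    best_s1 = 0
    best_s2 = 0
    for w in range(n_offsets):
        base = start + w
        s1 = 0
        s2 = 0
        ok = True
        for j in range(upos.size):
            if g[base + upos[j]] != uval[j]:
                ok = False
                break
            s1 += 1
            s2 += 1
        if not ok:
            continue
        for j in range(m1pos.size):
            x = g[base + m1pos[j]]
            if x == m1val[j]:
                s1 += 1
            elif x != m1alt[j]:
                ok = False
                break
        if not ok:
            continue
        for j in range(m2pos.size):
            x = g[base + m2pos[j]]
            if x == m2val[j]:
                s2 += 1
            elif x != m2alt[j]:
                ok = False
                break
        if not ok:
            continue
        inc = s1 if s1 > s2 else s2
        if inc > best_inc:
            best_inc = inc
            best_off = w
            best_s1 = s1
            best_s2 = s2
    if best_off < 0:
        return False, 0, -1, 0, 0
    return True, best_inc, best_off, best_s1, best_s2


@njit(cache=True)
def fitness_total(g, mode, n_domains, seg_len, n_offsets, delta,
                  upos, uval, tpos, tpref, talt,
                  m1pos, m1val, m1alt, m2pos, m2val, m2alt):
    """Staircase fitness: (total, found_prefix, min_increment_over_prefix).

    Segments are scanned left to right; the prefix stops at the first
    non-fitting segment and, in competitive mode, after any domain whose
    predecessor classifies as cloverleaf (s1 < s2).
    """
    total = 0
    prefix = 0
    ming = 0
    prev_rod = True
    for i in range(n_domains):
        start = i * seg_len
        if mode == MODE_SIMPLE:
            fits, inc, _ = scan_simple(g, start, n_offsets, upos, uval, tpos, tpref, talt)
            s1 = 1
            s2 = 0
        else:
            fits, inc, _, s1, s2 = scan_alternative(
                g, start, n_offsets, upos, uval, m1pos, m1val, m1alt, m2pos, m2val, m2alt)
        if not fits:
            break
        if mode == MODE_COMPETITIVE and i > 0 and not prev_rod:
            break
        if prefix == 0 or inc < ming:
            ming = inc
        prefix += 1
        total += delta + inc
        prev_rod = s1 >= s2
    return total, prefix, ming


@njit(cache=True)
def eval_population(pop, mode, n_domains, seg_len, n_offsets, delta,
                    upos, uval, tpos, tpref, talt,
                    m1pos, m1val, m1alt, m2pos, m2val, m2alt,
                    fit_out, prefix_out, ming_out):
    for r in range(pop.shape[0]):
        f, p, mg = fitness_total(pop[r], mode, n_domains, seg_len, n_offsets, delta,
                                 upos, uval, tpos, tpref, talt,
                                 m1pos, m1val, m1alt, m2pos, m2val, m2alt)
        fit_out[r] = f
        prefix_out[r] = p
        ming_out[r] = mg


@njit(cache=True)
def mutate_rows(pop, p, allowed, scratch):
    """Point-mutate every row of ``pop`` in place.

    Each position listed in ``allowed`` flips, independently with
    probability ``p``, to one of the three other symbols. Realized exactly:
    k ~ Binomial(len(allowed), p), then a uniform k-subset of ``allowed``
    via partial Fisher-Yates on ``scratch`` (a permutation of ``allowed``,
    reused across calls).
    """
    n = allowed.size
    for r in range(pop.shape[0]):
        k = np.random.binomial(n, p)
        for t in range(k):
            j = t + np.random.randint(0, n - t)
            tmp = scratch[t]
            scratch[t] = scratch[j]
            scratch[j] = tmp
            pos = scratch[t]
            nv = np.random.randint(0, 3)
            if nv >= pop[r, pos]:
                nv += 1
            pop[r, pos] = nv


@njit(cache=True)
def _mutation_range(local, mode, prefix, n_domains, seg_len, L):
    """Mutable position range [lo, hi) for the current epoch.

    Without local mutagenesis the whole chromosome mutates. With it, only
    the segment currently searched (index = found prefix) mutates; in
    competitive mode the segment of the previously found domain is also
    open, since continuing may require re-folding it.
    """
    if not local:
        return 0, L
    seg = prefix
    if seg >= n_domains:
        seg = n_domains - 1
    lo = seg * seg_len
    hi = lo + seg_len
    if mode == MODE_COMPETITIVE and seg > 0:
        lo -= seg_len
    return lo, hi


@njit(cache=True)
def _mutate_span(g, lo, n, nmut_rate, pos_buf, old_buf):
    """Bernoulli point mutations on g[lo:lo+n]; returns the change count.

    Changed positions/old values are recorded in pos_buf/old_buf so a
    rejected mutant can be reverted.
    """
    k = np.random.binomial(n, nmut_rate)
    m = 0
    while m < k:
        pos = lo + np.random.randint(0, n)
        dup = False
        for t in range(m):
            if pos_buf[t] == pos:
                dup = True
                break
        if dup:
            continue
        pos_buf[m] = pos
        old_buf[m] = g[pos]
        nv = np.random.randint(0, 3)
        if nv >= g[pos]:
            nv += 1
        g[pos] = nv
        m += 1
    return k


@njit(cache=True)
def rmhc(g, nmut_rate, local, eval_cap, min_inc, mode, n_domains, seg_len,
         n_offsets, delta, upos, uval, tpos, tpref, talt,
         m1pos, m1val, m1alt, m2pos, m2val, m2alt,
         epoch_evals, pos_buf, old_buf):
    """Random-mutation hill climbing on a single chromosome (in place).

    A mutant is accepted iff its fitness is >= the current fitness; the
    search ends when all domains are found (each with gradual increment >=
    ``min_inc``) or the evaluation cap is hit. One fitness evaluation per
    mutant, plus one for the start sequence. ``epoch_evals[q-1]`` records
    the evaluation count at which the found prefix first reached q.
    Returns (evaluations, best_fitness, best_prefix).
    """
    L = g.size
    cur_fit, cur_prefix, cur_ming = fitness_total(
        g, mode, n_domains, seg_len, n_offsets, delta,
        upos, uval, tpos, tpref, talt, m1pos, m1val, m1alt, m2pos, m2val, m2alt)
    evals = 1
    for q in range(cur_prefix):
        if epoch_evals[q] < 0:
            epoch_evals[q] = evals
    while not (cur_prefix == n_domains and cur_ming >= min_inc) and evals < eval_cap:
        lo, hi = _mutation_range(local, mode, cur_prefix, n_domains, seg_len, L)
        k = _mutate_span(g, lo, hi - lo, nmut_rate, pos_buf, old_buf)
        f, pf, mg = fitness_total(g, mode, n_domains, seg_len, n_offsets, delta,
                                  upos, uval, tpos, tpref, talt,
                                  m1pos, m1val, m1alt, m2pos, m2val, m2alt)
        evals += 1
        if f >= cur_fit:
            cur_fit = f
            cur_prefix = pf
            cur_ming = mg
            for q in range(pf):
                if epoch_evals[q] < 0:
                    epoch_evals[q] = evals
        else:
            for t in range(k - 1, -1, -1):
                g[pos_buf[t]] = old_buf[t]
    return evals, cur_fit, cur_prefix


@njit(cache=True)
def parallel_rmhc(pop, nmut_rate, local, eval_cap, min_inc, mode, n_domains,
                  seg_len, n_offsets, delta, upos, uval, tpos, tpref, talt,
                  m1pos, m1val, m1alt, m2pos, m2val, m2alt,
                  epoch_evals, pos_buf, old_buf):
    """M synchronized hill climbers sharing a rising fitness threshold.

    All climbers step in round-robin order. When any climber reaches the
    current threshold (multiples of delta, starting at delta), every
    climber is replaced by a copy of the best one and the threshold rises
    by delta; the search succeeds when a chromosome of fitness >=
    n_domains*delta (with every domain increment >= ``min_inc``) is found.
    Returns (evaluations, best_fit, best_prefix, best_row).
    """
    M, L = pop.shape
    fits = np.empty(M, dtype=np.int64)
    prefixes = np.empty(M, dtype=np.int64)
    mings = np.empty(M, dtype=np.int64)
    evals = 0
    for m in range(M):
        f, p, mg = fitness_total(pop[m], mode, n_domains, seg_len, n_offsets, delta,
                                 upos, uval, tpos, tpref, talt,
                                 m1pos, m1val, m1alt, m2pos, m2val, m2alt)
        evals += 1
        fits[m] = f
        prefixes[m] = p
        mings[m] = mg
        for q in range(p):
            if epoch_evals[q] < 0:
                epoch_evals[q] = evals
    threshold = delta
    while True:
        synced = False
        for m in range(M):
            if evals >= eval_cap:
                b = np.argmax(fits)
                return evals, fits[b], prefixes[b], b
            g = pop[m]
            lo, hi = _mutation_range(local, mode, prefixes[m], n_domains, seg_len, L)
            k = _mutate_span(g, lo, hi - lo, nmut_rate, pos_buf, old_buf)
            f, p, mg = fitness_total(g, mode, n_domains, seg_len, n_offsets, delta,
                                     upos, uval, tpos, tpref, talt,
                                     m1pos, m1val, m1alt, m2pos, m2val, m2alt)
            evals += 1
            if f >= fits[m]:
                fits[m] = f
                prefixes[m] = p
                mings[m] = mg
                for q in range(p):
                    if epoch_evals[q] < 0:
                        epoch_evals[q] = evals
            else:
                for t in range(k - 1, -1, -1):
                    g[pos_buf[t]] = old_buf[t]
            if prefixes[m] == n_domains and mings[m] >= min_inc:
                return evals, fits[m], prefixes[m], m
            if fits[m] >= threshold:
                # synchronize: clone the best climber into all M slots
                b = np.argmax(fits)
                for r in range(M):
                    if r != b:
                        pop[r, :] = pop[b, :]
                        fits[r] = fits[b]
                        prefixes[r] = prefixes[b]
                        mings[r] = mings[b]
                while threshold <= fits[b]:
                    threshold += delta
                synced = True
                break  # restart the sweep from climber 0
        if synced:
            continue
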
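"""Numba kernels for the O(n^3) folding recursions.

All kernels operate on precomputed per-pair score matrices so that the same
dynamic programs serve both single-sequence folding (scores = pair energies)
and alignment consensus folding (scores = averaged column-pair scores).

Decomposition (right-anchored, unambiguous):

    C(i,j)   best/partition over structures on [i,j] with (i,j) paired
    Ex(i,j)  ... with (i,j) NOT paired
    E(i,j)   all structures on [i,j]

    C(i,j)  = e(i,j) + min( C(i+1,j-1) + w(i,j), Ex(i+1,j-1) )
    Ex(i,j) = min( E(i,j-1),  min_{k=i+1..j-4} E(i,k-1) + C(k,j) )
    E(i,j)  = min( Ex(i,j), C(i,j) )

where w(i,j) is the stacking increment awarded when (i+1,j-1) is paired
directly beneath (i,j).  The partition-function kernels are the same
recursions with (min,+) replaced by (logsumexp,+) on Boltzmann weights, and
an outside pass recovers exact pair probabilities.
"""

import numpy as np
from numba import njit

BIG = 1e30
NEG_INF = -np.inf


@njit(cache=True)
def _ladd(a, b):
    """log(exp(a) + exp(b)), safe with -inf."""
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + np.log1p(np.exp(b - a))


@njit(cache=True)
def mfe_matrices(e, w, forced_paired, min_hairpin):
    """Fill the minimisation DP tables.

    e : (n,n) pair score, >= BIG where pairing is disallowed
    w : (n,n) stacking increment for (i,j) over (i+1,j-1)
    forced_paired : (n,) bool, position must be paired in every structure
    Returns (C, Ex, E) tables; empty regions have energy 0 unless a forced
    position makes them infeasible (BIG).
    """
    n = e.shape[0]
    FEAS = BIG / 2.0  # values >= FEAS are treated as infeasible
    C = np.full((n, n), BIG)
    Ex = np.full((n, n), BIG)
    E = np.full((n, n), BIG)
    for i in range(n):
        E[i, i] = BIG if forced_paired[i] else 0.0
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            # C
            if e[i, j] < FEAS and span >= min_hairpin + 1:
                a, b = i + 1, j - 1
                if b < a:
                    interior = 0.0
                elif b == a:
                    interior = E[a, a]
                else:
                    interior = Ex[a, b]
                    if C[a, b] < FEAS:
                        v = C[a, b] + w[i, j]
                        if v < interior:
                            interior = v
                if interior < FEAS:
                    C[i, j] = e[i, j] + interior
            # Ex
            best = BIG
            if not forced_paired[j]:
                left = E[i, j - 1] if j - 1 >= i else 0.0
                if left < best:
                    best = left
            for k in range(i + 1, j - min_hairpin):
                if C[k, j] >= FEAS:
                    continue
                left = E[i, k - 1] if k - 1 >= i else 0.0
                if left >= FEAS:
                    continue
                v = left + C[k, j]
                if v < best:
                    best = v
            Ex[i, j] = best
            E[i, j] = min(best, C[i, j])
    return C, Ex, E


@njit(cache=True)
def pf_inside(lq, ls, forced_paired, min_hairpin):
    """Inside pass of the partition function in log space.

    lq : (n,n) log Boltzmann weight of pairing (i,j)  (-inf if disallowed)
    ls : (n,n) log stacking weight for (i,j) over (i+1,j-1)
    Returns (lC, lEx, lE) with lE[i,j] = log Z over structures on [i,j].
    """
    n = lq.shape[0]
    lC = np.full((n, n), NEG_INF)
    lEx = np.full((n, n), NEG_INF)
    lE = np.full((n, n), NEG_INF)
    for i in range(n):
        lE[i, i] = NEG_INF if forced_paired[i] else 0.0
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            if lq[i, j] > NEG_INF and span >= min_hairpin + 1:
                a, b = i + 1, j - 1
                if b < a:
                    interior = 0.0
                elif b == a:
                    interior = lE[a, a]
                else:
                    interior = lEx[a, b]
                    if lC[a, b] > NEG_INF:
                        interior = _ladd(interior, lC[a, b] + ls[i, j])
                if interior > NEG_INF:
                    lC[i, j] = lq[i, j] + interior
            acc = NEG_INF
            if not forced_paired[j]:
                acc = lE[i, j - 1] if j - 1 >= i else 0.0
            for k in range(i + 1, j - min_hairpin):
                if lC[k, j] == NEG_INF:
                    continue
                left = lE[i, k - 1] if k - 1 >= i else 0.0
                if left == NEG_INF:
                    continue
                acc = _ladd(acc, left + lC[k, j])
            lEx[i, j] = acc
            lE[i, j] = _ladd(acc, lC[i, j])
    return lC, lEx, lE


@njit(cache=True)
def pf_outside(lq, ls, forced_paired, min_hairpin, lC, lEx, lE):
    """Outside pass; returns log pair probabilities lP[i,j] (upper triangle).

    Outside weights mirror every usage of the inside objects:
      hZ(a,b)  outside of E(a,b);  hEx, hB likewise for Ex and C.
    """
    n = lq.shape[0]
    hZ = np.full((n, n), NEG_INF)
    hEx = np.full((n, n), NEG_INF)
    hB = np.full((n, n), NEG_INF)
    lP = np.full((n, n), NEG_INF)
    if n == 0:
        return lP
    hZ[0, n - 1] = 0.0
    ltotal = lE[0, n - 1]
    for span in range(n - 1, 0, -1):
        for a in range(0, n - span):
            b = a + span
            # hZ(a,b): E(a,b) used in Ex(a,b+1) "b+1 unpaired" branch and in
            # Ex(a,j) split terms E(a,k-1)*C(k,j) with k=b+1.
            if not (a == 0 and b == n - 1):
                acc = NEG_INF
                if b + 1 <= n - 1 and not forced_paired[b + 1]:
                    acc = hEx[a, b + 1]
                k = b + 1
                for j in range(k + min_hairpin + 1, n):
                    if lC[k, j] == NEG_INF or hEx[a, j] == NEG_INF:
                        continue
                    acc = _ladd(acc, hEx[a, j] + lC[k, j])
                hZ[a, b] = acc
            # hEx(a,b): Ex used in E(a,b) and in C(a-1,b+1) interior; the
            # enclosing pair (a-1,b+1) must itself satisfy the hairpin rule.
            enclosing = (
                a >= 1
                and b + 1 <= n - 1
                and lq[a - 1, b + 1] > NEG_INF
                and (b + 1) - (a - 1) >= min_hairpin + 1
            )
            acc = hZ[a, b]
            if enclosing and hB[a - 1, b + 1] > NEG_INF:
                acc = _ladd(acc, hB[a - 1, b + 1] + lq[a - 1, b + 1])
            hEx[a, b] = acc
            # hB(a,b): C used in E(a,b), in Ex(i,b) splits (k=a), and in the
            # stacked interior of C(a-1,b+1).
            acc = hZ[a, b]
            for i in range(0, a):
                if hEx[i, b] == NEG_INF:
                    continue
                left = lE[i, a - 1] if a - 1 >= i else 0.0
                if left == NEG_INF:
                    continue
                acc = _ladd(acc, hEx[i, b] + left)
            if enclosing and hB[a - 1, b + 1] > NEG_INF:
                acc = _ladd(
                    acc, hB[a - 1, b + 1] + lq[a - 1, b + 1] + ls[a - 1, b + 1]
                )
            hB[a, b] = acc
            if lC[a, b] > NEG_INF and hB[a, b] > NEG_INF:
                lP[a, b] = lC[a, b] + hB[a, b] - ltotal
    # single-cell spans never pair; nothing to do for span 0
    return lP


@njit(cache=True)
def dinuc_counts(A, gap_code, n_codes):
    """Per-row dinucleotide counts over de-gapped rows.

    A : (n_rows, n_cols) int8 alignment matrix.
    Returns (n_rows, n_codes, n_codes) int32 counts.
    """
    n_rows, n_cols = A.shape
    out = np.zeros((n_rows, n_codes, n_codes), dtype=np.int32)
    for r in range(n_rows):
        prev = -1
        for c in range(n_cols):
            x = A[r, c]
            if x == gap_code:
                continue
            if prev >= 0:
                out[r, prev, x] += 1
            prev = x
    return out


@njit(cache=True, inline="always")
def _popcount64(x):
    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + (
        (x >> np.uint64(2)) & np.uint64(0x3333333333333333)
    )
    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (x * np.uint64(0x0101010101010101)) >> np.uint64(56)


@njit(cache=True)
def _dinuc_dev(A, native, gap_code):
    """Sum over rows of |dinucleotide count difference| vs `native`."""
    n_rows, n_cols = A.shape
    dev = 0
    cur = np.zeros((6, 6), dtype=np.int64)
    for r in range(n_rows):
        for x in range(6):
            for y in range(6):
                cur[x, y] = 0
        prev = -1
        for c in range(n_cols):
            x = A[r, c]
            if x == gap_code:
                continue
            if prev >= 0:
                cur[prev, x] += 1
            prev = x
        for x in range(6):
            for y in range(6):
                d = cur[x, y] - native[r, x, y]
                dev += d if d >= 0 else -d
    return dev


@njit(cache=True)
def dinuc_repair(A, native, members_flat, class_start, n_trials, seed, gap_code):
    """Greedy within-class column swaps reducing dinucleotide deviation.

    A is modified in place.  `members_flat`/`class_start` encode the
    conservation classes (only classes with >= 2 members).  Returns the
    final deviation.
    """
    np.random.seed(seed)
    n_classes = len(class_start) - 1
    dev = _dinuc_dev(A, native, gap_code)
    if n_classes == 0:
        return dev
    n_rows = A.shape[0]
    for _ in range(n_trials):
        c = np.random.randint(n_classes)
        lo, hi = class_start[c], class_start[c + 1]
        size = hi - lo
        p = members_flat[lo + np.random.randint(size)]
        q = members_flat[lo + np.random.randint(size)]
        if p == q:
            continue
        for r in range(n_rows):
            A[r, p], A[r, q] = A[r, q], A[r, p]
        new_dev = _dinuc_dev(A, native, gap_code)
        if new_dev < dev:
            dev = new_dev
        else:
            for r in range(n_rows):
                A[r, p], A[r, q] = A[r, q], A[r, p]
    return dev


@njit(cache=True)
def column_pair_stats(AT, pair_type, pair_energies, ribo, gap_code):
    """Per column-pair statistics for consensus folding.

    AT : (n_cols, n_rows) int8 transposed alignment; pair_type : (4,4) int8
    lookup (-1 if not canonical); pair_energies : (6,) energies per
    canonical pair type; ribo : (6,6) pair-type substitution scores.

    Returns (mean_e, n_types, ribo_cross, n_inc, n_can, stack_frac):
      mean_e[i,j]     mean over rows of the pair energy (0 for rows that
                      cannot pair or are gapped)
      n_types[i,j]    number of distinct canonical pair types observed
      ribo_cross[i,j] covariation evidence: mean substitution score over
                      ordered pairs of canonically-pairing rows carrying
                      *different* pair types (0 when fewer than 2 canonical
                      rows or no type variation)
      n_inc[i,j]      rows with two non-gap residues that cannot pair
                      (N counts as non-pairable)
      n_can[i,j]      rows pairing canonically
      stack_frac[i,j] fraction of rows pairing canonically at both (i,j)
                      and (i+1,j-1)
    """
    n, n_rows = AT.shape
    words = (n_rows + 63) // 64
    mean_e = np.zeros((n, n))
    n_types = np.zeros((n, n), dtype=np.int32)
    ribo_cross = np.zeros((n, n))
    n_inc = np.zeros((n, n), dtype=np.int32)
    n_can = np.zeros((n, n), dtype=np.int32)
    stack_frac = np.zeros((n, n))
    canon = np.zeros((n, n, words), dtype=np.uint64)  # bitmask of canonical rows
    counts = np.zeros(6, dtype=np.int64)
    for i in range(n):
        ci = AT[i]
        for j in range(i + 1, n):
            cj = AT[j]
            for t in range(6):
                counts[t] = 0
            inc = 0
            esum = 0.0
            for r in range(n_rows):
                x = ci[r]
                y = cj[r]
                if x == gap_code or y == gap_code:
                    continue
                if x < 4 and y < 4:
                    t = pair_type[x, y]
                else:
                    t = -1  # N never pairs
                if t >= 0:
                    counts[t] += 1
                    esum += pair_energies[t]
                    canon[i, j, r >> 6] |= np.uint64(1) << np.uint64(r & 63)
                else:
                    inc += 1
            can = 0
            ntyp = 0
            for t in range(6):
                if counts[t] > 0:
                    ntyp += 1
                    can += counts[t]
            mean_e[i, j] = esum / n_rows
            n_types[i, j] = ntyp
            n_inc[i, j] = inc
            n_can[i, j] = can
            if can >= 2:
                s = 0.0
                for t in range(6):
                    ct = counts[t]
                    if ct == 0:
                        continue
                    for u in range(6):
                        if u == t:
                            continue
                        cu = counts[u]
                        if cu == 0:
                            continue
                        s += ct * cu * ribo[t, u]
                ribo_cross[i, j] = s / (can * (can - 1))
    # stacking fractions via bitmask intersection
    for i in range(n - 1):
        for j in range(i + 3, n):
            cnt = 0
            for wd in range(words):
                cnt += _popcount64(canon[i, j, wd] & canon[i + 1, j - 1, wd])
            stack_frac[i, j] = cnt / n_rows
    return mean_e, n_types, ribo_cross, n_inc, n_can, stack_frac
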
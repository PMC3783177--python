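"""Brute-force enumeration of nested secondary structures.

Independent test oracle for the dynamic-programming folding engine: every
nested structure over a short sequence is enumerated explicitly and its
energy evaluated directly from the energy function, with no shared code path
with the DP recursions.  Exponential -- intended for n <= ~16 only.
"""

from functools import lru_cache

import numpy as np


def enumerate_structures(n, allowed, min_hairpin=3, forced_paired=None):
    """Yield every nested structure as a frozenset of (i,j) pairs.

    allowed : (n,n) boolean, True where (i,j) may pair.
    forced_paired : optional boolean array; structures leaving such a
        position unpaired are suppressed.
    """
    allowed = np.asarray(allowed, dtype=bool)

    @lru_cache(maxsize=None)
    def structs(i, j):
        # all structures on [i, j], as tuples of pairs
        if j - i < min_hairpin + 1:
            return ((),)
        out = []
        # position i unpaired
        out.extend(structs(i + 1, j))
        # position i paired with t
        for t in range(i + min_hairpin + 1, j + 1):
            if not allowed[i, t]:
                continue
            for inner in structs(i + 1, t - 1):
                for outer in structs(t + 1, j):
                    out.append(((i, t),) + inner + outer)
        return tuple(out)

    fp = None if forced_paired is None else np.asarray(forced_paired, dtype=bool)
    for s in structs(0, n - 1) if n else ((),):
        if fp is not None:
            paired = {i for p in s for i in p}
            if any(fp[k] and k not in paired for k in range(n)):
                continue
        yield frozenset(s)


def structure_energy(pairs, e, stack_w):
    """Direct energy of a structure: pair terms plus stacking increments.

    e : (n,n) pair energies;  stack_w : (n,n) increment charged to (i,j)
    when (i+1,j-1) is also paired.
    """
    total = 0.0
    ps = set(pairs)
    for i, j in ps:
        total += e[i, j]
        if (i + 1, j - 1) in ps:
            total += stack_w[i, j]
    return total


def brute_force_mfe(e, stack_w, allowed, min_hairpin=3, forced_paired=None):
    """Minimum energy over all enumerated structures (empty structure = 0)."""
    n = e.shape[0]
    best = None
    for s in enumerate_structures(n, allowed, min_hairpin, forced_paired):
        en = structure_energy(s, e, stack_w)
        if best is None or en < best:
            best = en
    return best


def brute_force_partition(e, stack_w, allowed, kT, min_hairpin=3):
    """(Z, pair probability matrix) by exhaustive Boltzmann summation."""
    n = e.shape[0]
    z = 0.0
    psum = np.zeros((n, n))
    for s in enumerate_structures(n, allowed, min_hairpin):
        w = np.exp(-structure_energy(s, e, stack_w) / kT)
        z += w
        for i, j in s:
            psum[i, j] += w
    return z, psum / z
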
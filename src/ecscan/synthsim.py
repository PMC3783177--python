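"""Synthetic structured-RNA families and matched neutral alignments.

The generator emulates the signal the pipeline detects: a nested consensus
structure under which sequences evolve along a tree, with substitutions at
paired sites accompanied (with probability `compensation_prob`) by the
compensatory partner change that restores canonical pairing.  Neutral
alignments use the same tree and composition machinery with no pairing
constraint, providing negatives with matched base composition and depth.

Trees are random-topology ultrametric trees whose root-to-tip height is
`branch_scale` expected substitutions per site, so pairwise tip divergence
is at most 2*branch_scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from . import _alphabet as ab
from .fold import SecondaryStructure
from .msa_io import AlignedSequence, Alignment, StructuredFamily
from .nullmodels import PhyloTree

__all__ = [
    "FamilySpec",
    "random_structure",
    "helical_structure",
    "random_tree",
    "evolve_family",
    "neutral_alignment",
    "anchor_alignment",
]

MIN_HAIRPIN = 3


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family.

    pair_fraction: fraction of columns that are paired (<= 0.45);
    branch_scale: root-to-tip height in substitutions/site;
    gc_target: percent G+C of the root draw;
    compensation_prob: probability that a substitution at a paired site is
    accompanied by the compensatory partner change;
    gap_rate: per-column probability of a clade-level gap event.
    """

    n_cols: int = 200
    pair_fraction: float = 0.3
    n_tips: int = 20
    branch_scale: float = 0.3
    gc_target: float = 50.0
    compensation_prob: float = 0.9
    gap_rate: float = 0.05
    kappa: float = 4.0

    def __post_init__(self):
        if not 0.0 <= self.pair_fraction <= 0.45:
            raise ValueError("pair_fraction must be in [0, 0.45]")
        if not 0.0 <= self.compensation_prob <= 1.0:
            raise ValueError("compensation_prob must be a probability")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")
        if self.n_tips < 2:
            raise ValueError("need at least 2 tips")


# ---------------------------------------------------------------------------
# uniform sampling of nested structures with a fixed pair count

@lru_cache(maxsize=32)
def _structure_counts(n, max_pairs):
    """F[L, m] = number of nested structures on L positions with m pairs
    (min hairpin loop 3), in float64 (exact for small m, ample for
    sampling weights).

    Recursion on the first position of a segment: unpaired, or paired with
    offset t (interior t-1 positions, remainder L-t-1)."""
    M = max_pairs
    F = np.zeros((n + 1, M + 1))
    F[:, 0] = 1.0
    for L in range(1, n + 1):
        row = F[L - 1].copy()
        for t in range(MIN_HAIRPIN + 1, L):
            conv = np.convolve(F[t - 1], F[L - t - 1])[:M]
            row[1:] += conv
        F[L] = row
    return F


def random_structure(n_cols, pair_fraction, rng):
    """Uniformly sampled nested structure with round(pair_fraction *
    n_cols / 2) pairs and minimum hairpin loop 3."""
    m = int(round(pair_fraction * n_cols / 2.0))
    if m == 0:
        return SecondaryStructure(n_cols)
    F = _structure_counts(n_cols, m)
    if F[n_cols, m] <= 0:
        raise ValueError(
            f"no structure with {m} pairs fits in {n_cols} columns"
        )
    pairs = []
    stack = [(0, n_cols, m)]  # (offset, length, pairs to place)
    while stack:
        off, L, mm = stack.pop()
        if mm == 0 or L <= 0:
            continue
        if rng.random() < F[L - 1, mm] / F[L, mm]:
            stack.append((off + 1, L - 1, mm))
            continue
        # first position pairs; choose partner offset t and inner count a
        ts = np.arange(MIN_HAIRPIN + 1, L)
        W = F[ts - 1][:, :mm] * F[L - ts - 1][:, :mm][:, ::-1]
        flat = W.ravel()
        k = int(rng.choice(flat.size, p=flat / flat.sum()))
        t = int(ts[k // mm])
        a_ = k % mm
        pairs.append((off, off + t))
        stack.append((off + 1, t - 1, a_))
        stack.append((off + t + 1, L - t - 1, mm - 1 - a_))
    return SecondaryStructure(n_cols, pairs)


def helical_structure(n_cols, pair_fraction, rng, mean_helix=5):
    """Nested structure whose pairs are organised into helical stems, the
    topology of real structural-RNA families (random placement of stems
    into available segments, producing hairpins, bulges and multiloops).

    Places up to round(pair_fraction * n_cols / 2) pairs; when space runs
    out fewer pairs are returned.  `random_structure` remains the uniform
    sampler; this one is what the family generator uses by default because
    stacked stems carry the thermodynamic-stability signal of real RNAs.
    """
    target = int(round(pair_fraction * n_cols / 2.0))
    pairs = []
    segments = [(0, n_cols - 1)]
    placed = 0
    while placed < target and segments:
        h = min(
            target - placed,
            MIN_HAIRPIN + int(rng.geometric(1.0 / (mean_helix - 2.0))),
        )
        h = max(h, 2)
        feasible = [
            (k, (lo, hi)) for k, (lo, hi) in enumerate(segments)
            if hi - lo + 1 >= 2 * h + MIN_HAIRPIN
        ]
        if not feasible:
            # shrink the helix until something fits, else stop
            if h > 2:
                sizes = [hi - lo + 1 for lo, hi in segments]
                h = (max(sizes) - MIN_HAIRPIN) // 2
                if h < 2:
                    break
                continue
            break
        k, (lo, hi) = feasible[int(rng.integers(len(feasible)))]
        a = int(rng.integers(lo, hi - 2 * h - MIN_HAIRPIN + 2))
        b = int(rng.integers(a + 2 * h + MIN_HAIRPIN - 1, hi + 1))
        for t in range(h):
            pairs.append((a + t, b - t))
        placed += h
        segments.pop(k)
        if (b - h) - (a + h) - 1 >= 2 * 2 + MIN_HAIRPIN:
            segments.append((a + h, b - h))
        if hi - b >= 2 * 2 + MIN_HAIRPIN + 1:
            segments.append((b + 1, hi))
        if a - lo >= 2 * 2 + MIN_HAIRPIN + 1:
            segments.append((lo, a - 1))
    return SecondaryStructure(n_cols, pairs)


# ---------------------------------------------------------------------------
# trees

def random_tree(n_tips, branch_scale, rng, tip_prefix="sp"):
    """Random-join ultrametric tree with root height `branch_scale`."""
    heights = np.sort(rng.random(n_tips - 1)) * branch_scale
    nodes = []  # (height, children)
    active = []
    for k in range(n_tips):
        nodes.append({"height": 0.0, "children": [], "name": f"{tip_prefix}{k}"})
        active.append(k)
    for j in range(n_tips - 1):
        i1, i2 = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i1)], active[int(i2)]
        h = float(heights[j]) if j < n_tips - 2 else float(branch_scale)
        h = max(h, nodes[a]["height"], nodes[b]["height"])
        nodes.append({"height": h, "children": [a, b], "name": None})
        new = len(nodes) - 1
        active = [x for x in active if x not in (a, b)] + [new]
    root = active[0]
    # flatten into PhyloTree arrays (preorder)
    parent = np.full(len(nodes), -1, dtype=np.int64)
    length = np.zeros(len(nodes))
    order = []
    stack = [root]
    while stack:
        k = stack.pop()
        order.append(k)
        for ch in nodes[k]["children"]:
            parent[ch] = k
            length[ch] = nodes[k]["height"] - nodes[ch]["height"]
            stack.append(ch)
    tips = {nodes[k]["name"]: k for k in range(n_tips)}
    return PhyloTree(parent, length, tips, np.array(order, dtype=np.int64))


def _descendant_tips(tree):
    """node index -> list of tip node indices at or below the node."""
    tipset = set(int(t) for t in tree.tips.values())
    tips_at = {k: ([k] if k in tipset else []) for k in range(tree.n_nodes)}
    for k in reversed(tree.preorder):
        k = int(k)
        par = int(tree.parent[k])
        if par >= 0:
            tips_at[par] = tips_at[par] + tips_at[k]
    return tips_at


# ---------------------------------------------------------------------------
# evolution

_WC = {ab.A: [ab.U], ab.C: [ab.G], ab.G: [ab.C, ab.U], ab.U: [ab.A, ab.G]}


def _jump_matrix(pi, kappa):
    """HKY embedded jump chain: P(next state | current state)."""
    transitions = {(ab.A, ab.G), (ab.G, ab.A), (ab.C, ab.U), (ab.U, ab.C)}
    J = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            J[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
        J[i] /= J[i].sum()
    return J


def _partner_base(base, rng):
    cands = _WC[int(base)]
    if len(cands) == 1:
        return cands[0]
    return cands[0] if rng.random() < 0.75 else cands[1]


def _sample_root(spec, partner, rng):
    g = spec.gc_target / 100.0
    pi = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    root = rng.choice(4, size=spec.n_cols, p=pi)
    for i in range(spec.n_cols):
        j = partner[i]
        if j > i:  # paired site: draw a canonical pair honouring GC target
            u = rng.random()
            if u < g:
                root[i], root[j] = (ab.G, ab.C) if rng.random() < 0.5 else (ab.C, ab.G)
            elif u < g + (1 - g) * 0.75:
                root[i], root[j] = (ab.A, ab.U) if rng.random() < 0.5 else (ab.U, ab.A)
            else:
                root[i], root[j] = (ab.G, ab.U) if rng.random() < 0.5 else (ab.U, ab.G)
    return root


def _evolve(spec, structure, tree, rng):
    """Evolve sequences along the tree; paired sites co-substitute with
    probability compensation_prob."""
    partner = (
        structure.partner_array()
        if structure is not None
        else np.full(spec.n_cols, -1, dtype=np.int64)
    )
    g = spec.gc_target / 100.0
    pi = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    J = _jump_matrix(pi, spec.kappa)
    cdfJ = np.cumsum(J, axis=1)
    root = _sample_root(spec, partner, rng)
    states = {int(tree.preorder[0]): root}
    for k in tree.preorder:
        k = int(k)
        par = int(tree.parent[k])
        if par < 0:
            continue
        seq = states[par].copy()
        L = float(tree.length[k])
        if L > 0:
            # unpaired sites: independent HKY jumps
            n_events = rng.poisson(L, size=spec.n_cols)
            for site in np.flatnonzero((n_events > 0) & (partner < 0)):
                for _ in range(n_events[site]):
                    u = rng.random()
                    seq[site] = int((u > cdfJ[seq[site]]).sum())
            # paired sites: joint events at rate 2L per pair
            for i in np.flatnonzero(partner > np.arange(spec.n_cols)):
                j = int(partner[i])
                for _ in range(rng.poisson(2 * L)):
                    site, other = (i, j) if rng.random() < 0.5 else (j, i)
                    u = rng.random()
                    seq[site] = int((u > cdfJ[seq[site]]).sum())
                    if rng.random() < spec.compensation_prob:
                        seq[other] = _partner_base(seq[site], rng)
        states[k] = seq
    return states


def _inject_gaps(M, tree, tip_row, spec, rng):
    """Whole-column gap events per tip clade (indel blocks, not salt-and-
    pepper gaps)."""
    non_root = [int(k) for k in tree.preorder[1:]]
    if not non_root:
        return M
    tips_at = _descendant_tips(tree)
    tipset = set(tree.tips.values())
    for c in range(spec.n_cols):
        if rng.random() < spec.gap_rate:
            node = non_root[int(rng.integers(len(non_root)))]
            below = tips_at.get(node, [node] if node in tipset else [])
            rows = [tip_row[t] for t in below if t in tip_row]
            if 0 < len(rows) < M.shape[0]:  # never create an all-gap column
                M[rows, c] = ab.GAP
    return M


def _assemble(spec, states, tree, rng, inject_gaps=True):
    tip_items = sorted(tree.tips.items())
    tip_row = {node: r for r, (_, node) in enumerate(tip_items)}
    M = np.vstack([states[int(node)] for _, node in tip_items]).astype(np.int8)
    if inject_gaps and spec.gap_rate > 0:
        M = _inject_gaps(M, tree, tip_row, spec, rng)
    seqs = [
        AlignedSequence(name, ab.decode(M[r]))
        for r, (name, _) in enumerate(tip_items)
    ]
    return Alignment(seqs)


def evolve_family(spec: FamilySpec, rng, structure=None, tree=None,
                  family_id="synth"):
    """Generate one structured family: tree + compensatory evolution under
    a (sampled or given) consensus structure."""
    if structure is None:
        structure = helical_structure(spec.n_cols, spec.pair_fraction, rng)
    if structure.length != spec.n_cols:
        raise ValueError("structure length does not match n_cols")
    if tree is None:
        tree = random_tree(spec.n_tips, spec.branch_scale, rng)
    states = _evolve(spec, structure, tree, rng)
    aln = _assemble(spec, states, tree, rng)
    return StructuredFamily(aln, structure, id=family_id)


def neutral_alignment(spec: FamilySpec, rng, tree=None):
    """Structure-free control: same tree/composition machinery, no pairing
    constraint and no compensation."""
    if tree is None:
        tree = random_tree(spec.n_tips, spec.branch_scale, rng)
    states = _evolve(spec, None, tree, rng)
    return _assemble(spec, states, tree, rng)


def anchor_alignment(aln, chrom="chrS", start=100000, src_size=10_000_000,
                     reference_first=True):
    """Attach synthetic genome anchors (MAF semantics) so scan-stage code
    paths can be exercised without real genome alignments."""
    seqs = []
    for k, s in enumerate(aln.sequences):
        seqs.append(
            AlignedSequence(
                f"{s.id}.{chrom}", s.residues, start, "+", src_size
            )
        )
    return Alignment(seqs, reference_index=0 if reference_first else None)
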
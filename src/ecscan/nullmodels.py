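"""Dinucleotide-controlled negative controls and Z-score calibration.

Two null generators produce composition-matched randomisations of an
alignment window:

  permute_alignment   within-window column permutation inside conservation
                      classes, followed by a greedy dinucleotide-repair
                      pass (the independent, model-free null);
  simulate_alignment  evolution of a fresh alignment along a neighbor-
                      joining tree under an HKY model with the native base
                      composition and gap pattern (the tree-based null).

`zscore` compares the native consensus-structure score against the score
distribution over nulls; backgrounds with a standard deviation below 0.5
are flagged degenerate because they produce unstable, extreme Z-scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.linalg import expm

from . import _alphabet as ab
from ._kernels import dinuc_counts, dinuc_repair
from .consensus import (
    DEFAULT_BETA,
    DEFAULT_DELTA,
    ConsensusFold,
    consensus_fold_multi,
    consensus_scores,
    load_ribosum,
)
from .fold import DEFAULT_MODEL
from .msa_io import AlignedSequence, Alignment

__all__ = [
    "PhyloTree",
    "ZScoreResult",
    "ConsensusScorer",
    "dinucleotide_shuffle",
    "permute_alignment",
    "build_tree",
    "simulate_alignment",
    "zscore",
    "zscore_multi",
]


# ---------------------------------------------------------------------------
# dinucleotide shuffle (Euler-path method)

def dinucleotide_shuffle(seq, rng):
    """Uniform-ish sample from sequences with the same dinucleotide multiset
    and the same first and last residues (Altschul-Erickson Euler method).

    Length-0/1 inputs are returned unchanged.  Gap characters are not
    allowed (shuffle operates on ungapped sequences).
    """
    if "-" in seq:
        raise ValueError("dinucleotide_shuffle expects an ungapped sequence")
    n = len(seq)
    if n < 3:
        return seq
    # adjacency: multiset of successor residues per vertex
    adj = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(adj)  # vertices with out-edges
    if len(set(seq)) == 1:
        return seq
    # choose random "last out-edge" per vertex (except the walk's end) such
    # that last-edges form an arborescence into `last`; rejection keeps the
    # draw uniform over arborescences.
    for _ in range(10000):
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = adj[v][int(rng.integers(len(adj[v])))]
        # every vertex must reach `last` by following last-edges
        ok = True
        for v in last_edge:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to sample an Eulerian arborescence")
    # shuffle remaining edges; append the reserved last edge
    pools = {}
    for v in vertices:
        edges = list(adj[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        order = rng.permutation(len(edges))
        edges = [edges[k] for k in order]
        if v in last_edge:
            edges.append(last_edge[v])
        pools[v] = edges
    # walk the Euler path
    out = [first]
    pos = {v: 0 for v in vertices}
    cur = first
    for _ in range(n - 1):
        nxt = pools[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# column permutation with dinucleotide repair

def _conservation_classes(A):
    """Group column indices by (gap/N pattern, monomorphic status)."""
    classes = {}
    n = A.shape[1]
    for c in range(n):
        col = A[:, c]
        residues = col[col < 4]
        mono = len(np.unique(residues)) <= 1
        key = (col[col >= 4].tobytes(), tuple(np.flatnonzero(col >= 4)), mono)
        classes.setdefault(key, []).append(c)
    return list(classes.values())


def _class_arrays(classes):
    """Flatten multi-member classes for the numba repair kernel."""
    multi = [c for c in classes if len(c) >= 2]
    if not multi:
        return np.zeros(0, dtype=np.int64), np.zeros(1, dtype=np.int64)
    flat = np.concatenate([np.asarray(c, dtype=np.int64) for c in multi])
    start = np.cumsum([0] + [len(c) for c in multi]).astype(np.int64)
    return flat, start


def _cached_classes(aln, A):
    classes = getattr(aln, "_cons_classes", None)
    if classes is None:
        classes = _conservation_classes(A)
        aln._cons_classes = classes
    return classes


def _repair(A, native_counts, classes, trials, rng):
    flat, start = _class_arrays(classes)
    seed = int(rng.integers(2**31 - 1))
    dinuc_repair(A, native_counts, flat, start, trials, seed, ab.GAP)


def permute_alignment(aln, rng, repair_trials=None):
    """Shuffle columns within conservation classes, then greedily swap
    same-class columns to pull per-row dinucleotide counts back toward the
    native window.

    Exactly preserves n_cols, per-column residue multisets and per-row gap
    counts; MPI is invariant under whole-column permutation.
    """
    A0 = np.ascontiguousarray(aln.encoded())
    native_counts = dinuc_counts(A0, ab.GAP, 6)
    classes = _cached_classes(aln, A0)
    perm = np.arange(aln.n_cols)
    for cls in classes:
        cls = np.array(cls)
        perm[cls] = cls[rng.permutation(len(cls))]
    A = np.ascontiguousarray(A0[:, perm])
    if repair_trials is None:
        repair_trials = 2 * aln.n_cols
    if repair_trials:
        _repair(A, native_counts, classes, repair_trials, rng)
    seqs = [
        AlignedSequence(s.id, ab.decode(A[k]), s.src_start, s.src_strand, s.src_size)
        for k, s in enumerate(aln.sequences)
    ]
    return Alignment(seqs, reference_index=aln.reference_index)


# ---------------------------------------------------------------------------
# phylogeny and simulation

@dataclass
class PhyloTree:
    """Rooted tree over sequence ids, stored as parent/length arrays.

    Node 0 is the root; `tips` maps sequence id -> node index; `preorder`
    lists nodes parent-before-child.
    """

    parent: np.ndarray
    length: np.ndarray
    tips: dict
    preorder: np.ndarray
    newick: str = ""
    saturated: bool = False
    _pmat_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self):
        return len(self.parent)

    def tip_ids(self):
        return set(self.tips)


def jukes_cantor_distance(p, cap=5.0):
    """JC69 distance from a proportion of differing sites; saturated
    inputs (p >= 0.75) are capped."""
    if p >= 0.7499999:
        return cap, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def build_tree(aln, cap=5.0):
    """Neighbor joining on JC distances (pairwise deletion of gap/N sites),
    midpoint-rooted, negative branch lengths clamped to zero."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    A = aln.encoded()
    n = aln.n_seqs
    if n < 3:
        raise ValueError("build_tree needs at least 3 sequences")
    ids = [f"t{k}" for k in range(n)]  # placeholder-safe labels
    dm = np.zeros((n, n))
    saturated = False
    for a in range(n):
        for b in range(a + 1, n):
            ok = (A[a] < 4) & (A[b] < 4)
            sites = int(ok.sum())
            if sites == 0:
                d, sat = cap, True
            else:
                p = float((A[a][ok] != A[b][ok]).mean())
                d, sat = jukes_cantor_distance(p, cap)
            saturated = saturated or sat
            dm[a, b] = dm[b, a] = d
    tree = nj(DistanceMatrix(dm, ids))
    if dm.max() > 0:
        try:
            tree = tree.root_at_midpoint()
        except Exception:  # degenerate trees keep the NJ rooting
            pass
    # flatten to arrays, clamping negative lengths
    nodes = list(tree.traverse(include_self=True))
    index = {id(nd): k for k, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    length = np.zeros(len(nodes))
    tips = {}
    for k, nd in enumerate(nodes):
        if nd.parent is not None and id(nd.parent) in index:
            parent[k] = index[id(nd.parent)]
            length[k] = max(0.0, nd.length or 0.0)
        if nd.is_tip():
            tips[aln.sequences[int(nd.name[1:])].id] = k
    order = np.array(
        [k for k, nd in enumerate(nodes)], dtype=np.int64
    )  # traverse() is preorder already
    return PhyloTree(parent, length, tips, order, newick=str(tree).strip(),
                     saturated=saturated)


def _hky_rate_matrix(pi, kappa):
    Q = np.zeros((4, 4))
    transitions = {(ab.A, ab.G), (ab.G, ab.A), (ab.C, ab.U), (ab.U, ab.C)}
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu > 0:
        Q /= mu  # one expected substitution per site per unit length
    return Q


def estimate_kappa(A):
    """Transition/transversion rate ratio from pairwise mismatch counts."""
    ts = tv = 0
    n = A.shape[0]
    transitions = {(ab.A, ab.G), (ab.G, ab.A), (ab.C, ab.U), (ab.U, ab.C)}
    for a in range(n):
        for b in range(a + 1, n):
            ok = (A[a] < 4) & (A[b] < 4) & (A[a] != A[b])
            for x, y in zip(A[a][ok], A[b][ok]):
                if (int(x), int(y)) in transitions:
                    ts += 1
                else:
                    tv += 1
    if tv == 0:
        return 4.0
    return float(np.clip(2.0 * ts / tv, 0.2, 20.0))


def simulate_alignment(aln, tree=None, rng=None, repair=False, repair_trials=None):
    """Dinucleotide-aware tree-based null: HKY evolution along the inferred
    phylogeny with the native base composition, transition bias, per-column
    root composition and the native gap/N pattern copied verbatim.

    With `repair=True` a column-swap repair pass (as in permute_alignment)
    further reduces deviation from the native dinucleotide counts.
    """
    if rng is None:
        raise ValueError("simulate_alignment requires an rng")
    if tree is None:
        tree = build_tree(aln)
    if set(aln.ids) != tree.tip_ids():
        raise ValueError("tree tips do not match alignment ids")
    A = aln.encoded()
    n_rows, n_cols = A.shape
    bases = A[A < 4]
    pi = np.bincount(bases, minlength=4).astype(float)
    pi = pi / pi.sum() if pi.sum() else np.full(4, 0.25)
    kappa = estimate_kappa(A)
    Q = _hky_rate_matrix(pi, kappa)

    def pmat(t):
        key = round(float(t), 10)
        P = tree._pmat_cache.get(key)
        if P is None:
            P = expm(Q * t)
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            tree._pmat_cache[key] = P
        return P

    # root draw from per-column compositions (vectorised inverse-CDF)
    counts = np.zeros((4, n_cols))
    for b in range(4):
        counts[b] = (A == b).sum(axis=0)
    tot = counts.sum(axis=0)
    probs = np.where(tot > 0, counts / np.where(tot > 0, tot, 1.0), pi[:, None])
    cdf_cols = np.cumsum(probs, axis=0)
    u = rng.random(n_cols)
    root = (u[None, :] > cdf_cols).sum(axis=0)
    root = np.minimum(root, 3)
    # evolve along the tree (preorder)
    states = np.empty((tree.n_nodes, n_cols), dtype=np.int64)
    for k in tree.preorder:
        par = tree.parent[k]
        if par < 0:
            states[k] = root
            continue
        P = pmat(tree.length[k])
        child = np.empty(n_cols, dtype=np.int64)
        u = rng.random(n_cols)
        cdf = np.cumsum(P, axis=1)
        parent_states = states[par]
        child = (u[:, None] > cdf[parent_states]).sum(axis=1)
        states[k] = np.minimum(child, 3)
    # assemble rows, copying the native gap/N pattern
    S = np.empty_like(A)
    for r, s in enumerate(aln.sequences):
        S[r] = states[tree.tips[s.id]]
        mask = A[r] >= 4
        S[r][mask] = A[r][mask]
    S = np.ascontiguousarray(S.astype(np.int8))
    if repair:
        native_counts = dinuc_counts(np.ascontiguousarray(A), ab.GAP, 6)
        classes = _cached_classes(aln, A)
        if repair_trials is None:
            repair_trials = 2 * n_cols
        if repair_trials:
            _repair(S, native_counts, classes, repair_trials, rng)
    seqs = [
        AlignedSequence(s.id, ab.decode(S[r]), s.src_start, s.src_strand, s.src_size)
        for r, s in enumerate(aln.sequences)
    ]
    return Alignment(seqs, reference_index=aln.reference_index)


# ---------------------------------------------------------------------------
# Z-scores

@dataclass(frozen=True)
class ConsensusScorer:
    """Consensus-structure scorer configuration for Z-scoring."""

    variant: str = "plain"
    model: object = DEFAULT_MODEL
    beta: float = DEFAULT_BETA
    delta: float = DEFAULT_DELTA
    ribosum: object = None

    def fold(self, aln) -> ConsensusFold:
        folds = consensus_fold_multi(
            aln, self.model, variants=(self.variant,), beta=self.beta,
            delta=self.delta, ribosum=self.ribosum,
        )
        return folds[self.variant]

    def __call__(self, aln) -> float:
        return self.fold(aln).score


@dataclass
class ZScoreResult:
    """Native consensus score against a null-score distribution.

    z is None when the background is degenerate (sd below `sd_floor`,
    default 0.5), which otherwise produces extreme Z-scores.  Negative z
    means the native window is more stable/conserved than the null.
    """

    native_score: float
    null_mean: float
    null_sd: float
    z: Optional[float]
    n_nulls: int
    mode: str
    degenerate: bool
    empty_native: bool = False
    native_fold: Optional[ConsensusFold] = None


def zscore_multi(aln, null_generator: Callable, n_nulls=100, rng=None,
                 variants=("plain", "ribosum"), model=DEFAULT_MODEL,
                 beta=DEFAULT_BETA, delta=DEFAULT_DELTA, ribosum=None, sd_floor=0.5):
    """Z-scores for several consensus variants sharing one set of nulls.

    Nulls are generated once and scored under every variant; returns
    {variant: ZScoreResult}.
    """
    if rng is None:
        raise ValueError("zscore requires an rng")
    if ribosum is None:
        ribosum = load_ribosum()
    native = consensus_fold_multi(aln, model, variants=variants, beta=beta,
                                  delta=delta, ribosum=ribosum)
    null_scores = {v: np.empty(n_nulls) for v in variants}
    for k in range(n_nulls):
        null = null_generator(aln, rng)
        scores = consensus_scores(null, model, variants=variants, beta=beta,
                                  delta=delta, ribosum=ribosum)
        for v in variants:
            null_scores[v][k] = scores[v]
    out = {}
    for v in variants:
        scores = null_scores[v]
        mean = float(scores.mean())
        sd = float(scores.std())
        degenerate = sd < sd_floor
        nat = native[v]
        z = None if degenerate else (nat.score - mean) / sd
        out[v] = ZScoreResult(
            native_score=nat.score, null_mean=mean, null_sd=sd, z=z,
            n_nulls=n_nulls, mode=v, degenerate=degenerate,
            empty_native=nat.is_empty, native_fold=nat,
        )
    return out


def zscore(aln, scorer: ConsensusScorer, null_generator: Callable,
           n_nulls=100, rng=None, sd_floor=0.5):
    """Z-score of the native consensus score against `n_nulls` nulls."""
    if n_nulls < 2:
        raise ValueError("need at least 2 nulls")
    res = zscore_multi(
        aln, null_generator, n_nulls=n_nulls, rng=rng,
        variants=(scorer.variant,), model=scorer.model, beta=scorer.beta,
        delta=scorer.delta, ribosum=scorer.ribosum, sd_floor=sd_floor,
    )
    return res[scorer.variant]
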
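"""Window descriptors and pre-scoring quality control.

Five descriptors drive scorer dispatch and reporting: mean pairwise
identity (MPI), its standard deviation, normalised Shannon entropy, GC
content and gap content.  MPI follows the shortest-ungapped-sequence
convention: identities / min(ungapped lengths) per pair, averaged over all
unordered pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from . import _alphabet as ab
from .msa_io import Alignment

__all__ = ["AlnStats", "QCResult", "pairwise_identity", "compute_stats", "qc_filter"]


@dataclass(frozen=True)
class AlnStats:
    """Descriptors of one alignment window.

    mpi / gc / gap are percentages; shannon is normalised to [0, 1].
    mpi and mpi_sd are NaN for alignments of fewer than two sequences
    (undefined rather than zero).
    """

    mpi: float
    mpi_sd: float
    shannon: float
    gc: float
    gap: float
    n_seqs: int


def _identity(row_a, row_b):
    """Identity percent between two encoded rows (shortest-sequence rule).

    Gap-vs-gap columns count toward neither numerator nor denominator;
    N never matches.
    """
    match = ((row_a == row_b) & (row_a < 4)).sum()
    len_a = (row_a != ab.GAP).sum()
    len_b = (row_b != ab.GAP).sum()
    denom = min(len_a, len_b)
    if denom == 0:
        return 0.0
    return 100.0 * float(match) / float(denom)


def pairwise_identity(a, b):
    """Percent identity between two equal-length gapped sequences."""
    ra = ab.encode(ab.normalize(a.residues if hasattr(a, "residues") else a))
    rb = ab.encode(ab.normalize(b.residues if hasattr(b, "residues") else b))
    if len(ra) != len(rb):
        raise ValueError("aligned lengths differ")
    return _identity(ra, rb)


def compute_stats(aln: Alignment) -> AlnStats:
    """Descriptors for one window; N residues are excluded from identity
    and GC counts, columns with <2 non-gap residues contribute entropy 0."""
    A = aln.encoded()
    n_seqs, n_cols = A.shape
    # MPI and its population SD
    if n_seqs >= 2:
        idents = [
            _identity(A[p], A[q]) for p, q in combinations(range(n_seqs), 2)
        ]
        mpi = float(np.mean(idents))
        mpi_sd = float(np.std(idents))  # population formula
    else:
        mpi = math.nan
        mpi_sd = math.nan
    # normalised Shannon entropy, mean over columns
    ent_sum = 0.0
    for c in range(n_cols):
        col = A[:, c]
        counts = np.bincount(col[col < 4], minlength=4)
        tot = counts.sum()
        if tot < 2:
            continue
        freq = counts[counts > 0] / tot
        ent_sum += -(freq * np.log(freq)).sum() / math.log(4.0)
    shannon = ent_sum / n_cols if n_cols else 0.0
    # GC and gap content
    base_counts = np.bincount(A[A < 4], minlength=4)
    acgu = base_counts.sum()
    gc = 100.0 * (base_counts[ab.C] + base_counts[ab.G]) / acgu if acgu else 0.0
    gap = 100.0 * (A == ab.GAP).sum() / (n_seqs * n_cols)
    return AlnStats(mpi, mpi_sd, shannon, float(gc), float(gap), n_seqs)


@dataclass
class QCResult:
    """Outcome of qc_filter: a filtered alignment or a rejection reason."""

    alignment: Optional[Alignment]
    reason: Optional[str] = None

    def __bool__(self):
        return self.alignment is not None


def _matches_reference(seq, reference_id):
    return seq.id == reference_id or seq.species == reference_id


def qc_filter(aln: Alignment, reference_id=None, min_seqs=3) -> QCResult:
    """Pre-scoring filters: collapse identical rows (reference copy
    preferred), drop rows that are >= 50% gaps+N, drop all-gap columns.

    Rejects (reason "too_few_seqs" or "reference_lost") unless at least
    `min_seqs` rows survive and, when `reference_id` is given, the
    reference row is among them.  Idempotent.
    """
    ref_idx = None
    if reference_id is not None:
        for k, s in enumerate(aln.sequences):
            if _matches_reference(s, reference_id):
                ref_idx = k
                break
        if ref_idx is None:
            return QCResult(None, "reference_lost")
    # collapse identical residue strings, preferring the reference copy
    groups = {}
    for k, s in enumerate(aln.sequences):
        groups.setdefault(s.residues, []).append(k)
    keep = []
    for members in groups.values():
        rep = members[0]
        if ref_idx is not None and ref_idx in members:
            rep = ref_idx
        keep.append(rep)
    keep.sort()
    # drop gappy/ambiguous rows
    surviving = []
    for k in keep:
        text = aln.sequences[k].residues
        frac = (text.count("-") + text.count("N")) / len(text)
        if frac < 0.5:
            surviving.append(k)
    if ref_idx is not None and ref_idx not in surviving:
        return QCResult(None, "reference_lost")
    if len(surviving) < min_seqs:
        return QCResult(None, "too_few_seqs")
    sub = aln.take_rows(surviving)
    if ref_idx is not None:
        sub.reference_index = surviving.index(ref_idx)
    # drop all-gap columns
    A = sub.encoded()
    keep_cols = ~(A == ab.GAP).all(axis=0)
    if not keep_cols.all():
        idx = np.flatnonzero(keep_cols)
        seqs = []
        for s in sub.sequences:
            # removed columns are all-gap: anchors are unaffected
            text = "".join(s.residues[c] for c in idx)
            seqs.append(
                type(s)(s.id, text, s.src_start, s.src_strand, s.src_size)
            )
        sub = Alignment(seqs, reference_index=sub.reference_index)
    return QCResult(sub)
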
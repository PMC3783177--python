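"""Structural congruence of the reference sequence with the consensus.

Consensus-based prediction only requires that half the rows support the
structure, so the reference sequence itself may be unable to fold into it.
The congruence test compares the unconstrained fold of the de-gapped
reference with the same sequence constrained to contain the projected
consensus pairs, via two ratios:

  delta_p       ratio of structure probabilities (projected consensus vs
                MFE structure) under the unconstrained pair-probability
                matrix, capped at 1;
  energy_ratio  E_constrained / E_mfe (0 when the reference cannot fold).

The reference is congruent when both ratios exceed 0.75 and either
exceeds 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _alphabet as ab
from .fold import (
    DEFAULT_MODEL,
    ConstraintError,
    FoldConstraint,
    SecondaryStructure,
    mfe_fold,
    partition_function,
    structure_score,
)

__all__ = [
    "CongruenceResult",
    "congruence_decision",
    "project_consensus",
    "congruence_test",
]


def congruence_decision(delta_p, energy_ratio, thresholds=(0.75, 0.9)):
    """The two-ratio rule: congruent iff both ratios exceed the lower
    threshold and at least one exceeds the upper one."""
    lo, hi = thresholds
    return (
        delta_p > lo and energy_ratio > lo and max(delta_p, energy_ratio) > hi
    )


@dataclass
class CongruenceResult:
    """Two-ratio congruence verdict for one reference sequence."""

    delta_p: float
    energy_ratio: float
    congruent: bool
    n_pairs_retained: int
    reason: Optional[str] = None


def project_consensus(aln, consensus: SecondaryStructure, reference_id):
    """Project an alignment-column consensus structure onto the reference.

    Columns where the reference is gapped are removed; pairs losing either
    partner are dropped (the orphaned position becomes unpaired); indices
    are remapped to ungapped reference coordinates.

    Returns (ungapped reference sequence, projected SecondaryStructure).
    """
    ref = None
    for k, s in enumerate(aln.sequences):
        if s.id == reference_id or s.species == reference_id:
            ref = s
            break
    if ref is None:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    if consensus.length != aln.n_cols:
        raise ValueError("consensus length does not match the alignment")
    text = ref.residues
    newpos = np.full(len(text), -1, dtype=np.int64)
    seq = []
    for c, ch in enumerate(text):
        if ch != "-":
            newpos[c] = len(seq)
            seq.append(ch)
    pairs = []
    for i, j in consensus.pairs:
        if newpos[i] >= 0 and newpos[j] >= 0:
            ni, nj = int(newpos[i]), int(newpos[j])
            if nj - ni >= 4:  # projection can shorten loops below the minimum
                pairs.append((ni, nj))
    return "".join(seq), SecondaryStructure(len(seq), pairs)


def congruence_test(refseq, s_c: SecondaryStructure, model=DEFAULT_MODEL,
                    kT=None, thresholds=(0.75, 0.9), aggregate="geometric"):
    """Two-ratio congruence decision for a de-gapped reference sequence.

    An empty projected consensus, an unfoldable reference (E_mfe = 0) or a
    consensus constraint the reference cannot satisfy all yield a
    not-congruent result with a reason code rather than an error.
    """
    lo, hi = thresholds
    n_ret = len(s_c.pairs)
    if not s_c.pairs:
        return CongruenceResult(0.0, 0.0, False, 0, reason="empty_consensus")
    if len(refseq) != s_c.length:
        raise ValueError("sequence and structure lengths differ")
    # consensus pairs the reference cannot form canonically are excluded
    # from both ratios; a reference unable to form at least half of the
    # projected pairs is immediately non-congruent
    codes = ab.encode(ab.normalize(refseq))
    formable = [
        (i, j) for i, j in s_c.pairs if ab.can_pair(codes[i], codes[j])
    ]
    if len(formable) < 0.5 * n_ret or not formable:
        return CongruenceResult(0.0, 0.0, False, n_ret,
                                reason="consensus_unformable")
    s_c_formable = SecondaryStructure(s_c.length, formable)
    s_mfe, e_mfe = mfe_fold(refseq, model)
    if e_mfe == 0.0:
        return CongruenceResult(0.0, 0.0, False, n_ret,
                                reason="unfoldable_reference")
    try:
        _, e_con = mfe_fold(
            refseq, model, FoldConstraint.from_structure(s_c_formable)
        )
    except ConstraintError:
        return CongruenceResult(0.0, 0.0, False, n_ret,
                                reason="unsatisfiable_constraint")
    _, P = partition_function(refseq, model, temperature_kT=kT)
    num = structure_score(P, s_c_formable, aggregate=aggregate)
    den = structure_score(P, s_mfe, aggregate=aggregate)
    delta_p = min(1.0, num / den) if den > 0 else 0.0
    energy_ratio = e_con / e_mfe  # both negative; <= 1 by optimality
    congruent = congruence_decision(delta_p, energy_ratio, thresholds)
    return CongruenceResult(
        float(delta_p), float(energy_ratio), bool(congruent), n_ret
    )
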
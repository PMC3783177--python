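"""RNAalifold-style consensus folding over an alignment.

Column pairs are scored by the mean thermodynamic contribution across rows
plus a covariation bonus, in two variants:

  plain    bonus proportional to the number of distinct canonical pair
           types observed at the column pair (covariation evidence counted
           directly);
  ribosum  bonus proportional to the mean pair-type substitution score over
           all pairs of canonically-pairing rows, read from a RIBOSUM-style
           log-odds table.

Rows that cannot pair canonically are penalised; column pairs incompatible
in more than half of the rows are forbidden (the consensus majority rule).
A Nussinov-style minimisation with stacking over these scores yields the
consensus structure in alignment-column space, and the structure
conservation index (SCI) relates its score to the mean single-sequence
folding energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import _alphabet as ab
from ._kernels import BIG, column_pair_stats, mfe_matrices
from .fold import DEFAULT_MODEL, SecondaryStructure, _FEAS, _traceback, mfe_fold

__all__ = [
    "RibosumMatrix",
    "ConsensusFold",
    "load_ribosum",
    "column_pair_score",
    "consensus_fold",
    "sci",
    "DEFAULT_BETA",
    "DEFAULT_DELTA",
]

# Covariance bonus and incompatible-row penalty weights, calibrated once on
# synthetic family fixtures: beta is the largest weight (on a 0.1 grid,
# scanned downward from 1.0) that keeps the high-confidence false-call rate
# on permuted structured negatives in line with published specificity while
# structured-family detection stays saturated; see docs/methods.md.
DEFAULT_BETA = 0.4
DEFAULT_DELTA = 0.5


class RibosumMatrix:
    """Symmetric pair-type-to-pair-type substitution scores (6 canonical
    pair types, extendable)."""

    def __init__(self, scores, names=ab.PAIR_NAMES):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(names), len(names)):
            raise ValueError("score matrix shape does not match pair names")
        if not np.allclose(scores, scores.T):
            raise ValueError("RIBOSUM matrix must be symmetric")
        self.names = tuple(names)
        self.scores = scores

    def score(self, pair_a, pair_b):
        return float(
            self.scores[self.names.index(pair_a), self.names.index(pair_b)]
        )

    @classmethod
    def from_tsv(cls, stream):
        """Free-format table: header row of pair labels, labelled rows."""
        rows = {}
        header = None
        for line in stream:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if header is None:
                header = fields
                continue
            rows[fields[0]] = [float(x) for x in fields[1:]]
        if header is None:
            raise ValueError("empty RIBOSUM table")
        mat = np.array([rows[name] for name in header])
        return cls(mat, names=tuple(header))


_DEFAULT_RIBOSUM = None


def load_ribosum():
    """The packaged synthetic RIBOSUM-style table (see data/ for provenance)."""
    global _DEFAULT_RIBOSUM
    if _DEFAULT_RIBOSUM is None:
        ref = resources.files("ecscan").joinpath("data/ribosum_synthetic.tsv")
        with ref.open("r") as fh:
            _DEFAULT_RIBOSUM = RibosumMatrix.from_tsv(fh)
    return _DEFAULT_RIBOSUM


@dataclass
class ConsensusFold:
    """Consensus structure in alignment-column space.

    per_pair holds (i, j, energy_term, covariance_term, n_incompatible);
    the energy term of a pair includes its stacking increment, so the score
    is exactly the sum of the per-pair contributions.
    """

    structure: SecondaryStructure
    score: float
    per_pair: list

    @property
    def is_empty(self):
        return not self.structure.pairs


def _raw_stats(aln, model, ribosum):
    """Column-pair statistics shared by both scoring variants."""
    A = aln.encoded()
    if ribosum is None:
        ribosum = load_ribosum()
    rmat = ribosum.scores[:6, :6]
    stats = column_pair_stats(
        np.ascontiguousarray(A.T),
        np.ascontiguousarray(ab.PAIR_TYPE[:4, :4]),
        model.energy_array(),
        np.ascontiguousarray(rmat),
        ab.GAP,
    )
    return stats, A.shape[0]


def _variant_matrices(stats, n_rows, model, variant, beta, delta):
    mean_e, n_types, ribo_cross, n_inc, n_can, stack_frac = stats
    if variant == "plain":
        cov = -beta * np.maximum(n_types - 1, 0)
    elif variant == "ribosum":
        cov = -beta * ribo_cross
    else:
        raise ValueError(f"unknown consensus variant {variant!r}")
    cov = cov + delta * n_inc
    total = mean_e + cov
    allowed = (2 * n_inc <= n_rows) & (n_can >= 1)
    e = np.where(allowed, total, BIG)
    e = np.triu(e, 1) + np.tril(np.full(e.shape, BIG), 0)
    w = model.stack_bonus * stack_frac
    return e, w, mean_e, cov, n_inc


def _score_matrices(aln, model, variant, beta, delta, ribosum):
    stats, n_rows = _raw_stats(aln, model, ribosum)
    return _variant_matrices(stats, n_rows, model, variant, beta, delta)


def column_pair_score(aln, i, j, model=DEFAULT_MODEL, ribosum=None,
                      beta=DEFAULT_BETA, delta=DEFAULT_DELTA, variant=None):
    """Score for pairing alignment columns i and j.

    Returns (total, mean_energy_term, covariance_term, n_incompatible).
    `variant` defaults to "ribosum" when a matrix is supplied, else "plain".
    """
    if variant is None:
        variant = "ribosum" if ribosum is not None else "plain"
    if not (0 <= i < j - model.min_hairpin and j < aln.n_cols):
        raise ValueError(f"column pair ({i},{j}) violates the hairpin rule")
    e, w, mean_e, cov, n_inc = _score_matrices(
        aln, model, variant, beta, delta, ribosum
    )
    return (
        float(mean_e[i, j] + cov[i, j]),
        float(mean_e[i, j]),
        float(cov[i, j]),
        int(n_inc[i, j]),
    )


def consensus_fold_multi(aln, model=DEFAULT_MODEL, variants=("plain", "ribosum"),
                         beta=DEFAULT_BETA, delta=DEFAULT_DELTA, ribosum=None):
    """Consensus folds for several scoring variants, sharing the (dominant)
    column-pair statistics computation.  Returns {variant: ConsensusFold}."""
    stats, n_rows = _raw_stats(aln, model, ribosum)
    out = {}
    for variant in variants:
        e, w, mean_e, cov, n_inc = _variant_matrices(
            stats, n_rows, model, variant, beta, delta
        )
        out[variant] = _fold_from_matrices(aln.n_cols, model, e, w, mean_e, cov, n_inc)
    return out


def consensus_scores(aln, model=DEFAULT_MODEL, variants=("plain", "ribosum"),
                     beta=DEFAULT_BETA, delta=DEFAULT_DELTA, ribosum=None):
    """Consensus scores only (no traceback): the fast path for scoring the
    large batches of null alignments behind Z-scores."""
    stats, n_rows = _raw_stats(aln, model, ribosum)
    n = aln.n_cols
    forced = np.zeros(n, dtype=bool)
    out = {}
    for variant in variants:
        e, w, *_ = _variant_matrices(stats, n_rows, model, variant, beta, delta)
        _, _, E = mfe_matrices(e, w, forced, model.min_hairpin)
        score = float(E[0, n - 1])
        out[variant] = 0.0 if score >= 0.0 or score >= _FEAS else score
    return out


def consensus_fold(aln, model=DEFAULT_MODEL, variant="plain",
                   beta=DEFAULT_BETA, delta=DEFAULT_DELTA, ribosum=None):
    """Minimum-score consensus structure over nested column pairings.

    The empty structure (score 0) is always admissible, so the returned
    score is <= 0; an empty consensus is a defined outcome that triggers
    the dispatch fallback downstream.
    """
    n = aln.n_cols
    if n == 0:
        return ConsensusFold(SecondaryStructure(0), 0.0, [])
    e, w, mean_e, cov, n_inc = _score_matrices(
        aln, model, variant, beta, delta, ribosum
    )
    return _fold_from_matrices(n, model, e, w, mean_e, cov, n_inc)


def _fold_from_matrices(n, model, e, w, mean_e, cov, n_inc):
    forced = np.zeros(n, dtype=bool)
    C, Ex, E = mfe_matrices(e, w, forced, model.min_hairpin)
    score = float(E[0, n - 1])
    if score >= _FEAS or score >= 0.0:
        return ConsensusFold(SecondaryStructure(n), 0.0, [])
    pairs = _traceback(C, Ex, E, e, w, forced, model.min_hairpin, n)
    structure = SecondaryStructure(n, pairs)
    partner = structure.partner_array()
    per_pair = []
    for i, j in sorted(structure.pairs):
        energy_term = mean_e[i, j]
        if partner[i + 1] == j - 1 and i + 1 < j - 1:  # stacked beneath (i,j)
            energy_term += w[i, j]
        per_pair.append(
            (i, j, float(energy_term), float(cov[i, j]), int(n_inc[i, j]))
        )
    return ConsensusFold(structure, score, per_pair)


def sci(aln, model=DEFAULT_MODEL, beta=DEFAULT_BETA, delta=DEFAULT_DELTA, variant="plain",
        ribosum=None):
    """Structure conservation index: consensus score over the mean
    single-sequence MFE of the de-gapped rows (0 when that mean is 0)."""
    cf = consensus_fold(aln, model, variant=variant, beta=beta, delta=delta,
                        ribosum=ribosum)
    energies = []
    for s in aln.sequences:
        seq = s.residues.replace("-", "")
        if not seq:
            energies.append(0.0)
            continue
        _, en = mfe_fold(seq, model)
        energies.append(en)
    mean_single = float(np.mean(energies)) if energies else 0.0
    if mean_single == 0.0:
        return 0.0
    return float(cf.score / mean_single)
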
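"""Single-sequence RNA secondary-structure engine.

Minimum-free-energy folding (optionally constrained), the McCaskill
partition function with exact posterior base-pair probabilities, and
base-pair set comparison metrics.

The energy model is a deliberately transparent stacking model -- per-pair
energies for the six canonical pairs plus a constant bonus for directly
stacked pairs -- rather than a full nearest-neighbour loop model.  All
downstream statistics of the pipeline (Z-scores, conservation indices,
probability and energy ratios) are relative to the model, so the choice
trades absolute-energy realism for auditability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _alphabet as ab
from ._kernels import BIG, NEG_INF, mfe_matrices, pf_inside, pf_outside

_FEAS = BIG / 2.0
_TOL = 1e-9

__all__ = [
    "EnergyModel",
    "SecondaryStructure",
    "PairProbabilityMatrix",
    "FoldConstraint",
    "ConstraintError",
    "mfe_fold",
    "partition_function",
    "structure_score",
    "basepair_metrics",
]


class ConstraintError(ValueError):
    """Raised for folding constraints that cannot be satisfied."""


@dataclass(frozen=True)
class EnergyModel:
    """Simplified stacking energy model over canonical pairs.

    pair_energies: kcal/mol-like energies, one per canonical pair type.
    stack_bonus:   constant increment for two directly nested pairs.
    min_hairpin:   minimum unpaired residues enclosed by a hairpin.
    kT:            Boltzmann factor used by the partition function.
    """

    pair_energies: dict = field(
        default_factory=lambda: {
            "GC": -3.0, "CG": -3.0, "AU": -2.0, "UA": -2.0, "GU": -1.0, "UG": -1.0,
        }
    )
    stack_bonus: float = -1.0
    min_hairpin: int = 3
    kT: float = 0.616

    def __post_init__(self):
        missing = set(ab.PAIR_NAMES) - set(self.pair_energies)
        if missing:
            raise ValueError(f"pair_energies missing {sorted(missing)}")
        if self.min_hairpin < 1:
            raise ValueError("min_hairpin must be >= 1")

    def energy_array(self):
        """Energies indexed by canonical pair-type code."""
        return np.array([self.pair_energies[p] for p in ab.PAIR_NAMES])


DEFAULT_MODEL = EnergyModel()


class SecondaryStructure:
    """A nested set of base pairs over a sequence of fixed length."""

    __slots__ = ("length", "pairs")

    def __init__(self, length, pairs=(), validate=True):
        self.length = int(length)
        self.pairs = frozenset((int(i), int(j)) for i, j in pairs)
        if validate:
            self._validate()

    def _validate(self):
        seen = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair ({i},{j}) out of range for length {self.length}")
            if j - i < 4:
                raise ValueError(f"pair ({i},{j}) violates the minimum hairpin loop")
            for k in (i, j):
                if k in seen:
                    raise ValueError(f"position {k} in more than one pair")
                seen.add(k)
        ordered = sorted(self.pairs)
        stack = []
        for i, j in ordered:
            while stack and stack[-1] < i:
                stack.pop()
            if stack and i < stack[-1] < j:
                raise ValueError(f"pair ({i},{j}) crosses another pair")
            stack.append(j)

    @classmethod
    def from_dot_bracket(cls, db):
        stack, pairs = [], []
        for idx, ch in enumerate(db):
            if ch == "(":
                stack.append(idx)
            elif ch == ")":
                if not stack:
                    raise ValueError("unbalanced dot-bracket string")
                pairs.append((stack.pop(), idx))
            elif ch != ".":
                raise ValueError(f"unexpected dot-bracket character {ch!r}")
        if stack:
            raise ValueError("unbalanced dot-bracket string")
        return cls(len(db), pairs)

    @property
    def dot_bracket(self):
        out = ["."] * self.length
        for i, j in self.pairs:
            out[i], out[j] = "(", ")"
        return "".join(out)

    def partner_array(self):
        """Partner index per position, -1 if unpaired."""
        pt = np.full(self.length, -1, dtype=np.int64)
        for i, j in self.pairs:
            pt[i], pt[j] = j, i
        return pt

    def __len__(self):
        return self.length

    def __eq__(self, other):
        return (
            isinstance(other, SecondaryStructure)
            and self.length == other.length
            and self.pairs == other.pairs
        )

    def __hash__(self):
        return hash((self.length, self.pairs))

    def __repr__(self):
        return f"SecondaryStructure({self.dot_bracket!r})"


class PairProbabilityMatrix:
    """Posterior pair probabilities p(i,j), stored upper-triangular."""

    __slots__ = ("length", "_p", "log_z")

    def __init__(self, matrix, log_z=None):
        self._p = np.asarray(matrix, dtype=float)
        self.length = self._p.shape[0]
        self.log_z = log_z

    def p(self, i, j):
        if i > j:
            i, j = j, i
        return float(self._p[i, j])

    def unpaired(self, i):
        """Probability that position i is unpaired."""
        return float(1.0 - self._p[i, :].sum() - self._p[:, i].sum())

    def to_array(self):
        return self._p.copy()


@dataclass(frozen=True)
class FoldConstraint:
    """Forced pairs and forced-unpaired positions for constrained folding."""

    forced_pairs: frozenset = frozenset()
    unpaired: frozenset = frozenset()

    @classmethod
    def from_structure(cls, structure):
        """Constraint forcing every pair of `structure` to be present."""
        return cls(forced_pairs=frozenset(structure.pairs))


def _pairing_matrices(codes, model, constraint):
    """(e, w, forced_paired) matrices implementing model + constraint."""
    n = len(codes)
    pe = model.energy_array()
    pt = ab.PAIR_TYPE[codes[:, None], codes[None, :]]
    e = np.where(pt >= 0, pe[np.clip(pt, 0, 5)], BIG)
    e = np.triu(e, 1) + np.tril(np.full((n, n), BIG), 0)
    w = np.full((n, n), model.stack_bonus)
    forced = np.zeros(n, dtype=bool)
    if constraint is not None:
        # validate the forced pairs as a (partial) structure
        try:
            SecondaryStructure(n, constraint.forced_pairs)
        except ValueError as exc:
            raise ConstraintError(str(exc)) from exc
        for k in constraint.unpaired:
            if not 0 <= k < n:
                raise ConstraintError(f"unpaired position {k} out of range")
            e[k, :] = BIG
            e[:, k] = BIG
        for i, j in constraint.forced_pairs:
            if i in constraint.unpaired or j in constraint.unpaired:
                raise ConstraintError(f"pair ({i},{j}) conflicts with unpaired mask")
            if e[i, j] >= _FEAS:
                raise ConstraintError(f"forced pair ({i},{j}) cannot form")
            forced[i] = forced[j] = True
            # i and j may pair only with each other
            keep = e[i, j]
            e[i, :] = BIG
            e[:, i] = BIG
            e[j, :] = BIG
            e[:, j] = BIG
            e[i, j] = keep
        # forbid pairs crossing any forced pair
        for a, b in constraint.forced_pairs:
            ii = np.arange(n)
            inside = (ii > a) & (ii < b)
            e[np.ix_(inside, ii > b)] = BIG
            e[np.ix_(ii < a, inside)] = BIG
    return e, w, forced


def _prepare(seq):
    codes = ab.encode(ab.normalize(seq))
    return codes


def mfe_fold(seq, model=DEFAULT_MODEL, constraint=None):
    """Minimum-energy nested structure under the model.

    Returns (SecondaryStructure, energy).  The empty structure has energy
    0; N residues never pair.  Raises ConstraintError when the constraint
    is inconsistent or unsatisfiable.
    """
    codes = _prepare(seq)
    n = len(codes)
    if n == 0:
        return SecondaryStructure(0), 0.0
    e, w, forced = _pairing_matrices(codes, model, constraint)
    C, Ex, E = mfe_matrices(e, w, forced, model.min_hairpin)
    energy = E[0, n - 1]
    if energy >= _FEAS:
        raise ConstraintError("constraint admits no structure")
    pairs = _traceback(C, Ex, E, e, w, forced, model.min_hairpin, n)
    return SecondaryStructure(n, pairs), float(energy)


def _traceback(C, Ex, E, e, w, forced, min_h, n):
    """Deterministic traceback; ties resolved toward pairing, with the
    smallest left index first."""
    pairs = []
    stack = [(0, n - 1, "E")]
    while stack:
        i, j, mode = stack.pop()
        if j <= i:
            continue
        if mode == "C":
            # (i,j) is paired; decide the interior of the helix
            a, b = i + 1, j - 1
            if b <= a:
                continue
            if C[a, b] < _FEAS and abs(C[i, j] - (e[i, j] + C[a, b] + w[i, j])) <= _TOL:
                pairs.append((a, b))
                stack.append((a, b, "C"))
            else:
                stack.append((a, b, "EX"))
            continue
        target = E[i, j] if mode == "E" else Ex[i, j]
        if target >= _FEAS:
            continue
        if mode == "E" and C[i, j] < _FEAS and abs(target - C[i, j]) <= _TOL:
            pairs.append((i, j))
            stack.append((i, j, "C"))
            continue
        # j unpaired?
        left = E[i, j - 1] if j - 1 >= i else 0.0
        if not forced[j] and left < _FEAS and abs(target - left) <= _TOL:
            stack.append((i, j - 1, "E"))
            continue
        done = False
        for k in range(i + 1, j - min_h):
            if C[k, j] >= _FEAS:
                continue
            lft = E[i, k - 1] if k - 1 >= i else 0.0
            if lft < _FEAS and abs(target - (lft + C[k, j])) <= _TOL:
                pairs.append((k, j))
                stack.append((k, j, "C"))
                stack.append((i, k - 1, "E"))
                done = True
                break
        if not done:  # pragma: no cover - should be unreachable
            raise AssertionError("traceback failed to explain the optimum")
    return pairs


def partition_function(seq, model=DEFAULT_MODEL, temperature_kT=None, constraint=None):
    """McCaskill partition function.

    Z = sum over all admissible nested structures of exp(-E/kT) (the open
    chain always included, weight 1).  Computed in log space; `log_z` on the
    returned matrix-bearing tuple is authoritative for long sequences.

    Returns (Z, PairProbabilityMatrix); the matrix carries exact posterior
    pair probabilities from the inside-outside recursions.
    """
    kT = model.kT if temperature_kT is None else float(temperature_kT)
    codes = _prepare(seq)
    n = len(codes)
    if n == 0:
        return 1.0, PairProbabilityMatrix(np.zeros((0, 0)))
    e, w, forced = _pairing_matrices(codes, model, constraint)
    lq = np.where(e < _FEAS, -e / kT, NEG_INF)
    ls = -w / kT
    lC, lEx, lE = pf_inside(lq, ls, forced, model.min_hairpin)
    log_z = lE[0, n - 1]
    if log_z == NEG_INF:
        raise ConstraintError("constraint admits no structure")
    lP = pf_outside(lq, ls, forced, model.min_hairpin, lC, lEx, lE)
    probs = np.where(lP > -700.0, np.exp(np.maximum(lP, -700.0)), 0.0)
    ppm = PairProbabilityMatrix(probs, log_z=float(log_z))
    z = math.exp(min(log_z, 709.0))  # saturates instead of overflowing
    return z, ppm


def structure_score(P, S, aggregate="geometric"):
    """Probability-like support of structure S under pair probabilities P.

    Aggregates p(i,j) over the pairs of S: "geometric" mean (default),
    plain "product", or arithmetic "mean" (the structure's average pair
    probability mass, robust to single near-zero pairs).  An empty
    structure scores 1 (empty product).
    """
    if P.length != S.length:
        raise ValueError("pair-probability matrix and structure lengths differ")
    if not S.pairs:
        return 1.0
    ps = np.array([P.p(i, j) for i, j in S.pairs])
    if aggregate == "mean":
        return float(ps.mean())
    if (ps == 0).any():
        return 0.0
    logs = np.log(ps).sum()
    if aggregate == "geometric":
        logs /= len(ps)
    elif aggregate != "product":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return float(np.exp(logs))


def basepair_metrics(pred, truth):
    """(sensitivity, PPV, base-pair distance) between two structures.

    sensitivity = |pred & truth| / |truth|; ppv = |pred & truth| / |pred|;
    distance = symmetric difference size.  Empty reference (or prediction)
    sets score 1.0 by convention.
    """
    if pred.length != truth.length:
        raise ValueError("structures have different lengths")
    inter = len(pred.pairs & truth.pairs)
    sens = inter / len(truth.pairs) if truth.pairs else 1.0
    ppv = inter / len(pred.pairs) if pred.pairs else 1.0
    dist = len(pred.pairs ^ truth.pairs)
    return sens, ppv, dist
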
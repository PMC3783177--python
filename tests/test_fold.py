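import numpy as np
import pytest

from ecscan import _alphabet as ab
from ecscan import _enumerate as oracle
from ecscan.fold import (
    ConstraintError,
    EnergyModel,
    FoldConstraint,
    SecondaryStructure,
    _pairing_matrices,
    basepair_metrics,
    mfe_fold,
    partition_function,
    structure_score,
)


def _matrices(seq, model):
    codes = ab.encode(seq)
    e, w, forced = _pairing_matrices(codes, model, None)
    return e, w, e < 1e15


class TestSecondaryStructure:
    def test_dot_bracket_round_trip(self):
        db = "((((...))))...((...))"
        assert SecondaryStructure.from_dot_bracket(db).dot_bracket == db

    @pytest.mark.parametrize("db", ["((...)", "...)..", "(..)"])
    def test_invalid_rejected(self, db):
        with pytest.raises(ValueError):
            SecondaryStructure.from_dot_bracket(db)

    def test_crossing_pairs_rejected(self):
        with pytest.raises(ValueError, match="cross"):
            SecondaryStructure(12, [(0, 6), (3, 10)])


class TestMfeExamples:
    def test_unpairable_sequence_is_open(self, model):
        s, e = mfe_fold("AAAAAA", model)
        assert s.dot_bracket == "......" and e == 0.0

    def test_pair_only_scoring_hairpin(self, pair_only_model):
        s, e = mfe_fold("GGGAAACCC", pair_only_model)
        assert len(s.pairs) == 3 and e == pytest.approx(-3.0)

    def test_all_unpaired_constraint(self, model):
        c = FoldConstraint(unpaired=frozenset(range(9)))
        s, e = mfe_fold("GGGAAACCC", model, c)
        assert s.dot_bracket == "........." and e == 0.0

    def test_inconsistent_constraint_rejected(self, model):
        with pytest.raises(ConstraintError):
            mfe_fold("GGGAAACCC", model, FoldConstraint(forced_pairs=frozenset({(0, 2)})))
        with pytest.raises(ConstraintError):  # AA cannot pair
            mfe_fold("AAAAAAAA", model, FoldConstraint(forced_pairs=frozenset({(0, 7)})))

    def test_n_never_pairs(self, model):
        s, _ = mfe_fold("GGNAAACNC", model)
        assert all(2 not in p and 7 not in p for p in s.pairs)


class TestOracleEquivalence:
    """DP against exhaustive enumeration on short random sequences."""

    def test_mfe_and_partition_match_enumeration(self, rng, model):
        for _ in range(60):
            n = int(rng.integers(1, 15))
            seq = "".join(rng.choice(list("ACGUN"), size=n, p=[0.24] * 4 + [0.04]))
            e, w, allowed = _matrices(seq, model)
            s, en = mfe_fold(seq, model)
            assert en == pytest.approx(oracle.brute_force_mfe(e, w, allowed), abs=1e-9)
            assert oracle.structure_energy(s.pairs, e, w) == pytest.approx(en, abs=1e-9)
            z, P = partition_function(seq, model)
            zb, pb = oracle.brute_force_partition(e, w, allowed, model.kT)
            assert z == pytest.approx(zb, rel=1e-9)
            np.testing.assert_allclose(P.to_array(), pb, rtol=1e-9, atol=1e-12)

    def test_probability_conservation(self, rng, model):
        for _ in range(10):
            n = int(rng.integers(8, 15))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            e, w, allowed = _matrices(seq, model)
            _, P = partition_function(seq, model)
            # enumeration probability that each position is unpaired
            z = 0.0
            unp = np.zeros(n)
            for s in oracle.enumerate_structures(n, allowed, model.min_hairpin):
                wgt = np.exp(-oracle.structure_energy(s, e, w) / model.kT)
                z += wgt
                paired = {i for p in s for i in p}
                for i in range(n):
                    if i not in paired:
                        unp[i] += wgt
            for i in range(n):
                assert P.unpaired(i) == pytest.approx(unp[i] / z, rel=1e-9, abs=1e-12)

    def test_constraint_monotonicity(self, rng, model):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=12))
            s, e0 = mfe_fold(seq, model)
            if not s.pairs:
                continue
            pair = sorted(s.pairs)[0]
            _, e1 = mfe_fold(seq, model, FoldConstraint(forced_pairs=frozenset({pair})))
            assert e1 >= e0 - 1e-12
            assert e1 == pytest.approx(e0)  # forcing an MFE pair is free


class TestPartitionFunction:
    def test_no_pairs_means_unit_z(self, model):
        z, P = partition_function("AAAA", model)
        assert z == pytest.approx(1.0)
        assert P.to_array().sum() == 0.0

    def test_infinite_temperature_counts_structures(self, model):
        seq = "GCAAAGC"
        z, P = partition_function(seq, model, temperature_kT=1e12)
        e, w, allowed = _matrices(seq, model)
        structures = list(oracle.enumerate_structures(len(seq), allowed, model.min_hairpin))
        assert z == pytest.approx(len(structures), rel=1e-6)
        counts = np.zeros((7, 7))
        for s in structures:
            for i, j in s:
                counts[i, j] += 1
        np.testing.assert_allclose(P.to_array(), counts / len(structures), atol=1e-6)

    def test_long_sequence_stays_finite(self, rng, model):
        seq = "".join(rng.choice(list("ACGU"), size=300))
        z, P = partition_function(seq, model)
        assert np.isfinite(P.log_z)
        assert np.isfinite(P.to_array()).all()

    def test_deterministic_traceback(self, rng, model):
        seq = "".join(rng.choice(list("ACGU"), size=60))
        s1, _ = mfe_fold(seq, model)
        s2, _ = mfe_fold(seq, model)
        assert s1 == s2


class TestStructureScore:
    def test_examples(self):
        P = np.zeros((10, 10))
        P[0, 8] = 0.5
        from ecscan.fold import PairProbabilityMatrix

        ppm = PairProbabilityMatrix(P)
        assert structure_score(ppm, SecondaryStructure(10)) == 1.0
        s = SecondaryStructure(10, [(0, 8)])
        assert structure_score(ppm, s) == pytest.approx(0.5)
        s2 = SecondaryStructure(10, [(0, 8), (1, 7)])  # p(1,7) = 0
        assert structure_score(ppm, s2) == 0.0
        assert structure_score(ppm, s2, aggregate="mean") == pytest.approx(0.25)


class TestBasepairMetrics:
    def test_identical(self):
        s = SecondaryStructure.from_dot_bracket("(((...)))")
        assert basepair_metrics(s, s) == (1.0, 1.0, 0)

    def test_partial(self):
        truth = SecondaryStructure(20, [(0, 19), (1, 18), (2, 17), (3, 16)])
        pred = SecondaryStructure(20, [(0, 19), (1, 18), (5, 12)])
        sens, ppv, dist = basepair_metrics(pred, truth)
        assert sens == pytest.approx(0.5)
        assert ppv == pytest.approx(2 / 3)
        assert dist == 3

    def test_both_empty_convention(self):
        e = SecondaryStructure(9)
        assert basepair_metrics(e, e) == (1.0, 1.0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            basepair_metrics(SecondaryStructure(9), SecondaryStructure(10))
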
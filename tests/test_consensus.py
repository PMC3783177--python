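import io

import numpy as np
import pytest

from ecscan import _enumerate as oracle
from ecscan.consensus import (
    RibosumMatrix,
    _score_matrices,
    column_pair_score,
    consensus_fold,
    consensus_fold_multi,
    consensus_scores,
    load_ribosum,
    sci,
)
from ecscan.fold import mfe_fold
from ecscan.msa_io import Alignment


class TestRibosumMatrix:
    def test_shipped_table_is_symmetric_log_odds(self):
        rib = load_ribosum()
        assert rib.scores.shape == (6, 6)
        np.testing.assert_allclose(rib.scores, rib.scores.T)
        # conserved pairs score highest; compensatory pairs clearly positive
        diag = np.diag(rib.scores)
        assert (diag >= rib.scores.max(axis=1) - 1e-9).all()
        assert rib.score("GC", "AU") > 0 and rib.score("CG", "UA") > 0

    def test_asymmetric_rejected(self):
        bad = np.arange(36, dtype=float).reshape(6, 6)
        with pytest.raises(ValueError):
            RibosumMatrix(bad)

    def test_tsv_round_trip(self):
        rib = load_ribosum()
        buf = io.StringIO()
        buf.write("\t" + "\t".join(rib.names) + "\n")
        for k, name in enumerate(rib.names):
            buf.write(name + "\t" + "\t".join(str(v) for v in rib.scores[k]) + "\n")
        buf.seek(0)
        again = RibosumMatrix.from_tsv(buf)
        np.testing.assert_allclose(again.scores, rib.scores)


class TestColumnPairScore:
    def test_conserved_pair_gets_no_bonus(self):
        aln = Alignment.from_strings([(f"s{i}", "GAAAAC") for i in range(4)])
        total, mean_e, cov, n_inc = column_pair_score(aln, 0, 5)
        assert cov == 0.0 and n_inc == 0
        assert mean_e == pytest.approx(-3.0)  # every row GC
        assert total == pytest.approx(-3.0)

    def test_compensatory_rows_earn_plain_bonus(self):
        aln = Alignment.from_strings(
            [("a", "GAAAAC"), ("b", "GAAAAC"), ("c", "AAAAAU")]
        )
        total, mean_e, cov, n_inc = column_pair_score(aln, 0, 5, beta=1.0)
        assert n_inc == 0
        assert cov == pytest.approx(-1.0)  # two pair types -> -beta*(2-1)
        assert total < mean_e

    def test_incompatible_row_penalised(self):
        aln = Alignment.from_strings([("a", "GAAAAC"), ("b", "GAAAAA")])
        total, mean_e, cov, n_inc = column_pair_score(aln, 0, 5)
        assert n_inc == 1
        assert cov == pytest.approx(0.5)  # delta * n_incompatible

    def test_gap_rows_contribute_nothing(self):
        aln = Alignment.from_strings([("a", "GAAAAC"), ("b", "-AAAAC")])
        total, mean_e, cov, n_inc = column_pair_score(aln, 0, 5)
        assert n_inc == 0 and cov == 0.0
        assert mean_e == pytest.approx(-1.5)  # averaged over both rows

    def test_hairpin_precondition(self):
        aln = Alignment.from_strings([("a", "GAAAAC")])
        with pytest.raises(ValueError):
            column_pair_score(aln, 0, 3)


class TestConsensusFold:
    def test_identical_rows_match_single_sequence_fold(self, model):
        aln = Alignment.from_strings([(f"s{i}", "GGGCAAAGCCC") for i in range(5)])
        cf = consensus_fold(aln, model)
        s, e = mfe_fold("GGGCAAAGCCC", model)
        assert cf.score == pytest.approx(e)
        assert cf.structure.pairs == s.pairs
        assert all(p[3] == 0.0 for p in cf.per_pair)  # covariance terms 0

    def test_score_is_sum_of_per_pair_terms(self, compensatory_alignment):
        cf = consensus_fold(compensatory_alignment)
        total = sum(p[2] + p[3] for p in cf.per_pair)
        assert cf.score == pytest.approx(total)

    def test_unalignable_rows_give_empty_consensus(self):
        aln = Alignment.from_strings(
            [("a", "GAGAGAGA"), ("b", "AGAGAGAG"), ("c", "GGAAGGAA")]
        )
        cf = consensus_fold(aln)
        assert cf.is_empty and cf.score == 0.0

    def test_majority_rule_forbids_incompatible_pairs(self):
        # 2 of 3 rows cannot pair columns 0/5 -> pair forbidden
        aln = Alignment.from_strings(
            [("a", "GAAAAC"), ("b", "GAAAAA"), ("c", "GAAAAG")]
        )
        cf = consensus_fold(aln)
        assert (0, 5) not in cf.structure.pairs

    def test_dp_matches_brute_force_in_column_space(self, rng, model):
        for _ in range(15):
            n = int(rng.integers(8, 14))
            rows = ["".join(rng.choice(list("ACGU-"), size=n, p=[0.23] * 4 + [0.08]))
                    for _ in range(4)]
            aln = Alignment.from_strings([(f"s{i}", r) for i, r in enumerate(rows)])
            for variant in ("plain", "ribosum"):
                e, w, *_ = _score_matrices(aln, model, variant, 0.7, 0.5, None)
                best = oracle.brute_force_mfe(e, w, e < 1e15, model.min_hairpin)
                cf = consensus_fold(aln, model, variant=variant, beta=0.7, delta=0.5)
                assert cf.score == pytest.approx(min(best, 0.0), abs=1e-9)

    def test_row_duplication_scale_law(self, compensatory_alignment):
        doubled = Alignment.from_strings(
            [(f"{s.id}{k}", s.residues) for k in range(2)
             for s in compensatory_alignment.sequences]
        )
        t1 = column_pair_score(compensatory_alignment, 0, 8)
        t2 = column_pair_score(doubled, 0, 8)
        assert t1[1] == pytest.approx(t2[1])  # mean energy unchanged
        assert t1[3] * 2 == t2[3]  # incompatible rows scale with copies

    def test_ribosum_bonus_exceeds_plain_on_compensatory_fixture(self, compensatory_alignment):
        _, _, cov_p, _ = column_pair_score(compensatory_alignment, 0, 8, variant="plain")
        _, _, cov_r, _ = column_pair_score(
            compensatory_alignment, 0, 8, variant="ribosum", ribosum=load_ribosum()
        )
        assert cov_r <= cov_p < 0

    def test_multi_and_scores_agree_with_single(self, compensatory_alignment):
        multi = consensus_fold_multi(compensatory_alignment)
        scores = consensus_scores(compensatory_alignment)
        for v in ("plain", "ribosum"):
            single = consensus_fold(compensatory_alignment, variant=v)
            assert multi[v].score == pytest.approx(single.score)
            assert scores[v] == pytest.approx(single.score)


class TestSci:
    def test_identical_rows_give_unity(self):
        aln = Alignment.from_strings([(f"s{i}", "GGGCAAAGCCC") for i in range(4)])
        assert sci(aln) == pytest.approx(1.0)

    def test_unfoldable_rows_guarded(self):
        aln = Alignment.from_strings([(f"s{i}", "AAAAAAA") for i in range(3)])
        assert sci(aln) == 0.0

    def test_compensatory_family_exceeds_permuted(self, rng):
        from ecscan.nullmodels import permute_alignment
        from ecscan import synthsim as ss

        fam = ss.evolve_family(ss.FamilySpec(n_cols=80, n_tips=8, branch_scale=0.2), rng)
        native = sci(fam.alignment)
        nulls = [sci(permute_alignment(fam.alignment, rng)) for _ in range(5)]
        assert native > np.mean(nulls)
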
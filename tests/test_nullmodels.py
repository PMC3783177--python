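from collections import Counter

import numpy as np
import pytest

from ecscan import synthsim as ss
from ecscan.alnstats import compute_stats, qc_filter
from ecscan.msa_io import Alignment
from ecscan.nullmodels import (
    ConsensusScorer,
    build_tree,
    dinucleotide_shuffle,
    estimate_kappa,
    jukes_cantor_distance,
    permute_alignment,
    simulate_alignment,
    zscore,
    zscore_multi,
)
from ecscan._kernels import dinuc_counts


def _dinucs(s):
    return Counter(zip(s, s[1:]))


class TestDinucleotideShuffle:
    def test_exact_conservation_random_battery(self, rng):
        for _ in range(150):
            n = int(rng.integers(2, 80))
            seq = "".join(rng.choice(list("ACGUN"), size=n, p=[0.24] * 4 + [0.04]))
            out = dinucleotide_shuffle(seq, rng)
            assert _dinucs(out) == _dinucs(seq)
            assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_degenerate_inputs_unchanged(self, rng):
        assert dinucleotide_shuffle("AAAA", rng) == "AAAA"
        assert dinucleotide_shuffle("A", rng) == "A"
        assert dinucleotide_shuffle("GCGCGC", rng) == "GCGCGC"  # unique walk

    def test_shuffle_actually_randomises(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=40))
        outs = {dinucleotide_shuffle(seq, rng) for _ in range(50)}
        assert len(outs) > 5

    def test_gapped_input_rejected(self, rng):
        with pytest.raises(ValueError):
            dinucleotide_shuffle("AC-GU", rng)


class TestPermuteAlignment:
    @pytest.fixture
    def window(self, rng):
        neu = ss.neutral_alignment(ss.FamilySpec(n_cols=120, n_tips=8), rng)
        return neu

    def test_columns_preserved_as_multisets(self, window, rng):
        perm = permute_alignment(window, rng)
        native_cols = Counter(
            "".join(s.residues[c] for s in window.sequences)
            for c in range(window.n_cols)
        )
        perm_cols = Counter(
            "".join(s.residues[c] for s in perm.sequences)
            for c in range(perm.n_cols)
        )
        assert native_cols == perm_cols

    def test_row_gap_counts_and_mpi_preserved(self, window, rng):
        perm = permute_alignment(window, rng)
        assert perm.n_cols == window.n_cols
        for s0, s1 in zip(window.sequences, perm.sequences):
            assert s0.residues.count("-") == s1.residues.count("-")
        # MPI invariance (well within the 2-point drift budget)
        m0 = compute_stats(window).mpi
        m1 = compute_stats(perm).mpi
        assert abs(m0 - m1) <= 2.0

    def test_identical_rows_stay_identical(self, rng):
        aln = Alignment.from_strings([(f"s{i}", "ACGUACGUAC") for i in range(4)])
        perm = permute_alignment(aln, rng)
        texts = {s.residues for s in perm.sequences}
        assert len(texts) == 1
        assert compute_stats(perm).mpi == 100.0

    def test_repair_reduces_dinucleotide_deviation(self, window, rng):
        A = np.ascontiguousarray(window.encoded())
        native = dinuc_counts(A, 5, 6)

        def deviation(aln):
            B = np.ascontiguousarray(aln.encoded())
            return int(np.abs(dinuc_counts(B, 5, 6) - native).sum())

        devs_raw, devs_rep = [], []
        for _ in range(5):
            devs_raw.append(deviation(permute_alignment(window, rng, repair_trials=0)))
            devs_rep.append(deviation(permute_alignment(window, rng)))
        assert np.mean(devs_rep) <= np.mean(devs_raw)


class TestBuildTree:
    def test_identical_sequences_star_tree(self):
        aln = Alignment.from_strings([(f"s{i}", "ACGUACGUAC") for i in range(4)])
        t = build_tree(aln)
        assert t.length.max() == 0.0
        assert set(t.tips) == {"s0", "s1", "s2", "s3"}

    def test_four_taxon_split_recovered(self):
        aln = Alignment.from_strings(
            [("a", "G" * 20), ("b", "G" * 20),
             ("c", "G" * 10 + "C" * 10), ("d", "G" * 10 + "C" * 10)]
        )
        t = build_tree(aln)
        # JC distance for p=0.5 splits evenly across the central branch
        d, sat = jukes_cantor_distance(0.5)
        assert not sat and d == pytest.approx(0.8239592165010822)
        nwk = t.newick
        assert ("t0" in nwk and "t1" in nwk)  # placeholder-labelled tips

    def test_saturation_capped(self):
        d, sat = jukes_cantor_distance(0.76)
        assert sat and d == 5.0
        aln = Alignment.from_strings(
            [("a", "ACAC" * 5), ("b", "GUGU" * 5), ("c", "CACA" * 5)]
        )
        t = build_tree(aln)
        assert t.saturated

    def test_too_few_sequences_rejected(self):
        aln = Alignment.from_strings([("a", "ACGU"), ("b", "ACGU")])
        with pytest.raises(ValueError):
            build_tree(aln)


class TestSimulateAlignment:
    def test_zero_branch_lengths_give_identical_rows(self, rng):
        aln = Alignment.from_strings([(f"s{i}", "ACGUACGUAC") for i in range(4)])
        tree = build_tree(aln)  # all lengths 0
        sim = simulate_alignment(aln, tree, rng)
        assert len({s.residues for s in sim.sequences}) == 1

    def test_gap_and_n_pattern_copied(self, rng):
        aln = Alignment.from_strings(
            [("a", "AC-GUACN-C"), ("b", "ACGUACGUAC"), ("c", "A--UACGUAC"),
             ("d", "ACGUACGU-C")]
        )
        sim = simulate_alignment(aln, build_tree(aln), rng)
        for s0, s1 in zip(aln.sequences, sim.sequences):
            for ch0, ch1 in zip(s0.residues, s1.residues):
                assert (ch0 in "-N") == (ch1 in "-N")
                if ch0 in "-N":
                    assert ch1 == ch0

    def test_long_branches_approach_stationary_identity(self, rng):
        # two tips at enormous distance: expected identity -> sum(pi^2)
        base = "".join(rng.choice(list("ACGU"), size=400))
        rows = [("a", base), ("b", base), ("c", base)]
        aln = Alignment.from_strings(rows)
        tree = build_tree(aln)
        tree.length[:] = 50.0  # saturate every branch
        idents = []
        for _ in range(10):
            sim = simulate_alignment(aln, tree, rng)
            idents.append(compute_stats(sim).mpi)
        assert np.mean(idents) == pytest.approx(25.0, abs=4.0)

    def test_mpi_tracks_native(self, rng):
        drifts = []
        for _ in range(6):
            fam = ss.evolve_family(ss.FamilySpec(n_cols=150, n_tips=10), rng)
            q = qc_filter(fam.alignment)
            if not q:
                continue
            native = compute_stats(q.alignment).mpi
            tree = build_tree(q.alignment)
            sims = [
                compute_stats(simulate_alignment(q.alignment, tree, rng)).mpi
                for _ in range(5)
            ]
            drifts.append(np.mean(sims) - native)
        assert abs(np.mean(drifts)) <= 2.0

    def test_kappa_estimator_bounds(self, rng):
        aln = Alignment.from_strings([("a", "AGAGAG"), ("b", "GAGAGA"), ("c", "AGAGAA")])
        k = estimate_kappa(aln.encoded())
        assert 0.2 <= k <= 20.0


class TestZScore:
    def test_zero_variance_background_is_degenerate(self, rng):
        aln = Alignment.from_strings(
            [("a", "GGGCAAAGCCC"), ("b", "GGCCAAAGGCC"), ("c", "GAGCAAAGCUC")]
        )
        res = zscore(
            aln, ConsensusScorer("plain"),
            null_generator=lambda a, r: a,  # nulls identical to native
            n_nulls=5, rng=rng,
        )
        assert res.degenerate and res.z is None
        assert res.null_sd == pytest.approx(0.0, abs=1e-12)

    def test_z_is_standardised_native_score(self, rng):
        fam = ss.evolve_family(ss.FamilySpec(n_cols=100, n_tips=8), rng)
        q = qc_filter(fam.alignment)
        res = zscore(
            q.alignment, ConsensusScorer("plain"),
            null_generator=lambda a, r: permute_alignment(a, r),
            n_nulls=20, rng=rng,
        )
        if not res.degenerate:
            assert res.z == pytest.approx(
                (res.native_score - res.null_mean) / res.null_sd
            )
        assert res.n_nulls == 20 and res.mode == "plain"

    def test_multi_shares_nulls_between_variants(self, rng):
        fam = ss.evolve_family(ss.FamilySpec(n_cols=100, n_tips=8), rng)
        q = qc_filter(fam.alignment)
        out = zscore_multi(
            q.alignment, lambda a, r: permute_alignment(a, r),
            n_nulls=15, rng=rng,
        )
        assert set(out) == {"plain", "ribosum"}
        for v, res in out.items():
            assert res.mode == v
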
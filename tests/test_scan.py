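import io
import math

import numpy as np
import pytest

from ecscan import synthsim as ss
from ecscan.alnstats import AlnStats
from ecscan.fold import SecondaryStructure
from ecscan.msa_io import Alignment, write_bed
from ecscan.scan import (
    HIGHMPI_WEIGHTS,
    EcsPrediction,
    ScanConfig,
    _ref_interval,
    cluster_predictions,
    dispatch,
    make_windows,
    scan_block,
    score_highmpi,
    truncate_to_structure,
)


def _stats(mpi=70.0, gc=50.0):
    return AlnStats(mpi, 5.0, 0.3, gc, 2.0, 10)


class TestMakeWindows:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (500, [(0, 200), (100, 300), (200, 400), (300, 500)]),
            (201, [(0, 200), (100, 201)]),
            (150, [(0, 150)]),
            (80, [(0, 80)]),
            (240, [(0, 200), (100, 240)]),
            (220, [(0, 200), (100, 220)]),  # 120-col tail >= window/2
            (110, [(0, 110)]),
        ],
    )
    def test_window_intervals(self, n, expected):
        aln = Alignment.from_strings([("x", "A" * n)])
        assert [iv for _, iv in make_windows(aln, ScanConfig())] == expected

    def test_window_contents_match_intervals(self):
        aln = Alignment.from_strings([("x", "ACGU" * 100)])
        for win, (c0, c1) in make_windows(aln, ScanConfig()):
            assert win.n_cols == c1 - c0


class TestDispatch:
    """The published dispatch rules on constructed descriptor values."""

    @pytest.mark.parametrize(
        "mpi,gc,mode",
        [
            (90.0, 50.0, "highmpi"),   # MPI > 85
            (85.1, 75.0, "highmpi"),
            (70.0, 50.0, "plain"),     # 60 <= MPI <= 85, GC < 70
            (85.0, 69.9, "plain"),
            (60.0, 50.0, "plain"),
            (70.0, 75.0, "ribosum"),   # GC >= 70
            (70.0, 70.0, "ribosum"),
            (59.9, 50.0, "ribosum"),   # below the twilight threshold
            (40.0, 80.0, "ribosum"),
        ],
    )
    def test_rules(self, mpi, gc, mode):
        assert dispatch(_stats(mpi, gc), ScanConfig()) == mode


class TestScoreHighmpi:
    def test_logistic_is_monotone_in_stability(self):
        w0, w1, w2 = HIGHMPI_WEIGHTS
        assert w1 > 0 and w2 < 0

        def logistic(s, z):
            return 1 / (1 + math.exp(-(w0 + w1 * s + w2 * z)))

        assert logistic(1.0, -3.0) > logistic(1.0, -1.0) > logistic(1.0, 0.0)

    def test_null_like_input_scores_below_threshold(self, rng):
        # identical rows with no stable fold: sci = 0, zstab ~ 0
        aln = Alignment.from_strings([(f"s{i}", "ACACACAC" * 5) for i in range(4)])
        p = score_highmpi(aln, ScanConfig(), rng)
        assert p < ScanConfig().p_cut_highmpi

    def test_score_in_unit_interval(self, rng):
        fam = ss.evolve_family(
            ss.FamilySpec(n_cols=100, n_tips=6, branch_scale=0.05), rng
        )
        p = score_highmpi(fam.alignment, ScanConfig(), rng)
        assert 0.0 <= p <= 1.0


class TestCoordinateMapping:
    def _window(self, residues, start=100, strand="+", size=1000):
        from ecscan.msa_io import AlignedSequence

        seqs = [
            AlignedSequence("hg.chr1", residues, start, strand, size),
            AlignedSequence("pt.chr1", residues, 0, "+", size),
            AlignedSequence("mm.chr9", residues, 0, "+", size),
        ]
        return Alignment(seqs, reference_index=0)

    def test_gap_skipping(self):
        w = self._window("AC-GU")
        assert _ref_interval(w, 0, 5) == ("chr1", 100, 104)

    def test_minus_strand_flips_to_assembly_forward(self):
        w = self._window("AC-GU", start=100, strand="-", size=1000)
        chrom, s, e = _ref_interval(w, 0, 5)
        assert (s, e) == (1000 - 104, 1000 - 100)

    def test_subinterval_width_counts_reference_residues(self):
        w = self._window("A--CGU--A")
        chrom, s, e = _ref_interval(w, 1, 8)
        assert e - s == 3  # C, G, U only

    def test_all_gap_interval_is_none(self):
        w = self._window("A--CG")
        assert _ref_interval(w, 1, 3) is None


def _pred(start, end, strand="+", chrom="chr1", structure=None, window=None):
    return EcsPrediction(
        chrom=chrom, genome_start=start, genome_end=end, strand=strand,
        stats=_stats(), mode="plain", score=-5.0, passed=True,
        high_confidence=True,
        structure=structure or SecondaryStructure(10),
        window=window,
    )


class TestTruncate:
    def _anchored_window(self, residues):
        from ecscan.msa_io import AlignedSequence

        seqs = [AlignedSequence("hg.chr1", residues, 100, "+", 10000)]
        return Alignment(seqs, reference_index=0)

    def test_flanks_trimmed(self):
        win = self._anchored_window("ACGUACGUACGUACG")  # 15 cols, no gaps
        st = SecondaryStructure.from_dot_bracket("...(((...)))...")
        p = _pred(100, 115, structure=st, window=win)
        t = truncate_to_structure(p)
        assert (t.genome_start, t.genome_end) == (103, 112)
        assert t.truncation_flag is None

    def test_fully_paired_ends_unchanged(self):
        win = self._anchored_window("GGGGACGUACGCCCC")
        st = SecondaryStructure.from_dot_bracket("((((.......))))")
        p = _pred(100, 115, structure=st, window=win)
        t = truncate_to_structure(p)
        assert (t.genome_start, t.genome_end) == (100, 115)

    def test_empty_structure_flagged(self):
        p = _pred(100, 115)
        t = truncate_to_structure(p)
        assert t.truncation_flag == "empty_structure"
        assert (t.genome_start, t.genome_end) == (100, 115)


class TestCluster:
    def test_three_overlapping_form_a_cluster(self):
        preds = [_pred(0, 100), _pred(50, 150), _pred(90, 200)]
        assert len(cluster_predictions(preds, 0, 3)) == 1

    def test_two_overlapping_below_min_size(self):
        preds = [_pred(0, 100), _pred(50, 150)]
        assert cluster_predictions(preds, 0, 3) == []

    def test_gap_within_reach_chains(self):
        preds = [_pred(0, 100), _pred(180, 250), _pred(300, 350)]
        assert len(cluster_predictions(preds, 100, 3)) == 1
        assert cluster_predictions(preds, 50, 3) == []

    def test_opposite_strands_not_chained(self):
        preds = [_pred(0, 100), _pred(80, 150, strand="-"), _pred(90, 160)]
        assert cluster_predictions(preds, 100, 3, same_strand=True) == []
        assert len(cluster_predictions(preds, 100, 3, same_strand=False)) == 1


class TestScanBlock:
    @pytest.fixture
    def block(self, rng):
        fam = ss.evolve_family(
            ss.FamilySpec(n_cols=220, n_tips=6, branch_scale=0.25,
                          compensation_prob=0.9, gap_rate=0.02),
            rng,
        )
        return ss.anchor_alignment(fam.alignment, chrom="chr10", start=5000)

    def test_predictions_and_threshold_consistency(self, block, rng):
        cfg = ScanConfig(n_nulls=25)
        preds, log = scan_block(block, cfg, rng, reference_id="sp0.chr10")
        assert preds and log.n_scored == len(preds)
        for p in preds:
            assert p.genome_start < p.genome_end
            if p.score is None:
                assert not p.passed
                continue
            cut = {"plain": cfg.z_cut_plain, "ribosum": cfg.z_cut_ribosum,
                   "highmpi": cfg.p_cut_highmpi}[p.mode]
            if p.mode == "highmpi":
                assert p.passed == (p.score >= cut)
            else:
                assert p.passed == (p.score <= cut)

    def test_both_strands_reported(self, block, rng):
        preds, _ = scan_block(block, ScanConfig(n_nulls=20), rng,
                              reference_id="sp0.chr10")
        assert {p.strand for p in preds} == {"+", "-"}

    def test_forward_only(self, block, rng):
        preds, _ = scan_block(
            block, ScanConfig(n_nulls=20, both_strands=False), rng,
            reference_id="sp0.chr10",
        )
        assert {p.strand for p in preds} == {"+"}

    def test_missing_reference_raises(self, block, rng):
        block.reference_index = None
        with pytest.raises(ValueError):
            scan_block(block, ScanConfig(n_nulls=20), rng)

    def test_deterministic_bed_output(self, block, rng):
        def run(seed):
            r = np.random.default_rng(seed)
            preds, _ = scan_block(block, ScanConfig(n_nulls=15), r,
                                  reference_id="sp0.chr10")
            buf = io.StringIO()
            write_bed([p for p in preds if p.passed], buf)
            return buf.getvalue()

        assert run(7) == run(7)
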
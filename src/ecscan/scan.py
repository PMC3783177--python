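"""Sliding-window genome screen for conserved RNA structure.

Blocks are cut into overlapping windows (200 nt / 100 nt step), QC-filtered
and dispatched to one of three scorers on their descriptors:

  highmpi  MPI > 85%: a transparent logistic classifier over the structure
           conservation index and per-row thermodynamic z-scores (stands in
           for an SVM-based classifier at high identity);
  plain    60% <= MPI <= 85% and GC < 70%: consensus Z-score against the
           tree-based simulation null;
  ribosum  otherwise, and as runtime fallback whenever the consensus is
           empty or the null distribution is degenerate (sd < 0.5).

Reporting thresholds are -2.7 (plain), -2.2 (ribosum) and 0.32 (highmpi);
high-confidence flags use z <= -4 / p >= 0.9.  Windows are scored on both
strands and mapped back to reference-genome coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .alnstats import AlnStats, compute_stats, qc_filter
from .consensus import DEFAULT_BETA, DEFAULT_DELTA
from .consensus import sci as sci_index
from .fold import DEFAULT_MODEL, SecondaryStructure, mfe_fold
from .msa_io import Alignment
from .nullmodels import (
    build_tree,
    dinucleotide_shuffle,
    simulate_alignment,
    zscore_multi,
)

__all__ = [
    "ScanConfig",
    "EcsPrediction",
    "ScanLog",
    "make_windows",
    "dispatch",
    "score_highmpi",
    "scan_block",
    "truncate_to_structure",
    "cluster_predictions",
]

# Logistic weights (w0, w_sci, w_zstab) for the high-identity scorer,
# calibrated once on synthetic structured/neutral high-identity families
# (scripts/calibrate_highmpi.py); see docs/methods.md.
HIGHMPI_WEIGHTS = (-2.055, 1.307, -1.096)


@dataclass(frozen=True)
class ScanConfig:
    """Screen parameters; defaults follow the published hybrid screen."""

    window: int = 200
    step: int = 100
    mpi_high: float = 85.0
    mpi_low: float = 60.0
    gc_cut: float = 70.0
    z_cut_plain: float = -2.7
    z_cut_ribosum: float = -2.2
    p_cut_highmpi: float = 0.32
    highconf_z: float = -4.0
    highconf_p: float = 0.9
    n_nulls: int = 100
    sd_floor: float = 0.5
    both_strands: bool = True
    min_seqs: int = 3
    n_row_shuffles: int = 16  # per-row nulls for the highmpi stability z
    beta: float = DEFAULT_BETA
    delta: float = DEFAULT_DELTA

    def __post_init__(self):
        if not 0 < self.step <= self.window:
            raise ValueError("require 0 < step <= window")


@dataclass
class EcsPrediction:
    """One scored window, genome-anchored on the reference assembly."""

    chrom: Optional[str]
    genome_start: Optional[int]
    genome_end: Optional[int]
    strand: str
    stats: AlnStats
    mode: str
    score: Optional[float]
    passed: bool
    high_confidence: bool
    structure: SecondaryStructure
    window: Optional[Alignment] = None  # QC'd forward-orientation window
    window_cols: Optional[tuple] = None  # column interval in the block
    degenerate: bool = False
    empty_native: bool = False
    truncation_flag: Optional[str] = None

    @property
    def anchored(self):
        return self.genome_start is not None


@dataclass
class ScanLog:
    """Run accounting: window tallies and per-window rejection reasons."""

    n_windows: int = 0
    n_scored: int = 0
    rejections: dict = field(default_factory=dict)
    mode_tally: dict = field(default_factory=dict)
    events: list = field(default_factory=list)

    def reject(self, window_id, reason):
        self.rejections[reason] = self.rejections.get(reason, 0) + 1
        self.events.append((window_id, f"rejected:{reason}"))

    def scored(self, mode):
        self.n_scored += 1
        self.mode_tally[mode] = self.mode_tally.get(mode, 0) + 1


def make_windows(aln, cfg=ScanConfig()):
    """Sliding column windows [k*step, k*step+window).

    Full windows are emitted while they fit; iteration stops once coverage
    reaches the end of the block; a final short window is emitted iff it
    spans at least window/2 columns (the first window is always emitted).
    """
    n = aln.n_cols
    out = []
    k = 0
    while True:
        start = k * cfg.step
        if start >= n:
            break
        stop = start + cfg.window
        if stop <= n:
            out.append((aln.slice_columns(start, stop), (start, stop)))
            if stop == n:
                break
        else:
            if k == 0 or (n - start) >= cfg.window / 2:
                out.append((aln.slice_columns(start, n), (start, n)))
            break
        k += 1
    return out


def dispatch(stats: AlnStats, cfg=ScanConfig()):
    """Scorer selection from window descriptors."""
    if stats.mpi > cfg.mpi_high:
        return "highmpi"
    if cfg.mpi_low <= stats.mpi <= cfg.mpi_high and stats.gc < cfg.gc_cut:
        return "plain"
    return "ribosum"


def _row_stability_z(seq, model, n_shuffles, rng):
    """z of the row's MFE against dinucleotide-shuffled versions."""
    seq = seq.replace("-", "")
    if len(seq) < 2 * (model.min_hairpin + 1):
        return 0.0
    _, e_native = mfe_fold(seq, model)
    nulls = np.empty(n_shuffles)
    for k in range(n_shuffles):
        _, nulls[k] = mfe_fold(dinucleotide_shuffle(seq, rng), model)
    sd = nulls.std()
    if sd < 1e-9:
        return 0.0
    return float((e_native - nulls.mean()) / sd)


def highmpi_features(aln, cfg, rng, model=DEFAULT_MODEL):
    """(SCI, mean per-row stability z) feature pair for the logistic
    high-identity scorer."""
    s = sci_index(aln, model, beta=cfg.beta, delta=cfg.delta)
    zs = [
        _row_stability_z(row.residues, model, cfg.n_row_shuffles, rng)
        for row in aln.sequences
    ]
    return float(s), float(np.mean(zs))


def score_highmpi(aln, cfg=ScanConfig(), rng=None, model=DEFAULT_MODEL):
    """Probability-like score in [0,1]: logistic over SCI and stability z.

    Monotone increasing in SCI and in -zstab; calibrated so structure-free
    high-identity windows fall well below the 0.32 reporting threshold.
    """
    if rng is None:
        raise ValueError("score_highmpi requires an rng")
    s, zstab = highmpi_features(aln, cfg, rng, model)
    w0, w1, w2 = HIGHMPI_WEIGHTS
    x = w0 + w1 * s + w2 * zstab
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# coordinate mapping

def _ref_interval(window, c0, c1):
    """Assembly-forward genome interval of reference columns [c0, c1).

    Returns (chrom, start, end) or None when the reference carries no
    residue in the interval."""
    ref = window.reference
    text = ref.residues
    a = sum(1 for ch in text[:c0] if ch != "-")
    m = sum(1 for ch in text[c0:c1] if ch != "-")
    if m == 0:
        return None
    s = ref.src_start + a
    e = s + m
    if ref.src_strand == "-":
        s, e = ref.src_size - e, ref.src_size - s
    return ref.chrom, s, e


def _flip_structure(structure):
    """Map a structure on the reverse complement back to forward columns."""
    n = structure.length
    return SecondaryStructure(
        n, [(n - 1 - j, n - 1 - i) for i, j in structure.pairs]
    )


def _score_window(window, stats, mode, cfg, rng, model):
    """Score one oriented window; returns (mode, score, passed, hc,
    structure, degenerate, empty_native)."""
    if mode == "highmpi":
        p = score_highmpi(window, cfg, rng, model)
        from .consensus import consensus_fold

        structure = consensus_fold(
            window, model, variant="plain", beta=cfg.beta, delta=cfg.delta
        ).structure
        return (
            "highmpi", p, p >= cfg.p_cut_highmpi, p >= cfg.highconf_p,
            structure, False, False,
        )
    tree = build_tree(window)
    res = zscore_multi(
        window,
        lambda a, r, tr=tree: simulate_alignment(a, tr, r),
        n_nulls=cfg.n_nulls, rng=rng, model=model,
        beta=cfg.beta, delta=cfg.delta, sd_floor=cfg.sd_floor,
    )
    chosen = res[mode]
    used_mode = mode
    if mode == "plain" and (chosen.degenerate or chosen.empty_native):
        # runtime escalation to the ribosum scorer
        used_mode = "ribosum"
        chosen = res["ribosum"]
    cut = cfg.z_cut_plain if used_mode == "plain" else cfg.z_cut_ribosum
    structure = chosen.native_fold.structure
    if chosen.z is None:
        return (used_mode, None, False, False, structure, chosen.degenerate,
                chosen.empty_native)
    return (
        used_mode, chosen.z, chosen.z <= cut, chosen.z <= cfg.highconf_z,
        structure, chosen.degenerate, chosen.empty_native,
    )


def scan_block(aln, cfg=ScanConfig(), rng=None, reference_id=None,
               model=DEFAULT_MODEL):
    """Scan one genome-anchored block; returns (predictions, log).

    Windows failing QC are counted in the log; when cfg.both_strands the
    reverse complement of each window is scored as well and reported on
    the opposite strand."""
    if rng is None:
        raise ValueError("scan_block requires an rng")
    log = ScanLog()
    if reference_id is None:
        if aln.reference_index is None:
            raise ValueError("block lacks a reference row")
        reference_id = aln.reference.id
    preds = []
    for win, (c0, c1) in make_windows(aln, cfg):
        log.n_windows += 1
        wid = f"cols{c0}-{c1}"
        qc = qc_filter(win, reference_id=reference_id, min_seqs=cfg.min_seqs)
        if not qc:
            log.reject(wid, qc.reason)
            continue
        window = qc.alignment
        if not window.reference.anchored:
            log.reject(wid, "unanchored_reference")
            continue
        interval = _ref_interval(window, 0, window.n_cols)
        if interval is None:
            log.reject(wid, "reference_all_gap")
            continue
        chrom, gstart, gend = interval
        stats = compute_stats(window)
        mode = dispatch(stats, cfg)
        orientations = [("+", window)]
        if cfg.both_strands:
            orientations.append(("-", window.reverse_complement()))
        for orient, oriented in orientations:
            used_mode, score, passed, hc, structure, degen, empty = \
                _score_window(oriented, stats, mode, cfg, rng, model)
            if orient == "-":
                structure = _flip_structure(structure)
            ref_strand = window.reference.src_strand or "+"
            strand = ref_strand if orient == "+" else ("-" if ref_strand == "+" else "+")
            preds.append(
                EcsPrediction(
                    chrom=chrom, genome_start=gstart, genome_end=gend,
                    strand=strand, stats=stats, mode=used_mode, score=score,
                    passed=passed, high_confidence=hc, structure=structure,
                    window=window, window_cols=(c0, c1),
                    degenerate=degen, empty_native=empty,
                )
            )
            log.scored(used_mode)
    return preds, log


def truncate_to_structure(pred: EcsPrediction):
    """Shrink the genome interval to the outermost paired columns of the
    consensus structure (mapped through the reference row)."""
    if not pred.structure.pairs:
        return replace(pred, truncation_flag="empty_structure")
    if pred.window is None or not pred.anchored:
        return replace(pred, truncation_flag="unanchored")
    cols = [c for p in pred.structure.pairs for c in p]
    cf, cl = min(cols), max(cols)
    interval = _ref_interval(pred.window, cf, cl + 1)
    if interval is None:
        return replace(pred, truncation_flag="reference_gap_only")
    chrom, s, e = interval
    return replace(
        pred, chrom=chrom, genome_start=s, genome_end=e, truncation_flag=None
    )


def cluster_predictions(preds, max_gap=0, min_size=3, same_strand=True):
    """Single-linkage chaining of predictions whose interval gap is at most
    `max_gap` nt (0 = touching/overlapping), per chromosome (and strand
    when `same_strand`).  Returns clusters with >= min_size members."""
    def key(p):
        return (p.chrom, p.strand) if same_strand else (p.chrom,)

    groups = {}
    for p in preds:
        if not p.anchored:
            raise ValueError("cannot cluster unanchored predictions")
        groups.setdefault(key(p), []).append(p)
    clusters = []
    for members in groups.values():
        members.sort(key=lambda p: (p.genome_start, p.genome_end))
        current = [members[0]]
        reach = members[0].genome_end
        for p in members[1:]:
            if p.genome_start - reach <= max_gap:
                current.append(p)
                reach = max(reach, p.genome_end)
            else:
                clusters.append(current)
                current = [p]
                reach = p.genome_end
        clusters.append(current)
    return [c for c in clusters if len(c) >= min_size]
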
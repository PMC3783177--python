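"""RFAM-style benchmarking of the three scoring modes.

Structured families are subsampled into fixed-size windows (mimicking a
sliding-window screen: random sequence subsets, random window placement,
truth structure projected onto the window), binned by mean pairwise
identity, scored by all three modes, and paired with dinucleotide-
controlled negatives to yield sensitivity / specificity / base-pair
recovery and inter-mode overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .alnstats import AlnStats, compute_stats, qc_filter
from .fold import DEFAULT_MODEL, SecondaryStructure, basepair_metrics
from .msa_io import StructuredFamily
from .nullmodels import build_tree, permute_alignment, simulate_alignment, zscore_multi
from .scan import ScanConfig, score_highmpi

__all__ = [
    "BenchmarkRecord",
    "BenchmarkSummary",
    "sample_subalignment",
    "bin_by_mpi",
    "evaluate",
    "paired_negative_specificity",
]

MODES = ("highmpi", "plain", "ribosum")


@dataclass
class BenchmarkRecord:
    """One sampled window with outcomes for every mode and null method."""

    family_id: str
    n_seqs: int
    window_len: int
    stats: AlnStats
    truth: SecondaryStructure
    outcomes: dict = field(default_factory=dict)  # mode -> (score, passed, hc)
    pair_sensitivity: dict = field(default_factory=dict)  # mode -> float
    negative_outcomes: dict = field(default_factory=dict)  # (null, mode) -> (score, passed, hc)
    mpi_bin: Optional[tuple] = None


@dataclass
class BenchmarkSummary:
    """Aggregated sensitivity/specificity per (mode, MPI bin) plus the
    high-confidence overlap matrix between modes."""

    table: pd.DataFrame
    overlap: pd.DataFrame
    n_records: int
    n_outside_bins: int

    def to_json(self):
        return {
            "n_records": self.n_records,
            "n_outside_bins": self.n_outside_bins,
            "table": self.table.to_dict(orient="records"),
            "overlap": self.overlap.to_dict(),
        }


def sample_subalignment(family: StructuredFamily, n_seqs, window_len, rng):
    """Random subset of rows and a random column window, with the truth
    structure projected onto the window (boundary-crossing pairs dropped).

    Returns (window Alignment, truth SecondaryStructure); raises
    ValueError when the family holds fewer than n_seqs sequences.
    """
    aln = family.alignment
    if aln.n_seqs < n_seqs:
        raise ValueError(
            f"family {family.id or '?'} has {aln.n_seqs} < {n_seqs} sequences"
        )
    rows = sorted(rng.choice(aln.n_seqs, size=n_seqs, replace=False))
    sub = aln.take_rows([int(r) for r in rows])
    # drop all-gap columns, keeping track of surviving truth columns
    A = sub.encoded()
    keep = ~(A == 5).all(axis=0)
    idx = np.flatnonzero(keep)
    colmap = np.full(aln.n_cols, -1, dtype=np.int64)
    colmap[idx] = np.arange(len(idx))
    seqs = [(s.id, "".join(s.residues[c] for c in idx)) for s in sub.sequences]
    n_eff = len(idx)
    start = 0 if n_eff <= window_len else int(rng.integers(n_eff - window_len + 1))
    stop = min(n_eff, start + window_len)
    window_seqs = [(sid, text[start:stop]) for sid, text in seqs]
    from .msa_io import Alignment

    window = Alignment.from_strings(window_seqs)
    pairs = []
    for i, j in family.ss_cons.pairs:
        ni, nj = colmap[i], colmap[j]
        if ni < 0 or nj < 0:
            continue
        if start <= ni < stop and start <= nj < stop:
            if (nj - start) - (ni - start) >= 4:
                pairs.append((ni - start, nj - start))
    truth = SecondaryStructure(stop - start, pairs)
    return window, truth


def bin_by_mpi(records, edges):
    """Assign each record to a half-open MPI bin [e_k, e_{k+1}); records
    outside all bins get mpi_bin None.  Returns (binned dict, outside)."""
    edges = list(edges)
    if edges != sorted(edges):
        raise ValueError("bin edges must be ascending")
    bins = {(lo, hi): [] for lo, hi in zip(edges, edges[1:])}
    outside = []
    for rec in records:
        for lo, hi in bins:
            if lo <= rec.stats.mpi < hi:
                rec.mpi_bin = (lo, hi)
                bins[(lo, hi)].append(rec)
                break
        else:
            rec.mpi_bin = None
            outside.append(rec)
    return bins, outside


def _score_all_modes(window, cfg, rng, model):
    """(outcomes, structures) for the three scorers on one window."""
    outcomes = {}
    structures = {}
    p = score_highmpi(window, cfg, rng, model)
    outcomes["highmpi"] = (p, p >= cfg.p_cut_highmpi, p >= cfg.highconf_p)
    tree = build_tree(window)
    res = zscore_multi(
        window, lambda a, r, tr=tree: simulate_alignment(a, tr, r),
        n_nulls=cfg.n_nulls, rng=rng, model=model, beta=cfg.beta,
        delta=cfg.delta, sd_floor=cfg.sd_floor,
    )
    for mode, cut in (("plain", cfg.z_cut_plain), ("ribosum", cfg.z_cut_ribosum)):
        z = res[mode].z
        if z is None:
            outcomes[mode] = (None, False, False)
        else:
            outcomes[mode] = (z, z <= cut, z <= cfg.highconf_z)
        structures[mode] = res[mode].native_fold.structure
    structures["highmpi"] = structures["plain"]
    return outcomes, structures


def evaluate(families, cfg=ScanConfig(n_nulls=50), rng=None,
             depths=(10, 20, 30), window_lens=(100, 200, 300),
             per_combo=5, null_methods=("simulate", "permute"),
             bin_edges=(40, 50, 60, 70, 80, 90, 100), model=DEFAULT_MODEL,
             min_seqs=3):
    """Run the benchmark: sample windows, score all modes, pair each native
    window with its dinucleotide-controlled negatives, and summarise.

    Sensitivity = TP/(TP+FN) over native windows; specificity =
    TN/(TN+FP) over negatives, per mode and null method.
    """
    if rng is None:
        raise ValueError("evaluate requires an rng")
    records = []
    for family in families:
        for n_seqs in depths:
            if family.alignment.n_seqs < n_seqs:
                continue
            for wlen in window_lens:
                for _ in range(per_combo):
                    window, truth = sample_subalignment(family, n_seqs, wlen, rng)
                    qc = qc_filter(window, min_seqs=min_seqs)
                    if not qc:
                        continue
                    win = qc.alignment
                    if win.n_cols != window.n_cols:
                        # row filtering created all-gap columns that QC then
                        # dropped: reproject the truth through the surviving
                        # rows' gap pattern
                        surviving = [
                            k for k, s in enumerate(window.sequences)
                            if s.id in set(win.ids)
                        ]
                        truth = _project_truth(window.take_rows(surviving), truth)
                    stats = compute_stats(win)
                    rec = BenchmarkRecord(
                        family.id, n_seqs, wlen, stats, truth
                    )
                    outcomes, structures = _score_all_modes(win, cfg, rng, model)
                    rec.outcomes = outcomes
                    for mode in MODES:
                        if outcomes[mode][1] and truth.pairs:
                            pred = structures[mode]
                            if pred.length == truth.length:
                                sens, _, _ = basepair_metrics(pred, truth)
                                rec.pair_sensitivity[mode] = sens
                    for nm in null_methods:
                        if nm == "permute":
                            neg = permute_alignment(win, rng)
                        else:
                            neg = simulate_alignment(win, tree=None, rng=rng)
                        neg_out, _ = _score_all_modes(neg, cfg, rng, model)
                        for mode in MODES:
                            rec.negative_outcomes[(nm, mode)] = neg_out[mode]
                    records.append(rec)
    return summarize(records, bin_edges, null_methods)


def _project_truth(window, truth):
    A = window.encoded()
    keep = ~(A == 5).all(axis=0)
    idx = np.flatnonzero(keep)
    colmap = np.full(window.n_cols, -1, dtype=np.int64)
    colmap[idx] = np.arange(len(idx))
    pairs = []
    for i, j in truth.pairs:
        ni, nj = colmap[i], colmap[j]
        if ni >= 0 and nj >= 0 and nj - ni >= 4:
            pairs.append((int(ni), int(nj)))
    return SecondaryStructure(len(idx), pairs)


def paired_negative_specificity(n_windows, rng, null_method="simulate",
                                window_lens=(100, 200), n_tips=20,
                                branch_scale=0.3, compensation_prob=0.9,
                                gap_rate=0.05, n_nulls=50, z_cut=-4.0,
                                modes=("plain", "ribosum"),
                                model=DEFAULT_MODEL):
    """Specificity protocol on paired dinucleotide-controlled negatives.

    For each synthetic structured subalignment one negative is produced
    (`null_method` = "simulate": tree-based simulation preserving
    composition and gap pattern; "permute": within-window conservation-
    class column permutation with dinucleotide repair) and Z-scored with
    the listed consensus variants against the tree-based null at the
    high-confidence cutoff.

    Returns (n_scored, n_passing): scorings performed and negatives called
    positive (z <= z_cut).  False-positive rate = n_passing / n_scored.
    """
    from . import synthsim as ss

    n_scored = 0
    n_passing = 0
    for k in range(n_windows):
        wlen = window_lens[k % len(window_lens)]
        spec = ss.FamilySpec(
            n_cols=wlen, n_tips=n_tips, branch_scale=branch_scale,
            compensation_prob=compensation_prob, gap_rate=gap_rate,
        )
        fam = ss.evolve_family(spec, rng)
        qc = qc_filter(fam.alignment)
        if not qc:
            continue
        native = qc.alignment
        if null_method == "simulate":
            tree = build_tree(native)
            negative = simulate_alignment(native, tree, rng)
        elif null_method == "permute":
            negative = permute_alignment(native, rng)
        else:
            raise ValueError(f"unknown null method {null_method!r}")
        neg_tree = build_tree(negative)
        res = zscore_multi(
            negative,
            lambda a, r, tr=neg_tree: simulate_alignment(a, tr, r),
            n_nulls=n_nulls, rng=rng, variants=modes, model=model,
        )
        for mode in modes:
            z = res[mode].z
            n_scored += 1
            if z is not None and z <= z_cut:
                n_passing += 1
    return n_scored, n_passing


def confusion_rates(tp, fn, tn, fp):
    """Sensitivity and specificity (percent) from confusion counts."""
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def summarize(records, bin_edges, null_methods):
    """Aggregate records into the benchmark summary tables."""
    bins, outside = bin_by_mpi(records, bin_edges)
    rows = []
    for (lo, hi), recs in bins.items():
        for mode in MODES:
            if not recs:
                continue
            tp = sum(1 for r in recs if r.outcomes[mode][1])
            fn = len(recs) - tp
            hc = sum(1 for r in recs if r.outcomes[mode][2])
            row = {
                "bin_lo": lo, "bin_hi": hi, "mode": mode, "n": len(recs),
                "sensitivity": confusion_rates(tp, fn, 0, 0)[0],
                "sensitivity_hc": 100.0 * hc / len(recs),
                "mean_pair_sensitivity": float(
                    np.mean([r.pair_sensitivity[mode] for r in recs
                             if mode in r.pair_sensitivity])
                ) if any(mode in r.pair_sensitivity for r in recs) else float("nan"),
            }
            for nm in null_methods:
                negs = [r.negative_outcomes.get((nm, mode)) for r in recs]
                negs = [o for o in negs if o is not None]
                fp = sum(1 for o in negs if o[1])
                tn = len(negs) - fp
                row[f"specificity_{nm}"] = confusion_rates(0, 0, tn, fp)[1]
                fp_hc = sum(1 for o in negs if o[2])
                row[f"specificity_hc_{nm}"] = (
                    100.0 * (len(negs) - fp_hc) / len(negs) if negs else float("nan")
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    # high-confidence overlap between modes: P(col passed | row passed)
    overlap = pd.DataFrame(index=MODES, columns=MODES, dtype=float)
    for m1 in MODES:
        base = [r for r in records if r.outcomes[m1][2]]
        for m2 in MODES:
            overlap.loc[m1, m2] = (
                sum(1 for r in base if r.outcomes[m2][2]) / len(base)
                if base else float("nan")
            )
    return BenchmarkSummary(table, overlap, len(records), len(outside))
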
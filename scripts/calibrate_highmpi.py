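"""One-off calibration of the high-identity logistic scorer.

Generates high-identity synthetic structured families (positives) and
matched neutral alignments (negatives), computes the (SCI, stability-z)
feature pair for each, fits a logistic regression, and prints the weights
that are frozen into ecscan.scan.HIGHMPI_WEIGHTS.

Usage: python scripts/calibrate_highmpi.py [--seed N] [--n N]
"""

import argparse

import numpy as np

from ecscan import synthsim as ss
from ecscan.alnstats import compute_stats, qc_filter
from ecscan.scan import ScanConfig, highmpi_features


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20130711)
    ap.add_argument("--n", type=int, default=60, help="families per class")
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    cfg = ScanConfig()
    X, y = [], []
    kept = {"pos": 0, "neg": 0}
    for label, structured in (("pos", True), ("neg", False)):
        for _ in range(args.n):
            spec = ss.FamilySpec(
                n_cols=int(rng.choice([120, 200])),
                n_tips=10,
                branch_scale=float(rng.uniform(0.02, 0.10)),
                gc_target=float(rng.uniform(40, 60)),
                compensation_prob=0.95,
                gap_rate=0.02,
            )
            if structured:
                aln = ss.evolve_family(spec, rng).alignment
            else:
                aln = ss.neutral_alignment(spec, rng)
            qc = qc_filter(aln)
            if not qc:
                continue
            stats = compute_stats(qc.alignment)
            if stats.mpi <= 80:  # calibrate in the high-identity regime
                continue
            X.append(highmpi_features(qc.alignment, cfg, rng))
            y.append(1 if structured else 0)
            kept[label] += 1
    X = np.asarray(X)
    y = np.asarray(y)
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0).fit(X, y)
    w0 = float(clf.intercept_[0])
    w1, w2 = (float(v) for v in clf.coef_[0])
    acc = clf.score(X, y)
    print(f"kept: {kept}")
    print(f"feature means pos: {X[y == 1].mean(axis=0)}")
    print(f"feature means neg: {X[y == 0].mean(axis=0)}")
    print(f"training accuracy: {acc:.3f}")
    print(f"HIGHMPI_WEIGHTS = ({w0:.3f}, {w1:.3f}, {w2:.3f})")
    null_score = 1 / (1 + np.exp(-w0))
    print(f"score at (sci=0, zstab=0): {null_score:.3f}")


if __name__ == "__main__":
    main()
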
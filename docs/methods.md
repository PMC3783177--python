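# Methods

This note documents the models, the numerical choices, and the design
decisions behind `ecscan`, in the order the pipeline applies them.

## Alignment model and QC

Alignments are stacks of equal-length gapped rows over {A,C,G,U,N,-}; DNA
is converted on read, IUPAC ambiguity codes other than N are mapped to N,
and genome anchoring follows MAF semantics (0-based starts in source-strand
coordinates, `srcSize` for strand flips). Duplicate rows per species in MAF
blocks are resolved by keeping the first-listed row, a deterministic and
order-stable choice.

Pre-scoring QC collapses identical rows (preferring the reference copy),
removes rows that are ≥ 50% gaps+N, drops all-gap columns, and rejects
windows with fewer than 3 surviving rows or a lost reference. The filter is
idempotent.

Window descriptors: MPI is the average over unordered row pairs of
(identical non-gap, non-N columns) / (shorter ungapped length) — the
shortest-sequence convention; its spread uses the population standard
deviation. Normalised Shannon entropy averages per-column entropies of
non-gap residue frequencies over log 4, with columns carrying fewer than
two residues contributing 0. GC% excludes N; gap% is computed after QC,
over the filtered matrix.

## Folding engine

The energy model is deliberately transparent rather than a full
nearest-neighbour model: per-pair energies GC/CG −3, AU/UA −2, GU/UG −1
(kcal/mol-like), a constant −1 stacking increment for directly nested
pairs, minimum hairpin loop 3, kT = 0.616 for the partition function. The
stacking increment is a single scalar (no per-stack identity table):
nothing downstream distinguishes stack identities, and every statistic the
pipeline reports (Z-scores, SCI, ΔP, energy ratios) is *relative* to the
model, so the simplification trades absolute-energy realism for
auditability. Lonely pairs are allowed; pseudoknots are excluded
everywhere.

MFE folding and the McCaskill partition function use the same unambiguous
decomposition (C = paired, Ex = unpaired-at-(i,j), E = all), with an
inside–outside pass in log space for exact posterior pair probabilities —
long windows therefore never overflow, and `log_z` is the authoritative
normaliser. Constraints implement forced pairs (position may pair only
with its partner, crossing pairs forbidden, forced positions may not be
unpaired) and forced-unpaired masks; forcing pairs can only raise the
optimum. Traceback ties are resolved toward pairing, outermost pair first,
then the smallest left partner — outputs are byte-stable. The engine is
validated against exhaustive enumeration of all nested structures for
n ≤ 14 (energies, Z, and every p(i,j) to 1e-9 relative tolerance).

## Consensus folding and covariation scoring

Column pairs are scored as

    score(i,j) = mean_energy(i,j) + covariance(i,j) + delta * n_incompatible

where `mean_energy` averages the pair energy over all rows (0 for rows
that are gapped or cannot pair), and `n_incompatible` counts rows with two
residues that cannot form a canonical pair (N included). Pairs
incompatible in more than half of the rows are forbidden — the consensus
majority rule. Two covariance variants exist:

- **plain**: −beta × (number of distinct canonical pair types − 1), a
  direct count of covariation evidence;
- **ribosum**: −beta × mean substitution score over *cross-type* row pairs
  (rows carrying different canonical pair types), read from a
  RIBOSUM-style log-odds table. Restricting to cross-type pairs makes the
  term a covariation score: with the full mean the conserved-pair diagonal
  dominates and swamps the Z statistic with conservation signal that the
  null shares. The shipped 6×6 table
  (`data/ribosum_synthetic.tsv`) is constructed for this package —
  patterned on the ribosomal-RNA-derived log-odds family (identity >
  compensatory > single wobble shift) but not copied from any published
  matrix, which this environment cannot redistribute.

Stacking transfers to column space as stack_bonus × (fraction of rows
pairing canonically at both (i,j) and (i+1,j−1)), so for an alignment of
identical rows the consensus DP reduces exactly to the single-sequence
fold and the structure conservation index (consensus score over mean
per-row MFE) is exactly 1.

**Weights.** beta = 0.4 and delta = 0.5 ship as defaults, calibrated once
on synthetic family fixtures: scanning beta downward on a 0.1 grid,
detection of compensatory families at the high-confidence cutoff stays
saturated (100% across compensation 0.7–0.9 and divergence 0.3–0.55)
while the false-call rate on permuted structured negatives — whose
covarying column pairs survive permutation and can be re-paired by the DP
— falls to the few-percent range consistent with published
permutation-null specificities. Both weights are config-exposed.

## Null models and Z-scores

- `dinucleotide_shuffle` implements the Euler-path (Altschul–Erickson)
  method: a uniformly sampled arborescence of last-edges plus random edge
  orderings yields a sequence with exactly the native dinucleotide
  multiset and endpoints.
- `permute_alignment` permutes whole columns within conservation classes
  keyed by the column's gap/N pattern and monomorphic status, then runs a
  greedy within-class column-swap pass that reduces the summed per-row
  dinucleotide-count deviation from the native window. Column permutation
  preserves per-column compositions, per-row gap counts and MPI exactly.
- `simulate_alignment` evolves a fresh alignment along a neighbor-joining
  tree (JC distances with pairwise deletion, saturated distances capped at
  5 with a flag, midpoint rooting, negative branches clamped) under an HKY
  model whose stationary frequencies equal the native base composition and
  whose transition/transversion ratio is estimated by counting; the root
  is drawn per column from the native column composition, and the native
  gap/N pattern is copied verbatim. Site-specific neighbour-interaction
  processes are *not* modelled; the optional dinucleotide-repair pass is
  the only dinucleotide control beyond composition matching.

Z-scores standardise the native consensus score against the null-score
distribution (population SD). Backgrounds with SD < 0.5 are flagged
degenerate — they produce extreme, meaningless Z values — and trigger the
dispatch fallback. Scoring neutral windows against their own permutation
nulls yields an approximately standard-normal empirical z (|mean| < 0.15,
SD ≈ 0.9 at 50 nulls, verified on 200 windows). The tree-based null is
*conservative*: scoring neutral windows against simulation nulls shifts
the empirical mean near −0.9 with SD ≈ 0.6, because the simulation
homogenises per-column substitution rates; the stringent −4 cutoff keeps
the false-positive rate on genuinely unstructured input negligible
despite the shift.

## The hybrid screen

Windows of 200 columns advance in steps of 100; full windows are emitted
while they fit, iteration stops once the block end is covered, and a final
short window is emitted iff it spans at least half a window (the first
window is always emitted — this reproduces the 500→4-window and
201→2-window arithmetic exactly). Dispatch: MPI > 85% → the high-identity
scorer; 60–85% MPI and GC < 70% → plain Z-score; otherwise the RIBOSUM
variant, which also takes over at runtime when the consensus is empty or
the background degenerate. Reporting thresholds −2.7 (plain), −2.2
(ribosum) and 0.32 (high-identity), with high-confidence flags at Z ≤ −4
and p ≥ 0.9. Both strands are scored (the reverse complement re-runs the
full scorer) and reported separately.

The high-identity scorer is a transparent logistic classifier,
p = σ(w0 + w1·SCI + w2·zstab), where zstab is the mean per-row Z of MFE
energy against 16 dinucleotide shuffles. It stands in for SVM-based
classifiers used at high identity, where covariation statistics lose
power. Weights (−2.055, 1.307, −1.096) were fitted once by logistic
regression on high-identity synthetic structured vs neutral families
(`scripts/calibrate_highmpi.py`); structure-free input (SCI = 0,
zstab = 0) scores 0.11, well under the 0.32 reporting threshold. At high
identity the two features separate only moderately (training accuracy
0.77) — an honest reflection of how little evolutionary signal such
windows carry.

Genome mapping skips reference gaps; minus-strand anchors are flipped to
assembly-forward coordinates for BED output. Truncation shrinks intervals
to the outermost paired columns mapped through the reference row;
clustering chains intervals per chromosome (and strand) whose gap is at
most a threshold, keeping clusters of a minimum size.

## Structural congruence

The consensus structure is projected onto the de-gapped reference (pairs
losing a partner are dropped, as are pairs whose loop shrinks below the
minimum hairpin); consensus pairs the reference cannot form canonically
are excluded from the ratios, and a reference unable to form at least half
of the projected pairs is immediately non-congruent. ΔP is the capped
ratio of structure scores (projected consensus vs reference MFE) under the
unconstrained pair-probability matrix; the energy ratio divides the
constrained by the unconstrained MFE (0 for an unfoldable reference).
Congruent ⇔ both ratios > 0.75 and either > 0.9.

The ΔP aggregation is configurable (geometric mean — the
`structure_score` default — product, or arithmetic mean). Under this
package's energy model the Boltzmann ensemble is sharply peaked, so the
geometric mean collapses to ~0 whenever a single consensus pair falls
outside the reference MFE set, and the arithmetic mean (the structure's
average pair-probability mass) is the form under which the two-threshold
rule has operating room; the separation analyses use it. Even so the
filter is conservative here: its value is checked as a separation property
(structured families dominate matched neutral alignments in both ratios
and in congruence calls), not as an absolute retention rate.

## Synthetic families

`FamilySpec` defaults define the study conditions: 200 columns, pair
fraction 0.3, 20 tips, root-to-tip height 0.3 substitutions/site (random
ultrametric topology, so pairwise divergence ≤ 0.6 — mid-60s% MPI, the
regime where covariation statistics matter), GC 50%, compensation
probability 0.9, clade-level gap columns at rate 0.05. Roots honour the
structure (paired sites drawn canonical, GC-weighted); evolution is a
Poisson jump process under HKY (κ = 4), and a substitution at a paired
site co-substitutes the partner to a canonical complement with the
compensation probability — modelling the selected end state, not the
mutational path. Gaps are whole-column events under a random clade,
mimicking indel blocks. Neutral alignments reuse the same tree and
composition machinery without pairing constraints, giving negatives with
matched GC and depth.

Family structures come from a helix-based sampler (stems of mean length
~5 placed into available segments), because real structural-RNA families
are helical and scattered single pairs carry no stacking signal;
`random_structure` retains the uniform-over-nested-structures contract
(counting DP + recursive sampling in float64) for property testing.

What the generator does **not** emulate: realistic indel evolution,
rate-heterogeneity across sites beyond the structure itself, alignment
error (no realignment step is simulated), protein-coding overlap, and
pseudoknots. Passing tests therefore demonstrate that the statistics
detect clean covariation signals at realistic divergence and depth — not
that the thresholds transfer unchanged to heuristic genome alignments.

## Problem sizes and runtime choices

The test suite and the acceptance script are sized for a single CPU: the
folding oracle runs 500 sequences of length ≤ 14 against full enumeration;
null-model invariants use 1000 shuffles, 100 permuted windows and 200
simulated replicates; Z-calibration scores 200 neutral 120-column windows
at 50 nulls; the specificity protocols score 300 negatives per
randomisation strategy (60 in the test suite) at 50 nulls, pooling the
plain and RIBOSUM scorers. The O(n³) dynamic programs are numba-compiled;
column-pair statistics use transposed access and bitmask popcounts for the
stacking fractions.

## Known limitations

- The energy model is not the Turner nearest-neighbour model; absolute
  energies and ensemble shapes differ from thermodynamic folding engines,
  and only ratio/Z statistics are comparable.
- The tree-based null inherits no per-column rate variation, making its
  Z-scores conservative (see above).
- The high-identity classifier is weakly informative by construction of
  the regime; its thresholds are package defaults, not claims of
  equivalence to SVM-based tools.
- Reported thresholds (−2.7 / −2.2 / 0.32) are carried as defaults from
  the published screen; on other data they should be recalibrated against
  the desired false-discovery rate.
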
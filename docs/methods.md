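# Methods

## Model and procedure

`sucbigram` predicts whether a lysine residue is succinylated from two
per-residue profiles of its protein: an L×20 matrix of amino-acid
substitution probabilities (the percentage block of a PSI-BLAST ASCII
PSSM, divided by 100) and an L×3 matrix of secondary-structure
probabilities over helix, strand and coil. The method assumes these
profiles are probability-like (entries in [0, 1], secondary-structure
rows summing to ~1) and aligned row-for-row with the sequence; the
loader enforces both and rejects PSSMs whose residue column disagrees
with the FASTA sequence.

The pipeline is:

1. **Windowing.** For each annotated lysine, take the profile rows of
   the surrounding segment of `flank` residues on each side
   (default 15, i.e. 31 rows). Out-of-range indices are reflected about
   the terminal residue without duplicating it (j < 0 → −j,
   j ≥ L → 2(L−1) − j, applied ping-pong for very short proteins).
   Mirroring acts on profile rows, not on re-looked-up letters, because
   every downstream quantity is profile-derived.
2. **Bigram features.** Each windowed profile is condensed into the
   matrix of summed products of consecutive row pairs
   (`B[p,q] = Σ_k M[k,p]·M[k+1,q]`, 30 pairs for a 31-row window).
   Row-major flattening of the 20×20 and 3×3 blocks gives 409 features
   per site. The dimension does not depend on the flank; total bigram
   mass equals Σ rowsum(k)·rowsum(k+1), hence exactly W−1 for a
   row-stochastic window — a conservation law the tests assert.
3. **Balancing.** Negatives whose k nearest neighbors (Euclidean on the
   raw 409-dim vectors, self excluded) include a positive are removed,
   simultaneously within a round; k starts at ⌊N⁻/N⁺⌋ and escalates in
   integer multiples, with distances recomputed on the surviving set
   each round, until negatives ≤ positives or a round cap (default 20)
   is hit, in which case the result is flagged unbalanced. Ties in
   distance resolve to the lower original row index, making the
   procedure deterministic. Features are not standardized before the
   distance computation.
4. **Classification.** AdaBoost.M1 by reweighting over decision stumps.
   The stump search considers every feature, every midpoint between
   consecutive distinct sorted values plus −∞ (a constant classifier),
   and both side polarities, breaking ties toward the lower feature
   index, then the lower threshold, then the (left=0, right=1)
   polarity. A round with weighted error ε ≥ ½ is discarded and
   training stops; ε = 0 stops after keeping the round with a large
   finite weight. Otherwise α = ln((1−ε)/ε) and misclassified weights
   are multiplied by (1−ε)/ε before renormalization. The ensemble score
   is the α-weighted vote rescaled to [−1, 1]; label 1 iff score > 0.
5. **Evaluation.** Sensitivity, specificity, accuracy and MCC are
   computed from the class totals and per-class error counts; the MCC
   expression used is algebraically identical to the textbook
   correlation form (property-tested to 1e−12). AUC is the Mann–Whitney
   rank statistic with ties counted one half. Cross-validation is
   stratified n-fold with a seeded shuffle; per-fold metrics are
   averaged, while AUC is computed on the pooled out-of-fold scores
   (per-fold averaging is an option). Balancing is applied to the full
   dataset before fold splitting, matching the order in which the
   procedure is normally described; this leaks neighborhood information
   across folds and therefore biases cross-validated metrics
   optimistically — a caveat inherited by any evaluation that balances
   first.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `flank` | 15 | residues on each side of the lysine; window = 2·flank+1 rows |
| `base_k` | auto = ⌊N⁻/N⁺⌋, min 1 | first-round neighbor count for balancing |
| `max_rounds` (balance) | 20 | escalation cap; real data balanced by round 6 (k = 60) |
| `n_rounds` (boost) | 1000 | boosting iterations; early stop on ε ≥ ½ or ε = 0 |
| `n_folds` | 10 | cross-validation folds (6, 8 and 10 are customary) |
| `seed` | — | drives fold shuffling and all synthetic generation |

## Synthetic data

The generator emulates the four input families without PSI-BLAST or
SPIDER2. Sequences are uniform over the 20 amino acids with lysines
placed at roughly proteome frequency (rate 0.06) but spaced more than
2·flank residues apart; profile rows are Dirichlet draws around the
uniform simplex point with concentration 8 (moderately peaked rows,
quantized to the file formats' printed resolution so disk round-trips
are exact). A positive site's window rows are redrawn with the mean
shifted toward a fixed amino-acid pair — alternating by residue parity,
so consecutive rows form one strong bigram transition — and toward
helix, with the shift proportional to the effect size δ. At δ = 0 the
classes are identically distributed; AUC rises monotonically with δ.

The lysine spacing exists because the planted signal is defined to be
window-local: with independently placed lysines, negative windows
overlap positive planted regions, which contaminates the negative class
and confounds δ with label noise. Spacing guarantees that no window
reaches into another site's planted region, making δ cleanly
interpretable.

What the generator does **not** emulate: realistic PSSM column
correlations and alignment statistics, secondary-structure segment
length distributions, sequence-profile consistency (profile rows are
independent of the letters), homology structure between proteins, and
the species composition of curated succinylation data. Passing tests
therefore demonstrate that the implementation recovers plantable
profile signal under controlled conditions — not that the predictor
attains any particular accuracy on real proteomes, which additionally
depends on PSI-BLAST and SPIDER2 output quality.

At δ = 1 the planted classes are fully separable in bigram space, so
the k-NN balancer finds no negative with a positive neighbor (removal
count 0, flagged unbalanced) — the geometry real data does not have; at
δ = 0 the balancer removes negatives in escalating rounds exactly as on
real, overlapping classes.

## Numerical choices

* Stump weighted errors compare with an absolute guard of 1e−12; errors
  below it count as exact separation.
* The −∞ threshold represents the constant stump; the all-left split is
  dropped as a duplicate of the constant stump with swapped polarity.
* MCC with a vanishing denominator (an empty predicted class) is
  reported as 0 with an explicit `mcc_undefined` flag.
* Secondary-structure rows are accepted when summing to 1 ± 0.02
  (readers) since upstream predictors round to three decimals; row sums
  outside [0.9, 1.1] in a file are rejected as malformed.
* PSSM "normalization" is the percentage block ÷ 100 with no per-row
  renormalization.
* Repeated negative-set resampling holds the cross-validation fold seed
  fixed so that only the negative draw varies between repeats.

## Problem sizes

The default test and reproduction runs use scaled-down sizes chosen for
desk-scale iteration: planted-signal recovery at 400 sites and 100
boosting rounds, null calibration at 200 sites × 20 seeds with 30
rounds, and an end-to-end run at ~1,100 sites under 10.3:1 imbalance.
Paper-scale settings (tens of thousands of sites, 1,000 rounds) are
plain parameter changes (`--rounds 1000`, larger `--n-proteins`).

## Known limitations

* Discrete AdaBoost over axis-aligned stumps cannot learn symmetric
  XOR-type interactions: every stump has weighted error exactly ½ there,
  so training stops with an empty ensemble (tested explicitly).
* Balancing before fold splitting optimistically biases CV metrics (see
  above); re-balancing inside each training fold would remove the leak
  at the cost of fold-dependent training sets.
* The k-NN balancer materializes chunked distance blocks against the
  full remaining set; fine at 10⁴ points, not intended for 10⁶.
* `X` residues are accepted and their profile rows used as-is; the
  bigram transform needs no alphabet lookup, so no masking is applied.
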
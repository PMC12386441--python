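# Methods

This note documents the model implemented by `epibesl`, its parameter
defaults, the numerical decisions taken where the design was genuinely
open, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Data model

An EP pair is one enhancer–promoter instance: two DNA sequences over
{A,C,G,T,N}, optional 0-based half-open genomic intervals (BED
convention), a binary interaction label, and a cell-line tag.  Element
sequences are standardized to fixed windows — 3000 nt (enhancer) and
2000 nt (promoter) by default, configurable — by center-cropping or
symmetric N-padding.  Signal tracks expose one value per base; missing or
unmapped bases read as 0, the usual convention for coverage tracks, and
both BigWig files and in-memory array tracks satisfy the same query
interface.  Tracks are treated as strand-agnostic.  Any k-mer window
containing N contributes nothing to any count-based encoder.

## Sequence encoders

**KNF.**  For each K in the configured list (default 1,2,3,4) the encoder
builds an (L−K+1) × 4^K block in which row *i* holds, at the
lexicographic index of the K-mer starting at *i*, that K-mer's
whole-sequence frequency.  Blocks are concatenated after right-padding
with zero rows to a common height, giving 340 columns for the default K
list.  A configuration switch substitutes pure one-hot indicators for the
frequency weights; a plain one-hot base encoder is also available as an
optional fifth channel but is disabled by default (it is dominated by the
other encodings).

**TPCP.**  Trinucleotide frequencies over N-free windows are multiplied
by 11 per-trinucleotide physicochemical property values, min–max
normalized to [0,1], giving a 704-long vector (trinucleotide-major
layout).  The packaged default table
(`data/trinucleotide_properties_synthetic.csv`) is a deterministic
synthetic surrogate built from composition and nearest-neighbour
thermodynamic descriptors (GC/purine/keto content, stacking free energy
and melting enthalpy sums, pyrimidine–purine step fraction, A/T run
length, CpG steps, base diversity).  It is a stand-in with the correct
shape and scaling, not a published property set; the table is an explicit
input so users can substitute their own 64 × P CSV.

**PCPS.**  The conservation of position *i* is
C_k(i) = Σ_n (f_i(n) − f_e)² / f_e over all 4^k length-k fragments n,
with k = 6 and background f_e = 1/4^k, computed over a training
population of equal-length sequences; C is zero exactly when fragment
usage is uniform and grows with positional constraint.  The M = 10 most
conserved positions (ties to the smaller index) define a pseudocount
position score matrix with entries m_x = (n_x + α)/(N + 4^k·α) and
log-odds PSF = ln(m/f₀) against f₀ = 1/200.  We take α = f₀, which makes
every column an exact probability vector and zeroes the PSF at the
background; this pseudocount form is our interpretation of a
position-score construction whose printed definition is ambiguous, and it
is the standard PSM-with-pseudocounts estimator.  The per-sequence PCPS
feature is the 2M-vector of the M conservation values followed by the M
PSF lookups of the sequence's own fragments at the selected positions
(fragments containing N score 0).

The conservation/score model is fitted per element type (enhancers and
promoters separately) on the **positive** training pairs only: conserved
regulatory sites characterize the interacting class, and fitting on the
20-fold larger negative background would dilute the profile toward
uniformity.  Positions are indexed from the configured element 5′ end.

**DNA2vec.**  Sequences tokenize into overlapping k-mer words (k = 5,
stride 1, L−k+1 words).  A skip-gram model with negative sampling (window
5, 5 negatives, unigram^0.75 noise distribution, single worker, fixed
seed) learns an 8-dimensional vector per word; the trainer is a compact
vectorized numpy implementation and is deterministic given the seed.
Out-of-vocabulary words (including any containing N) map to the zero
vector.  The embedded (L−k+1) × 8 matrix is adaptively average-pooled to
1000 × 8: bucket *i* averages rows ⌊i·n/P⌋ … ⌈(i+1)·n/P⌉−1, repeating
rows when n < P.  When P divides n this pooling preserves the global mean
exactly.

**Fusion.**  Positional encoders (KNF, DNA2vec, optional one-hot) are
pooled to a common row count (default 1000) and concatenated along the
feature axis into the convolutional input; per-sequence encoders (TPCP,
PCPS) are vectors, not position series, and are concatenated into a dense
feature vector that bypasses the convolutional path and joins the fusion
layer directly.  A channel manifest records which columns belong to which
encoder, identically for enhancer and promoter.  All encoder state is
fitted on fold-training data only, and encoding never mutates fitted
state (tested by hashing).

## Genomic features

Each pair contributes a fixed-order 4 × 2 matrix — rows (RAD21, ATAC-seq,
H3K27ac, distance) — holding the mean per-base signal over the enhancer
and promoter windows for the three assays, and
(log₁₀(1 + |midpoint separation|), 0) for the distance row.  Pairs on
different chromosomes are rejected (benchmark pairs are cis).  Rows for
absent tracks or fully uncovered intervals are masked and excluded from
attention.  Min–max normalization constants are computed on training
folds only; test values are clipped to [0,1], and constant features
normalize to 0.  The row order is part of the interface: per-row
attention weights remain interpretable.

## The network

**Sequence branch (MCNet).**  conv(k=9, 64 filters) → ReLU → average
pool (width 4) → dropout; three structurally identical parallel
sub-blocks, each conv(k=5, 32) → BN → ReLU → dropout → conv(k=3, 64) → BN
→ ReLU; channel concatenation (192 channels) → conv(k=1) → dropout → BN →
ReLU → dropout → global average pooling.  Enhancer and promoter share one
tower (a parameter-economy choice, configurable to separate towers) and
run as a single stacked batch.  The double dropout after the merge is
retained as stated even though it is partially redundant.

**Genomic branch (MANet).**  The normalized 4 × 2 matrix is linearly
projected to d = 32; each of H = 4 heads computes u = tanh(xW_h + b_h),
scores s_i = u_i·w_h, masks invalid rows, and normalizes with
a_i = exp(s_i)/(Σ_j exp(s_j) + ε), ε = 1e−8.  The per-head weights are
non-negative, masked rows get exactly 0, and the total equals
S/(S+ε) < 1, approaching 1 as ε → 0.  Head outputs (weighted sums of the
projected rows) are concatenated, batch-normalized, dropped out, and
mapped to the 128-wide genomic dense vector.  Attention operates over the
4 feature rows — the object of interest is the dependency structure among
genomic features, not positions.

**Fusion.**  [enhancer vector, promoter vector, genomic vector, dense
per-sequence vector] → fully connected → ReLU → dropout → fully connected
→ 2-way softmax; training minimizes mean categorical cross-entropy with
probabilities clipped at 1e−7.  A sequence-only mode replaces the genomic
vector with zeros.

**Optimization defaults.**  Adam, learning rate 1e−3, batch size 64,
dropout 0.2 (convolutional) / 0.5 (dense), batch-norm momentum 0.9.
Batch normalization keeps zero-debiased (bias-corrected) EMA running
statistics: sub-models here train for only tens of optimizer steps, and
uncorrected 0/1-initialized EMAs lag so far behind the true activation
statistics that inference-mode losses saturate and early stopping selects
collapsed epochs.  The correction divides the EMA by (1 − momentum^t),
making inference statistics unbiased from the first update.

## BESL

(i) ratio = round(n_neg/n_pos) (round-half-even, floored at 1);
(ii) negatives are partitioned into ratio disjoint subsets by seeded
shuffle + round robin (sizes differ by ≤ 1, union exhaustive);
(iii) each subset plus all positives forms one 1:1 training set, split
80/20 (stratified, seeded) into training and early-stopping validation;
training stops after 5 consecutive epochs without strict validation-loss
improvement and the best-epoch weights are restored; (iv) the ensemble
prediction is the unweighted mean of the sub-model probabilities;
(v) stratified 5-fold cross-validation wraps the whole procedure — each
outer test fold is scored by an ensemble fitted on the remaining folds,
with encoders and normalization re-fitted per fold.  The 80/20 split in
(iii) is internal to each sub-model; the outer fold is the test set.
Positives are reused across sub-models; negatives are sampled without
replacement, maximizing negative coverage.  The classification threshold
for MCC/F1/recall is 0.5 on the averaged probability.

## Metrics

AUROC (trapezoidal; equals the Mann–Whitney probability that a random
positive outranks a random negative, ties counting ½), AUPR (step-wise,
non-interpolated), MCC (0 when the denominator vanishes) and F1 at
threshold 0.5.  Accuracy is omitted as uninformative at 1:20 imbalance.
Reports carry both pooled metrics (on concatenated out-of-fold
predictions) and mean-over-folds.

## Synthetic data

The generator emulates the structure of EPI benchmarks: n_pos positives
and n_pos·ratio negatives (default 50 and 1:20, matching benchmark class
balance), fixed-width element windows (defaults 200/150 nt — sized so
validation runs finish in seconds per sub-model while leaving the planted
6-mers statistically recoverable), uniform base composition, an E-box-like
enhancer motif (CACGTG) and TATA-like promoter motif (TATAAA) planted at
fixed offsets in positives with probability p_plant, per-base track noise
N(1.0, 0.5²) elevated by Δ (default 3σ = 1.5) over positive windows, and
class-conditional log₁₀ midpoint distances (positives N(4.3, 0.4),
negatives N(4.8, 0.4)).  Motifs are 6-mers deliberately matching the PCPS
fragment length, so the planted offset must surface among the selected
conserved positions — an internal validation of the conservation
statistic.  `SyntheticSpec.null()` removes every class signal, including
equalizing the distance distributions (otherwise distance alone would
carry label information and the null calibration would be dishonest).

What the generator does **not** emulate: realistic motif degeneracy and
positional jitter, sequence composition biases, peak-shaped (rather than
uniformly elevated) signal tracks, Hi-C contact structure, and
cell-type-specific effects.  Passing the recovery tests therefore shows
that the pipeline is correctly wired and can learn planted signal at
benchmark-scale imbalance — not that it attains any particular accuracy
on real cell-line data.

## Validation-scale configuration

`RunConfig.reduced()` keeps the architecture and the protocol and shrinks
tensor sizes so the full pipeline (encode → 20 sub-models → ensemble
predictions) runs in well under a minute on one CPU core: pooled row
count 24 (pool width 2), filters (16, 8, 16, 32), attention d = 8,
genomic/fusion dense widths 32, batch size 32, at most 15 epochs,
one-epoch embedding training capped at 30k word pairs.  The default
configuration retains the full published scale (1000 rows, 64/32/64
filters, 128-wide dense layers).

## Known limitations

- The packaged trinucleotide property table is a synthetic surrogate (see
  above); results depending on the *identity* of physicochemical
  properties require a user-supplied table.
- The balanced-vs-imbalanced ablation is only informative when the
  learning problem is genuinely hard.  Under the planted-signal
  validation conditions (p_plant = 1, Δ = 3σ) the window-mean effect size
  is ≈ Δ/(σ/√L) ≈ 40 per track — the classes are fully separable — and
  both the balanced ensemble and a single imbalanced-trained model reach
  recall = MCC = 1.0 on held-out data.  At that ceiling a strict
  improvement from balancing cannot manifest; the benefit of BESL is
  expected on real data where positives are scarce *and* hard.
- Benchmark-scale training (multi-Mb sequence windows, GPU throughput,
  real cell-line tracks) is out of scope; model checkpointing is limited
  to in-memory ensembles plus prediction/metric artifacts.
- Constructions whose published definitions are ambiguous (the PSM
  pseudocount form, the PCPS per-sequence feature layout) are implemented
  as the documented interpretations above and flagged as such.
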
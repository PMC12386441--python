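# epibesl

Enhancer–promoter interaction (EPI) prediction from DNA sequence and
genomic signal features, built around three ideas:

1. **Four fused sequence encodings.** Each element (enhancer, promoter) is
   encoded four ways and the encodings are merged along the feature axis:
   - **KNF** (k-mer nucleotide frequency): for K ∈ {1,2,3,4}, position *i*
     carries the whole-sequence frequency of the K-mer starting there at
     that K-mer's lexicographic index; block widths 4+16+64+256 = **340**.
   - **TPCP** (trinucleotide physicochemical properties): the product
     pc_p(t)·f_t of each trinucleotide's frequency with each of 11
     normalized property values; **64 × 11 = 704** features.
   - **PCPS** (position conservation and position-specific scoring): a
     conservation profile C_k(i) = Σ_n (f_i(n) − f_e)²/f_e over length-k
     fragments (k = 6, f_e = 1/4^k), the top-10 most conserved positions,
     and a pseudocount position score matrix (**4096 × 10**) with log-odds
     PSF = ln(m/f₀) against background f₀ = 1/200.
   - **DNA2vec**: overlapping 5-mer "words" embedded with a word2vec-style
     skip-gram model into 8 dimensions, adaptively average-pooled to a
     fixed **1000 × 8** matrix per sequence.
2. **BESL** (balanced ensemble subset learning) for the 1:20 class
   imbalance of EPI benchmarks: negatives are partitioned into
   `ratio = round(n_neg/n_pos)` disjoint subsets; each subset plus *all*
   positives trains one 1:1-balanced sub-model (80/20 internal validation
   split, early stopping with patience 5, best weights restored); the
   ensemble prediction is the unweighted mean of the sub-model
   probabilities, wrapped in stratified 5-fold cross-validation.
3. **MCANet**: a multi-scale convolution branch (kernel-9 stem, three
   parallel conv-5/conv-3 sub-blocks, channel concatenation, global
   pooling) for the positional sequence features, and a multi-head tanh
   attention branch over the four genomic feature rows (RAD21 ChIP-seq,
   ATAC-seq, H3K27ac, log₁₀ enhancer–promoter distance) with masking of
   invalid rows and weights normalized to S/(S+ε).  Sequence, genomic and
   per-sequence dense features fuse into a 2-way softmax trained with
   categorical cross-entropy.

Evaluation uses AUROC, AUPR, MCC and F1 (accuracy is deliberately omitted:
it is uninformative at 1:20 imbalance).  A synthetic-data module generates
EP-pair datasets with planted co-occurring motifs, label-correlated signal
tracks and log-spaced distances, so the entire pipeline is testable with
no external downloads.  The network and the skip-gram embedding are
self-contained numpy implementations.

## Worked example

```python
from epibesl import RunConfig, SyntheticSpec, generate_dataset
from epibesl.pipeline import holdout_run

# 50 positive pairs at 1:20 imbalance, motifs planted in every positive,
# track elevation delta = 3*sigma
pairs, tracks, truth = generate_dataset(SyntheticSpec(n_pos=50, ratio=20, seed=1))
result = holdout_run(pairs, tracks, RunConfig.reduced(), seed=1)
print(result.metrics)
```

prints (about half a minute on one CPU core):

```
{'auroc': 1.0, 'aupr': 1.0, 'mcc': 1.0, 'f1': 1.0, 'recall': 1.0,
 'threshold': 0.5, 'tp': 10, 'fp': 0, 'fn': 0, 'tn': 200}
```

The ensemble of 20 balanced sub-models recovers the planted signal
perfectly on the held-out 20% (10 positives, 200 negatives).  On
signal-free data (`SyntheticSpec.null(seed=...)`) the same pipeline stays
at chance level (AUROC ≈ 0.5).

A thin CLI mirrors the library (`epibesl synth`, `epibesl holdout`,
`epibesl cv`, `epibesl evaluate`); see `epibesl --help`.

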
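# Methods

## Problem and scope

Given a fixed-length DNA window (default 101 bp), decide whether it
contains a transcription-factor binding site (TFBS). Real benchmarks derive
positives from 101-bp windows centred on ChIP-seq peaks and negatives from
composition-matched rearrangements of the positives. This package
implements the classifier, its embeddings, the evaluation metrics, the
attention-based interpretation, and a synthetic generator that emulates the
benchmark's construction; it does not download or process ChIP-seq data,
call peaks, or handle genome extraction.

## Synthetic data generator

`generate_dataset(n_pos, motifs, window_length=101, split_fracs=(0.6, 0.3, 0.1), ...)`

* **Background**: i.i.d. uniform over {A,C,G,T}. Uniform is the simplest
  null; a 0-order base-frequency parameter (`base_freqs`) is exposed for
  harder, composition-biased benchmarks.
* **Positives**: each window receives a motif sampled from a position
  probability matrix (PPM). The default motif is the CRE-like 8-bp
  palindrome `TGACGTCA` as a degenerate PPM (probability 1 per base) —
  strong, biologically plausible, and deterministic so localization tests
  have a known ground truth. One motif goes at the window centre,
  `floor((L − m)/2)` (start 46 for L=101, m=8). For the two-site case
  (`n_motifs_per_positive=2`) motifs go at fixed evenly spaced loci,
  starts `floor((j+1)·L/(m_sites+1) − m/2)` (29 and 63 for L=101) —
  fixed rather than random so the dataset-averaged attention profile can
  form two stable peaks; overlapping placements are rejected.
* **Negatives**: Altschul–Erikson dinucleotide-preserving shuffles of the
  positives (uniform over Eulerian rearrangements with the original start
  and end base), the field-standard composition-matched negative. Because
  "recombining" a positive could also mean a plain permutation, a
  mononucleotide mode is available behind `negative_mode`.
* **Splits**: 60/30/10 train/test/validation. Counts are floored per
  fraction and the remainder goes to train (deterministic rounding). Each
  positive and its matched negative land in the *same* split: a shuffle of
  a training window is a near-duplicate in composition, and pairing
  prevents that information from straddling the train/test boundary. With
  per-label rounding this reproduces 600/300/100 records at `n_pos=500`.
* The generator is a pure function of its seed; provenance (all parameters
  and the seed) is stored on the dataset and logged on write.

**What the generator does not emulate**: genomic background structure
(repeats, GC heterogeneity, flanking-sequence bias), degenerate/low-
information motifs, variable motif placement relative to the peak centre,
and label noise. Passing tests on this data show the pipeline learns and
localizes an implanted positional signal against a composition-matched
null — not that it reaches any particular accuracy on real ChIP-seq data.

## Embeddings

All variants index bases and k-mers lexicographically with A<C<G<T — a
single documented convention that makes one-hot columns reproducible.

* `onehot_base`: (L, 4) per-base one-hot.
* `onehot_kmer`: (T, 4^k) one-hot over the stride-1 k-mer tokens,
  T = L − k + 1.
* `dna2vec`: (T, d) distributed k-mer vectors. The package trains its own
  skip-gram with negative sampling on the fitting corpus (d = 100,
  window 5, 3 epochs, 5 negatives from the unigram^0.75 distribution,
  linearly decaying learning rate 0.025, minibatch 1024 with dense one-hot
  accumulation — exact for the tiny 4^k vocabulary). External
  word2vec-text-format tables are accepted via `load_kmer_vectors`.
  Three epochs suffice for a 64-word vocabulary on a few-hundred-window
  corpus; the co-occurrence geometry test in the suite checks the learned
  space is meaningful.
* `positional` (default): per-position concatenation
  `[onehot_kmer | reduce(dna2vec)]`, 2·4^k features. The d → 4^k reduction
  is a width-1 convolution along positions (equivalently one shared linear
  map per row) trained **jointly** with the classifier. Width 1 is the
  minimal choice that achieves the dimension change without altering T and
  keeps the reduction position-equivariant.

k defaults to 3; k ∈ 1..6 is supported and all shapes scale as 4^k.
Ambiguity codes: 'N' is accepted on file read but rejected at embedding
time unless `allow_n=True`, which maps N-containing k-mers to zero rows.

## Network

Defaults (per architecture):

| parameter        | cnn_bilstm_att | cnn_bilstm | bilstm_att |
|------------------|---------------|------------|------------|
| conv blocks      | 2             | 2          | –          |
| kernel / pad     | 5 / 2         | 5 / 2      | –          |
| conv channels    | 64            | 64         | –          |
| BiLSTM hidden    | 16            | 16         | 32         |
| attention dim    | 16            | –          | 32         |
| dense neurons    | 16            | 32         | 32         |
| dropout          | 0.2           | 0.2        | 0.2        |

learning rate 0.001 (Adam), 20 epochs, batch 64 throughout.

Design choices where the design was genuinely open:

* **BiLSTM merge = element-wise sum** (not concatenation). The attention
  vector size equals the BiLSTM hidden size in the default configuration,
  which is only dimensionally consistent if the two directions are summed;
  concatenation is available via `merge="concat"` (attention dim then
  doubles).
* **Convolution channel count = 64 for both blocks.** No canonical channel
  count exists for this family's parameterization; 64 keeps the BiLSTM
  input dimension uniform across embedding variants and the CPU cost of a
  20-epoch run low. Configurable via `cnn_channels`.
* **No pooling.** The stated geometry (kernel 5, padding 2, stride 1,
  "constant length") requires the position count to survive the CNN, which
  pooling would destroy.
* **Dense head order**: FC → dropout → FC → sigmoid, dropout rate 0.2. No
  hidden activation — the head is deliberately a (regularized) linear
  readout of the nonlinear attention context.
* **Attention orientation**: the per-window math is stated on H ∈
  R^(d_w × T); the batched implementation stores (batch, T, d_w) and
  `attention_forward` accepts the (d_w, T) orientation for single windows.
* **Weight init**: seeded Glorot-uniform (fan-based); biases zero. The
  scheme is documented because determinism requires one.
* **Loss clipping**: probabilities are clipped to [1e-7, 1 − 1e-7] inside
  the BCE, which is undefined at exactly 0 or 1. Gradients are taken
  w.r.t. pre-sigmoid logits ((p − y)/N), which is algebraically identical
  and numerically stable.
* **Classification threshold** 0.5 (sigmoid-symmetric default), recorded
  in every metrics report.

All layers are NumPy with explicit backward passes; a finite-difference
gradient check (attention vector and dense parameters, relative error
< 1e-4) is part of the test suite, as is a 100-case comparison of the LSTM
cell against an independent scalar implementation of its update equations.

## Training protocol

Fit on the train split; after every epoch compute the validation-split
loss in eval mode; after the fixed 20-epoch budget restore the
checkpoint with the lowest validation loss (no early stopping). Shuffling,
initialisation, dropout masks and the skip-gram all derive from one user
seed through `derive_seed(seed, component_name)` (CRC-32 of the component
name XORed into the seed, reduced below 2^31), so single-threaded runs are
bit-reproducible. The learning-rate schedule is step decay every
`lr_step = 20` epochs (×0.1), i.e. effectively constant over the default
budget.

`repeat_evaluate` reports mean ± sd over 3 reseeded trainings of the fixed
60/30/10 split. A fixed split is incompatible with literal k-fold
cross-validation, so repeats are the default reading; a literal stratified
k-fold is available via `kfold=True`.

## Metrics

Sen, Spe, Acc, MCC literally from the confusion table (prediction = score
≥ threshold). MCC with a zero denominator is 0 by the standard convention;
Sen/Spe with zero denominators are reported as missing (NaN), not coerced.
AUC is the tie-aware Mann–Whitney statistic from average ranks and is
tested to equal O(n²) pair counting exactly.

## Interpretation

Attention weights are averaged over the *positive* windows of a subset by
default (negatives carry no motif; `positives_only=False` includes all).
Averaging happens on the normalized per-window distributions, so the mean
profile is itself a distribution. Position i of the profile indexes the
i-th k-mer and covers bases [i, i+k) (0-based, half-open). `locate_peaks`
returns up to `max_peaks` maxima, greedy by height with suppression of
neighbours within `min_separation` positions and leftmost-wins ties; note
that with more requested peaks than real modes, the greedy rule will
return background positions after the true modes. Heatmaps export as TSV
(the artifact of record) with best-effort PNG rendering.

## Problem sizes used by the tests and the acceptance script

The benchmark configuration is `n_pos=500` (1,000 windows, 600/300/100
split), the default motif, and the default training configuration; the
interpretability checks run that configuration over 5 seeds (single- and
two-motif). The ablation-grid checks are structural (column layout,
shared test ids) and run a shortened 4-epoch budget on `n_pos=150`, since
the contract they verify does not depend on converged training. The
skip-gram uses d=100 and 3 epochs throughout.

## Known limitations

* CPU-only, single-threaded by design; no GPU kernels or multi-TF heads.
* The skip-gram embedder targets the small 4^k DNA vocabulary; it is not a
  general word2vec replacement (no subsampling, no hierarchical softmax,
  no variable-length k-mers).
* Reverse-complement structure is ignored (no rc-aware embedding or
  augmentation).
* AUC confidence intervals and precision-recall analysis are out of scope.
* Synthetic-data results do not transfer quantitatively to real ChIP-seq
  datasets (see the generator's non-emulated features above).
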
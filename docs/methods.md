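# Methods

## Problem

Circular RNAs (circRNAs) are covalently closed transcripts whose functions
are largely mediated by interactions with RNA-binding proteins (RBPs).
Given a full-length circRNA sequence, the task is a binary classification:
does the molecule carry a binding site for a given RBP anywhere along its
length?  Two properties make this hard: sequences span a very wide length
range (the preprocessing keeps 500–7,000 nt), and true binding regions are
short relative to the full molecule, so almost all of the input is
uninformative background.

## Sequence encoding: double embeddings

A sequence of length `L` is segmented into `m = ⌊L/k⌋` non-overlapping
k-mer words (`k = 7`); the trailing remainder shorter than `k` is discarded
because no partial-word token exists in the vocabulary.  Each word `w_i`
contributes one column

    D_i = R_i ⊕ P_i,

where `R_i` (dimension `p`) is a pre-trained RNA word embedding and `P_i`
(dimension `q`) is the embedding of the word's *pseudo-peptide*: the
`(k−2)`-residue string obtained by translating the word's `k−2` overlapping
codons (`w_i[j:j+3]`, `j = 0 … k−3`) under the standard genetic code.  The
codon alphabet has 21 symbols — the 20 amino acids plus `*` for the three
stop codons — so translation is total and the worked example CACUAUA →
(CAC, ACU, CUA, UAU, AUA) → HTLYI holds by construction.  The sequence
becomes a `(p+q) × m` matrix.

Decisions on under-specified corners:

- DNA input is uppercased and `T → U` converted.  IUPAC ambiguity codes are
  replaced deterministically by `A` with a logged warning (a strict mode
  raises instead): no embedding token contains `N`, and a deterministic
  substitution preserves reproducibility.
- Length filtering keeps `500 ≤ L ≤ 7000` with inclusive bounds.
- Out-of-vocabulary tokens map to the zero vector by default (the
  least-informative choice; a strict mode raises).  Small pre-training
  corpora can miss rare 7-mers.
- The default padding target is 1,000 words = ⌊7000/7⌋; padding appends
  zero columns and is accompanied by a mask.  Padding is never silently
  truncating: exceeding the target raises unless the caller explicitly asks
  for truncation (the dataset builder does, and logs the count).

## Embedding pre-training

Token embeddings are static, GloVe-style: with `X_ij` the distance-weighted
co-occurrence counts (tokens at sentence distance `d ≤ window` contribute
`1/d`; symmetric; zero diagonal — self co-occurrence is excluded because
repetitive k-mer corpora otherwise degenerate the log scale), the trainer
minimizes

    J = Σ_ij f(X_ij) (w_i·w̃_j + b_i + b̃_j − log X_ij)²,
    f(x) = min((x/x_max)^α, 1),

by AdaGrad over shuffled chunks of the nonzero entries; the emitted vector
is `w_i + w̃_i`.  Defaults follow the original GloVe choices (`x_max = 100`,
`α = 0.75`, lr 0.05, window 10); dimension defaults to 32 for both the RNA
(`p`) and peptide (`q`) tables, a configuration choice: the architecture
places no constraint on `p` and `q` beyond `p + q` fixing the input depth.  Training is exactly reproducible
from the seed.  Embeddings of this kind are ideally trained on
genome-scale corpora; this trainer accepts any corpus at desk scale, and
the reader accepts externally pre-trained tables in the plain-text
token-vector dialect.

## Cross-branch attention network

Three convolutional branches with kernel sizes 3/5/7 (three layers of 100
filters each) process the input matrix in parallel:

    X_j^1 = f(W_j^1 * X + b_j^1),      X_j^i = f(W_j^i * X_j^{i−1} + b_j^i),

with `*` a valid (no padding, stride 1, no dilation) 1-D cross-correlation
along the word axis and `f` = ReLU (configurable; the standard choice for
convolutional sequence models of this kind).  After each layer every branch is globally max-pooled to
a 100-vector `Y_j^i`; the global (rather than windowed) max yields
fixed-length vectors for arbitrary sequence lengths.  A per-layer attention
module with weight vector `W_a^i` (one independent module per layer,
initialized from a normal distribution, standard deviation 0.1) computes

    a^i = softmax(g(W_a^i · [Y_1^i; Y_2^i; Y_3^i]^T)),
    Y_attn^i = Σ_j a_j^i Y_j^i,

with `g` = tanh (bounded scores stabilize the 3-way softmax).  The three
fused vectors are concatenated (`Y_out`, length 300) and a fully connected
softmax head produces the two class probabilities.  The head activation
defaults to identity: a bounded activation inside the softmax caps the
reachable probabilities (tanh limits them to ≈0.88) and is therefore only
offered as an option.

Stacked valid convolutions at stride 1 give layer `n` of a kernel-`k`
branch an analytic receptive field of `1 + n(k−1)` input words — 3 and 5
for kernel 3 at layers 1–2, 5 and 9 for kernel 5 — which the test suite
also verifies empirically by perturbation probing.

Padding interacts with global max pooling: a padded zero tail can win the
max when all true features are negative.  This is the documented behavior
of the default configuration; masked pooling (restricting the max to true-data columns, propagated
through the per-layer width shrinkage) is available as an option.  Bucketed
batching keeps padding short in practice.

## Training and evaluation

Datasets are balanced 1:1 and split 70/30 stratified by label.  The loss is
binary cross-entropy on the softmax outputs, optimized by Adam (lr 0.001,
batch 32).  Early stopping monitors cross-entropy on a stratified
validation slice (10% of the training portion) — monitoring the test set
would leak — and stops after 10 non-improving epochs, restoring the
best-scoring parameters, never the last.  Batches are bucketed by word
count and padded only to the longest member, so compute scales with true
lengths; only the batch visiting order is shuffled, keeping runs
seed-deterministic.  Evaluation reports F1 (= 2TP/(2TP+FP+FN), threshold
0.5) and the trapezoidal ROC AUC.  On a single-class evaluation set the
AUC is undefined and reported as NaN with a warning while F1 is still
computed.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes:
lengths uniform on 500–7,000 nt, balanced classes, negatives i.i.d. uniform
background, positives carrying 1–3 non-overlapping copies of one fixed
12-nt motif at uniformly random positions (recorded 0-based half-open).  A
12-nt implant in a multi-kilobase sequence reproduces the sparse-signal
premise; implants may straddle the 7-mer word grid, as real binding sites
do.  Not simulated: circular topology, secondary structure, realistic
genomic composition, and motif degeneracy — so passing the benchmark shows
the architecture can find sparse exact motifs in long sequences, not that
it reaches any particular accuracy on real CLIP-derived data.

The end-to-end benchmark (`run_synthetic_benchmark`) runs the whole method
at desk scale: 2,000 sequences encoded at full length; GloVe tables
(dim 32, window 3, 6 epochs — the AdaGrad objective plateaus early on these
corpora) pre-trained on the training-split sequences, the desk-scale
analogue of pre-training on a genome, which likewise contains the binding
sites (labels and the held-out 30% are never touched during pre-training);
Adam for up to 12 epochs.  These sizes are the package's desk-scale
defaults, chosen to keep a full run within minutes on one CPU core; all
are overridable.  Pre-training the tables on out-of-domain background
sequences instead leaves the motif words without distinctive vectors and
degrades held-out accuracy substantially — static embeddings carry much of
the signal, consistent with the double-embedding design premise.

## Numerical choices

- float32 everywhere in the network; convolution as im2col + GEMM.
- Softmax is computed with the max-subtraction stabilization; probabilities
  are clipped at 1e-12 inside the cross-entropy only.
- Ties in the global max pool resolve to the first (leftmost) position,
  `argmax` semantics, making backpropagation deterministic.
- Gradients are hand-derived and verified against central finite
  differences (relative error ≤ 1e-4 in float64) in the test suite.
- Adam uses the standard bias correction; AdaGrad accumulators in the
  GloVe trainer start at 1 so the first step equals the learning rate.

## Known limitations

- The network is CPU-oriented NumPy; it is adequate for desk-scale
  experiments, not for training on genome-scale corpora.
- Global max pooling discards all positional information; the model
  predicts presence, not location, of binding sites.
- The unmasked-pooling default reproduces the padding artifact discussed
  above; use masked pooling when true lengths are available.
- Checkpoints store raw parameter arrays with an embedded config and format
  version; loaders refuse mismatched versions rather than migrating.
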
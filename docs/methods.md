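# Methods

## Overview

`xraycap` implements a two-stage report generator for chest images and
exercises it end to end on a synthetic phantom corpus.  The first stage
is a Show-Attend-Tell (SAT) captioner: a CNN encoder produces a spatial
grid of feature vectors, an additive-attention MLP weights the grid at
every decoding step, and an LSTM emits the report word by word.  The
second stage is a decoder-only transformer language model over BPE
subwords that continues the captioner's output into a fuller report.
Two combination strategies are provided, along with the caption metrics
used to evaluate and select models.

All neural components run on a small reverse-mode automatic
differentiation engine over NumPy arrays (`xraycap.autodiff`,
`xraycap.nn`).  Computation is float64 throughout; every model is a
pure function of its integer seed.

## The captioner

The encoder output is a grid `a = {a_1 .. a_N}` of `C`-dimensional
location features with `N = D^2` (default `D = 7`, so 49 locations).
Attention is computed **over spatial locations**: a location's score is

    e_ti = v . relu(W_f a_i + W_h h_{t-1} + b),
    alpha_t = softmax(e_t),      context_t = sum_i alpha_ti a_i,

so the context vector lives in feature space (dimension `C`) and each
`alpha_t` is a distribution over the 49 image regions — this is what
makes the per-word heatmaps spatial.  An alternative reading in which
attention runs over channels was considered and rejected: it admits no
2-D localization map.

The LSTM consumes `[E z_{t-1}; h_{t-1}; context_t]` through a single
affine map into the four gates (input, forget, output: sigmoid;
candidate: tanh).  Hidden and cell states are initialised by two
separate linear-tanh layers applied to the mean location feature.  The
next-word distribution is a deep output layer,
`softmax(L_o (L_h h_t + L_a context_t + E z_{t-1}))`, with dropout
(default 0.1) applied immediately before `L_o`.

Training is teacher-forced cross-entropy over non-pad positions:
batches are sorted by decreasing caption length and the per-step
effective batch size excludes finished captions.  There is **no**
doubly-stochastic attention regulariser: chest anatomy sits in a stable
position from image to image, so encouraging attention to spread over
the whole frame is counterproductive; the loss is plain cross-entropy.

Decoding is greedy or length-synchronous K-beam search (inference
only), both built on one generic search routine (`xraycap.search`);
argmax and beam ties break toward the lowest token id so decoding is
fully deterministic.  Attention weights are recorded at every step;
heatmaps are produced by mass-preserving bilinear upsampling of the
`D x D` weight grid to image resolution (each grid cell distributes
exactly its attention mass, so the upsampled map still sums to 1
before per-map rescaling to [0, 1]).

### Encoder

The default backbone is a three-block unpadded CNN
(1→16→32→64 channels, strides 4/2/2) trained from scratch; unpadded
convolutions keep a constant image mapping to a constant feature grid
(no border artefacts in attention).  Convolutions use He
initialisation — with three stacked ReLU layers the more conservative
uniform fan-in scheme shrinks activations by an order of magnitude and
measurably slows the image-conditioned part of caption learning.
Features are adaptively average-pooled to `D x D` and flattened
row-major.  Heavier classification backbones are pluggable (any module
mapping images to a channel map); their documented channel counts
(DenseNet-121: 1024, VGG-16: 512, ResNet-101/InceptionV3: 2048) are
recorded in `backbone_channels`.  A fine-tune toggle freezes the
backbone; frozen runs cache the feature grids once, which makes
decoder-only training roughly seven times faster and is the default in
the desk-scale studies.

## The language model

BPE merges are learned greedily on the report corpus: at each step the
most frequent adjacent symbol pair is merged, ties broken toward the
lexicographically smallest pair, stopping early when no pair occurs
twice.  Words carry an explicit end-of-word symbol; characters outside
the training set fall back to byte tokens, so encoding never produces
an unknown token and decoding inverts encoding exactly (model-generated
byte sequences that are not valid UTF-8 decode with replacement).

The LM is a GPT-style stack: learned token and positional embeddings,
pre-norm blocks of masked multi-head self-attention and a GELU
feed-forward net, and a linear head.  Fine-tuning is self-supervised
next-token cross-entropy over fixed-length blocks with global
gradient-norm clipping (default 1.0; a threshold of 0 freezes the
model).  Report continuation appends a start-of-continuation marker to
the seed and beam-searches to the end-of-text token; following the
two-stage design, the returned continuation is the **second-best**
completed hypothesis, falling back to the best when `k = 1` or only
one hypothesis completes.  The rule is applied to the whole
continuation (not per sentence); `second_best=False` restores rank 1.

Because positional embeddings are learned, a model fine-tuned only on
plain text has never seen the continuation marker; fine-tuning streams
therefore include marker-split copies of each document
(`continuation_corpus`), placed at the start of the stream so the
marker context occupies the same positions at training and inference.

## Combining the models

**Approach 1 (joint distribution).**  At each step the captioner's
log-softmax over its word vocabulary and the LM's aligned scores are
concatenated and passed through a feed-forward head
(2W → W → W, ReLU) whose softmax is the fused next-word distribution.
Alignment discretises the LM's subword distribution onto the word
vocabulary: a word's score is the chain-rule log-probability of its
greedy BPE segmentation (one extra LM step per additional subword);
words with no support receive a large negative floor.  Both branches
are log-probabilities so their scales are commensurable.  The head is
trained teacher-forced with both backbones frozen; per-step score
vectors are precomputed, which makes head training cheap.  Both models
advance with each emitted word (the LM consumes the word's subwords);
a flag disables LM advancement.  Emitted words are necessarily limited
to the captioner's vocabulary — the discretisation cost of this
approach.

**Approach 2 (stacked).**  The captioner decodes a seed report from
the image; the LM continues it.  The seed is preserved verbatim as the
report prefix, and the output records seed and continuation separately.

## Report preprocessing

A report is the concatenation of its impression and findings sections;
if both are empty the report is excluded (a sentinel, not an
exception).  Tokens are lower-cased and stripped of non-alphanumeric
characters — the stripping happens inside tokens (hyphens deleted,
digits kept), so "X-ray" becomes "xray".  An abbreviation dictionary
(two-column TSV) is expanded in a single pass; cyclic dictionaries are
rejected at load.  Pathology label tokens are prepended to the report
followed by a literal period token, giving the models a summary
"sentence" first; the same prefixed text is used for training and for
evaluation references.  The word vocabulary keeps every token with
frequency ≥ 1 by default (the phantom grammar is closed; the cutoff is
configurable for real corpora) with four fixed special tokens
(start/end/pad/unk, ids 0–3) and frequency-then-lexicographic ordering
for reproducibility.

## The phantom corpus

A phantom is a fixed parametric torso (two lung ellipses, one heart
ellipse) with additive Gaussian noise (sigma 0.02 grey levels) and up
to two planted pathologies from {left/right lung opacity, enlarged
heart, support line}; about a quarter of samples are normal.  Opacities
are Gaussian blobs (amplitude 0.4, half-max disc as ground-truth mask)
placed randomly within a lung; the enlarged heart scales the heart
ellipse by 1.45 with the added ring as mask; the line is a thin bright
streak.  Reports come from a template grammar with 2–3 surface variants
per pathology, chosen per-sample, so captions are learnable but not
constant.  Per-sample randomness derives from `SeedSequence(seed,
index)`, making the whole corpus a pure function of its spec and
random-access reproducible.  Images are stored as float32 in [0, 1] at
224×224 in HDF5; reports as JSON-lines.

What the phantom does **not** emulate: anatomical texture, projection
physics, inter-reader report variability, the label imbalance of real
corpora, and negated/uncertain label mentions.  Tests passing on
phantoms demonstrate that the machinery is correct and that attention
localizes planted signal; they say nothing about clinical performance
on real radiographs.

## Metrics

BLEU-1..4 are corpus-level clipped n-gram precisions with the brevity
penalty (closest-reference length, ties to the shorter); BLEU-n uses
n-grams up to order n.  ROUGE-L is the LCS F-measure with the
captioning convention beta = 1.2, max over references, averaged over
samples.  CIDEr is the TF-IDF n-gram cosine consensus (n = 1..4,
candidate counts clipped by reference counts, Gaussian length penalty
sigma = 6, scaled by 10).  Model selection uses the geometric mean of
the four BLEU scores.  Clinical-efficacy metrics extract a binary
presence vector over a closed label-term vocabulary from each text by
exact token matching after normalization, then micro-average TP/FP/FN/TN
over all (sample, label) pairs; zero denominators yield 0.  The
extractor is presence-only (no negation handling) — on the phantom
grammar label mentions are never negated, so this is exact there.

## Study conditions (desk scale)

The published full-scale recipe is kept visible in the `paper` profile
(captioner: 70 epochs, batch 16, embedding 100, attention/decoder 512,
dropout 0.1, learning rates 4e-7/3e-7; LM: 30 epochs, batch 4, lr 5e-5,
Adam eps 1e-8, block 1024, clip 1.0; split 75%/24.75%/0.25%), which
requires a real report corpus and refuses to run on phantoms alone.
The desk-scale studies are sized for a single CPU:

* **Memorisation** — 10 phantoms, captioner with embedding 32 and
  hidden 64, Adam lr 2e-3, batch 2, up to 200 epochs (early stop at
  99.5% teacher-forcing accuracy).
* **LM memorisation** — a one-sentence corpus, 2-layer/2-head LM of
  width 64, block 256 so the whole stream fits one window, lr 3e-3,
  early stop below 0.01 nats/token.
* **Localization** — 500 training phantoms, 50 held-out lesioned
  phantoms, embedding 48 / hidden 128, frozen encoder, 20 epochs at
  lr 1e-3.  The score is the attention mass inside the lesion mask at
  the step that predicts the pathology's label token, compared with
  the mask's area fraction (exactly the uniform-attention score).
* **Evaluation** — 300 training phantoms, 25 epochs, greedy decoding
  on 30 fresh phantoms, scored with the full metric set.

## Numerical choices and edge cases

* Softmaxes subtract the running maximum; sigmoids clip pre-activations
  at ±60.
* Argmax/beam ties break to the lowest token id; `pad_and_sort` is a
  stable sort, so equal-length captions keep their order.
* The beam expands k+1 candidates per live hypothesis (one may retire
  at the end token); completed hypotheses sort by score then
  lexicographic ids.
* Empty corpora, unsorted batches, fraction vectors that do not sum to
  1, unknown pathology kinds and empty label vocabularies are rejected
  with explicit errors; a single-sample CIDEr corpus warns that the
  IDF is degenerate.
* Checkpoints are NumPy archives holding the state dict plus JSON
  metadata (config and vocabulary), written at run time.

## Known limitations

* The from-scratch CNN and small LM are orders of magnitude below the
  pretrained backbones and GPT-scale LM the full method assumes; the
  desk profile demonstrates mechanism, not clinical quality.
* Approach 1's vocabulary discretisation discards LM probability mass
  outside the word vocabulary, and its alignment cost grows with
  vocabulary size (one LM step per extra subword).
* Attention heatmaps are soft-attention weights, not gradient-based
  saliency; they localize only what the captioner actually used.
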
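# Methods

## Scope and design

`plantlm` re-implements, at configurable scale, the methodology of a plant
genomic language model: a hexamer-tokenized encoder-only transformer
pre-trained with masked language modeling on genome chunks, fine-tuned
parameter-efficiently with IA3 rescaling vectors, and used downstream for
zero-shot variant-effect scoring and in silico saturation mutagenesis. The
published architecture (a ~1-billion-parameter model trained on 472.5
billion tokens from 48 plant genomes) is out of reach on a workstation; the
package therefore separates *mechanism* from *scale*: every algorithmic rule
is implemented exactly, architecture presets range from `tiny` (2 blocks,
64-dim) to `paper_1b` (40 blocks, 1500-dim, documented but never allocated),
and parameter accounting is symbolic so the billion-parameter preset can be
audited without tensors.

No deep-learning framework is used. The transformer forward and backward
passes are written directly in NumPy (pre-layer-norm blocks: layer norm →
multi-head attention → layer norm → GELU MLP, learned positional embeddings,
final layer norm before the LM projection). The backward pass is verified
against central finite differences on float64 models in the test suite.
This keeps every gradient path auditable and the dependency footprint
minimal; the cost is speed, which the desk-scale presets absorb.

## Tokenization

The vocabulary contains all `4^k` k-mers over {A,C,G,T} in lexicographic
order, five standalone tokens (A, C, G, T, N), and four specials ([PAD],
[MASK], [CLS], [UNK]) — 4105 entries at k = 6. Tokenization is a single
greedy left-to-right scan: a full k-mer over the alphabet is emitted when it
fits at the cursor, otherwise one standalone base. Splitting on N falls out
of this rule (no emitted k-mer can contain an N), and concatenating the
emitted tokens always reproduces the input, which gives the lossless
round-trip property tested on 10,000 random sequences. Lowercase
(soft-masked) input is uppercased; over-long inputs right-truncate with a
logged warning. Model encoding prepends [CLS] and pads to the configured
input length (1025 at the published scale).

## Pre-training

Genomes are tiled into 6100-nt chunks overlapping by 50 nt (stride 6050);
the final chunk per chromosome is clipped at the chromosome end. Per epoch
and chunk, a start offset is drawn uniformly from [0, 100] before
tokenization. The objective selects each non-special token independently
with probability 0.15 (an exact-count mode exists behind a flag); selected
tokens are replaced by [MASK] with probability 0.8, by a uniformly drawn
*different* non-special token with probability 0.1, and kept with
probability 0.1. Cross-entropy is averaged over selected positions only;
[CLS] and [PAD] are never selected. All selected positions carry labels,
including the kept ones.

The learning-rate schedule warms up linearly from 5e-5 to 1e-4 over 64,000
steps. The post-warmup "square decay" is under-specified in the recipe this
follows; we use `peak_lr * (warmup/step)^p` with p = 0.5
(inverse-square-root) by default and expose the exponent. Adam uses
β₁ = 0.9, β₂ = 0.999. Token accounting (effective batch tokens × steps)
reproduces the published 472.5B total for 1.5M × 315k.

## IA3 fine-tuning

IA3 inserts per-block multiplicative rescaling vectors on attention keys
(length d), attention values (length d), and the MLP intermediate activation
(length f), initialized to ones — the adapted model is therefore *exactly*
the base model before any update, a property the tests assert bitwise.

Two task-head designs are provided, chosen by the target's structure. The
`mean` head is a linear map on the hidden state mean-pooled over non-special
positions — the natural readout for dense targets such as expression. The
`detection` head scores every adjacent pair of non-special positions with a
width-2 convolution and aggregates by log-sum-exp (a soft maximum): the
multiple-instance readout for presence tasks, where the label is carried by
a short local signal anywhere in the window. Mean pooling provably dilutes
such signals (a ~3-token motif among ~34 tokens), and single-token evidence
is ambiguous because individual motif-length k-mers also occur by chance in
negative windows; consecutive-pair evidence resolves both. The head's
read-out depth is configurable (final layer by default). Because the
soft-max pooling gradient spreads credit across pairs, gradient training of
a binary detection head is followed by a few EM-style hardening rounds: the
highest-scoring pair of each positive window is pseudo-labeled positive, all
pairs of negative windows negative, and the pair scorer is refit as a convex
logistic problem on the frozen features, keeping the round with the best
validation ranking. Classification heads train with BCE-with-logits,
regression heads with squared error. Under the frozen-backbone mode only
adapters and head receive updates (0.033% of parameters at the `paper_1b`
preset, comfortably under the ~1% the method targets); optionally the last
k blocks can be unfrozen. Model selection keeps the best-validation-loss
snapshot of the trainable parameters; early stopping on validation loss with
a patience flag is available. Split manifests are audited for identifier
leakage before training.

## Benchmark construction rules

Coordinate conventions: BED 0-based half-open, GFF3 1-based inclusive,
positions inside emitted windows 1-based.

- **Polyadenylation**: 400-bp windows, 300 nt upstream + site + 99 nt
  downstream, so the site is window position 301; minus-strand sites are
  reverse-complemented so upstream reads leftward. Negatives re-extract the
  window around the site shifted by a uniform magnitude in [1, 50] with
  uniform sign (2 negatives per positive); out-of-bounds shifts redraw with
  bounded retries. Sites too close to a chromosome edge are skipped and
  counted.
- **lncRNA vs mRNA**: sequences over 6000 bp are removed; each lncRNA is
  matched greedily (seeded random order, no mRNA reuse) to an mRNA within
  100 bp in length and 1 percentage point in GC (GC computed over A/C/G/T
  only).
- **Chromatin accessibility**: 1000-bp windows are positive for a track when
  the union of that track's open-chromatin intervals covers strictly more
  than half of the central 200 bp (> 100 bp). With a single overlapping
  interval this coincides with the per-interval rule; union coverage is what
  the per-base oracle in the tests computes.
- **Promoter-proximal expression windows**: 5000 bp upstream to 1000 bp
  downstream of the TSS (strand-aware, reverse-complemented for minus-strand
  genes), with the sliding variants 4000/2000 … 1000/5000 available.
- **Count normalization**: median-of-ratios size factors (median over
  all-positive genes of count / per-gene geometric mean), division by the
  factor, replicate averaging per tissue, then log2(x+1). Implemented
  directly (~15 lines) since only this step of the differential-expression
  pipeline is in scope; verified against a hand-computed example and a
  column-scaling recovery test.
- **Splits**: gene families are connected components of a thresholded
  pairwise-similarity graph (provider pluggable; default shared-k-mer
  Jaccard, standing in for all-by-all protein BLAST so the logic is testable
  without an aligner). Whole families are assigned to the test set in seeded
  random order until the test fraction is closest to the target (80/20
  default); chromosome-holdout mode sends named chromosomes to test. Both
  are audited post hoc.

## Zero-shot variant scores

A window (6000 bp default) is centered on the SNP (1-based window position
window/2 + 1, clipped with a warning near edges; the reference allele is
checked against the genome). Embedding scores (L1, L2, cosine, dot product)
compare mean-pooled per-layer embeddings of the ref and alt windows; the
layer list is configurable, defaulting to the final layer. The LLR masks the
variant-containing token and reads log p(alt token) − log p(ref token) from
the MLM head; because the two windows differ only inside the masked token,
one forward pass serves both alleles and ref/alt swap negates the LLR
exactly. Only the forward strand is scored (a strand-averaged mode is a
flag). Enrichment statistics: missense/synonymous count ratios per
frequency bin (< 0.1%, 0.1–1%, 1–5%, > 5%) with 95% percentile intervals
from 100 chromosome-level bootstrap resamples, and odds ratios of group
membership against score quantiles with log-OR normal-approximation
intervals and the Haldane–Anscombe 0.5 correction for zero cells.

## Mutagenesis and importance

Saturation mutagenesis substitutes every position of the scanned region to
the three alternative bases and records LFC = log2(P1/P0). For classifiers
P is the positive-class probability; for regression heads trained on
log2(x+1) targets, predictions are mapped back to the linear scale
(2^y − 1) before the ratio — applying the LFC formula to log-scale values
would conflate a log of logs, so the linear-scale choice is deliberate and
flagged here. Per-position letter heights for logo rendering are the
maximum |LFC| over the three alternatives; lower-tail thresholds (e.g. the
0.01% quantile) use the standard interpolated quantile. Token importance
replaces each token position with a random different non-special token and
averages |Δprediction| over output dimensions and sequences.

## Synthetic study conditions (desk scale)

The synthetic generators define the conditions under which the end-to-end
suites run; they were fixed once and are not tuned to test outcomes:

- **Motif-rich pre-training genome**: 4 chromosomes × 50 kb, uniform base
  composition, tiled with a fixed 36-bp consensus separated by 2–8 bp
  uniform random spacers (~88% motif coverage). A masked-language model can
  in principle drive the loss near the spacer-entropy floor on such a
  sequence, which is what makes a halving of the masked loss a meaningful
  desk-scale bar; a scattered-motif layout (the generator default) leaves
  most tokens at background entropy and bounds any model near the unigram
  floor instead.
- **Pre-training run**: `tiny` preset (2 blocks, 64-dim, 4 heads, 64-token
  input), 350-nt chunks, 500 Adam steps at batch 24 with a 50-step warmup to
  peak lr 6e-3 then inverse-square-root decay. Problem sizes were chosen so
  the whole suite trains in about two minutes on one CPU.
- **Planted-motif task**: 200-bp windows, 500 positives (one 18-bp consensus
  embedded at a uniform offset in a motif-free background) and 500
  rejection-sampled motif-free negatives, 70/15/15 split; the GC
  distributions of the classes match by construction and the label is a
  deterministic function of motif presence, so a string-matching classifier
  is Bayes-optimal at AUROC 1.0.
- **Variant panel**: half motif-disrupting (inside a planted motif), half
  neutral background positions; synthetic MAFs Beta(0.5, 20) vs Beta(2, 5)
  so disrupting variants are rarer (means ≈ 0.024 vs 0.286).

What passing these suites shows — and does not. The synthetic genomes have
uniform composition, exact motif instances, no repeats, no phylogenetic
structure and no measurement noise; success demonstrates that the machinery
(tokenization, objective, gradients, adapters, window arithmetic,
statistics) is correct and that the learning loop can extract a planted
signal, not that a tiny model would approach published performance on real
genomes.

## Numerical choices

Layer-norm epsilon 1e-5; GELU uses the exact erf form; attention masks PAD
keys with a −1e9 bias; parameters initialize N(0, 0.02²) from a seeded
generator, so identical seeds give bit-identical models. Weights are
float32 by default (float64 for gradient checks). Adam keeps float64
moments. Degenerate cases are defined explicitly: empty masking selection →
loss 0 with a warning; direction-accuracy ties (zero observed or predicted
LFC) are excluded from the denominator and counted; zero-synonymous bins and
degenerate score quantiles are reported as undefined/skipped rather than
raising mid-analysis.

## Known limitations

The published model's MLP width, head count, dropout and norm epsilon are
not printed in the text we follow; the `paper_1b` preset uses the 4×
expansion convention and 20 heads and is marked approximate. The NumPy
training loop is single-device and unsuitable beyond toy scale. The
Roberta-style LM head is simplified to final-norm + projection. Loading
published checkpoint weights is not supported.
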
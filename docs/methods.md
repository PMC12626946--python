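# Methods

## Problem and model

`paratopenet` predicts, for every residue of an antibody variable domain,
whether that residue contacts the antigen (is part of the paratope), using
the amino-acid sequence alone.  The prediction target is a per-residue
binary label; positives are rare (~10% of residues) and cluster in a few
short loop segments, mostly the complementarity-determining regions.

The predictor is a hybrid recurrent–convolutional network applied to each
chain independently:

1. **Encoding.**  Chains are zero-padded on the right to a fixed length
   L = 130 (the upper end of the variable-domain length range) and encoded
   either as 21-dimensional one-hot vectors (20 standard residues plus an
   explicit 'X' unknown category) or as integer tokens 1–20 feeding a
   learnable 21-dimensional embedding, with token 0 shared by padding and
   unknowns.  The asymmetry — 'X' is a real one-hot category but shares the
   padding token in the index scheme — is deliberate and preserved.  The
   alphabet ordering (`ACDEFGHIKLMNPQRSTVWY` then `X`) is fixed and stored
   in every checkpoint.
2. **Context.**  A single bidirectional LSTM with hidden size H = 64 per
   direction produces a contextual vector h_t ∈ R^128 per position by
   concatenating the forward and backward states.
3. **Local motifs.**  A length-preserving ("same"-padded) 1-D convolution
   with 64 output channels per kernel size, followed by ReLU, extracts
   local features.  Kernel sizes come from {7, 15, 31, 71, 130}; 130 spans
   the whole padded sequence ("full-length" convolution).  Several kernel
   sizes may run in parallel, their feature maps concatenated channel-wise;
   the sweep protocol uses one size at a time.  There is no pooling:
   per-residue resolution is the point.
4. **Head.**  A single affine map per position produces one logit;
   a sigmoid turns it into a binding probability.

Dropout (p = 0.3) is applied after the encoding, after the BiLSTM and after
the convolution, in training mode only.  Padded positions flow through the
network unhindered; they are excluded from the loss and all metrics via the
mask, never by truncation.

The network, backpropagation through time, and the Adam optimizer are
implemented directly in NumPy with hand-derived gradients.  Analytic
gradients are verified against central finite differences to 1e-4 in the
test suite, and the convolution against an independent nested-loop oracle.

## Loss and training

The training loss is a masked, class-weighted binary cross-entropy.  The
positive class is weighted by w+ = N_neg/N_pos computed over the unpadded
residues of the training portion only (recomputed per fold and chain
regime); the negative weight is 1.  The masked weighted sum is divided by
the number of real residues, so the reported quantity is a mean; the
normalization stabilizes learning-rate behaviour across batch sizes and
does not move the optimum.  Log arguments are clamped at 1e-7.

Optimization uses Adam at learning rate 0.001 with batch size 32 (a
desk-scale CPU default) and at most 100 epochs by default.  Early stopping
monitors the validation MCC (maximize) with patience 5 — training stops
after five consecutive epochs without strict improvement and the parameters
of the best epoch are restored.  Monitoring the validation loss instead is
a configuration option; MCC is the default because it is the quantity the
evaluation protocol ranks by.  All randomness (initialization, dropout,
batch shuffling) is driven by explicit seeds; two runs with identical
seeds and single-threaded BLAS are bit-identical.

## Data contracts and splitting

The unit of grouping is the antibody–antigen complex: one heavy and one
light chain sharing a complex id.  Every split operates on complex ids, so
the two chains of one antibody can never land on opposite sides — an
invariant the test suite audits exhaustively.  The blind split withholds
round(n × 0.10) complexes by seeded shuffle.  The remaining modeling set is
divided into five folds, stratified on the quartile-binned per-complex
binding-residue fraction; class balance is the only stratification variable
available from sequences and labels alone, and it is the one the
imbalance-sensitive metrics care about.  If a quantile bin is too sparse
for k folds the binning coarsens gracefully down to a plain seeded k-fold.

Chain regimes: H uses heavy chains only, L light chains only, and HL pools
both chains of each complex as independent examples (never concatenated).

Length filtering keeps complexes whose chains are both within [110, 130]
residues (inclusive, configurable) — the typical span of variable domains;
shorter entries are usually incomplete and longer ones include constant
domains.  Non-standard residues (B, Z, J, U, O, `*`, anything else) are
normalized to 'X' with a logged count.

## Evaluation

Metrics are computed over real residues pooled across all chains of the
evaluated subset (micro-averaging), at a default decision threshold of 0.5
(ties count as positive calls).  The panel is ROC AUC, PR AUC, accuracy,
precision, recall, F1, MCC, plus balanced accuracy.  Zero-division
conventions are the scikit-learn ones (precision/recall/F1 → 0; MCC → 0
when a marginal is empty).  ROC AUC and PR AUC are delegated to
scikit-learn (rank statistic with half-credit ties; step-integrated
precision–recall area) and cross-checked in the tests against exhaustive
pair counting.  Cross-validation results are reported as mean ± sample
(n−1) standard deviation across folds.  The blind evaluator takes the set
of training-time complex ids and refuses to run on any overlap.

## Synthetic data: what it emulates, and what it does not

The generator produces paired H/L chains of 110–130 residues with
round(0.104 × length) positive residues per chain — the ~10% positive rate
of real residue-contact annotations — arranged in 3 contiguous loop
segments of length ≥ 3 (capped at 12).  Heavy chains route surplus
positives to their last loop, a CDR-H3 analog, and carry a stronger
sequence signal (motif strength 0.9 vs 0.6), emulating the observation
that heavy chains are more learnable from sequence.

The planted signal is purely compositional.  With probability equal to the
motif strength, a binding residue is drawn from a biased distribution over
tyrosine, tryptophan and arginine (residues genuinely enriched in real
paratopes) instead of the uniform background, and the residues immediately
flanking each loop are set to cysteine with the same probability — the
analog of the conserved anchors framing real CDR loops.  Loop segments are
placed uniformly at random over all non-overlapping placements (gaps drawn
uniformly over compositions of the slack).  This placement choice is
deliberate: any positional regularity would let a class-weighted model
predict labels from position alone, independent of sequence content, which
would contaminate the motif-strength-0 null control.  As built, strength 0
yields labels carrying no sequence information, a trained model scores
|MCC| < 0.1, and recovered skill rises monotonically with motif strength.

What the generator does *not* emulate: germline/V(D)J structure, framework
conservation, somatic hypermutation, inter-chain dependence of real
paratopes, or any structural notion of contact.  Passing the recovery
tests therefore demonstrates that the pipeline can learn plantable
sequence-to-label signal under realistic imbalance and length conditions —
not that it reaches any particular accuracy on real antibody complexes.

## Numerical and design choices

- Same-padding asymmetry: pad-left = floor((k−1)/2), pad-right the
  remainder; symmetric for the odd kernels, documented for the even
  full-length kernel.
- Initialization: uniform ±1/sqrt(fan_in) for LSTM/conv/dense weights,
  standard normal for the embedding table, all from the model seed.
- Arithmetic is float64 throughout; this keeps the finite-difference
  gradient checks sharp and determinism trivial, at some speed cost.
- Decision threshold 0.5 with p ≥ τ counted positive; configurable.
- The sweep protocol instantiates 2 encodings × 3 chain regimes × 5 kernel
  sizes = 30 configurations, 150 fold-runs at k = 5, ranked by mean MCC.
- Test-suite and acceptance-script problem sizes (200 synthetic complexes,
  one fold, ≤ 30 epochs; smaller models in unit tests) were chosen so the
  full pipeline exercises every component at desk scale; they are the
  package's own defaults for its built-in study, not statements about real
  data volume.

## Known limitations

- No GPU path, learning-rate schedules, gradient clipping or weight decay;
  the optimizer is plain Adam.
- The loss normalization makes per-epoch losses comparable across batch
  sizes but means the printed loss is not the raw summed cross-entropy.
- Checkpoints are NumPy archives; they reproduce eval-mode outputs
  bit-exactly on the writing platform, but bit-exactness across different
  BLAS builds is not guaranteed.
- Real residue-contact datasets carry curation subtleties (inconsistent
  residue numbering, missing density, redundancy) that the length filter
  alone does not address; the package consumes labels, it never computes
  them from structures.
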
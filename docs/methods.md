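# Methods

## Model

The language model is a three-layer LSTM over a 28-token vocabulary: the 20
standard amino acids (alphabetical, ids 2–21), the six non-standard symbols
B, J, O, U, X, Z (ids 22–27), `<PAD>` = 0 and `<BOS>` = 1. Every tokenized
sequence starts with `<BOS>`; the backward direction reverses the residue
order while keeping `<BOS>` first. Layer widths are E → H → H → E so the
decoder can share the embedding matrix (weight tying); with tying on, the
decoder weight *is* the embedding tensor, so the tying invariant holds
identically under any optimizer step.

Training uses truncated backpropagation through time on `batch_size`
parallel token streams formed by concatenating the (seed-shuffled) corpus.
Window lengths are drawn per step: the base length is `bptt_mean` with
probability 0.95 and `bptt_mean/2` otherwise, then perturbed by N(0, 5) and
clamped to [5, 2·bptt_mean]; the learning rate is scaled by
`length/bptt_mean`. Hidden state persists across windows within an epoch and
is detached between windows. Regularization follows the named dropout
taxonomy: embedding dropout zeroes whole token rows, input/hidden/output
dropouts are locked (variational) activation masks, and weight dropout
(DropConnect) masks the hidden-to-hidden matrices once per forward pass.
Loss is categorical cross-entropy under AdamW with global-norm gradient
clipping.

The classifier replaces the decoder with concat pooling — last valid hidden
state, element-wise max and mean over time, padding positions excluded — and
two dense layers (ReLU between them). Fine-tuning proceeds in four stages of
gradual unfreezing over the layer groups {embedding}, {LSTM 1},
{LSTM 2–3}, {head}; stage k trains the last k groups. Discriminative
learning rates halve per group toward the input (at base 0.008:
0.008/0.004/0.002/0.001 from head to embedding) and apply in every stage.
Each stage runs a one-cycle schedule (cosine rise to the base rate over the
first 30% of steps, cosine fall to base/10⁴); the final stage defaults to 30
epochs with the best epoch selected on the validation metric (accuracy for
single-label tasks, Fmax for multi-label, AUC for detection; ties resolve to
the earliest epoch). Sequences longer than the 1024-token maximum context
are fully encoded but the leading excess is run without graph construction,
so only the trailing 1024 tokens receive gradient — truncation concerns
backpropagation, not the input. Forward/backward ensembles average output
probabilities element-wise.

The CNN baseline consumes a 1024×46 input (one-hot over the 26 residues ‖
20-column PSSM log-odds, zero-padded; sequences beyond the maximum keep
their N-terminal part, a documented and configurable choice). Architecture:
seven valid-padding convolutions of kernel 3 with filter counts
1024/512/512/512/256/256/256, each followed by ReLU and max-pooling by 2,
then dense layers 512/256/128 with 25% dropout and a softmax output.
Training minimizes categorical cross-entropy with AdaMax. A `width_scale`
parameter shrinks every width while preserving the layer structure; the
tests and the acceptance study run width_scale 1/8–1/16 at input length 512
(the synthetic sequences are ≤100 residues, so nothing is truncated). The
minimum input length for the seven pool stages is 512.

## Numerical core

No GPU framework is used: `protlm.nn` is a small float64 reverse-mode
autodiff engine (tape-based, topological backward) with exactly the
primitives the models need. Every primitive's gradient is tested against
central finite differences. Initialization required care at these widths:
uniform ±1/√fan init lets activations shrink several-fold per layer, which
at three LSTM layers (or seven conv layers) starves the output of signal and
traps training on the unigram plateau. The package therefore uses a gain-3
uniform init for LSTM input weights with forget-gate bias 1, and He-style
init for convolutional/dense-ReLU layers. Default optimizer settings
(AdamW, lr 10⁻², weight decay 10⁻⁶, clip 2.0) were fixed once on the
deterministic-corpus sanity task.

## Synthetic data

The generator emulates the structure the protocols depend on. Families are
defined by (i) a short implanted residue motif (defaults: six distinct
5-mers) and (ii) a family-specific residue composition: the uniform
background tilted by a log-normal factor of scale 0.75 per family, drawn
from `family_seed` so pre-training and task corpora can share family
definitions while sampling disjoint clusters. The compositional tilt is what
real protein families exhibit (hydrophobicity/charge biases) and is what
gives a language model something persistent to learn at this scale; with an
iid background, an LM rationally forgets everything but transient motif
state and pooled features carry no family signal. Identity clusters are
built by mutating a common ancestor: each non-motif position substitutes
independently with probability `mutation_rate`, uniformly over the other 19
standard residues, so expected ancestor–member identity over non-motif
positions is exactly 1 − mutation_rate (verified by Monte-Carlo in the
tests). There are no indels — point substitutions suffice to exercise the
splitting, redundancy and profile machinery — and non-standard residues
appear only when explicitly enabled.

The multi-label task ties each term to its own motif with implantation
probabilities decaying geometrically (common → rare), so the ≥50-occurrence
label filter has terms on both sides of its boundary; labels are derived by
scanning the final sequences, making them exactly recoverable by a
brute-force motif scan at zero noise. The detection benchmark builds one
binary dataset per family (positives = that family), with whole clusters
held out for testing and at least one positive cluster guaranteed on each
side of the split.

What passing these tests shows — and does not show. The synthetic corpora
have no indels, no domain architecture, no realistic evolutionary model and
much lower sequence entropy structure than real proteins; results here
demonstrate that the machinery (splits, protocols, optimization, metrics,
attribution) behaves as specified and that the qualitative phenomena
(transfer benefit, redundancy benefit, split-leakage direction) appear under
controlled conditions. They do not certify real-data performance levels.

## Study design and problem sizes

The acceptance study (scripts/acceptance.py) and the test suite use these
desk-scale conditions, chosen once:

- **Pre-training corpus**: 6 families × 40 clusters × 3 members (720
  sequences, ~58k tokens), LM profile E=32, H=64, 20 epochs.
- **Transfer task**: same families (`family_seed` shared), 20 clusters × 4
  members, cluster split 60:20:20, training capped at 200 sequences;
  fine-tuning budget one epoch per unfreezing stage plus a 6-epoch final
  one-cycle stage; means over 3 classifier seeds against an identically
  budgeted from-scratch control.
- **Split-mode comparison**: a deliberately redundant corpus (4 clusters per
  family × 8 members, mutation rate 0.02) trained for 20 epochs into the
  overfitting regime, where memorization of near-duplicates separates the
  random-split from the cluster-split perplexity cleanly.
- **Detection**: 3 binary datasets, stratified cluster-level validation
  split (plain cluster splits frequently produce single-class validation
  sets at a few hundred examples; stratification restores the protocol's
  intent), 4 epochs, snapshot at the highest validation AUC.
- **Multi-label**: 8 terms over the transfer-task corpus, term filter at 50
  training occurrences, Fmax-selected epoch.
- **Attribution**: a two-family, motif-only corpus (composition bias 0) so
  the motif is the classifier's only usable signal; integrated gradients use
  the all-padding baseline with `<BOS>` kept (its path contribution is zero,
  so the per-residue map satisfies completeness), midpoint rule, post-softmax
  probability by default (pre-softmax exposed by flag). Completeness is
  asserted as an absolute gap ≤ 0.01 on the probability scale: a relative
  criterion degenerates when F(input) ≈ F(baseline).

## Design choices where the design was open

- Cluster-mode split ratios target cluster counts, not sequence counts —
  this makes training-set subsampling (which removes whole clusters,
  nested across fractions under one seed) well defined.
- The "LM acquires non-trivial knowledge" margin (held-out accuracy ≥ 5×
  the 1/26 uniform baseline) is tested on a strongly biased corpus
  (composition scale 1.5): at the default tilt the composition-only Bayes
  accuracy is 0.158 < 5/26 ≈ 0.192, i.e. the margin is
  information-theoretically out of reach there for any model.
- The internal profile-search PSSM provider performs query-anchored,
  ungapped, same-length iterative search (3 iterations, per-residue score
  threshold 0, at most 50 hits), the no-indel analogue of position-specific
  iterative BLAST; the external adapter shells out to `psiblast`
  (3 iterations, e-value 0.001) and remaps the ASCII PSSM columns from
  BLAST residue order to the package's alphabetical order.
- Leakage direction: at these scales the clean-vs-leaky accuracy gap sits
  below the seed-to-seed noise floor (consistent with the finding that the
  effect is small); the stochastic test asserts that leakage never clearly
  hurts (leaky ≥ clean − 0.1) while the exact database-composition
  guarantee (clean databases exclude every held-out-cluster member) is
  checked exhaustively.
- Information content uses flat training-frequency estimates in log base 2
  (base configurable); terms unseen in training fall back to the maximum
  observed IC. Fmax/Smin use a threshold grid of step 0.01 on [0, 1].
- AUC ties count ½ (averaged ranks); AUC50 uses stable ordering with
  midpoint counting for score ties, and equals AUC whenever negatives ≤ 50.

## Known limitations

- Desk scale only: corpus sizes, model widths and epoch counts are orders of
  magnitude below production pre-training; absolute perplexities and
  accuracies are not comparable to published large-corpus numbers.
- The numpy core is single-threaded and eager; it favours correctness and
  testability over speed.
- The internal profile search requires equal-length homologs (no-indel
  corpora); real data should use the PSI-BLAST adapter.
- Intermediate LM fine-tuning on the task corpus and hierarchy-aware
  multi-label output layers are deliberately out of scope.
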
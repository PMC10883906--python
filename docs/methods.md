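# Methods

## Problem and model

`guideoff` predicts whether a CRISPR Cas-9 guide will cleave a candidate
genomic site that imperfectly matches it (an *off-target*). The input is a
pair of 23-mers — the sgRNA spacer plus PAM context, and the candidate
target-DNA site — differing only by substitution mismatches (no bulges).
Coordinates are 1-based with position 1 at the PAM-distal end and the NGG
PAM at positions 21–23; position 21 of the guide is the wildcard N.

### Pair encoding

Each sequence is one-hot encoded over four channels in the fixed order
(A, T, C, G), and the two matrices are superposed with a logical OR. A
matched position therefore activates one channel (row sum 1) and a
mismatched position two (row sum 2). The wildcard N encodes as an all-zero
row and never counts as a mismatch: it carries no base identity, and
inventing a fifth base channel for it would let the model key on an
artifact of the file format rather than on sequence. An optional fifth
*direction* channel is 1 exactly at mismatches where the higher-precedence
base (precedence A > T > C > G) originates from the DNA strand, and 0 at
every match — the encoding without the direction bit is symmetric in its
two arguments, with it the ordered base pair at every position is
recoverable.

### Classifier

The classifier is a generic parameterized recurrent network: one or two
recurrent layers (vanilla RNN, LSTM or GRU cells; optionally
bidirectional) read the 23×C matrix position by position; the final
time-step state — concatenating the last forward state and the
first-position backward state when bidirectional — feeds a stack of dense
hidden layers whose widths halve layer by layer starting from the hidden
size, each followed by ReLU and dropout; a 2-unit output layer is trained
with softmax cross-entropy under Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).
Design points the architecture sketch leaves open, fixed here:

* the first dense layer is `hidden_size` wide even under bidirectionality
  (its input is then `2·hidden_size`);
* dense widths must stay ≥ 2 and at most six hidden layers are allowed,
  which makes the admissible hidden-layer count a function of the hidden
  size (`max_hidden_layers`);
* with two recurrent layers, dropout at the same probability is applied
  between them;
* zero hidden layers wires the recurrent representation straight to the
  output layer.

The networks are implemented directly in NumPy with hand-derived
backpropagation through time. This keeps the dependency surface to the
scientific Python stack and gives the interpretation stage exact
analytical gradients with respect to inputs and intermediate activations.
Correctness is enforced by central-difference gradient checks over every
parameter family and cell type in the test suite.

### Training protocol

The benchmark population is ~1:230 positive:negative, so training uses
balanced bootstrapping: each mini-batch holds equal class counts, with
negatives drawn without replacement and positives resampled with
replacement. One *epoch* is defined as one pass over the negatives — the
majority class — so every real negative is seen exactly once per epoch
and epoch cost stays comparable to plain training. Splitting is a
stratified 60/20/20 train/validation/test partition, randomized over loci
(largest-remainder apportionment per class, so subset label counts are
within one record of exact proportionality). The decision threshold is
the argmax of the two output scores; AUPRC is computed as step-wise
average precision (no linear interpolation, which inflates the area under
heavy imbalance) and is the model-selection objective throughout.

## Hyperparameter search

Eight discrete genes define a model: batch size {32…256, doubling},
epochs {10…100 by 10}, recurrent layers {1, 2}, bidirectionality,
dropout {0.10…0.50 by 0.05}, hidden size {32…512, doubling}, hidden
layers {0…6, capped by hidden size} and learning rate
{1e-5…5e-1, 1–5 ladder}. Excluding the hidden-layer gene the grids
multiply to 72 000 combinations; including it under the width-≥-2 cap,
489 600.

The search is a genetic algorithm over genomes, fitness = validation
AUPRC, with a plain variant (full generational replacement) and an
elitist variant (the 4 fittest carried unchanged, 16 offspring fill the
rest). Parents are chosen by binary tournaments without replacement (ties
to the earlier index); crossover swaps values gene by gene with
probability 0.3; mutation redraws genes uniformly from their grids with
probability 0.2 (the redraw may return the current value, so the per-gene
change rate on a g-value grid is 0.2·(g−1)/g). Defaults: population 20,
20 generations, one cell type per run (crossing cell types is not
meaningful). Offspring whose hidden-layer count exceeds the cap for their
(possibly newly acquired) hidden size are re-clamped and the clamp
logged. Each distinct genome is trained once and its fitness cached; the
returned winner is the best individual *ever evaluated*, not merely the
best of the final generation — with elitism the two coincide, without it
they need not. Elitist best-so-far trajectories are non-decreasing by
construction.

The GA correctness tests use a deterministic separable landscape with a
unique mid-grid optimum over a 64-genome space, checked against
exhaustive enumeration. On a completely unstructured (random-permutation)
landscape a GA has no gradient to follow and degrades toward biased
random sampling — that regime is exercised for the replay/robustness
tests but not for optimum recovery.

## Interpretation

Integrated gradients attribute the target-class *logit margin* (log-odds) to input
entries: entry (i, c) receives
(x − x′)ᵢ𝒸 · mean over α ∈ {(k−½)/steps} of ∂score/∂xᵢ𝒸 at x′ + α(x − x′).
The baseline x′ is the all-zero matrix — the natural "no sequence
information" reference for a binary encoding. The midpoint Riemann rule
makes attributions exact for linear scorers at any step count; the
completeness residual |Σ attribution − (score(x) − score(x′))| is checked
against max(1e-3, 10/steps · |score gap|) and against an 8192-step
path-integral oracle. Default 50 steps; residuals are reported.

Feature aggregation follows a per-sample normalize-then-average scheme:
attributions are L1-normalized over the features *present* in the sample
(the nonzero entries of the encoded input; L1 chosen over L2/max so the
normalized magnitudes of one sample sum to 1), summed per position over
the position's active channels, keyed by (position, sgRNA base, DNA base)
with a match/mismatch/wildcard tag, and averaged separately over
positive-labeled, negative-labeled and all samples. A feature absent from
a sample contributes zero to that sample's term, which makes the
all-sample mean exactly the prevalence-weighted mean of the two
class-conditional means. Features (and neurons) rank per aggregate by
the *magnitude* of their mean attribution: "top contributing" features
include strong negative correlates — e.g. PAM-proximal mismatches — not
only positive ones, and a class whose evidence is the absence of
features (a rule rewarding mismatch-free seeds) still surfaces its rule
positions at the top. Region summaries report signed means and
positively-correlated mismatch-feature counts over PAM (21–23),
PAM-proximal seed (16–20), seed core (11–15) and PAM-distal (1–10);
the seed sub-region boundary is configurable (literature places it at
15/16 ± 1).

Neuron-level importance is a conductance along the same input path: for
each dense hidden layer, each neuron accumulates (gradient of the target-class
logit margin with respect to its post-ReLU activation at the step midpoint) ×
(its activation increment over the step). Summed over a layer's neurons
this telescopes to the score gap, so completeness carries over up to
discretization. Activation heatmaps export the raw post-ReLU activations
(samples × neurons).

## Synthetic benchmark generator

The generator emulates the published benchmark's statistical shape:
uniform random 20-mer spacers + NGG PAM, targets derived by injecting a
uniform 0–6 substitutions at distinct non-wildcard positions (position 21
is N on the guide, a concrete random base on the DNA), default class
ratio 230 negatives per positive, optional symmetric label noise. Labels
come from a planted rule over per-region mismatch counts; the default —
positive iff the PAM is intact and positions 16–20 are mismatch-free —
encodes the accepted biological picture that PAM-proximal mismatches
suppress cleavage while distal ones are tolerated. The class ratio is hit
by rule-conditioned rejection (proposals routed into per-class pools), so
the realized mismatch-count distribution is uniform *per proposal* and
rule-conditioned per class. Everything derives from a single seed;
identical configurations produce byte-identical datasets.

What the generator does not emulate: realistic sequence composition (GC
content, genomic context), guide-level structure (all pairs are
independent, so locus-level random splits carry no guide leakage), and
assay noise beyond iid label flips. Passing the recovery study therefore
demonstrates that the pipeline can learn and *re-discover* a positional
mismatch rule end to end — not that it reaches any particular accuracy
on real off-target data.

## Study sizes and numerical choices

The end-to-end recovery study (`guideoff.experiments.planted_rule_recovery`)
uses 20 000 noiseless records at a 9:1 negative:positive ratio — at this
problem size a 230:1 ratio would leave ~17 test positives, too few for a
stable AUPRC, so the generator keeps 230:1 only as its default while the
study uses the milder ratio — with a compact bidirectional LSTM (hidden
64, two dense layers, dropout 0.1, batch 64, 10 epochs, learning rate
1e-3; every value on the search grids). It reports held-out AUPRC and how
many of the top-10 positive-aggregate features lie on the rule positions
16–20. GA statistics in the acceptance script use 20 seeded runs on the
64-genome landscape.

Other numerics: parameters initialize U(−1/√H, 1/√H); dropout is
inverted (masks scaled by 1/(1−p)) and disabled at evaluation; softmax
and sigmoid are computed in overflow-safe form; non-finite training loss
aborts with the epoch index; metric ties in rankings break by first
occurrence so ranks are always permutations. All randomness flows from
`numpy.random.SeedSequence` spawns of a single user seed: parameter
initialization, batch composition, bootstrap resampling and dropout use
separate streams, and identical seeds reproduce identical trained
parameters bit for bit.

## Known limitations

* Substitution mismatches only; insertion/deletion bulges, context
  windows beyond the 23-mer and epigenetic features are out of scope.
* The NumPy training loop is CPU-bound and single-threaded apart from
  BLAS; it is sized for the study scales above, not for GPU-scale
  hyperparameter sweeps over the full benchmark.
* Published real-data scores (e.g. test AUPRC ≈ 0.72 for the best LSTM on
  the 153k-locus benchmark) are not reproduced here: they require the
  external dataset and large-scale training. The property suite — exact
  encoding bits, gradient checks, attribution axioms, GA-vs-enumeration,
  balanced-batch conservation and planted-rule recovery — is the
  verification surface instead.
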
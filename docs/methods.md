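# Methods

## Model and framing

Z-DNA calling is treated as per-nucleotide segmentation. Each chromosome
is a `C x L` multi-channel signal; a network maps it, length-preserving,
to two per-position logits whose softmax gives the probability that the
nucleotide lies in a Z-DNA-forming region. The segmentation framing is
what makes learning feasible at all: labelled regions average ~400 nt,
so a few hundred regions provide >10^5 minor-class nucleotides, at a
nucleotide-level class imbalance of roughly 1:50 inside the selected
windows — which is why ROC AUC and F1 (not accuracy) are the metrics
reported throughout.

Assumptions inherited by everything downstream:

- features are strand-symmetric; labels are unstranded intervals;
- a marker's presence in *any* tissue is informative (union
  aggregation) — tissue identity is deliberately discarded;
- window boundaries carry no information (chromosomes are tiled evenly,
  never cut relative to labels).

## Channels

- One-hot sequence (4 channels). `N` and other ambiguity codes are not
  one-hot-able; `N` yields an all-zero column (no fifth channel), any
  other letter is an error.
- Dinucleotide B→Z transition energy: position `i` carries the energy of
  step `(i, i+1)`; the final position repeats its predecessor so the
  channel stays length `L`. Steps containing `N` get the table's maximum
  (least Z-favourable) energy. The shipped table follows the classical
  Z-Hunt energetics (kcal/mol per dinucleotide in anti/syn context;
  alternating d(CG) lowest at 0.66, d(AT) highest at 5.9) with junction
  costs B–Z = 5.0 and Z–Z = 4.0 kcal/mol; it is a config input and can be
  replaced by any complete 16-entry TSV.
- Junction energies enter as two constant channels. A constant channel
  min–max scaled per chromosome would collapse to zero, so these two are
  instead divided by the table's maximum energy at matrix-construction
  time (staying in [0, 1] while retaining their value). The generic
  `scale_channel` operation keeps the convention constant → all-zeros,
  avoiding 0/0 on degenerate data channels.
- Binary marker channels pass through scaling unchanged.

All channels are stored run-length encoded. RLE is exact (round-trip
equality is a tested invariant), matches the long-constant-stretch
structure of peak indicators, and keeps a genome-scale `L x C` matrix in
RAM; slicing is random-access by binary search over run boundaries.

## Windows, splits, folds

Defaults (all configurable): window length 5000 nt; background ratio 3
(zero-label windows sampled genome-wide, uniformly, without replacement —
sampling with replacement would duplicate training windows); train
fraction 4/5 with per-stratum test size `round(n/5)`; 5 folds. Both the
split and the folds are stratified by (chromosome, label presence);
strata smaller than 2 go wholly to train with a warning. Fold assignment
deals shuffled stratum members cyclically over folds ordered by current
global load, which bounds both the per-stratum spread and the global
fold-size difference at one. Trailing partial windows are dropped. All
randomization flows from a single integer seed; identical inputs and
seed reproduce the window set byte-identically.

## Networks and training

The grammar: optional convolutional block (1–2 stride-1 layers, kernel
sizes odd, 1–17, same padding `(k-1)/2`, ReLU between layers), optional
recurrent block (1–2 stacked LSTMs, optionally bidirectional —
implemented as a second cell over the reversed sequence, outputs
concatenated), exactly one final dense block (per-position linear
layers, dropout 0.5 between them, final width 2). Hybrids are
convolution → recurrence → dense. Cross-kernel max pooling is available
as an option on the conv block but off by default: pooling along the
length axis would break the per-position output contract, and pooling
across kernels is subsumed by the dense block.

Reference architectures shipped as presets: `best_rnn` (two
bidirectional LSTMs + two dense layers with dropouts), `best_cnn` (one
conv layer, 3 kernels + one dense layer), `interpretation_cnn` (two
kernel-5 conv layers; receptive field 9 nt).

Training is RMSprop (rho 0.9) on mean per-nucleotide two-class
cross-entropy, gradients averaged over minibatches of whole windows.
The two output units with softmax are the consistent reading of a
two-neuron head with a sigmoid-like output; the reported probability is
the class-1 unit. Defaults: learning rate 1e-3, batch 16 windows, 30
epochs. Early stopping on validation F1 (a held-aside fraction of the
training windows) is implemented but off by default: at 1:50 imbalance
the F1 at a fixed 0.5 cutoff is zero through the early epochs, so
patience-based stopping truncates training spuriously on small
fixtures. Divergence (non-finite loss) aborts with a diagnostic rather
than returning a broken model. The layer stack, backpropagation
(including input gradients) and the optimizer are implemented in numpy
inside the package; analytic gradients are verified against central
differences in the test suite.

Prediction over long ranges is chunked (default 100 kb) with an overlap
of the receptive-field half-width, making the stitched CNN output
bit-identical to a single pass; recurrent models, whose context is
unbounded, are evaluated in one pass.

## Annotation

One model per held-out fold (trained only on its 4 training folds; the
alternative — retraining on everything — would leave no honest pooled-F1
surface for threshold selection); each model predicts the full genome;
probabilities are averaged. Threshold selection maximizes F1 over the
distinct observed probabilities, scoring each candidate `t` by the calls
`p >= t` (every realizable call set is scored; F1 ties resolve to the
smallest threshold). Region assembly applies, in order: strict `p >
threshold` runs → join gaps `< 11` bp → drop lengths `< 11` bp (a gap of
exactly 11 stays split; a length of exactly 11 is kept) — 11 bp being
one turn of the helix. Because selection uses `>=` and assembly `>`, the
pipeline assembles at `nextafter(t, -1)` so the selected call set is
reproduced exactly. Assembly is idempotent on its own indicator
re-encoding and is tested against an independent O(L) dense-scan oracle.
Two annotations are combined as a union in which regions closer than
10 bp merge. The published operating threshold 0.343 ships as the
config default; `auto` re-derives it for the data at hand.

## Interpretation

Importance: the CNN is retrained with L1 penalties as part of the loss
(subgradient `lambda * sign(w)` added before RMSprop) plus a
preconditioned proximal shrink `lr * lambda / sqrt(cache)` after each
update. The proximal step is what produces *exact* zeros — plain
subgradient descent oscillates around zero instead — and exact zeros are
the pruning criterion: channels whose first-layer weights are all zero
are dropped. The penalty pair defaults to (1e-2 on the first layer,
1e-3 elsewhere): the first-layer weights gate the input features, and
nullifying unnecessary features is the purpose of the exercise; the
opposite ordering is one flag away. Surviving channels are ranked by
their extreme signed first-layer weight, positives divided by the
maximum positive, negatives by the largest negative magnitude (the
normalization has two defensible readings; this per-sign-group reading
makes the top feature of each sign score exactly +/-1).

Input maximization: the patch width is the receptive field (9 nt for the
kernel-5 pair). The objective is the central nucleotide's Z probability;
the ascent follows the logit margin `z1 - z0` — a strictly monotone
transform with the same maximizer whose gradient does not vanish when
the softmax saturates (maximizing the probability directly stalls at
machine-1.0 before the optimum is reached). RMSprop with learning rate
1e-2; values clipped to [-1, 1] after every step, the widened range
making negatively influencing features visible. A monotone safeguard
returns the best iterate; convergence is declared after 50
non-improving iterations.

Motif extraction: the four sequence channels are mutually dependent
(a real one-hot column sums to 1), so they are optimized jointly under
per-column simplex constraints (entries in [0, 1], columns summing to 1,
equality constraints with analytic Jacobians) by SLSQP, all other
channels held fixed at the box-optimal patch (fixing them at zero is the
other defensible choice; the box-optimal patch is the default because
the sequence solve is a refinement of that optimum). The start point is
the Euclidean projection of the box patch's sequence rows onto the
simplex. Column sums are exact to 1e-6 after a final clip-and-renormalize.
On hand-built linear models both solvers land on the closed-form optima
exactly (box: `sign(w)`; simplex: per-column argmax) — a tested contract.

## Synthetic fixtures

The generator emulates: multi-chromosome genomes (default 3 x 100 kb) of
i.i.d. uniform ACGT; 12 planted regions with lengths ~ Normal(400, 80)
clipped at 100 nt, separated by >= 2 kb, carrying an alternating-GC
motif tiled to the region length; informative binary tracks equal to the
label indicator with whole-peak Bernoulli dropout at 10% (peak-level
dropout mimics a marker missing in some tissues; per-base noise would
not); and noise tracks with matched interval count and length
distribution placed uniformly. Three chromosomes ensure stratified
splitting and folding are genuinely exercised.

What the fixtures do **not** emulate: read-level ChIP-seq noise, peak
callers, GC-content and mappability biases, repeat structure,
correlated marker co-occurrence, supercoiling physics, or the weak and
partially redundant signal of real compendia. Passing the recovery tests
therefore demonstrates that the machinery is correct and can extract the
statistical structure it assumes — not that real-genome performance
figures would be reproduced; those depend on data at a scale outside
this package's fixtures.

The motif-recovery experiment trains on the one-hot channels of a
fixture with no informative omics tracks: a near-perfect omics channel
would let the model ignore sequence entirely, leaving no motif to
recover. The planted alternating-GC matrix is compared at both tiling
phases (region starts have random parity, so the learned preference can
lock onto either phase) and the better correlation is scored.

## Problem sizes and numerical choices

Test and example runs use 100–300 kb genomes, 500–5000 nt windows, and
2–60 training epochs; training the small CNNs takes seconds on one CPU,
the full suite a few minutes. Float64 throughout (gradient checks to
1e-6; exactness contracts — slicing, stitching, receptive-field
containment — are bitwise). Degenerate inputs have defined behaviour:
empty vectors, empty window sets, single-class labels (AUC reported
missing), strata of one window, constant channels, zero-weight models,
chromosomes without peaks (all-zero channel), and background shortfalls
(take all, warn). AUC uses the midrank tie convention.

## Known limitations

- LSTM training is O(L) per window in Python-level steps; practical
  here, but genome-scale recurrent training would want a compiled loop.
- The L1 penalty pair interacts with RMSprop's normalization; the
  preconditioned proximal form used here is one principled choice among
  several, and rankings near the pruning boundary can shift with it.
- Motif width is fixed by the architecture (9 nt for the kernel-5
  pair); longer motifs require wider receptive fields.
- The energy table ships with literature values at dinucleotide
  resolution; tetranucleotide or methylation-dependent effects are out
  of scope.
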
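# Methods

## The model

`epimotif` implements paired multi-task convolutional sequence models for
histone-modification prediction:

* a **cell model** predicts, for one cell type, which of its histone marks
  (e.g. H3K4me1, H3K27ac, ...) modify a genomic bin — one sigmoid output per
  mark;
* a **mark model** predicts, for one histone mark, which cell types carry it
  at a bin — one sigmoid output per cell type.

The input is the one-hot encoded 1000-bp DNA context of a 200-bp genome bin
(rows A, C, G, T; an `N` becomes `[0.25, 0.25, 0.25, 0.25]`).  The network is
a stack of three units, each

    convolution -> ReLU -> batch normalization -> max pooling,

followed by a sigmoid-activated dense layer and an independent sigmoid output
per task.  The loss is mean binary cross entropy over tasks; an elastic
penalty `l1*sum|w| + l2*sum w^2` applies to the dense layer's weights only, so
the convolutional filters are free to grow into motif detectors.  Training is
minibatch RMSprop with early stopping on validation loss; the parameter state
with the best validation loss is restored after training.

The position of batch normalization relative to the nonlinearity is a design
point on which conventions differ; this package places it between the ReLU
and the pooling, and an empirical comparison showed the alternative (batch
normalization before the ReLU) trains no better on the synthetic benchmark.

All layers, backpropagation and the optimizer are implemented in numpy
(channels-last, BLAS matmuls).  This keeps CPU training bit-reproducible for
a fixed seed; every backward pass is validated against central finite
differences in the test suite.

### Data preparation

Peak calls (BED with a −log10 q-value column, narrowPeak convention) are
cleaned per track:

1. drop peaks with −log10(q) < 2 (boundary kept) or length > 10,000 bp
   (boundary kept);
2. drop any peak sharing ≥ 1 bp with a genome-blacklist interval (the whole
   peak, no trimming);
3. keep only bases covered by ≥ 2 replicates when two or more replicates
   exist (a single replicate passes through unchanged);
4. merge to a minimal sorted disjoint set (touching intervals merge).

Filtering precedes the replicate intersection: filtering first means a
low-quality call in one replicate cannot create consensus support.

The genome is cut into consecutive 200-bp bins (trailing partial bins
dropped).  A bin is positive for a task when the fraction of the bin covered
by that task's merged peaks reaches the overlap threshold (default 0.5;
candidates 0.5–0.9, inclusive boundary, denominator = bin length).  Bins
positive for no task are discarded, so every training example carries at
least one positive label — a consequence is that a model may also learn
*negative* evidence (absence of another task's motif).  Bins whose 1000-bp
context would cross a chromosome end are dropped rather than padded, which
keeps the input dense and avoids inventing an N-fill convention.  Examples
are split 2:1:1 into train/validation/test by seeded random permutation
(largest-remainder apportionment); a chromosome-holdout mode is available but
not the default.

### Hyper-parameters

Full-scale defaults: 320/300/300 filters, dense 1000, batch 128, RMSprop lr
0.001, ≤ 20 epochs, patience 5000 validation checks, and a random-search
grid of six paired (L1, L2) rows — L1 1e-7…6e-7 against L2 2e-8…8e-7 —
crossed with the overlap thresholds.  Filter widths default to (19, 11, 7)
and pools to (4, 4, 4), all configurable and recorded in every artifact.

Patience is counted in validation checks at minibatch granularity (an
epoch-level reading would be vacuous against the 20-epoch cap).  Model
selection in the search uses mean validation accuracy at cutoff 0.5.

**Desk scale.**  The package's benchmark runs on a 2-Mbp synthetic genome
with ~1,700 examples, about three orders of magnitude less data than the
full-scale setting.  `reduced_config()` therefore uses 32/16/16 filters,
widths (15, 7, 5) — the first-layer width covers the widest planted motif —
dense 64, batch 32, lr 0.02, L1 3e-4 on the dense layer, validation checked
every 10 minibatches, ≤ 10 epochs.  The larger learning rate and smaller
batch compensate for the few updates per epoch; the stronger L1 curbs
memorization, which at this scale otherwise outruns feature learning.  These
values were chosen by validation-loss comparison on the default bundle, the
same selection rule the full-scale search uses.  Because a small network
occasionally settles in a poor optimum — typically sacrificing one task —
`fit_with_restarts()` trains eight random restarts and keeps the one whose
weakest task has the highest validation AUC (ties broken by validation
loss); the multi-task model must serve every task, and selection touches
only the validation split.

## Interpretation

**Filter → PWM.**  For each first-layer filter, every window of the test
sequences whose post-ReLU activation exceeds

    threshold = (alpha_max − alpha_min) · beta

(extremes over all positions of all test sequences) is collected; base counts
plus a 0.5 pseudocount, normalized, give the PWM.  β runs over
{0.3, …, 0.8}; the PWM with the highest information content
(`sum_j (2 + sum_b p log2 p)`, uniform background) wins; filters whose best
PWM has zero information content, or that never activate, yield no motif.

**Influence (inference score).**  A filter is nullified by replacing its
post-ReLU activation map with its scalar mean over all positions of all test
sequences; its influence on a task is the sum over test sequences of the
squared change in that task's predicted probability.  The across-task sum is
the filter's scalar score; both are reported, along with the per-sequence
mean, since the raw sum scales with the test-set size.  Influence measures
prediction *sensitivity*, not accuracy: any filter whose readout weights are
non-trivial moves the output when nullified, whether or not it encodes a
clean motif.  At full scale, with hundreds of filters and abundant data, most
non-motif filters end up with negligible readout; a desk-scale 32-filter
network uses nearly all its capacity, so the contrast between motif-matching
and non-matching filters is present but much weaker (about 2–3× rather than
an order of magnitude in our runs; the acceptance suite records this
honestly).

**Interactions.**  For a filter pair (i, j) and a task, 2000 test sequences
are sampled (with replacement when fewer are available) and, per sequence,
the squared prediction changes `dPi`, `dPj`, `dPij` under single and joint
nullification are computed.  The no-intercept least-squares fit

    dPij = alpha·dPi + beta·dPj + gamma·(dPi·dPj)

defines the interaction coefficient γ (positive = cooperative, negative =
antagonistic) with its two-sided p-value.  The third regressor is the
elementwise product of the two single-nullification changes, and the
regression variables are per-sequence squared changes (the scalar
influence sums the same quantities over the test set; the 2000-point
regression needs them per sequence).  The regression is symmetric under swapping i and
j (α and β swap, γ is invariant).  Either side may also be a *set* of
filters: a learned motif is often carried redundantly by several filters,
and nullifying one member leaves its duplicates active, diluting the
measured interaction; joint nullification of the whole group removes the
motif's information.  Two caveats on γ magnitudes: for pairs whose
nullification barely moves the predictions, the product regressor is
quadratically small and the fitted |γ| can be arbitrarily large (an
ill-conditioning artifact, recognizable by its p-value), so |γ| values are
comparable only between pairs of similar effect size; and the *sign* of γ
for a given pair is far more stable across sequence resamples than its
magnitude.

**Motif merging.**  Pairs of motifs are aligned over all offsets with ≥ 7
aligned columns, in both orientations (the reverse complement is searched;
omitting it would miss half the matches).  The per-offset score is the mean
per-column Pearson correlation of the frequency vectors; significance comes
from a permutation null (target columns shuffled, ≥ 1000 permutations,
seed-fixed, +1-corrected), E = p × number of candidate targets.  This is a
functional substitute for Tomtom with the same threshold semantics (E < 0.1
to merge, E ≤ 0.5 for known-motif annotation) but an empirical null.  Each
unordered pair is compared once (query = lower index) so best-hit ranking is
symmetric; best hits rank by E with ties broken by overlap, then name.
Motifs that are mutual best hits at E < 0.1 are joined; connected components
of the graph are the unique motifs.  A merged PWM pools the members' site
counts (frequency × n_sites) at their best alignment offsets over the union
of columns — a closed-form replacement for re-running de novo discovery on
the pooled sites, using the same information.

**Conservation.**  Motif sites are found FIMO-style: log2 odds against the
0-order marginal of a 5th-order Markov background fitted to the scanned
sequences (add-one smoothing); p-values come from a dynamic program over the
per-column integer score distribution (1000 bins over the score range), and
scoring uses the same discretization, so exhaustive enumeration over all
4^w words reproduces the p-values exactly.  Both strands are scanned; sites
at p ≤ 1e-5 are kept, overlapping strand-pair sites both reported.  Per
motif, the mean per-base conservation over its sites is correlated with its
influence score (Pearson r, two-tailed t-test p).  The full 5th-order model
is used by the synthetic generator; the scanner's score model uses the
0-order marginal, the standard behaviour of the tool it mirrors.

**Model profile clustering.**  Models are clustered on binary unique-motif
presence profiles with hamming distance and average linkage; the dendrogram
is exported as Newick with merge-height branch lengths.

## The synthetic study

`GrammarSpec`/`generate_study` emulate the *structure* of a multi-cell-type
histone-mark compendium at desk scale: 2 cell types × 3 marks over a 2-Mbp,
4-chromosome genome; per-track peak calls with 2 jittered replicates
(σ = 30 bp, 5% dropout); low-quality calls (5%), overlong calls and
blacklist-region calls included as cleaning-pipeline fodder; a per-base
conservation track (Beta(2,8) baseline, +0.5 at planted sites, clipped to 1);
and a MEME file plus JSON table of the full ground truth.

The grammar plants five sharp motifs (widths 10–14, consensus base 0.95):
mark1 is driven by a cell-specific motif, mark2 by a motif shared across
cells, mark3 by a cooperative AND pair — a peak is positive only when both
partners are present.  Single-motif rules implant a homotypic pair of
instances (TF sites cluster in vivo); instances land on a random strand near
the peak centre, so every positive bin's 1000-bp context contains them.
Negatives are made non-trivial in three ways.  Each non-rule motif appears in
10% of other peaks, and a lone AND partner in 40% of non-pair peaks, so the
pair task cannot be solved from either partner alone.  And 30% of each
track's peaks are *co-marked*: one locus carries two marks of the same cell,
with both rules' motifs implanted and the peak written to both tracks.
Histone marks co-occur at shared loci in vivo, and without co-marked peaks
the discard-all-negative-bins representation makes the labels one-hot, so a
model could predict any mark from the mere absence of the other marks'
motifs instead of learning its own motif.

Width and sharpness were set by an ideal-observer analysis: a 1000-bp,
two-strand context gives ~2000 background windows per example, so a motif
must carry clearly more information than ~11 bits for *any* detector to
separate planted from background instances; 8–9-bp motifs fail this bound
(the true-PWM scan oracle tops out near AUC 0.8), while 10–14-bp motifs at
0.95 consensus give an oracle ceiling around 0.95.  Peaks of all tracks
occupy disjoint slots separated by a 500-bp gap so that one bin's context
cannot reach a neighbouring track's planted motif.

What the generator does **not** emulate: read-level noise (no reads or
fragment model — peaks are intervals), copy-number or mappability artifacts
beyond the blacklist decoys, realistic motif families (planted PWMs are
independent and sharp), and genomic composition structure (the background is
i.i.d. with a mild AT bias).
Passing tests therefore demonstrate that the implementation recovers a known
grammar under clean conditions, not that the full-scale biological results
would reproduce.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open throughout; wiggle input converts from
  its 1-based convention at the reader.
* Touching intervals merge; boundary overlap fractions are inclusive (≥).
* AUC uses midrank tie handling; single-class tasks yield NaN with a warning.
* The scan p-value DP and the site scores share one integer discretization;
  p-values are monotone in the discretized score (raw scores within one
  rounding quantum may swap).
* Batch normalization uses momentum 0.9 running statistics; inference is
  deterministic.  BCE is computed from logits in stable form.
* Zero-variance motif columns correlate as 0 in the comparator; degenerate
  (all-zero) interaction regressors produce a flagged record, not a fit.
* Model artifacts are a directory of `.npy` files plus JSON — zip containers
  embed timestamps and would break byte-identical reruns.
* All randomness flows from explicit seeds; derived seeds stay below 2^31.

## Known limitations

* The numpy network is CPU-only and desk-scale; the full 320/300/300
  configuration on millions of peaks is out of reach here by design.
* The permutation-null motif comparator is less powerful than Tomtom's
  analytic null at a given permutation count; borderline matches (E near
  0.1) can flip between runs of different power.
* Influence separation between motif-matching and non-matching filters is
  muted at desk scale (see above); rankings within a model remain
  informative, absolute ratios are not comparable across scales.
* `MarkovBackground.sample` is a per-base python loop — fine for toy
  genomes, not for chromosome-scale generation (the default generator uses
  an i.i.d. background for exactly this reason).
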
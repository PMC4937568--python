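# Methods

## The model

`peaknet` predicts, for each genomic site, a vector of probabilities that
the site is accessible (DNase-hypersensitive) in each of T cell types,
from the site's DNA sequence alone.  A site is a fixed-width window
(default 600 bp) one-hot encoded as a 4 x L matrix (rows A, C, G, T; an
ambiguous N contributes 0.25 to every row so columns stay normalized).

The network is a multi-task convolutional stack:

    [conv -> batchnorm -> ReLU -> maxpool] x k
    -> flatten -> [linear -> batchnorm -> ReLU -> dropout] x m
    -> linear -> sigmoid (T outputs)

Convolutions are valid (unpadded) cross-correlations, so the first-layer
filters are directly interpretable as position weight matrices scanned
across the sequence.  Max pooling uses non-overlapping windows; a
trailing partial window is kept as the max of the remainder rather than
dropped, so no sequence positions are silently discarded.  Batch
normalization sits between every linear/convolution operation and its
ReLU; conv-layer statistics are pooled over batch and positions
(per-filter), and eval mode applies running moments maintained as an
exponential moving average (momentum 0.9, epsilon 1e-5).

Training minimizes binary cross entropy summed over the T targets and
averaged over the minibatch, by RMSprop (per-parameter squared-gradient
EMA, decay 0.98, epsilon 1e-8) on shuffled minibatches of 128.  The
library default learning rate is 0.002; the desk-scale experiments use
0.005, which roughly halves the epochs needed on the synthetic grammar
without destabilizing training.  Gradients are exact analytic backpropagation
through every stage, including the batch statistics of batch norm;
a finite-difference check is part of the test suite.  The entire model
and optimizer are implemented in NumPy (float32 by default, float64 for
gradient checking); the numerical core of this package is its own.

## Early stopping

Training monitors a held-out validation set each epoch and stops after
`patience` (default 12) epochs without improvement, restoring the
best-epoch parameters (including batch-norm running moments).  The
monitored quantity is the validation mean AUC by default
(`TrainConfig.monitor="auc"`), with validation loss available as an
alternative.  The accuracy criterion is deliberate: on desk-scale data
the model's *ranking* keeps improving for many epochs while its held-out
*calibration* (BCE) deteriorates, because confident errors on a few
mislabeled (label-noise) sites dominate the loss.  Monitoring loss stops
training near epoch 0 with clearly inferior AUC; monitoring what the
procedure is meant to maximize does not.

## Transfer seeding

A model for a new (single-target) data set is seeded from a pretrained
multi-task model by copying every stage below the final linear layer
verbatim — convolution filters, fully connected weights, batch-norm
scale/shift and running moments — and re-initializing only the final
layer for the new target count.  Fine-tuning is exactly one pass through
the new data at half the learning rate; more passes overfit small
single-target tasks.

## Interpretation

*Filter PWMs.*  A first-layer filter is summarized by scanning it over a
sequence set (post-batch-norm, post-ReLU activations in eval mode),
collecting every filter-width window whose activation exceeds half the
filter's maximum over the whole set, and counting nucleotides
position-wise.  A total pseudocount of 1 per position (0.25 per
nucleotide) keeps PWMs defined for sparsely supported filters.  Each
supporting window counts once, unweighted.  Information content is

    IC = sum_i [ -sum_j b_j log2 b_j + sum_j m_ij log2 m_ij ]

with background b (uniform by default) charged once per position and
0 log 0 = 0; a deterministic W-position PWM against uniform background
scores 2W bits.  PWMs are exported in MEME minimal format so motif
comparison against a reference database can be done with standard
external tools (e.g. TomTom against CIS-BP); motif-alignment statistics
are deliberately not re-implemented here.

*Influence by nullification.*  A filter's influence is measured by
replacing its post-ReLU activation map everywhere with a single scalar —
the filter's mean activation over all positions of all evaluation
sequences — and recording the change in mean predicted accessibility per
cell type; the influence score is the sum of squares of that vector.
The scalar (rather than per-position) constant is the only reading that
blocks positional as well as magnitude information.  Influence profiles
can be clustered (average linkage, Euclidean) to reveal modules of
filters with shared cell-type preferences.

*What filter PWMs can and cannot show.*  Half-max counting
faithfully recovers a motif when a single filter carries it: on the
tiny single-conv-stage fixtures the planted 7/8-mers come back at mean
per-position total-variation distance well under 0.3.  Under the
desk-scale two-stage architecture, however, the trained representation
distributes motifs across several filters that each cover a portion,
with the second convolution stage combining them — most strongly for
the 19-bp CTCF-like motif, whose best-matching single filter stays at
TVD ~0.5-0.6 from the planted PWM however long training runs.  This is
a property of the learned representation, not of the extraction: the
same behaviour is the norm for compendium-scale models, where CTCF is
represented by many filters focused on overlapping portions of its
site.  Influence ranking inherits the effect: ablating one of several
redundant partial detectors moves predictions little, so a distributed
motif's best-matching filter can sit below the median influence.

*Motif insertion.*  The complementary protein-centric probe replaces the
central W bases of a set of sequences with a motif (consensus, or
samples drawn from its PWM) and reports the per-sequence, per-cell
prediction change.

## Variant scoring

*Saturation mutagenesis.*  All 3L single-base mutants of an L-bp
sequence are batched through the model in eval mode.  Per position, the
loss score is the reference prediction minus the minimum mutant
prediction, and the gain score is the maximum mutant prediction minus
the reference; gain + loss = max - min >= 0 always.  The reference base's
delta entry is zero by definition.

*SAD profiles.*  A SNP's accessibility difference profile is
prediction(alt) - prediction(ref), per cell type, on the
model-input-length window centered on the variant (variant at index
floor(L/2)).  VCF records are 1-based and converted at the boundary;
only ACGT single-nucleotide alleles are scored — indels and symbolic
alleles are skipped with a logged reason; a reference allele that
disagrees with the genome raises an error naming the position.
Multi-allelic records yield one profile per alternative allele.
Profiles are ranked by the largest per-cell |SAD|, and profiles whose
|mean| exceeds a threshold (default 0.1) are flagged.

## Peak harmonization

Per-sample peak calls are reduced to fixed-width sites: each peak is
extended from its integer midpoint to the target width (600 bp; edge
peaks that would leave the chromosome are dropped by default, or the
window is shifted inside bounds with `edge_policy="clip"`).  Within a
chromosome, midpoint-sorted peaks are then merged greedily: while any
adjacent pair overlaps by more than the bound (200 bp), the
most-overlapping pair (leftmost on ties) is replaced by one peak whose
active-cell set is the union, whose weight is the sum of the two
weights (a fresh peak weighs the number of samples it is active in),
and whose midpoint is round((w1 m1 + w2 m2)/(w1 + w2)), rounding half
up.  Merging iterates to convergence — a single left-to-right pass
cannot guarantee the overlap bound, since a merged midpoint moves —
and the implementation (a lazy heap over a linked list, re-scoring only
the two overlaps a merger changes) is checked against a brute-force
reference that rescans every pair at every step.  All coordinates are
BED-style 0-based half-open.

## The synthetic compendium

Because no public data download can be assumed, the package ships a
generator for a miniature multi-cell compendium with a fully known
regulatory grammar: N sites (default 10,000) of L bp (default 600),
T cell types (default 4), and a motif vocabulary of three planted
motifs — an AP-1-like `TGASTCA`, a CTCF-like 19-mer
(`TGGCCASCAGGWGGCGCTA`) and a GC-rich `GGGGCGGG` — each cognate to a
set of cells (one cell listens to two motifs, so the cell code is not
diagonal).  Each motif is planted independently with probability 0.35
at a uniform position in the central half of the site, on a uniform
random strand.  A site is accessible in a cell iff it contains a motif
cognate to that cell; labels are then flipped with probability 0.05
(`label_noise`), which caps the attainable test AUC near 0.95.

Two design points matter:

- **Labels equal content.**  Short motifs arise by chance in long
  random backgrounds (a 7-mer pattern appears in roughly one in seven
  600-bp uniform sequences), which would break the equivalence between
  "was planted" and "is present" and put an information ceiling far
  below the noise ceiling.  Backgrounds (and the genome's pads and
  spacers) are therefore rejection-sampled to contain no motif match,
  plants are exact PWM samples (consensus columns carry probability 1;
  degenerate IUPAC columns split evenly), and a site is redrawn in the
  rare event that a plant junction fabricates a spurious match.  The
  clean activity matrix consequently equals both the plant record and
  an independent content scan, and a Bayes classifier on ground truth
  attains AUC 1 at zero noise.
- **Ground truth is exported.**  The generator emits a synthetic genome
  FASTA (sites concatenated with motif-free spacers), per-sample BED
  files with a manifest, a site BED, an activity table, a VCF of
  labeled variants and a JSON of every plant, so the peak-preparation
  and variant-scoring paths are exercised through real files.

Labeled variants: a *causal* SNP substitutes a full-information position
of a planted motif with a base the PWM forbids (destroying the match);
a *bystander* SNP hits background at least 10 bp from any plant.

What the generator does **not** emulate: genomic background composition
and repeats, graded binding affinities, motif syntax (spacing/orientation
rules), chromatin context beyond sequence, and read-level noise.
Passing the end-to-end checks therefore demonstrates that the
implementation — data plumbing, optimization, interpretation and variant
scoring — behaves correctly on a task where truth is known; it does not
certify accuracy on real compendia.

## Architectures and problem sizes

The full-scale default mirrors the three-stage design appropriate for
millions of training sites: conv 300x19 (pool 3), 200x11 (pool 4),
200x7 (pool 4), then fully connected 1000, 1000 with dropout 0.3.

The desk-scale experiments in the test suite and acceptance script use
`small_architecture`: two conv stages of 50 filters each (width 19 and
7) and one small fully connected stage, with aggressive pooling in the
second stage.  The pooling choice is deliberate: with ~10^4 training
sites, a positional flatten of ~50 x 47 features lets the network
memorize one-hot training sequences outright instead of learning
shift-invariant motif detectors (observed as train loss collapsing
while held-out AUC stalls, even when true-motif filters are hand-seeded
at initialization).  Pooling the second stage to a handful of positions
removes that capacity while leaving the motif-combination code
learnable.

Problem sizes used by the acceptance script: the default grammar
(10,000 sites) for learnability, motif recovery, influence, saturation
mutagenesis (50 planted test sites) and SAD scoring (100 causal + 100
bystander SNPs); a 4,000-site five-cell grammar for the transfer
experiment; 200 random instances for the peak-merge oracle; n = 10,000
for the null-AUC calibration.  These sizes keep every statistical
margin wide while the whole script completes on a single CPU.

## Numerical choices and degenerate inputs

- float32 forward/backward by default; float64 for oracles and gradient
  checks.  Probabilities are clipped to [1e-7, 1-1e-7] inside the
  evaluation-mode BCE because a float32 sigmoid rounds to exactly 0/1.
- Midpoint rounding in peak merging is half-up (`floor(x + 0.5)`).
- AUC uses midrank tie handling; AUPRC is the step-wise
  average-precision sum.  Cells with single-class test labels are
  excluded from means and reported as NaN.
- Dead filters (no positive activation anywhere) are skipped in motif
  export with a logged notice; `filter_to_pwm` raises a dedicated
  `DeadFilterError`.
- `merge_peaks` rejects unsorted input and chromosomes split across
  runs rather than silently re-sorting.
- Merge tie-breaking (equal overlap) favors the leftmost pair, making
  the greedy procedure deterministic.
- Sequences containing characters outside {A, C, G, T, N} are rejected
  with the offending position named.

## Known limitations

- Single-strand model: no reverse-complement weight sharing or
  prediction averaging (the synthetic grammar plants on both strands,
  so filters learn both orientations where needed).
- The NumPy implementation is CPU-bound; it is sized for desk-scale
  experiments, not for compendium-scale training.
- Motif comparison to databases is delegated to external tools via the
  MEME export rather than re-implemented.
- The loss/gain-versus-conservation and GWAS fine-mapping analyses that
  motivate variant scoring require external annotation resources and
  are out of scope; the package computes the scores themselves.
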
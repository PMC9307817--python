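# Methods

## Overview

`somaticnet` calls somatic SNVs and short indels from matched tumor/normal
aligned reads. Instead of a statistical allele-frequency model with
hand-tuned filters, it treats each candidate locus as an image-classification
problem: the aligned reads around the locus are encoded as a fixed-shape
multi-channel numeric image, and a convolutional network outputs the
probability that the locus is somatically mutated. A permissive pileup
pre-filter proposes candidates, the network scores them, and a
germline-proximity post-filter removes calls that look like germline
contamination. Training uses weak supervision: labels come from an ensemble
callset (or, in the synthetic studies, from simulator truth with injectable
label noise), not from curated annotation.

## Input encoding

For every candidate the encoder builds one tensor with reads as rows,
alignment columns as columns, and five channels:

| channel | content | scaling |
|---|---|---|
| base | A=0.25, C=0.50, G=0.75, T=1.00; deletion=-0.50; padding=0 | categorical codes in [-1,1] |
| base quality | Phred / 40 | clipped to [0,1] |
| mapping quality | MAPQ / 60 | clipped to [0,1] |
| strand | forward=+1, reverse=-1 | 0 where no base |
| reference base | base code of the local reference | -1 at inserted columns |

The normal sample occupies the left half of the width and the tumor the
right half, so the classifier sees the matched evidence jointly. SNV images
are `(100, 70, 5)`: up to 100 reads per sample, 35 columns per sample
consisting of the candidate locus repeated in 5 adjacent columns (signal
amplification) with 15 columns of sequence context on each side. Indel
images are `(140, 150, 5)`: up to 140 reads and 75 columns per sample, with
the candidate anchor at column 37. Indels are encoded in place: inserted
bases occupy their own columns immediately right of the anchor (reference
channel = -1 there, since those columns have no reference locus), deleted
reference bases show the deletion code, and flanking context is truncated on
the right to keep the fixed width. Indels longer than 35 bp do not fit and
are rejected (the pre-filter never emits them). Candidate repetition is not
applied to indels because their in-place width is variable.

Per-sample coverage above the row budget is reduced by seeded uniform
subsampling; missing rows are zero in every channel. Rows are ordered by
leftmost aligned position with CRC32(name) as the tie-break, which is
deterministic across processes (unlike Python's salted `hash`). The
reference channel is broadcast down all rows that hold a read; fully padded
rows stay zero in all channels so that shape invariants ("padding rows are
padding in every channel") hold exactly. In indel rows the column-to-
reference mapping is per-row to the right of an insertion, which is the only
self-consistent reading of in-place encoding.

## Pre-filtering

The scan tallies quality-gated allele counts (base quality >= 15, mapping
quality >= 10) at every position in both samples and emits a candidate when
the tumor shows at least 2 alternate reads at fraction >= 0.02 and the
normal's alternate fraction is <= 0.25. These defaults are deliberately
permissive: the network, not the pre-filter, is the classifier, and the
pre-filter's job is to keep essentially every true somatic site (measured
sensitivity >= 99% at VAF >= 0.1 and 60x depth) while discarding ~99.5% of
positions. Indel events are keyed by parsimony-trimmed, left-aligned
representation (the `vt`-style normalization algorithm) so candidates,
truth records, and VCF output all share one canonical form. Multi-allelic
positions emit one candidate per alternate allele. BED regions restrict the
scan when provided.

Note on monotonicity: raising the count/fraction thresholds can only shrink
the candidate set, and the tests assert this. Raising the *quality gates*
can both add and remove candidates — they change the depth denominator, so
surviving fractions can move either way. This is a property of any gated
pileup filter, not an implementation artifact.

## Networks and training

Both classifiers are built on an in-package numpy layer stack (convolution,
ReLU, batch normalization, average pooling, dense) with explicit forward and
backward passes. Writing the backward pass by hand is what makes guided
backpropagation exactly testable (see below); convolutions are evaluated
tap-wise as per-tap GEMMs on contiguous shifted copies, with persistent
scratch buffers so allocator churn does not dominate single-CPU training.

The SNV model (`plain_conv`) has 10 convolutional blocks, each
convolution -> ReLU -> batch normalization, with two average-pooling layers
between blocks, then global average pooling and dense layers of 256, 128,
and 64 units into a single sigmoid output. Filter counts grow linearly with
depth (32, 64, ..., 320), giving ~3.4 million trainable parameters at
`scale=1.0`; `scale` multiplies all filter counts to produce desk-scale
variants (scale 0.25 ~ 253k parameters, scale 0.1 ~ 81k). Pooling sits
after blocks 1 (4x4) and 6 (2x2): the candidate-fraction signal trivially
survives early averaging, and early pooling is what makes a numpy backend
train in minutes rather than hours at one CPU. The indel model default is
`inception_style`: blocks of parallel 1x1 / 3x3 / 5x5 convolution branches
(each conv -> BN -> ReLU) concatenated along channels — a scaled-down
inception backbone suited to the wider indel images.

Training minimizes binary cross-entropy with the Adam optimizer at
mini-batch size 32. The production-style default learning rate is 1e-4; the
desk-scale studies use 1e-3, chosen once because with thousands rather than
millions of training sites an epoch is only tens of optimizer steps and
1e-4 leaves the model undertrained inside a 10-epoch budget. Early stopping
watches validation loss (15% split) with patience 3, restores the best
weights, and is suppressed for the first 6 epochs — small-batch validation
loss fluctuates strongly during warmup and would otherwise abort runs that
are still converging. One master seed fans out to weight initialization,
shuffling, batching, and read subsampling; training is bit-reproducible on
a fixed BLAS (BLAS thread scheduling is the only residual source of
nondeterminism we know of, and single-threaded runs are exactly
reproducible).

Model selection under label noise inherits the same rule: validation labels
are then themselves noisy, which biases model selection slightly downward;
this is part of what the noise-degradation study measures.

Training this objective from scratch is non-convex, and a minority of
initialization seeds converge to a visibly poor basin (validation accuracy
stuck near 0.75-0.8 while other seeds on identical data reach 0.95+). The
study drivers therefore use random restarts: up to two differently seeded
attempts per model, keeping the attempt with the best validation accuracy
and stopping early once validation accuracy reaches 0.85 (0.80 under label
noise, whose validation ceiling is lower). Selection is on validation data
only — held-out test sets are never consulted — and each attempt keeps the
same per-model epoch budget.

## Germline post-filter

For each somatic call the matched normal is scanned in a +/-10 bp window.
Any non-reference allele (SNP or short indel) whose quality-gated read
fraction strictly exceeds 10% is a suspected germline variant; a call that
overlaps or lies within 1 bp of one is flagged `GERMLINE_PROX`. Flagging is
non-destructive and idempotent; records are retained with their filter
status. Detection reuses the pre-filter quality gates. The asymmetric
constants (10 bp scan, 1 bp removal radius) are implemented literally; the
wide scan matters for indel spans whose left-aligned anchor can sit several
bases from the call. The 10% rule is strict: a fraction of exactly 0.10
does not trigger detection, and the boundary tests pin all four
fraction/offset edges.

## Calling pipeline

`call_variants` composes scan -> encode -> score -> threshold -> germline
filter -> VCF. Candidates are routed to the SNV or indel model by class;
scores below the threshold (default 0.5) are flagged `LOW_SCORE`; the
germline filter runs on the remainder. Encodings are produced and scored in
batches of 64 so peak resident encodings stay bounded. Output is
coordinate-sorted VCF 4.2 with `SCORE` (6 decimal places, so
threshold sweeps on a re-read callset reproduce the original curve), per-
sample `DP`/`AD`, and the three filter states. Two runs with the same seed
produce byte-identical VCF bodies.

## Evaluation

Matching is exact on normalized representations; genotype is ignored.
Precision-recall curves sweep every distinct score; because matching is by
unique normalized site, the per-threshold counts can be accumulated in one
pass, and the tests verify equality with a brute-force per-threshold
recount on random callsets. F1 is the harmonic mean. VAF-stratified
reports bin truth by designed VAF (half-open bins); false positives are
binned by observed tumor VAF, and bins without truth are reported as empty
rather than zero. Non-PASS calls are excluded unless requested.

## Synthetic data

The simulator emits a random uniform-composition contig, germline SNPs
(heterozygous at rate 1e-3/bp, homozygous 3e-4/bp), and spiked somatic
SNVs/indels at designed VAFs, then synthesizes pre-aligned single-end reads
with exact CIGARs: uniform read starts, per-read Bernoulli allele carriage
(probability designed VAF x purity for somatic, 0.5/1.0 for het/hom
germline), uniform substitution errors at 0.002/base (~Q27), base qualities
uniform on 25..40, MAPQ 60, and 50% strand balance. Planted variants keep
>= 50 bp spacing so events stay independently resolvable; indel truth is
stored left-aligned. `dilute_tumor` mixes seeded subsamples of normal reads
into the tumor at a given fraction, emulating subsample-and-merge purity
dilution.

Defaults mirror the study conditions used throughout the tests: 60x tumor /
40x normal coverage, purity 1.0, VAF ~ Uniform(0.2, 0.6), read length 100.

Training labels from simulator truth use hard negatives: the non-mutated
class is drawn first from pre-filter candidates (loci with real error-driven
alternate reads) and only then padded with random non-variant loci. This
mirrors the hard-negative character of weak supervision — negatives that
some caller believed in — and is what teaches the classifier to reject the
borderline candidates it will actually meet at calling time; with easy
(zero-alt) negatives only, calling precision drops measurably.

What the simulator deliberately does not model: platform-specific error
profiles and quality miscalibration, indel sequencing errors, GC and
mappability bias, read pairing (no encoder channel depends on it),
soft-clipping, phasing between neighboring variants, and multi-contig
genomes. Consequences worth keeping in mind: error bases carry the same
quality law as correct bases, so the base-quality channel is uninformative
here (on real data it is not); with no indel noise, indel candidates are
nearly all real, so the indel model's negative class is synthesized from
non-variant loci encoded under a hypothetical insertion. Passing the
synthetic studies therefore demonstrates that the pipeline's machinery is
correct and that the learning problem is solvable at desk scale — not that
the trained toy models would transfer to real tumors.

## Desk-scale study sizes

The validation studies are sized for minutes-scale runs at one CPU, as the
package's own choice of desk scale:

* Parameter recovery: 3000 training + 500 held-out sites (half mutated),
  scale 0.25, <= 10 epochs. Clean-label held-out accuracy is required to
  reach >= 0.95; training on labels with 10% random flips must cost < 5
  accuracy points against clean truth. The pytest suite runs this at a
  single seed; `scripts/acceptance.py` uses the same sizes with the
  caller-provided seed.
* Purity dilution: 50 spiked SNVs at VAF 0.5, 60x, normal fractions
  {0, 0.3, 0.5}; recall must be non-increasing with dilution and precision
  must stay >= 0.9.
* Pre-filter sensitivity: 800 spiked variants at VAF >= 0.1, 60x, 150 kb.
* Attribution: guided backprop equals the plain gradient on a
  rectifier-free model and a hand-derived chain rule on a one-rectifier
  net; averaged over dozens of mutated sites, summed column importance must
  peak inside the 5 tumor candidate columns.

## Guided backpropagation

Implemented as a backward pass in inference mode (batch normalization uses
its running statistics, so maps depend only on the input being explained)
where every ReLU zeroes the backward signal wherever the forward activation
or the incoming gradient is negative. The map is the guided gradient of the
output logit; the sigmoid is monotone, so using the logit rather than the
probability changes only a positive scale factor. Display normalization
divides by the maximum absolute value. For the averaged-map studies the
high-VAF site cutoff defaults to VAF >= 0.3.

## Numerical and degenerate-input choices

* All tensor math is float32; batch-norm statistics use a single-pass
  sum/sum-of-squares estimate (adequate for unit-scale activations).
* Zero-coverage candidates encode as all-padding halves; the caller decides
  their fate (they cannot pass the pre-filter, which requires tumor reads).
* Ties in PR thresholds are handled by treating each distinct score as one
  operating point; `max_f1` reports the first threshold attaining the
  maximum.
* Reads with MAPQ 0 are still encoded; inclusion is the pre-filter's
  decision.
* VCF is the only 1-based boundary; everything internal is 0-based
  half-open.

## Known limitations

* The numpy backend trains desk-scale models only; production-scale
  training (millions of sites, full filter widths) would need a GPU
  framework, though the architecture definition scales by construction.
* Single-end encoding ignores pair-level artifacts (e.g. FFPE strand
  bias across mates).
* Exact-match evaluation has no distance tolerance for indels beyond
  left-alignment; complex-representation equivalence (MNP decomposition)
  is out of scope.
* The germline filter consults only the matched normal, not population
  allele-frequency databases.
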
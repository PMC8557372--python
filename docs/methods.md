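# Methods

`tn5prefer` re-implements a complete analysis of Tn5 transposase insertion
preference on naked genomic DNA: where the enzyme inserts relative to
genomic features, what drives that preference (sequence motif, DNA shape,
nucleotide dependence, DNA methylation), and how to remove the resulting
bias from single-base insertion signal.  This note documents the models,
the parameter choices, and what the synthetic validation does and does not
establish.

## Coordinates and the insertion-site shift

All coordinates are 0-based half-open (BED convention) internally; 1-based
formats are converted at the boundary.  Tn5 transposition duplicates 9 bp
of target sequence, so the two sequenced fragment ends flanking one
insertion event bracket a 9-bp duplication.  The single-base event center
is recovered by shifting the forward fragment end by +4 bp and the reverse
(half-open) end by −5 bp; on a fragment of length exactly 9 both shifted
positions coincide, and in general `minus − plus = length − 9`.  Fragments
shorter than 9 bp cannot carry a duplication and are rejected with a
counter, not an error.

*Read-level input:* only fragment-level shifting is defined.  For
single-end data the reverse-end site is undefined, and the package does not
guess; BAM/BED input is assumed to be pre-filtered upstream (flags, MAPQ,
duplicates), and the package applies no alignment-level filtering itself.

**Paired fragments.** Two adjacent fragments whose coordinates overlap by
exactly 9 bp evidence one insertion event seen from both sides.  These
high-confidence sites (`paired_fragment_sites`) are the preferred input for
PWM building and classifier training.  Only the coordinate criterion
(overlap exactly 9) is enforced; the reverse-complementarity of the
duplicated sequence is automatic in double-stranded data and is not checked
at the sequence level.

## Feature enrichment

For a feature with merged interval length `L`, total site count `T` and
mappable genome size `G` (non-N bases, minus blacklist overlap when one is
supplied — whether to subtract the blacklist is a flag, as conventions
differ):

    E = L · T / G,    statistic = log2(O / E)

`O` is counted directly in the merged intervals (half-open membership,
strand-merged counts).  Significance is the two-cell (inside/outside)
chi-square goodness of fit with df = 1 — the minimal GOF consistent with
one O/E pair per feature — without continuity correction by default
(intended counts are large; a Yates flag exists for small-count toys).
FDR is Benjamini–Hochberg within one sample across its feature list, and
the per-sample rows are assembled into a sample × feature matrix with
complete-linkage hierarchical clustering (Euclidean distance) of samples.
Overlapping intervals within a feature are always merged before measuring,
so no base is counted twice.

## Motif model

Because candidate windows are already center-aligned at insertion sites, no
motif *discovery* is needed: the PWM is the positional base-frequency
matrix over windows (19 bp default for the core motif, 51 bp for the
classifier's motif vector), with pseudocount, each event weighted by its
count.  Minus-strand sites contribute the reverse complement of their
window; strand-merged sites contribute the forward window.  The background
is the genome-wide base composition.

Scanning follows FIMO semantics: log-odds scores discretized to a grain of
1e−4 of the score range, the exact null score distribution computed by
dynamic programming over positions under the background model, per-window
p-values from its survival function, and BH q-values with the number of
scanned windows (both strands) as the test count.  Hits are windows with
q below threshold (default 0.001); overlapping hits are all retained.
The DP is exact up to discretization, which the test suite verifies against
exhaustive enumeration over all `4^w` sequences for small widths.  Width is
bounded at 30 so the DP table stays small.

Usage taxonomy: a site is *inside* if its position falls within any hit
interval (strand-agnostic); a hit is *used* if at least one site falls
within it; fractions are over distinct sites and distinct hits, with
used/unused reported absent when there are no hits.

## Feature encodings (51-bp windows)

* **Motif vector** — per-position log-odds of the observed base under a
  51-bp PWM; its sum equals the full-window scan score (this identity is
  tested).  The per-position log-odds of the observed base was chosen over
  alternatives (e.g. column maxima) exactly because of that identity.
* **DNA shape** — 14 descriptors by sliding-pentamer lookup.  Intra-base-
  pair shapes (MGW, ProT, Shear, Stretch, Stagger, Buckle, Opening, EP)
  give one value per pentamer center; inter-base-pair step shapes (Shift,
  Slide, Rise, Tilt, Roll, HelT) carry two central steps per pentamer,
  averaged to the center so every shape yields the same 47-long vector
  (edge positions without a full pentamer are dropped, not imputed —
  imputation would inject undefined information).  Shape tables are TSV
  assets (`pentamer, shape, value1[, value2]`); the bundled default is a
  **synthetic** table of seeded Gaussian values per pentamer, sufficient
  for planted-signal recovery and shuffled-table controls, and explicitly
  not a biophysical model — published pentamer tables can be dropped in.
  The shuffled-table negative control permutes values across pentamers with
  a seed, preserving the value multiset exactly.
* **k-mer one-hot** — mono/di/trinucleotide indicators per start position
  (51×4, 50×16, 49×64 columns), encoding nucleotide dependence directly.
* **Methylation** — per-position percent methylation from a per-cytosine
  track (0 where no cytosine is covered).

Windows containing N or running off a contig are dropped with a counter;
shape and PWM tables are undefined on N.  Controls are uniform random
N-free genomic positions, seeded.

## Classifier

Elastic-net logistic regression distinguishing insertion sites (label 1)
from random genomic controls (label 0), balanced classes:

    (1/n) Σ loss(yᵢ, xᵢᵀβ + β₀) + λ ( α‖β‖₁ + (1−α)/2 ‖β‖₂² )

Features are min-max standardized to [0, 1] (bounds computed on the
training matrix and reapplied, with clipping, to held-out data) so
coefficient magnitudes are comparable as importance measures; this explicit
scaling is the only standardization applied.  α defaults to 0.5
(configurable).  λ is selected on a log-spaced grid from λ_max (the
smallest penalty zeroing all coefficients) spanning 3 decades, 12 values by
default, by stratified K-fold cross-validation (K = 10) minimizing CV
deviance; the reported accuracy is the CV-fold mean at the selected λ,
with accuracy = (TP+TN)/(TP+TN+FP+FN) at a 0.5 threshold.  The grid was
kept at 12 points over 3 decades (rather than a denser/wider path) because
the deviance curve is flat near its minimum on these problems and the
selection is CV-noise-limited, not grid-limited.

The optimizer is accelerated proximal gradient (FISTA) with soft
thresholding for the L1 part, a fixed step 1/L with
L = σ_max([X,1])²/(4n) + λ(1−α) (spectral norm by power iteration),
warm starts along the descending λ path, an unpenalized intercept, and
convergence declared when the maximum coefficient change drops below 1e−5
(1e−6 would change reported accuracies by < 0.001 at several times the
cost).  The implementation agrees with an independent saga-based solver to
~1e−5 in coefficients on reference problems (see the model tests).

Fold assignment is a seeded stratified shuffle of row *positions*;
consequently the fit is deterministic for a fixed matrix and seed but not
invariant under row permutation (hash-based row identity was judged not
worth the complexity).

Cross-sample generalization trains on a seeded stratified 70% split of one
sample and evaluates on every sample's 30% split, reporting the full
train × test accuracy matrix.  Coefficient importance reshapes |β| into
parameter (block) × window-position rows, with row and column sums as
total parameter and position importance; k-mer blocks sum their letter
indicators per position, and positions absent from a block are excluded
from sums rather than zero-filled.

## Methylation: matched-context 9-mer procedure

The genome is tiled into non-overlapping 9-bp bins (trailing partial bins
and N-containing bins dropped).  Bin methylation per condition is the
*unweighted* mean percent over covered cytosines (a coverage-weighted mean
is not computable from percent-only tracks); bins with no covered cytosine
are *absent*, not 0 — treating coverage gaps as unmethylated would
misclassify them.  Eligible bins are classified by the two conditions'
levels, taking "> 0" literally on the bin mean: A-only (>0, =0), B-only,
Both, None.  Insertion frequency (raw count within one condition; the
final Z-scaling absorbs library-size scale) is averaged per unique 9-mer
within each group, 9-mers not present in all four groups are discarded
(so sequence context is identical across groups), and the retained means
are Z-scored within each condition.  9-mers are not reverse-complement
collapsed.  The 11-level stratification puts exactly-0% bins in level 0
and splits (0, 100] into ten equal left-open right-closed levels,
summarizing each level's per-bin insertion counts by quartiles (top and
bottom 1% trimming is available for plotting exports).

## k-mer bias model and signal correction

Insertion counts are modelled per masked k-mer context centered at the
(strand-merged) position, on the '+' strand, k odd (default 19, matching
the span over which sequence affects insertion).  For each context `w`:

    rate(w)  = (site-weighted count + pc) / (genome occurrences + pc)
    scale(w) = mean rate / rate(w)

with pseudocount pc = 0.5 by default, guarding rare contexts.  Contexts
spanning a contig edge or containing N are excluded from numerator and
denominator alike.  The table is sparse (only contexts occurring in the
genome), so full k = 19 is memory-bounded by the genome, not by 4¹⁹; a
mask string over {X, .} can coarsen the context, and an all-'.' mask
collapses everything to one context, making correction the identity.
Corrected signal is raw count × scale(context), rescaled so the global
total equals the raw total (downstream peak-caller thresholds see the same
depth); positions with undefined context pass through uncorrected and are
counted.  This rate-ratio scaling is this package's own definition of
k-mer correction; other tools differ in normalization details.  Peak-set
comparison partitions two interval sets into shared (≥ 1 bp overlap) and
specific intervals.

## Synthetic data and what the tests show

The generator emulates naked-DNA tagmentation at desk scale.  The genome is
i.i.d. from a configurable base composition; when a PWM is planted,
`n_planted_motifs` instances drawn column-wise from it are written at
seeded non-overlapping positions, reflecting that real genomes carry motif
occurrences far above i.i.d. expectation (an i.i.d. genome alone yields
essentially no q < 0.001 scan hits, because BH q-values cannot beat a
uniform empirical p distribution).  Insertion events are multinomial over

    propensity(i) ∝ exp( w_m·pwm_score(i) + Σ dinucleotide weights over the
                         19-bp context + w_s·mean shape value over the
                         context + w_meth·meth(i) )

with `meth(i)` the fractional (0–1) methylation.  Sampling is with
replacement, so multi-count pileups arise as in real pileups.  A
`SimulationTruth` records the exact normalized propensity and all planted
parameters.  One global seed fans out to fixed per-stage child seeds.
Fragments are emitted in flanking pairs with exact 9-bp overlaps so
paired-fragment recovery reproduces the planted positions; the *outer*
fragment ends are random, which deliberately mimics the fact that a
fragment's other end belongs to a different event — shifted-site sets are
therefore a 1:1 mix of true events and incidental ends, and analyses that
need pure events use the paired subset.

Notable calibrations (chosen from the model, not tuned to outcomes):

* `motif_weight = ln 2` makes the propensity equal the PWM odds ratio, so
  the window distribution at sampled sites equals the PWM product
  distribution and PWM recovery is unbiased.  The recovery check uses a
  breadth-0.6 consensus PWM on a 500-kb genome: a sharper PWM's consensus
  would simply never occur in a desk-scale i.i.d. genome, capping
  achievable recovery regardless of the estimator.
* The dinucleotide recovery condition uses double-centered weights (zero
  row/column sums) so mononucleotide content carries no first-order signal
  and the mono/dinucleotide comparison isolates true dependence.
* The two-condition methylation demonstration uses an AT-rich composition
  (0.7/0.1/0.1/0.1) so 9-mers recur often enough for the shared-9-mer
  filter to retain several hundred contexts at a 450-kb genome; with a
  uniform composition virtually every 9-mer is unique at this scale.
* Problem sizes in the test-suite and acceptance script (genomes of 100 kb
  to 500 kb, 15 000–100 000 insertions, 2 000 + 2 000 classifier rows) are
  the package's desk-scale defaults; planted effects are set well clear of
  the pass thresholds so the checks measure correctness, not luck.

What passing does **not** show: the generator has no chromatin, nucleosome
periodicity, PCR duplicates, sequencing error, mappability structure, or
real shape physics (the bundled table is synthetic), so recovered
accuracies and importance maps validate the machinery, not biological
effect sizes.  Quantitative results on real data (accuracy ranges, usage
percentages, shared-9-mer counts) depend on real genomes and libraries and
are outside what desk-scale synthetic validation can reproduce.

## Numerical and degenerate-input choices

* Exact-p discretization: scores are binned at 1e−4 of the score range;
  DP mass is conserved to ~grain·width and p-values are monotone in score.
* `log2(O/E)` with O = 0 is reported as −inf and flagged; features with
  E = 0 or E = total are untestable (p absent), excluded from FDR.
* Zero-variance features map to 0 under min-max scaling, with a warning.
* Ties in subsampling are broken by position order after the seeded draw.
* All-zero propensity (e.g. an all-N genome) is an error, not a silent
  empty result.
* Empty hit lists leave motif-usage fractions undefined (`None`), never 0.
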
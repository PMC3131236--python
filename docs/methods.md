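# Methods

## The promoter ratio statistic

A gene's bivalency balance is summarised as the ratio of H3K4me3 to
H3K27me3 ChIP-seq signal in a promoter window anchored at the TSS. The
window is strand-oriented and half-open, default −3,000…+3,000 bp
(alternative extents such as −4 kb/+1 kb or −0.5 kb/+2 kb are a
`WindowSpec` away); for symmetric windows orientation is immaterial, which
the test suite proves as an invariant. A read is counted in every window it
overlaps ("any-overlap", the common convention); midpoint and 5′-end rules
are selectable. Counting is implemented with sorted-coordinate binary
search — for half-open intervals the overlap count is
`N − #(end ≤ window_start) − #(start ≥ window_end)`, exact because the two
excluded events are disjoint — and is cross-checked against a brute-force
per-read scan in the tests.

Counts are converted to reads per million before the ratio. The two
libraries in a bivalency comparison rarely have equal depth, and without
depth correction the ratio would carry a constant spurious factor; RPM is
the minimal correction. A `raw_counts` mode reproduces the literal
raw-read-number ratio for single-dataset work. The ratio is pseudocounted,
`(K4 + ε)/(K27 + ε)`, with ε defaulting to the RPM equivalent of one read
in the smaller library: this keeps ratios finite on empty windows, is
symmetric in behaviour under reciprocal swap (`ratio(a,b)·ratio(b,a) = 1`),
and scales sensibly with depth. Genes with no signal for either mark get
ratio exactly 1 — agnostic, not extreme.

The array (ChIP-chip) path is separate: background-subtracted ChIP divided
by background-subtracted input, both globally normalised to a common
median. Subtraction is floored at a small positive value (10⁻⁶) so
negative or zero probes cannot produce undefined ratios; the output is
invariant to rescaling either track.

## Population analyses

Scores are joined to expression by gene identifier (inner join; unmatched
counts logged — cross-referencing data sources silently loses genes, so
attrition is always reported). X- and Y-linked genes are excluded by
default: expression and chromatin data often come from different cell
lines, including lines of different sex, where allosomal dosage confounds
the comparison.

Expression bins: the reference mean *m* is computed over expressed genes
only; a gene is `above_mean` if value > *m*, `mean_to_one` if
1 ≤ value ≤ *m*, `below_one` if value < 1. The boundary rule (closed at 1,
closed at *m* for `mean_to_one`) is a documented convention — any fixed
rule partitions the set; this one is asserted in tests. A configuration in
which *m* < 1 would ill-order the bins and is rejected with a diagnostic.
Box statistics use linear-interpolation quartiles, whiskers at the most
extreme points within 1.5 × IQR of the quartiles, and outliers listed
individually. Pairwise bin comparisons use the classic pooled-variance
unpaired Student's t (two-sided); a `welch` flag switches to the
unequal-variance form.

The moving-average curve ranks genes by expression ascending (ties broken
by gene identifier, so the curve is deterministic) and averages ratios in a
sliding window, default 100 observations with step 1. The Spearman
correlation is computed on the *unwindowed* per-gene pairs — smoothing is
presentation, not inference. Spearman uses average ranks for ties; the
p-value is an exact permutation enumeration for n ≤ 10 and the t
approximation otherwise. Constant inputs report r = 0 with a warning
rather than NaN.

Top-quantile subsets take the round-half-up share of genes with the
largest key value (default: top 20% by H3K27me3 RPM), ties at the boundary
broken by gene identifier.

## ChIP-qPCR model

Recovery of an amplicon is `E^(Ct_input − Ct_chip)` with amplification
efficiency E fixed at 2.0 (perfect doubling per cycle); a per-call
efficiency parameter exists but no standard-curve calibration is modelled.
Chip and input Ct values are paired by replicate index — the conservative
default when the plate layout does not say otherwise. Fold enrichment is
the per-replicate ratio of recoveries, target over control amplicon,
summarised as mean ± sd over replicates; the control's own fold is 1 with
sd 0 by construction. Sequential-ChIP (re-ChIP) quantification uses the
identical machinery with the first-antibody eluate as the "input" channel.

Replicate significance tests run on log₂ folds by default (folds are
multiplicative; a linear-scale flag exists). The zero-variance degenerate
case — both groups constant but different — reports t = ±∞ with p = 0 and
a warning rather than NaN, because noise-free simulated fixtures hit it
legitimately.

The cell-mixture model is linear: a population mixed at fractions
(f, 1−f) contributes chromatin in proportion to cell numbers, so expected
enrichment is Σ fᵢ·Eᵢ. This is a model assumption (additive chromatin
mass), stated as such, and is tied to read-level reality by a test: pooled
simulated read sets re-quantified at a focal locus match the linear
prediction within Poisson error.

## Single-cell scoring and the copies estimate

Only wells positive for the control transcript are informative — a
negative control well cannot distinguish "cell absent/lysis failed" from
"target off", so target-positive/control-negative wells are excluded (and
logged). The expressing fraction is target-positives over informative
wells with a Wilson score interval; Wilson rather than Wald because the
relevant counts are small and often extreme (0 positives in 110 wells is a
real case) where Wald collapses to zero width.

Copies per expressing cell combines four quantities:
`molecules_per_reference_cell × gene_fraction / relative_deficit`
is the population-mean copy number, and dividing by the expressing
fraction concentrates it on cells that transcribe at all. `gene_fraction`
defaults to 0.5, for the case where the reference count covers two
paralogous genes jointly and the target is one of them; it is an exposed
parameter because that convention is a modelling choice, not a formula.
`relative_deficit` accepts a (low, high) range; the point estimate uses
the midpoint and the report carries the range-propagated interval. With
20,000 reference molecules, gene fraction 0.5, deficit 30,000–40,000 and
fraction 0.12, the estimate is 2.38 copies (interval 2.08–2.78), i.e.
between two and three copies per expressing cell. With gene fraction 1.0
the same inputs give ≈ 4.8 — the 0.5 convention is what makes the
estimate land in the two-to-three range, and it is documented as an
assumption.

## The simulator

The generator emulates the statistical structure the analyses assume, not
any particular organism's data:

- **Expression**: silent with probability `p_silent` (default 0.4), else
  LogNormal(μ = 1.0, σ = 1.0) — a silent mass plus a right-skewed
  expressed tail with mean of expressed ≈ 4.5, comfortably above the
  binning threshold of 1.
- **Occupancies**: H3K27me3 at `k27_occupancy_high` = 0.8 everywhere (the
  bivalent background), H3K4me3 at
  `clip(0.1 + 0.3·log1p(expression) + N(0, 0.05), 0, 1)` — monotone
  coupling with Gaussian noise. The stored ground truth includes the
  Spearman correlation between the log₂ occupancy ratio (pseudocount
  0.01) and expression, recomputed from the emitted table, never assumed.
- **Reads**: per gene, Poisson(100 × occupancy) focal reads with starts
  Normal(TSS, 500 bp), rounded and clipped; Poisson(10⁻⁵ × chromosome
  length) uniform background; fixed 36-bp reads. The Gaussian placement
  kernel is a single-parameter stand-in for a promoter-mark pileup shape.
  100 focal reads per fully occupied 6-kb promoter window over a
  1-read-per-100-kb background is a realistic early-generation ChIP-seq
  yield.
- **TSS placement**: uniform with ≥ 20 kb spacing (sorted uniforms on a
  shrunk interval plus deterministic offsets), so promoter windows never
  overlap and per-gene counts are independent.
- **Detection classes**: silent genes are `absent`; expressed genes below
  the mean of expressed are `sporadic`, above it `all_cells` — a
  deterministic proxy for the fraction of cells in which a transcript
  would be detected.
- **qPCR**: Ct = intercept − log₂(signal) + N(0, noise_sd) per replicate.
- **Single cells**: control positive ~ Bernoulli; target copies
  zero-inflated, zero-truncated Poisson; detection thins per copy.

Each operation draws from an RNG stream keyed by (seed, operation name),
so adding operations never perturbs existing draws, and all outputs are
byte-identical given seed and config. The full config is written as a JSON
manifest next to generated datasets.

What the simulator does **not** model — and hence what passing tests do
not show about real data: mappability and GC bias, peak-shape diversity,
input-chromatin structure for ChIP-seq, copy-number variation, probe-level
microarray noise, amplification-efficiency drift in qPCR, and RT dropout
correlated across genes in a well. Recovery of the programmed coupling on
synthetic data demonstrates the statistics are implemented correctly, not
that any particular biological dataset will show the same correlation.

## Problem sizes and numerical choices

The recovery analyses use 2,000-gene populations over 10 seeds (Spearman
recovery within ±0.05 of ground truth; bin-mean ordering), 100 trials for
the mixture check (3 Poisson SDs), 100 random fixtures of 1,000 reads ×
50 windows for the counting oracle, 10,000-well plates for fraction
recovery and 1,000 plates of 270 wells for Wilson coverage — sizes at
which the binomial/Poisson tolerances are meaningful while the whole
suite runs in seconds. Tolerances on exact round trips are 10⁻⁹;
scale-invariance checks use relative 10⁻¹².

## Known limitations

- No peak calling, no input correction for ChIP-seq, no multi-replicate
  merging beyond read-set pooling; bivalent gene lists are inputs, not
  derived.
- BAM/SAM input is not implemented; BED3 is the native read format.
- The qPCR model assumes a shared amplification efficiency and pairs
  replicates by index; no batch or plate-position effects.
- The copies estimate propagates only the deficit range, not uncertainty
  in the expressing fraction or the reference molecule count.
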
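# Methods

This note documents the models, estimators, defaults and numerical choices
behind `titinpsi`, and what the synthetic generators do and do not emulate.

## Transcript model and counting bins

The unit of quantification is the *counting bin*, a sub-exonic interval of a
single transcript model. Exons are indexed in transcript (5'→3') order; the
mouse titin gene is on the minus strand, so exon 1 is the genomically last
exon, and the code handles either strand generically. Coordinates are
0-based half-open internally and 1-based inclusive at GTF/GFF3/TSV
boundaries — conversions happen only at I/O, which removes off-by-one
ambiguity.

Bin flattening splits an exon wherever an observed splice-junction donor or
acceptor falls strictly inside it, provided the junction carries at least
`min_junction_reads` (default 3) supporting reads. This makes the bin
structure deterministic and evidence-driven rather than dependent on read
density heuristics. Sub-bins are numbered `.1`, `.2`, … in transcript
order. Junction ends landing in intronic space create `_hang` bins attached
to the nearest annotated exon boundary; they carry no parent exon and are
excluded from the exon-tiling invariant (non-`_hang` bins always partition
their parent exon exactly). `_hang` bins participate in PSI quantification
like any other bin but are not part of any named exon region, so they do
not enter region-level mass estimates.

Named domain regions default to Z-repeats = exons 10–14, PEVKI = 112–135,
PEVKII = 136–155, PEVKIII = 156–209, MEx = 342–347. Published sources vary
on PEVKI's start (112 vs 113) and share boundary exons between adjacent
PEVK segments; the default here is the non-overlapping variant, and the
overlapping bounds are retained as the `PAPER_41_REGIONS` preset. Region
bounds are plain configuration, not hard-coded behaviour.

Amplicon prediction enumerates all inclusion subsets of the cassette exons
between two primers: product length = flank + sum of included exon lengths,
deduplicated by length and sorted descending. With K equal-length exons this
is the familiar K+1-band gel ladder.

## PSI estimation

For bin *b* in sample *s*:

* inclusion reads `I`: primary alignments (MAPQ ≥ `mapq_min`, default 10)
  with an aligned block overlapping the bin body, or a splice junction
  ending exactly at a bin boundary;
* exclusion reads `E`: alignments whose intron fully contains the bin.

A read contributes to a given bin at most once, and inclusion evidence wins
if both rules match. Reads overlapping two bins of the same exon count once
per bin (bin-level, not exon-level, accounting). Duplicate flags are not
filtered; typical bulk RNA-seq here carries none.

PSI is the position-normalised ratio
`(I/pI) / (I/pI + E/pE)` with `pI = bin_length + L − 1` and `pE = L − 1`
for read length `L` (median observed length unless given). The
normalisation corrects for the larger placement space of body reads versus
junction-spanning reads; a `raw` mode (`pI = pE = 1`) is available for
comparison and for pre-tabulated junction counts, where both evidence
classes already have unit placement. Bins with fewer than `min_support`
(default 10) informative reads in a sample yield a missing PSI rather than
a noisy one.

## Group comparison

Group summaries use the sample mean and the n−1 standard deviation;
single-sample groups are flagged and assigned SD 0. dPSI is
mean(mdm) − mean(WT) per bin within each muscle (negative = higher
inclusion in WT), with the degrees-of-freedom-weighted pooled SD attached,
appropriate for the small group sizes involved (n < 30, equal-variance
assumption). The per-muscle p-value is the pooled-variance two-sample
t-test implied by that SD.

The per-bin factorial test is a two-way ANOVA (genotype × muscle plus
interaction) with Type III sums of squares and sum-to-zero contrasts —
the factorial default of common commercial statistics software — fitted via
statsmodels OLS. Unbalanced designs are supported; missing PSI cells are
dropped listwise per bin with no imputation, keeping small-sample behaviour
transparent.

Family-wise error is controlled with the Holm step-down (sequential
Bonferroni): p-values sorted ascending, `p_adj(i) = max_{j≤i} min(1,
(m−j+1)·p(j))`, rejecting while `p_adj ≤ α` (default α = 0.05). The family
is configurable: all bins within a muscle (default) or the global bin ×
muscle set. Missing p-values propagate as missing and do not count toward
m. Holm rejections always contain Bonferroni's and are contained in the
unadjusted rejections — a property the test suite checks on random inputs.

## Segment mass estimation

Per-exon masses come from a user table or from in-frame translation of the
spliced CDS, using standard average residue masses (free amino-acid weight
minus one water); codons spanning exon boundaries are apportioned pro rata
by nucleotide count, so per-exon amino-acid lengths are codon-equivalents
and may be fractional. Water termini are not assigned to any exon, keeping
masses additive over segments. The mass table is deliberately decoupled
from the estimator so any external mass convention can be reproduced.

Three estimators per region and group: **min** (exons with PSI = 1),
**max** (exons with PSI > 0) and **weighted** (`Σ mass·psi`, the expected
transcript mass under independent Bernoulli inclusion — verified against
exhaustive enumeration in the tests). Because estimated PSI never hits 0
or 1 exactly, values within `psi_tolerance` (default 0.005) of a bound are
snapped to it before use; applying the snap to all three estimators keeps
min ≤ weighted ≤ max even at the boundaries. Missing PSI for a massed exon
is an error by default; an optional impute mode substitutes the region-mean
PSI (weighted) while treating the exon as non-constitutive (min) but
possibly expressed (max). Mass differences are reported as WT − mutant in
kDa with no internal rounding.

## Passive-stress decomposition

Cross-sectional area assumes a cylindrical bundle: `π(d/2)²` with µm→mm²
conversion. The protocol is a 2.6→3.0 µm sarcomere-length ramp at
0.04 µm/s followed by a 60-s isometric hold; the steady-state stress is the
mean of force/area over the final `window` seconds (default 5 s — long
relative to the observed relaxation time, short enough to avoid drift) of
the hold, detected as the trailing run of samples with |SL − 3.0| ≤ 0.01 µm
(the scale of SL-tracking resolution). Missing hold phases and windows
longer than the hold are errors, not silent truncations.

Per bundle, with control, post-trypsin and post-trypsin+KCl+KI stresses:
collagen-based = the final residual, titin-based = control − residual, so
conservation `titin + collagen = total` holds to floating-point precision
by construction. The trypsin drop (control − post-trypsin) is reported
separately; a stress that *increases* along the extraction sequence sets a
monotonicity flag but is never clipped, and negative components are
reported as-is so group means stay unbiased. Group statistics treat the
bundle as the unit and compare genotypes with a Welch two-sample t-test per
component; a mixed model with muscle-of-origin as a random effect (as used
in some published analyses of such data) is intentionally out of scope —
the decomposition, not the inference machinery, is the core computation.

## Synthetic data

**Splicing.** Per bin × sample, total junction-informative reads are
Poisson(coverage) and inclusion reads beta-binomial with mean PSI and
intra-class correlation ρ (default 0.01; exactly binomial at ρ = 0) —
the standard choice for overdispersed inclusion ratios. The default truth
profile encodes the qualitative mdm phenotype: PEVK hotspot exons
(124–127, 133–134, 138–145) at 0.80 in WT and 0.45 in mdm, Z-repeat exons
12–13 raised from 0.30 to 0.70 in mdm fast muscles only, Mex5 (exon 346)
at the published group means (WT EDL 0.63, psoas 0.58, soleus 0.97; mdm
0.88/0.93/0.97), and 0.9 elsewhere. These are generator inputs, not claims
about any real dataset.

**Mechanics.** Per bundle, total steady stress is Normal(µ_genotype, σ)
truncated at 0, with defaults calibrated to the published soleus group
statistics (mdm 27.0 ± 0.97, WT 13.0 ± 2.14 mN/mm², n = 20/21). The titin
fraction (1 − collagen/total: mdm ≈ 0.752, WT = 0.800) and the
trypsin-resistant titin fraction (solved from the post-trypsin means:
mdm ≈ 0.463, WT ≈ 0.548) fix the three per-condition steady stresses.
Each condition is rendered as a quadratic toe-region rise to a 25% peak
overshoot during the 10-s ramp, exponential relaxation (τ = 5 s) to the
steady stress during the hold, and additive Gaussian noise (0.2 mN/mm²)
at 25 Hz sampling; diameters are uniform in 120–220 µm (a 4–5-fiber
bundle). Because the relaxation remnant in the analysis window is
proportional to each condition's steady stress, component *ratios* are
recovered exactly in the noise-free case — a property the tests exploit.

What the generators do **not** emulate: read-level artifacts (sequencing
error, mapping bias, positional coverage non-uniformity, paired-end
fragment-length effects), correlated inclusion across exons on one
transcript, muscle-to-muscle random effects within a genotype, rig
compliance and SL-tracking noise. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated statistical
model, not robustness to every artifact of real data.

## Problem sizes and determinism

All randomised tests and the acceptance script are seeded; generators
refuse to run without an explicit seed (no wall-clock entropy). The test
suite uses deliberately small problem sizes — toy genes of ≤ 6 exons,
4 samples per group at coverages of 500–1000, ~100 simulation replicates,
41 synthetic bundles at 25 Hz — chosen so the statistical checks (recovery
error < 0.02, sign recovery ≥ 95%, type-I error in [0.03, 0.07]) are
well-powered while the whole suite stays fast. The group-mean calibration
check is a 2-standard-error sampling test at the study's own n and is
expected to fail for a small fraction of seeds by construction.

## Known limitations

* PSI normalisation constants assume a single effective read length; mixed
  read-length libraries are approximated by the median.
* Reads spanning two junctions contribute to each affected bin
  independently; no transcript-level (EM) assignment is attempted.
* The per-muscle dPSI p-value is a pooled-variance t-test on bin means; it
  inherits the equal-variance assumption of the pooled SD.
* Amplicon prediction assumes clean products (no heteroduplexes or
  partial digestion) and reports lengths only, not band intensities.
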
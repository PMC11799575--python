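# Methods

## Scope and data model

`epsbloom` starts from a per-sample per-ORF read-count matrix: read QC,
rRNA removal, mapping and counting, MAG assembly and binning, ORF
prediction and homology annotation are upstream concerns whose outputs
(FASTA contigs, a contig→MAG membership table, GFF3 CDS calls, an
ORF→identifier annotation table, TSV counts and sample metadata) are the
package's inputs.  Coordinates follow the GFF3 convention (1-based,
inclusive); ORF length in kb is `(end − start + 1)/1000`.  Strand is stored
but ignored by all computations — the normalizations and the cluster scan
are strand-agnostic (a co-strand filter for clusters exists but is off by
default, since operon co-orientation is common but not guaranteed in draft
MAGs).  ORFs without a MAG assignment are rejected at load time: the
analysis is defined per genome, so an orphan ORF has no denominator.

## Normalizations

**TPM** is computed per sample: length-normalized rates `c/L` rescaled to
sum to 10^6.  All-zero samples produce all-zero rows (not NaN) and are
flagged rather than dropped, so time axes stay aligned.

**Marker-gene (MG) normalization** divides an ORF's rate by the median rate
of its MAG's 10 universal single-copy marker COG families (COG0012, 0016,
0018, 0172, 0215, 0495, 0525, 0533, 0541, 0552).  The ratio is taken in raw
rate space with no 10^6 factor: any common per-sample scale cancels, so the
result is identical whether the numerator and denominator are rates or TPM.
This cancellation is the reason the implementation does not carry the TPM
rescale into the ratio.  A MAG with fewer than 10 detected markers is
normalized by the median of those available (with a warning) — incomplete
genomes are the norm in MAG catalogs; a MAG with none is an error.  Where
the marker median is zero the value is undefined (NaN, flagged), never
infinity.  The even-count median is the midpoint of the central pair.

**MAG relative activity** is the MAG's share of total sample TPM divided by
its share of total catalog length (kb).  A sample with zero total TPM has
undefined activity (flagged); a MAG with zero TPM in a defined sample has
activity 0.  Because both numerator and denominator are shares, activity is
invariant to any uniform rescaling of contig lengths, and the
length-weighted sum of activities is exactly 1 in every defined sample.

## Phase comparison

Rows (MAGs or clusters) are compared between bloom phases with the
difference of phase means as statistic and a one-sided permutation test on
the phase labels (alternative: phase 2 greater).  When the number of
distinct label splits `C(n, n2)` is at most the permutation budget (default
10,000) the splits are enumerated exhaustively and the p-value is exact;
otherwise random permutations are drawn from a fixed, logged seed and the
add-one estimator `(b + 1)/(B + 1)` is used.  The reported log2 ratio of
phase means is the ranking key; "higher-activity" calls combine a
configurable one-sided α (default 0.05) with a log2 ratio ≥ 1, since no
canonical threshold exists for this quantity.

Heatmap scaling of profiles defaults to a per-row z-score with sample
(n−1) standard deviation; min-max and no scaling are selectable.  Constant
rows map to all zeros and are flagged rather than erroring, because
zero-variance profiles are legitimate (for example a MAG absent from every
sample).

## EPS gene-cluster detection

Modules scanned by default: **alginate** (algA, algC, alg8, alg44, algK,
algE, algX, algL, algI, algJ, algF, algG; core alg8 + alg44 + algA — the
polymerase, co-polymerase and precursor-synthesis steps), **cellulose**
(bcsA, bcsB, bcsZ, bcsC; core bcsA + bcsB), and the **wzx/wzy-dependent**
pathway (wzx flippase, wzy polymerase, wbaP priming glycosyltransferase, a
further glycosyltransferase, wzz chain-length co-polymerase, wza outer
membrane export; core wzx + wzy).  These lists reconstruct the standard
pathway components; every identifier, the required core and the minimum
key-gene fraction (default 0.5) are configurable so a curated table can
replace them verbatim.

Matching is identifier equality against any member of an ORF's annotation
set.  A cluster is a maximal run of matched ORFs on one contig in which
consecutive matches are separated by at most 2 intervening ORFs and at most
5,000 bp (both configurable); a run is reported only if it contains the
full required core and the minimum fraction of key genes.  The gap defaults
reflect typical operon architecture (small regulatory insertions tolerated,
long intergenic stretches not).  Overlapping runs cannot arise from this
left-to-right maximal scan, so no separate merge step is needed.  Cluster
counts are monotone non-decreasing in the gene-gap parameter whenever each
core gene occurs once per contig; with duplicated cores two reportable runs
can merge into one as the gap widens, which is a property of the maximal-run
definition, not a defect of the scan.

Cluster expression is the per-sample mean of member ORFs' MG-normalized
values (NaN members skipped per sample); clusters whose values are entirely
undefined are excluded from scaling and flagged.

## TEP assay

The calibration line is ordinary least squares through the XG standards
(mass µg, absorbance at 787 nm).  The fit includes an intercept, but the
concentration formula uses only the slope — the additive level is handled
by the measured filter blank, keeping the formula literal:
`TEP = (A_sample − A_blank)/(m787 · V)`.  A non-positive fitted slope
aborts the assay as invalid.  Negative computed TEP (sample below blank) is
clamped to 0 and flagged.  The group contrast is a one-tailed two-sample
t-test, pooled-variance by default ("2-sample t-test" with three replicates
per group; Welch selectable), asking whether the full-strength nutrient
regime exceeds the quarter-strength one.  Two constant equal groups make
the statistic undefined; the implementation returns t = 0, p = 0.5 with a
degeneracy flag.

Units follow the inputs: TEP is µg XG-equivalent per the volume unit of V,
and per-cell values divide by the density as given (cells/µL or CFU/µL),
echoed in the output.

## Synthetic-study generator

The generator emulates the target study's shape, not its content: a catalog
of MAGs (default 50, three contigs each, log-normal contig lengths around
60 kb), ORFs laid head-to-tail with log-normal lengths (mode ≈ 900 bp) and
exponential intergenic gaps, exactly one ORF per marker COG per MAG, and
planted EPS operons as contiguous runs annotated with all key genes of
their module.  Counts are negative-binomial, parameterized by mean and
dispersion k (variance = µ + µ²/k, default k = 2 — moderate metatranscriptome
overdispersion), with mean proportional to library size (default 10^6),
a log-normal per-MAG abundance (σ = 1), ORF length, and a log-normal
per-ORF relative rate (σ = 1).  Marker ORFs get rate 1, treating them as
constitutively expressed, and never receive expression fold-changes — this
is what makes them a valid normalization baseline.

The study conditions are 30 samples with the phase boundary after sample
15, a Gaussian nutrient bump (phosphate 0.2 → 2 µM, nitrate 4 → 22 µM,
width 2 samples — coastal-bloom scale, far below the lab medium's 36/882 µM)
centered at sample 16, five active MAGs with activity fold f_act = 4 in
phase 2, and EPS clusters with expression fold f_eps = 4; the default
config also plants fold-1 clusters so ranking has genuine competitors.
Nutrient covariates are carried as metadata only — no mechanistic coupling
is simulated, matching the correlational nature of the claim being tested.

All randomness flows from `numpy.random.default_rng` (PCG64) through three
`SeedSequence.spawn` streams (community, counts, assay), so one seed gives
byte-identical files across runs and platforms.

What the generator does *not* emulate: sequencing error and rRNA carryover,
assembly chimerism and binning contamination, compositional coupling
between MAGs beyond the shared library-size constraint, multi-copy or
horizontally transferred marker genes, and partial or rearranged EPS
operons.  Passing the planted-effect recoveries therefore shows the
pipeline's statistics recover effects of the stated size under clean,
correctly annotated genomes; it does not certify robustness to annotation
noise or binning artifacts.

## Problem sizes and numerical choices

Recovery checks run 20 independent 50-MAG, 30-sample studies; calibration
precision uses 1,000 simulated assays (absorbance noise sd 0.005) and the
t-test's type-I error 2,000 null plates — sizes at which the binomial
uncertainty of the measured rates is well inside the asserted bands.
Permutation p-values in the recovery loops use reduced budgets because only
the ranking enters those checks.  Comparisons of permutation statistics use
a 1e-12 absolute guard so that exact ties (the identity split) count as
exceedances.  Matrices are written with 12 significant digits, which is
also the round-trip guarantee for real-valued tables; integer counts round
trip bit-exactly.

## Known limitations

* The MG ratio's behaviour degrades for near-zero marker coverage:
  low-abundance MAGs in shallow samples produce undefined (flagged) cells
  rather than estimates.
* Cluster detection trusts the annotation identifiers verbatim; synonym
  resolution (gene symbol vs KO vs OG for the same function) must happen in
  the annotation table or the module config.
* Relative activity is compositional: boosting some MAGs necessarily
  depresses the others' shares, so log-ratios understate absolute
  fold-changes and anticorrelated profiles can be artifacts of closure.
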
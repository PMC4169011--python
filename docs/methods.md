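# Methods

## Region methylation and the percentile null

The per-CpG methylation level (mC value) is the fraction of reads
supporting methylation at that CpG; a CpG with coverage below `min_cov`
(default 1 read) is undefined and ignored. CpG identity is the position of
the plus-strand C; counts from the two strands are assumed merged upstream
— the package never sees strand-resolved bisulfite calls. A region's mC
ratio is the **unweighted** mean of its covered CpGs' mC values: a CpG at
1× coverage counts as much as one at 50×. This makes the statistic a
property of the region's methylation landscape rather than of the coverage
profile; the coverage-weighted alternative would converge to the same value
at uniform depth but is deliberately not used (tests pin the distinction:
CpGs {0.5 at 10×, 1.0 at 1×} give 0.75, not 0.545).

Differential methylation between two conditions is `Δ = mC_B − mC_A`
(oriented later-state minus earlier-state, so "hypomethylated in
reprogramming" is a negative Δ). The null model is empirical: random
genomic loci with the same length distribution as the regions under test
(each template length tiled to at least 10× the number of regions and never
fewer than 10,000 loci), scored identically in both conditions. Chromosomes
are chosen with probability proportional to length and starts uniformly; a
locus is redrawn (up to 100 times) until it contains at least `min_cpg`
CpGs covered in *both* conditions, so every null locus is scorable where a
real region would be. The hypomethylation cut-off is the nearest-rank fifth
percentile of the null Δ distribution; hypermethylation mirrors it at the
95th. Nearest-rank (no interpolation) keeps thresholds exactly reproducible
across numeric stacks. With a degenerate null (all Δ equal) both cuts
coincide and a Δ exactly at the cut classifies as hypo — an arbitrary but
documented tie-break that cannot occur with continuous data.

Only the fifth percentile is prescribed for the hypo side; mirroring it at
100−p for the hyper side (rather than a percentile of |Δ|) was an open
design choice, made because it keeps the two tails independently calibrated
at p% each and is symmetric under swapping the conditions. The percentile
is a parameter throughout.

## Windows and CpG content

Promoters are TSS −1000/+500 bp, gene bodies TSS +2000 bp to the TES, both
mirrored on the minus strand. Promoters are clamped at chromosome edges;
gene bodies that would be empty (TES within 2000 bp of the TSS) are
excluded as too short. The two windows of a gene never overlap (gap
[TSS+500, TSS+2000)).

CpG content is plus-strand CpG dinucleotide density per bp — not the
observed/expected CpG island statistic — because the low/high split at
0.03 is stated as a plain density threshold; content exactly at the
threshold classifies as high (`≥`). When a sequence rather than a position
index is supplied, only CpGs fully inside the window are counted. Gene
models use a single TSS per gene; isoform-resolved windows are out of
scope.

## Expression classes and the decile analysis

Fold change is `(FPKM_B + ε)/(FPKM_A + ε)` with ε = 0.1 FPKM by default, a
pseudocount that keeps genes switching from zero finite while barely
perturbing expressed genes; ε = 0 is supported (and used by the exact
boundary and rescaling-invariance properties: calls at ε = 0 are invariant
to a common rescaling of both conditions). Activation/repression
boundaries are inclusive (≥ 2, ≤ 0.5). "Excluded" means zero FPKM in every
condition of the cohort, not just the tested pair. The Pearson correlation
summarising global variation is computed on log10(FPKM+1) — the scale on
which FPKM noise is approximately additive; raw-scale PCC would be
dominated by the few highest-expressed genes.

The decile analysis sorts genes by region mC ratio with ties broken by
gene id (a stable, deterministic order), takes the bottom and top
`floor(0.10 n)` genes and compares each group's FPKM to all genes with a
two-sided Wilcoxon rank-sum test. It can be run pooled and per CpG-content
class.

## Site integration

Site–gene association is interval-to-interval: a site links to every gene
whose span [min(TSS,TES), max(TSS,TES)) lies within 3,000 bp (overlap =
distance 0, boundary inclusive, many-to-many). Measuring to the TSS point
instead is available via `anchor="tss"`; the span anchor is the default
because the 3 kb rule is stated for genes, not promoters.

Representation of differentially methylated sites within a mark's site set
is an exact binomial test with occurrence probability p₀ = 0.05 — the
per-tail rate the percentile null produces by construction. Both one-sided
tails are reported side by side (`p_over = P(X ≥ k)`, `p_under = P(X ≤ k)`),
uncorrected; a Benjamini–Hochberg option is deliberately not applied by
default since the representation grid is read as raw P < 0.05 calls. A
"hypomethylated site" is the site's own interval called hypo by the region
caller — not the promoter of a linked gene.

DE-within-DM enrichment is a Fisher exact test on the 2×2 membership table
over a caller-supplied universe, with one-sided p-values for enrichment and
depletion plus the odds ratio (infinite when an off-diagonal cell empties;
depletion is then reported as impossible). The enrichment grid bins genes
by (mC_A, mC_B) at width 0.05, masks bins with background count < 5, and
normalises within unmasked bins so the background-weighted mean enrichment
is exactly 1.

Marker-gene selection intersects "linked to ≥ 1 hypomethylated site" with
"activated", returning a sorted list.

## The synthetic cohort

The generator emulates the three processed data layers of a three-condition
stem-cell study — not reads, not alignment, not peak calling:

- **Genome/annotation.** Two 3 Mb chromosomes, 300 non-overlapping genes
  (4.5–8 kb) with ≥ 3.5 kb flanks. Background CpG density 0.015/bp; half
  the promoters are boosted to 0.05/bp so the 0.03 content threshold
  separates two planted classes.
- **Methylation.** Each region class has a mean level π: promoter π is
  coupled *negatively* to the gene's expression rank (high-CpG promoters
  0.50→0.05, low-CpG 0.95→0.35), gene-body π *positively* (0.35→0.85), and
  intergenic π is Beta(6, 1.5) per 1 kb tile (mean 0.8). Counts are
  beta-binomial: depth ~ Poisson(28) (the study-scale coverage), per-CpG
  level ~ Beta(π·s, (1−π)·s) with concentration s = 50 (sd ≤ 0.07 at
  π = 0.5) to model biological overdispersion beyond binomial sampling,
  methylated reads ~ Binomial(depth, level).
- **Planted differential methylation.** Promoter DMRs shift π by ±0.4 in
  exactly one condition: 40 hypo + 20 hyper for the reprogramming pair,
  6 + 3 for the differentiation pair — the many-vs-few asymmetry of the
  design. Sixty 1 kb intergenic DMRs (π 0.75 → 0.35 in the differentiated
  condition) are placed 0.2–1.2 kb beyond gene TES ends, i.e. within the
  3 kb association reach of their host gene but clear of every
  promoter/gene-body window.
- **Signal sites.** The TF-like mark has 2,000 sites with 15% placed inside
  intergenic DMRs (matching the observed hypomethylated-site fraction at
  TF binding sites of roughly 15%); the two histone-mark analogs have 1,500
  sites each at 0% DMR overlap, with footprint methylation pinned low
  (0.10, activation mark) or high (0.85, repression mark). Non-DMR sites
  are uniform *outside* all planted DMRs so the configured overlap fraction
  is exactly the planted truth.
- **Expression.** log10 FPKM ~ N(0.8, 0.6), 5% of genes silent (exactly
  zero everywhere), per-condition log10-scale noise sd 0.08. Genes owning a
  hypomethylated promoter or hosting an intergenic DMR are activated
  (log2 fold +2) with probability 0.6 in the matching condition;
  hypermethylated promoters couple to repression; 40 further genes per
  pair change direction at random so both comparisons show similar global
  expression variation.

All randomness flows through one `numpy.random.Generator`; a fixed seed
reproduces every output byte-for-byte.

**What passing tests do and do not show.** The cohort has uniform coverage,
no mappability gaps, no strand or conversion artefacts, piecewise-constant
methylation with a single noise scale, and planted effects of a single
magnitude. Calibration and recovery results on it demonstrate the
statistics behave as designed under their own assumptions; they do not
demonstrate robustness to the heterogeneous coverage, partially methylated
domains, or copy-number structure of real bisulfite data.

## Problem sizes and runtime choices

The default cohort (6 Mb, ~97k CpGs × 3 conditions, 5,000 sites) was sized
so that every stage — including two 10,000-locus null draws per comparison
— completes in seconds on one core while keeping ≥ 20 CpGs per low-CpG
promoter, the regime in which a planted |ΔmC| of 0.3–0.4 at 28× coverage is
recovered with ≥ 90% sensitivity at the nominal 5% per-tail false-positive
rate. Null-calibration checks use 10,000 training and 10,000 fresh loci,
giving a combined sampling sd of ≈ 0.3 percentage points on the 5% rate
(tolerance ±1 point).

## Known limitations

- No per-CpG differential tests, smoothing or HMM segmentation: the unit of
  inference is the fixed region.
- Hydroxymethylation is indistinguishable from methylation in the input
  counts and is not modelled.
- The random-loci null is genome-wide; restricting it to mappable or
  autosomal sequence is not implemented (synthetic genomes have no such
  structure).
- Fold-change DE classification ignores count uncertainty; it is a
  thresholding rule, not a test.
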
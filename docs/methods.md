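# Methods

## Coordinates and windows

All intervals are 0-based, half-open (`[start, end)`), the BED convention;
GTF input is converted on load. On the minus strand the TSS is the
interval's `end` coordinate (first transcribed base `end − 1`), which keeps
window arithmetic exactly mirror-symmetric under strand reversal (a property
the test suite asserts). When several transcripts share a gene id the
longest is kept as the canonical model; per-isoform statistics are out of
scope.

Fixed windows:

| window | definition | role |
|---|---|---|
| TSSR | TSS − 50 bp … TSS + 300 bp (sense) | PI numerator |
| gene body | TSS + 300 bp … TES + 3000 bp (sense) | PI denominator |
| promoter | TSS ± 1 kb | occupancy/expression statistics |

TSSR and body are disjoint by construction. Windows clip at position 0 and,
when a chromosome-size table is supplied, at the chromosome end.

## Densities and input subtraction

A region's density is its mean per-base read coverage scaled by
1e6 / library size (reads-per-million per bp). Reads contribute coverage
over their full aligned interval; a `count_mode="five-prime"` knob switches
to 5′-end counting for comparison with tag-based tools, since the upstream
density tool's extension behavior is not part of this package's contract.
Net density is ChIP minus matched input over the identical region; net ≤ 0
is flagged invalid. Equality is folded into "invalid" deliberately: a gene
whose body net density is 0 would otherwise divide by zero, and a ChIP
signal that fails to exceed background carries no usable pausing
information.

The pausing index is the ratio of TSSR to body net densities. Genes are
excluded (never imputed) when not expressed (default threshold FPKM ≥ 1 in
the matched expression table — "transcriptionally active" is not given a
number upstream, so the threshold is an explicit knob) or when either net
density is non-positive. PI is invariant to global rescaling of both
tracks; library normalization cancels in the ratio.

"Bound genes" for conditional PI comparisons are genes with at least one
assigned factor peak whose midpoint lies within 1 kb of the TSS; peak-gene
assignment is nearest-TSS by peak midpoint within a configurable window
(default 50 kb), ties broken lexicographically by gene id so results are
deterministic.

## Distribution comparisons

Two-sample Kolmogorov–Smirnov for PI and expression shifts, with the exact
two-sided p-value below a combined n of 25 and the asymptotic approximation
above (the regime in which genome-wide comparisons operate). KS is invariant
to strictly increasing transforms of both samples, so raw and log10 PI give
identical results (asserted in tests). The shift direction is reported from
the sample medians. Signal-gain comparisons between region sets use the
two-sided Mann–Whitney U test (Wilcoxon signed-rank when paired), with
box summaries whose whiskers sit at median ± 1.5 × IQR. All-tied input
yields p = 1 with a warning rather than an error.

## Occupancy–expression trends

Trend curves are smoothing splines with the penalty chosen by generalized
cross-validation — no degrees of freedom are fixed by hand — evaluated on a
uniform grid over the observed range, and reported next to a Spearman rank
correlation computed on the raw pairs (duplicate abscissae are averaged
only for the spline fit). Fold-change regression groups genes into
0.2-log2-unit bins of occupancy change, drops bins with fewer than 10 genes,
and fits ordinary least squares through the per-bin means, reporting the
Pearson R over bin means and the regression p-value. Fold changes use a
pseudocount (default 0.1) before log2 to admit zeros.

## Spike-in loess normalization

For each non-reference sample, M = log2(sample/ref) and
A = ½(log2 sample + log2 ref) are formed with a pseudocount of 0.01; a
degree-1 loess (span 0.6, robustifying iterations as in standard MA
normalization) is fitted over spike-in rows that are nonzero in every sample
(at least 20 required), and the fitted M̂(A) is subtracted from every row's
M. Outside the spike-in A range the boundary correction value is held
constant, with a warning. Spike-in abundance is fixed per cell-equivalent,
so the subtracted trend is precisely the per-cell depth/intensity artifact;
after normalization the spike-in median log2 ratio to the reference is 0
within ±0.05 (tested). The table carries an explicit state
(`raw → spikein_normalized`, one-way) and the amplification statistics
refuse raw input. The fraction-upregulated statistic drops transcripts below
0.5 FPKM in both samples and counts strict increases.

## Peak-set intersections

Peak "sharing" across timepoints is evaluated on the merged-union scaffold:
all peaks are merged into non-overlapping regions and each region is tagged
with the timepoints overlapping it by ≥ 1 bp (configurable). Exclusive
combination counts therefore always partition the merged union — a
conservation property checked on a thousand random families. Because the
upstream convention (per-timepoint peak counts vs merged regions) is
ambiguous, both per-set raw peak counts and merged-region hit counts are
emitted. Gene-set intersections are plain set algebra on assigned gene ids.

## Synthetic-data generator

The generator exists so that every estimator can be checked against closed
form. It deliberately models the *densities* the statistics consume, not
polymerase kinetics or base-level sequence.

**RNAPII.** Each gene receives Poisson(α·depth) reads uniform in its TSSR
and Poisson(α·r·depth·L2/L1) reads uniform in its body, where α is a
per-gene log-normal initiation rate, r ∈ (0, 1] the pause-release
probability, and L1/L2 the window lengths. After length normalization the
expected TSSR/body density ratio — hence the expected PI — is exactly 1/r.
A treatment multiplies r at a designated "bound" subset (capped at 1):
stimulated release lowers PI. Reads are 50 bp, matching short-read ChIP-seq.

**Background and library sizes.** ChIP and input both receive uniform
background at a per-bp rate over an hg19-scale mappable genome (default
2.5 × 10⁹ bp). Reads falling on the gene-bearing chromosomes are
materialized; the (vastly larger) remainder contributes a Poisson-sampled
count to the library size only. This matters: input subtraction normalizes
each track by its own total, so it only cancels background when signal
reads are a small fraction of the library, as in real data. On a small
dense genome the subtraction would be badly biased; with the genome-scale
library the residual PI bias is ~1% at default settings. Generated read
sets therefore carry explicit library sizes which must accompany the BED
files (`library_sizes.json` in pipeline output).

**Promoter ChIP.** Promoter read intensity is scale·log(1 + μ_g) with
log-normal noise, so occupancy–expression correlation is positive with
known strength. At noise 0 the generator emits rounded expected counts;
the rank correlation with μ is then 1 up to integer quantization.

**Spike-in RNA-seq.** Per-cell gene abundances μ_g are log-normal
(sdlog 1.5, a realistic several-decade dynamic range); sequenced counts are
negative binomial with variance μ + φμ² around s·μ_g (control) and
s·g·μ_g (treatment), where s scales the control library to `rnaseq_depth`
(default 3 × 10⁷ fragments, a typical bulk library — spike-in loess
precision depends directly on spike read depth). Dispersion φ defaults to
0.05, a typical gene-wise dispersion for cell-line bulk RNA-seq; φ = 0
degenerates to noiseless expectations for exact closed-form tests. The 92
spike-ins form a fixed log-uniform ladder over 4 decades taking 3% of gene
reads (within the 1–5% range of ERCC practice). Both samples are then
rescaled to exactly equal fragment totals, so naive depth normalization
hides g entirely and only the spike-in anchor recovers it — the core
contrast the module exercises. Note total *FPKM* is only approximately
equalized (~1%), since FPKM reweights counts by transcript length.

Every stage draws from an independent child stream of the config seed;
identical configs give byte-identical outputs, and the config hash is
recorded in the run manifest.

**What the generator does not emulate.** Mappability and GC bias, duplicate
reads, fragment-length variation, isoform structure, correlated biological
replicates, and peak calling. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generative assumptions, not
robustness to every artifact of real libraries.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale chosen to make
Monte-Carlo tolerances comfortable on one CPU: 500 genes at 500 TSSR reads
per gene for PI recovery (median within 5% of 1/r), 2,000 genes for the
pause-release KS shift, 5,000 genes with 92 spike-ins for amplification
recovery (median log2 ratio within ±0.07 of log2 g), and 200 genes for the
exact per-base counting oracle. Exact p-values for 3-vs-3 toy samples are
cross-checked against full enumeration of all 20 group assignments.
Degenerate inputs fail loudly: empty annotations, constant-x trends,
fewer than 3 surviving regression bins, and non-positive intervals all
raise typed errors; unknown chromosomes in density queries warn and return
zero rather than aborting a genome-wide scan.

The CLI accepts `--threads` for interface compatibility but runs
single-threaded; all heavy steps are vectorized.
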
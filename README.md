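# pausekit

Quantitative analysis of RNA polymerase II promoter-proximal pausing and
global transcriptional amplification from ChIP-seq and spike-in RNA-seq.

Many metazoan genes load RNAPII at the promoter and hold it paused 30–60 bp
downstream of the transcription start site; regulated *release* of this
paused polymerase into elongation is a major control point. Factors that
stimulate release genome-wide (transcriptional amplifiers such as MYC, or
ETS1 in endothelial cells responding to VEGF) raise mRNA output *per cell* —
a signal that ordinary depth-normalized RNA-seq cancels out and that only
external spike-in normalization can detect.

`pausekit` is for computational biologists who have aligned ChIP-seq reads,
peak calls, and FPKM tables and want the downstream statistics:

* **Pausing index (PI)** per gene: input-subtracted, length- and
  library-normalized RNAPII density in the TSS region (TSSR, −50 to +300 bp
  around the TSS) divided by that in the gene body (+300 bp to 3 kb past the
  TES),

  `PI = (TSSR net density) / (gene-body net density)`,

  with genes excluded when not expressed or when ChIP signal does not exceed
  input; Kolmogorov–Smirnov comparison of PI distributions between
  conditions.
* **ERCC spike-in loess normalization**: an MA-space loess fitted on
  spike-in rows only and subtracted from all transcripts, converting FPKM to
  per-cell-comparable expression; fraction of transcripts upregulated and
  the median log2 amplification.
* **Promoter occupancy statistics**: TSS ± 1 kb net densities, smoothed-spline
  occupancy/expression trends with Spearman correlation, binned (0.2 log2
  units) fold-change regression, Mann–Whitney signal-gain tests with
  box-plot summaries.
* **Peak-set dynamics**: exclusive UpSet-style intersection counts for peak
  and gene-set families across a time course; TSS-anchored tag heatmaps and
  aggregation profiles.
* **A synthetic-data generator** with closed-form ground truth (expected
  PI = 1/r for release probability r; known amplification factor g), so
  every stage is testable without downloading sequencing data.

## Worked example

Simulate a 300-gene cohort in which the treatment doubles pause release at
the bound half of genes and amplifies per-cell mRNA 1.3-fold, then run the
full analysis:

```sh
cat > demo.yaml <<EOF
seed: 11
simulate:
  n_genes: 300
  release_prob: 0.25
  bound_fraction: 0.5
  treatment_release_multiplier: 2.0
  amplification: 1.3
EOF
pausekit run --config demo.yaml --out demo_out
cat demo_out/report.txt
```

```
pausekit 0.1.0 run report (config 579ad57c664f5ae6, seed 11)

Pausing-index shift (control vs treatment, defined PIs):
  KS D = 0.5067, p = 3.35e-36, treatment shifted lower (n = 300/300)

Spike-in-anchored expression (per cell):
  fraction of expressed transcripts up in treatment = 0.827
  median gene log2(treatment/control) = 0.445
  KS D = 0.0867, p = 0.198, shifted higher
```

Reading the numbers: control genes carry release probability r = 0.25
(expected PI = 1/r = 4); the treatment doubles release at bound genes
(expected PI = 2 there), so the treatment PI distribution is shifted to
*lower* values — detected here at D = 0.51, p ≈ 3e-36. The 1.3-fold per-cell
amplification is invisible to depth-normalized FPKM but recovered by the
spike-in anchor: the median gene log2 ratio is 0.445 (expected
log2 1.3 ≈ 0.38, at this small cohort size the estimate is noisy) and 83% of
expressed transcripts score higher in treatment. The output directory also
contains the per-gene PI tables, the raw and normalized expression tables,
the simulated reads/annotation, and `manifest.json` with checksums of every
output (identical configs reproduce identical manifests).

Individual steps are available as subcommands (`pausekit pi`, `ks`,
`occu-expr`, `fc-bins`, `spikenorm`, `overlap`, `heatmap`, `assign`,
`simulate`) and as library functions (`pausekit.pausing_index`,
`pausekit.loess_normalize_to_spikeins`, ...).

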
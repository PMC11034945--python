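# epipair

Matched-pair epigenome/transcriptome analysis pipeline with a synthetic
study generator. Given a cohort of individually matched case/control pairs
split into antipsychotic-free (AF) and antipsychotic-treated (AT) groups,
two sorted nuclei fractions (NeuN+/NeuN-) and three assays (H3K27ac,
H3K4me3, RNA), the package implements:

- **synthetic_data** — a deterministic study generator: toy genome with
  genes, TF motifs (PWMs), a planted regulatory network, distal enhancers
  with chromatin loops; negative-binomial count matrices with planted
  AF-reversed / AT-induced / shared / age-correlated effects; strand-specific
  read tags with set fragment length and duplication rate; recovery metrics
  against the planted truth.
- **qc_metrics** — ENCODE-style ChIP QC: FRiP, PBC (PBC1), strand
  cross-correlation with NSC/RSC and fragment-length estimation, saturation
  curves, replicate correlation, and the ChIP-qPCR fold-enrichment formula
  `2^(Cq_N - Cq_P)`.
- **peaks_counts** — a minimal Poisson-background peak caller,
  replicate-supported high-confidence peaks, the union-merge master
  consensus set, count matrices with input subtraction, TMM normalization,
  the "fewer than 20 reads in over 50% of samples" filter, and PC-guided
  covariate selection/regression.
- **differential** — per-feature negative-binomial Wald tests with
  trend-shrunk dispersions and library/TMM offsets, Bonferroni and BH
  adjustment, enhancer/promoter classification (4 kb up / 1 kb down
  promoter windows), loop-based and nearest-gene enhancer linking,
  basal-plus-extension region-to-gene mapping, exact hypergeometric overlap
  tests, and QQ inflation lambda.
- **regnet_pagerank** — PWM motif scanning with exact p-values (dynamic
  program over the discretized score distribution), per-sample TF->gene
  networks with `e^z` node weights and expression-x-peak-intensity edge
  weights, and personalized PageRank on the edge-reversed graph seeded by
  the normalized node weights.
- **cohort_compare** — pairwise case-minus-control differences, AF/AT
  reversal classification (threshold 0.5 on the mean-delta gap, signed-rank
  FDR filter), regulatee extraction via differential edge weights,
  cohort-specific DEG sets, and Pearson age correlations with t-distribution
  (df = n-2) p-values and inclusive 0.50 / 0.60 thresholds.
- **episig_cluster** — genome-wide 5 kb bin signal integration, Poisson
  enrichment selection, K-means clustering of bin profiles, K-means
  grouping of clusters into sections, annotation coverage, and per-cluster
  hypergeometric enrichment of differential features.
- **io_cli** — plain-text formats (sample sheet CSV, BED/narrowPeak,
  BEDPE-like loop TSV, MEME-like PWMs, TSV count matrices, YAML config),
  validation of the matched-pair design, deterministic TSV outputs with a
  JSON run manifest, and the stage-oriented CLI.

## CLI

One executable with stage subcommands; every stage reads the shared YAML
config plus flag overrides and logs to stderr:

```bash
# full synthetic pipeline, deterministic at a fixed seed
epipair run --seed 1 --out results/run

# individual stages on files
epipair simulate --seed 1 --out study/
epipair qc --tags study/tags.tsv --out qc.tsv
epipair peaks --tags rep1.tsv --tags rep2.tsv --out master.narrowPeak
epipair differential --counts study/counts_RNA_NeuNpos.tsv \
    --libsizes study/libsizes_RNA_NeuNpos.tsv \
    --sheet study/sample_sheet.csv --adjust bh --out diff.tsv
epipair compare --ppr ppr.tsv --sheet study/sample_sheet.csv --out reversal.tsv
epipair episig --tags d1.tsv --tags d2.tsv --out episig/
epipair report --dir results/run
```

## Notes

- All coordinates are 0-based half-open internally.
- Every generator and stage is a pure function of its inputs and the seed;
  reruns at a fixed config are byte-identical.
- The peak caller and the bin-clustering stage are documented stand-ins for
  external tools at synthetic scale; their contracts (consensus logic,
  filters, thresholds, enrichment statistics) are what the tests pin down.
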
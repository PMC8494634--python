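# crosstax

Tools for building cross-species consensus cell-type taxonomies and the
regulatory-genomics statistics that accompany a multi-species,
multi-omic cell census:

- **`crosstax.taxonomy`** — metacell aggregation (mean log2(CPM+1) per
  over-cluster), Ward merge trees, subsample-based node assessment
  (size / species mixing / branch stability), recursive pruning into
  consensus clusters, gene-subset bootstrap confidence on
  correlation-distance dendrograms, ROC (AUC) marker selection, and
  maximum-frequency taxonomy matching.
- **`crosstax.species_stats`** — Spearman correlation of cluster median
  profiles across species, pseudobulk construction per
  (species, donor, cluster), a minimal negative-binomial Wald
  differential-expression test (method-of-moments dispersion, vectorized
  IRLS, BH correction), and conserved / species-enriched marker
  partitions.
- **`crosstax.peaks`** — summit extension to fixed 501-bp width,
  score-per-million normalization, ranked iterative overlap merging
  (no daisy-chaining), and SPM filtering.
- **`crosstax.linkage`** — candidate cCRE-gene pairs in a 1-Mb window
  around each TSS, Pearson correlation of cluster-level accessibility
  vs expression, shuffled cross-chromosome backgrounds, a normal-fit
  empirical-FDR threshold, and NMF cis-regulatory module discovery with
  Hoyer-sparseness rank selection.
- **`crosstax.enrichment`** — exact Mann-Whitney rank tests (full null
  enumeration via the partition-counting recurrence),
  Benjamini-Hochberg adjustment, retrograde-tracing projection
  enrichment ratios (r_p / r_u), projection-fraction dot-plot tables,
  and subclass-selective transcription-factor calls combining
  expression and motif criteria.
- **`crosstax.synthetic`** — seeded generators that plant known ground
  truth (a 2-level type hierarchy across species, regulatory modules
  and cCRE-gene links on a toy genome, summit overlap chains,
  projection enrichment factors) so every stage is testable offline.

## CLI

The `crosstax` entry point groups one subcommand per stage:

```sh
# synthetic inputs with planted truth
crosstax simulate taxonomy  --config cfg.yaml --out data/ --seed 1
crosstax simulate regulatory --out reg/ --seed 1
crosstax simulate summits   --out summits/ --seed 1
crosstax simulate projection --out proj/ --seed 1

# consensus taxonomy (over-cluster, Ward tree, assess, prune)
crosstax taxonomy build --data data/ --out tax/ --overcluster-k 90 \
    --n-subsamples 100 --min-size 20 --min-mixing 0.1 --min-stability 0.6
crosstax taxonomy markers --data data/ --labels-column cell_type --out markers.tsv

# pseudobulk differential expression
crosstax de run --data data/ --cluster sc0 --cluster-column subclass \
    --pair sp0,sp1 --out de.tsv

# cCRE union building
crosstax peaks extend --summits summits/cl000.narrowPeak --chrom-sizes chrom.sizes --out ext.tsv
crosstax peaks spm    --peaks ext.tsv --out spm.tsv
crosstax peaks merge  --peaks spm.tsv --out merged.tsv
crosstax peaks filter --peaks merged.tsv --cutoff 5 --out ccres.tsv

# enhancer-gene linking and modules
crosstax link pairs  --data reg/ --out pairs.tsv
crosstax link pcc    --data reg/ --pairs pairs.tsv --out pcc.tsv
crosstax link select --data reg/ --pcc pcc.tsv --fdr 0.01 --seed 1 --out links.tsv
crosstax nmf rank    --matrix reg/accessibility.tsv --grid 2,3,4,5,6 --out curve.tsv
crosstax nmf run     --matrix reg/accessibility.tsv --rank 4 --out modules/

# projection and rank-test statistics
crosstax enrich retro    --runs proj/runs.tsv --baseline proj/baseline.json --out enr.tsv
crosstax enrich wilcoxon --u 0 --n1 4 --n2 22
```

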
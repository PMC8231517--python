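# depthsat

Sequencing-depth saturation analysis for long-read (Nanopore-style)
RNA-seq. Given a read library (or a count table), `depthsat` draws
replicated random subsets at a ladder of fractions and quantifies how gene
detection and expression estimates degrade with depth:

- **synthetic data** — a generator for gene catalogs (coding / non-coding
  biotypes, log-normal abundances with non-coding genes shifted low) and
  atomic read records (gene assignment, length, mean Phred quality,
  optional barcode), so the whole pipeline is testable with no downloads;
- **read processing** — mean-quality filtering (reads below Q7 discarded
  by default), barcode demultiplexing, read-to-gene counting, and a parser
  for featureCounts-style count tables;
- **quantification** — CPM and log2(CPM), the count > 3 expressed-gene
  rule, and expression-quartile classes (per coding class or pooled);
- **depth profiling** — replicated subsampling (read-level, or count-level
  via multivariate hypergeometric draws), detection-saturation curves by
  biotype with replicate CVs, and the percent expression-variation
  statistic `(ref − subset) / ref × 100` on log2(CPM), restricted to genes
  detected in ≥80% of a fraction's replicates;
- **concordance** — Pearson correlations between replicates / subsets /
  barcoded samples, and qPCR delta-Ct agreement.

## Test

```sh
python -m pytest tests/
```

## CLI

One entry point with per-stage subcommands:

```sh
depthsat simulate --n-genes 20000 --n-reads 2000000 --seed 7 --outdir data/
depthsat filter   --reads data/reads.tsv --out data/passed.tsv --min-q 7
depthsat demux    --reads data/passed.tsv --outdir data/demux/
depthsat count    --reads data/passed.tsv --catalog data/catalog.tsv --out data/counts.tsv
depthsat quantify --counts data/counts.tsv --out data/expression.tsv
depthsat profile  --reads data/passed.tsv --catalog data/catalog.tsv \
                  --outdir data/profile/ --replicates 10 --seed 7
depthsat concord  --expr data/expression.tsv --panel panel.tsv
depthsat run      --config config.yaml --outdir out/   # full pipeline
depthsat table1   --total 48495343                     # expected subset sizes
```

`depthsat run` executes simulate → filter → count → quantify → profile →
concord and writes TSV tables plus a deterministic `summary.json` with the
headline numbers (detected genes per fraction, variation summaries,
correlations). The YAML config mirrors `depthsat.RunConfig`; every stage
is reproducible from the config and its seeds.

File formats are plain TSV with a header: read tables use the columns
`read_id, gene_id, length, mean_q, barcode` with `*` as the null sentinel;
catalogs use `gene_id, biotype, weight`; qPCR panels use
`gene_id, ct_target, ct_reference`.

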
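# cnvscape

Analysis toolkit for multi-sample CNV catalogs called from short-read
structural-variant pipelines (LUMPY/svtyper-style VCFs). It covers:

- **Catalog filtering & summary** — drop loci shorter than 1 kb or carried by
  fewer than two individuals; compute counts by SV type, mean length,
  per-sample burden, carrier-locus frequencies, genome coverage of the CNV
  union, and a Welch t-test comparing deletion vs duplication lengths.
- **Spatial architecture** — genome-wide two-sample Kolmogorov–Smirnov test of
  CNV midpoints against positions sampled uniformly from the non-CNV fraction
  of the genome; sliding-window CNV counts (2 Mb windows, 1 kb step) and
  hotspot detection by merging windows whose counts exceed the genome-wide
  97.5% quantile.
- **Gene overlap** — interval intersection of CNVs with GFF3 gene models, with
  per-type genes-per-CNV aggregates.
- **DAPC divergence scan** — a from-scratch discriminant analysis of principal
  components on the dosage matrix (PCA by SVD, two-group linear discriminant
  on retained PC scores), per-locus squared-loading contributions normalized
  to sum to one, and upper-tail (2.5%) selection of group-divergent loci, with
  an optional label-permutation null.
- **Synthetic data** — a seeded generator for truth-known fixtures: genome
  index, gene models, and a 20-sample diploid CNV catalog with a deletion
  excess, heavy-tailed lengths ≥ 1 kb, planted hotspots, and planted
  divergent loci with a fixed between-group carrier-frequency difference.

Coordinates are 0-based half-open internally; VCF/GFF3 conversion happens at
the format boundary, BED is written as-is.

## CLI

```sh
# generate a truth-known fixture bundle (VCF, GFF3, genome TSV, groups TSV, truth JSON)
cnvscape simulate --out-dir bundle --seed 1

# filter + summarize + KS test + hotspots + gene overlap
cnvscape characterize --vcf bundle/cnv.vcf --genome bundle/genome.tsv \
    --gff3 bundle/genes.gff3 --out-dir results --seed 1

# DAPC divergence scan (two-group sample->group TSV required)
cnvscape dapc --vcf bundle/cnv.vcf --genome bundle/genome.tsv \
    --groups bundle/groups.tsv --out-dir results --n-perm 99 --seed 1

# both stages in one call
cnvscape report --vcf bundle/cnv.vcf --genome bundle/genome.tsv \
    --gff3 bundle/genes.gff3 --groups bundle/groups.tsv --out-dir results
```

Options may also come from a YAML config (`--config cfg.yaml`); explicit
flags win over the config, which wins over the documented defaults
(min length 1000, min carriers 2, window 2 Mb, step 1 kb, quantile 0.975,
variance target 0.875, q 0.025). Logs go to stderr; machine-readable
TSV/BED/JSON outputs go to `--out-dir`.

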
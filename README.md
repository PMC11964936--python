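# parevo

Paralogue expression evolution toolkit: per-species rank-standardized
coexpression networks, classification of retained paralogue pairs into four
expression-fate groups, a cross-species test for constraint on the total
expression dosage of duplicate gene pairs, and gene-level expression
annotations (breadth, tau tissue specificity, functional status, positional
duplication type). A synthetic multi-species data generator with planted
ground truth makes every stage testable without any external download.

## What the pipeline does

1. **QC** (`parevo.qc`) — replicate agreement by pairwise Spearman
   correlation (samples with mean rho ≤ 0.75 removed, worst-first within
   each replicate group), removal of all-zero genes, replicate averaging,
   and a PCA of singleton-gene expression as a samples-cluster-by-tissue
   sanity check.
2. **Coexpression** (`parevo.coexpression`) — per species: subset genes to
   those with greater-than-median expression in ≥ 1 sample, Pearson
   correlation over all samples, per-gene ascending ranks (average ties,
   undefined correlations get the median rank), symmetrization and division
   by the maximum rank, giving weights in [0, 1].
3. **Fate classification** (`parevo.fates`) — every within-species pair
   from the orthogroup table is funnelled into
   low/insufficient/classified/threshold-gap buckets; classified pairs get
   group I (dosage balanced), II (paralogue dominance), III (specialized)
   or IV (diverged) from (coexpression, |mean log2 FC|, sd log2 FC).
4. **Dosage constraint** (`parevo.dosage`) — per tissue and species pair,
   log2 ratios of summed two-copy orthogroup expression are z-scored across
   orthogroups; two-sided normal p values are averaged over species
   comparisons, BH-adjusted within (species, tissue), and orthogroups with
   adjusted p < 0.05 are called dosage-unconstrained.
5. **Gene features** (`parevo.features`) — expression breadth, tau,
   tissue-specific calls, functional status, tandem/proximal/dispersed
   classification from gene order (WGD/transposed labels pass through).
6. **Simulator** (`parevo.simulate`) — multi-species, multi-tissue TPM
   matrices with planted fate modes, planted dosage drift, planted
   tissue-specific/pseudogene genes, and chromosome layouts covering
   tandem/proximal/dispersed pairs; truth tables are exported separately
   from the analysis inputs.

## CLI

```sh
# end to end on simulated data
parevo run-all --out runs/demo --seed 1

# or stage by stage
parevo simulate --out runs/sim --seed 1
parevo qc --in runs/sim --out runs/qc
parevo network --in runs/qc --out runs/net
parevo classify-pairs --sim runs/sim --qc runs/qc --out runs/results
parevo dosage-test --sim runs/sim --qc runs/qc --out runs/results
parevo features --sim runs/sim --qc runs/qc --out runs/results
```

Inputs are plain text: TSV expression matrices (first column gene IDs, one
column per sample), a sample sheet TSV (`sample_id`, `species`, `tissue`,
`replicate`, optional `pct_uniquely_mapped` — samples at or below 50% are
dropped), OrthoFinder-style `Orthogroups.tsv`, and GFF3 gene models.
Outputs are TSV tables plus JSON summaries; `--config` accepts a YAML/TOML
file of thresholds (see `parevo.config.RunConfig`), `--seed` overrides the
seed, and identical seeds give byte-identical outputs.

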
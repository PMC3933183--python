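# plastidphylo

Tools for building and diagnosing plastid (chloroplast) phylogenomic
character matrices. Starting from per-taxon protein-coding sequences and
an all-vs-all similarity hit table, the package

- clusters putative homologs by **single linkage** over significant hits
  (e-value ≤ 1e-5, coverage ≥ 40% of query and target), refines clusters
  that mix genes from one taxon by **stringency re-clustering**, resolves
  **inverted-repeat duplicates** (identical → keep one; slightly
  different → drop both), and applies a **50% taxon-occupancy** filter;
- assembles a **codon-aware concatenated supermatrix** (gap-fraction
  trimming, exact back-translation against the CDS, per-gene partition
  bookkeeping in RAxML-style files);
- derives the standard **character codings** — all positions (ntAll),
  no third positions (ntNo3rd), third positions only (nt3rdOnly),
  purine/pyrimidine binary (**RY**: A/G → R, C/T → Y), and amino acids —
  with remapped partitions;
- quantifies **compositional bias**: per-taxon GC by codon position,
  Pearson χ² tests of base-frequency homogeneity across taxa
  (df = (T−1)(S−1)), and OLS regressions of GC-rich (G, A, R, P) and
  AT-rich (F, Y, M, I, N, K) amino-acid usage on GC content;
- compares **partitioning schemes by AICc** — none / by codon position /
  by gene / by codon-within-gene — with a partitioned likelihood engine
  (Felsenstein pruning; GTR+Γ, binary+Γ, WAG+Γ; shared branch lengths;
  AICc = −2lnL + 2k + 2k(k+1)/(n−k−1));
- checks **phylogenetic decisiveness** of the gene × taxon coverage
  pattern (triplet/quadruple coverage, exact or Monte-Carlo, plus the
  edge-display criterion per tree and over all trees);
- summarises tree sets by **majority-rule consensus** and bipartition
  support (a resolved unrooted tree on T taxa has T−3 splits).

A bundled synthetic plastome simulator generates all inputs with known
truth — lineage-heterogeneous GC built so that RY recoding is *exactly*
neutral, gene-wise missingness calibrated to ~15.6%, IR duplicates,
paralogs, and hit tables — so the entire pipeline is testable end to end
without downloads.

## Worked example

Run the full pipeline on the default simulated data set (40 taxa, 12
genes) and print the summary:

```bash
plastidphylo run --n-taxa 40 --n-genes 12 --seed 42 --out runs/demo
```

```
plastidphylo 0.1.0 run summary
taxa: 40  genes simulated: 12
clusters retained: 12
matrix ntAll: 40 x 8097 (nt), missing 15.1%
matrix ntNo3rd: 40 x 5398 (nt), missing 15.1%
matrix nt3rdOnly: 40 x 2699 (nt), missing 15.1%
matrix RY: 40 x 8097 (ry), missing 15.1%
matrix AA: 40 x 2699 (aa), missing 19.1%
composition homogeneity (chi-square):
     all: chi2=5347.0 df=117 p=0 mean GC=43.3%
   no3rd: chi2=1200.1 df=117 p=4.96e-179 mean GC=41.9%
    pos1: chi2=635.5 df=117 p=2.92e-72 mean GC=40.2%
    pos2: chi2=633.5 df=117 p=6.65e-72 mean GC=43.6%
    pos3: chi2=6216.7 df=117 p=0 mean GC=46.0%
partition-scheme comparison (AICc):
  by_codon_gene: partitions=  36 lnL=-204522.26 AICc=409966.28 dAICc=0.00
    by_codon: partitions=   3 lnL=-205624.43 AICc=411463.69 dAICc=1497.41
     by_gene: partitions=  12 lnL=-205873.22 AICc=412148.21 dAICc=2181.93
     onepart: partitions=   1 lnL=-206736.00 AICc=413645.87 dAICc=3679.60
decisiveness: triplets 100.0% quadruples 100.0% (exact)
```

Reading the output: all twelve simulated genes were recovered as
clusters and pass the 50% occupancy rule; the five coded matrices share
one taxon order and ~15% missing data; the χ² tests reject base-frequency
homogeneity in every stratum, most strongly at third codon positions
(where the simulator concentrates the lineage GC shifts, as real
plastomes do); the most finely partitioned scheme — codon position within
gene — fits best by AICc; and the coverage pattern contains every taxon
triplet and quadruple, so the matrix is decisive for every tree.

The `runs/demo` directory holds the matrices (relaxed PHYLIP + FASTA +
partition files), the cluster table with its provenance log, the
diagnostic tables, the model-selection table, a decisiveness report, and
`manifest.json` with SHA-256 hashes of every artifact (re-running the
same configuration reproduces the hashes byte for byte).

Each stage is also available separately (`simulate`, `cluster`, `build`,
`recode`, `diagnose`, `modelsel`, `decisive`, `consensus`) and as plain
library functions.

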
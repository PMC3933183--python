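# Methods

This note documents the models and procedures implemented in
`plastidphylo`, the assumptions behind them, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
demonstrate about real data.

## The analysis the package implements

Plastid (chloroplast) genomes carry on the order of 80 protein-coding
genes, are effectively a single linked locus, and are the workhorse of
deep green-plant phylogenetics. Assembling a multi-genome character
matrix from them involves a chain of decisions — which sequences are the
"same gene", how to handle the inverted-repeat (IR) duplicates, how to
keep codon structure intact through alignment and concatenation, how to
code the characters, how to partition the matrix for likelihood analysis
— and each decision interacts with the genomes' pronounced GC
heterogeneity among lineages. The package implements that chain as
composable, tested stages.

## Homolog clustering

Input is an all-vs-all protein similarity hit table (12-column tabular
format). A hit is significant when its e-value is ≤ 1e-5 and the aligned
region covers ≥ 40% of both query and target; significant hits form an
undirected graph whose connected components are the initial clusters
(single linkage: a sequence joins if any path of significant hits reaches
it).

Refinement rules, in order:

1. **Stringency re-clustering.** A cluster is flagged when some taxon
   contributes two copies that look like *different genes*: the pair is
   neither an identical string nor linked by an IR-grade hit (e-value at
   or below the stringency floor, default 1e-30). Flagged clusters are
   re-clustered at successively stricter e-values (÷10 per step down to
   the floor; schedule configurable). If offenders persist at the floor,
   the offending taxon's sequences are removed from the cluster —
   conservative: the gene survives, the taxon is lost there. The
   pair-based benign test matters: a slightly diverged IR pair is
   near-identical and would otherwise drag the whole gene through
   pointless, destructive re-clustering, while a taxon carrying both an
   IR pair *and* a paralog must still flag the cluster.
2. **Split-gene merging.** With per-sequence annotations available,
   clusters sharing a majority label are merged only when their taxon
   sets are pairwise disjoint; any overlap flags the group and blocks the
   merge (overlap suggests paralogy, not a split gene). Without
   annotations this stage is the identity — the original criterion was
   human judgement, which we do not simulate.
3. **IR duplicates.** Within a cluster, a taxon with multiple copies
   keeps exactly one if all copies are identical; if any pair differs the
   taxon's copies are all removed from that gene. Identity is exact
   string equality of the *nucleotide* CDS after uppercasing — a
   synonymous difference between IR copies still counts as "differing",
   which is the stricter and better-defined reading.
4. **Occupancy.** A cluster is retained iff it holds distinct taxa
   ≥ ceil(0.5 × n_taxa); exactly half qualifies.

Every non-trivial action is appended to a provenance log (JSON lines).

## Supermatrix assembly

Per-gene amino-acid alignments are trimmed with a plain gap-fraction rule
(column kept iff gap fraction ≤ 0.5 by default). This is an intentionally
simple, documented stand-in for heuristic trimmers; an externally
produced column mask can be supplied instead. Back-translation expands
each kept residue column to its source codon after verifying that the
ungapped row translates exactly to the CDS (genetic code: NCBI table 11,
bacterial/plastid, by default), so the reading frame is exact by
construction. Genes are concatenated in lexical order of gene id; absent
taxon × gene blocks are filled with `-`; `-`, `?`, `N`/`X` all count as
missing in statistics. Column coordinates are 1-based inclusive in all
files (partition files use the `DNA, name = a-b[\3]` dialect) and 0-based
internally.

## Character codings

From the codon supermatrix: `ntAll` (identity), `ntNo3rd` (positions 1+2),
`nt3rdOnly`, `RY` (A/G→R, C/T→Y; gap preserved; every other ambiguity
code → `?` since it straddles or is silent about the purine/pyrimidine
divide), and `AA` (translation; all-gap codon → `-`, any in-codon
ambiguity → `X`, half-gapped codons are treated as corruption and raise).
Partition coordinates are remapped through each coding. The AA matrix
derived from the supermatrix is cross-checked in tests against per-gene
translation.

## Composition diagnostics

Per-taxon state counts (by codon-position stratum for nucleotides) count
unambiguous states only. The homogeneity test is Pearson's chi-square on
the taxa × states table, df = (T−1)(S−1), upper-tail p from the χ²
distribution, no continuity correction. The amino-acid class fractions
use the fixed sets {G, A, R, P} (GC-rich codons) and {F, Y, M, I, N, K}
(AT-rich codons); regressions of those fractions on GC content are
ordinary least squares over taxa, with a two-sided t-test on the slope.
Taxa are not phylogenetically independent points; the regression (like
the chi-square test) is a descriptive diagnostic, not a corrected
inference, and no contrasts correction is applied.

The chi-square test's nominal level is only meaningful when taxa are
independent draws; the calibration test therefore simulates on a star
tree with long branches. On a clustered tree, shared ancestry correlates
the rows and the test is anticonservative — which is exactly how it is
used in practice: as a loud alarm, not a calibrated test.

## Likelihood engine and model selection

Felsenstein pruning over compressed site patterns, one reversible model
per partition — GTR+Γ (nt), two-state binary+Γ (RY), or fixed empirical
WAG+Γ (AA) — with one shared set of branch lengths taken from the input
tree (no tree search, by design). Rate matrices are built as
Q = S·diag(π), rescaled to mean rate 1; P(t) comes from the
symmetrised eigendecomposition. Gaps/`?`/`N` enter as all-ones tip
vectors; IUPAC partial ambiguities as partial vectors. Per-node rescaling
guards against underflow. Discrete gamma uses four equal-probability
categories represented by their means (renormalised so Σp·r = 1 exactly).

Nuisance parameters are fitted by bounded coordinate search (Brent on
log-scale coordinates: gamma shape in [0.02, 100], exchangeabilities
(G–T pinned at 1), frequency log-odds), accepting only improving moves,
so the lnL trajectory is monotone; iteration stops when a round gains
< 1e-4 or the round budget is exhausted (best-so-far returned). Because
every Q is normalised, among-partition rate differences are inexpressible
unless per-partition rate multipliers are also fitted; the engine
supports them and then counts m−1 additional free parameters.

Parameter counting: k = (2T−3) shared branch lengths + per-partition free
parameters (GTR+Γ: 5 exchangeabilities + 3 frequencies + 1 shape = 9;
binary+Γ: 1 + 1 = 2; WAG+Γ: 1), plus m−1 when rate multipliers are
estimated. AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) with n = alignment
columns; schemes on the same matrix are ranked by AICc with ties broken
by fewer parameters. Published AICc tables from other software are not
reproduction targets (their internal parameter counts are not fully
documented); only difference arithmetic on printed values is asserted.

## Decisiveness

From the supermatrix and gene partitions, a taxon "has" a gene iff ≥ 1
non-missing character in the gene's columns (threshold configurable).
Three related quantities are reported rather than guessing which one a
given study meant: the fraction of taxon triplets jointly covered by some
gene, the fraction of quadruples, and the edge-display test — a coverage
pattern is decisive for a binary unrooted tree iff every internal edge
has some gene with ≥ 1 taxon in each of the four adjacent subtrees, and
decisive overall iff that holds for every tree (exact enumeration of all
(2n−5)!! topologies up to 7 taxa, uniform sampling above with an explicit
flag; 100% quadruple coverage implies decisiveness for all trees).
Exact tuple enumeration uses per-taxon gene bitmasks; Monte-Carlo mode
reports a binomial standard error and a logged seed.

## Bootstrap-consensus summaries

Splits are canonicalised as the side not containing the reference (first
sorted) taxon. Majority-rule consensus keeps splits with frequency
strictly greater than the cutoff (≥ 0.5), so a split in exactly half the
trees is excluded; retained splits are pairwise compatible by pigeonhole
and the builder asserts it. Supports are rounded percentages on internal
nodes. `support_summary` counts splits at or above a threshold out of the
T−3 possible for a resolved unrooted tree. Rooting places the root on the
edge whose bipartition equals the outgroup; a non-monophyletic outgroup
is an error.

## The synthetic-data generator

The generator is first-class, tested code: it defines the study
conditions the rest of the package is validated under.

**Defaults** (desk-scale rendering of a 360-taxon, 78-gene plastome
matrix): 40 taxa, 12 genes; codons per gene ~ Normal(249, 60) clipped at
60 (249 ≈ 19,449/78); Yule tree rescaled to mean edge length 0.08
substitutions/site; base frequencies (A, C, G, T) = (.31, .18, .21, .30),
i.e. GC 39%; codon-position rate multipliers (1.0, 0.5, 2.5); gamma
(shape 0.8) codon-rate variation; per-gene lognormal(0, 0.4) rate
multipliers and ±0.06 jitter on the subtype equilibria (plastid genes
differ in both speed and composition); occupancy per gene
0.5 + 0.5·Beta(5.5, 2.5), whose mean (≈ 0.844) puts global missingness
near 15.6%; IR duplication probability 0.25 per gene with 10% of copies
receiving one point difference; paralog probability 0.1 per gene over 55%
of its taxa; hit-table false-positive/negative rates 0.

**Layered GC machinery.** Sites evolve as a shared binary
purine/pyrimidine chain plus two independent *subtype* chains (A-vs-G
given purine, T-vs-C given pyrimidine). Lineage GC shifts act only on the
subtype equilibria: inside a shifted clade both subtype equilibria move
to the target GC (re-equilibrating fully on the clade's stem edge), with
third positions shifted hardest (targets 0.15 and 0.70 for the two
default clades, positions 1–2 moving 30% of the way), which reproduces
the observed pattern of a ~27–55% per-taxon GC range concentrated at
third positions. Because the class layer and the random streams that
drive it never depend on the shift map, re-running with shifts removed
changes the nucleotide matrix but leaves its RY projection
*byte-identical* — the package's sharpest statement of why RY recoding
neutralises this kind of bias. The composite process is a generative
construction, not a single stationary GTR; a plain GTR+Γ simulator
(`simulate_gtr_alignment`) is provided separately and is what the
likelihood calibration tests use.

**Stop codons.** A leaf codon that lands on TAA/TAG/TGA is repaired by a
within-pyrimidine T→C edit at position 1 (→ CAA/CAG/CGA), and one other
codon with C at position 1 is flipped back C→T (skipping flips that would
create a stop). The repair is deterministic, leaves the RY layer
untouched, and is composition-balanced; simple resampling would have tied
the random stream to the shift map and broken the exact RY invariance.
Residual effect on composition is negligible (stop repair touches a few
percent of codons and the compensation canceling is exact except when a
sequence runs out of C-initial codons).

**Simulated e-values are labels** for threshold rehearsal, not
statistics: within-gene pairs get 1e-25..1e-15, within-taxon duplicate
pairs 1e-180 (IR-grade), paralog cross-pairs (1e-6, 1e-5] (pass the
default filter, separate at the first stringency step), spurious
cross-gene pairs (1e-5, 1e-3] (removed by the default filter).

**What passing tests do not show.** The generator emits already-aligned,
gap-free genes (no indel process, no alignment error), a correct guide
tree for model selection, and hit tables whose errors are parametric
rather than alignment-driven. Tests passing on it validate the
bookkeeping, the statistics and the algorithms — not the robustness of
single-linkage clustering to real BLAST noise, nor trimming behaviour on
genuinely misaligned regions, nor model selection under tree error.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at the
default 40 × 12 scale (model selection over 1/3/12/36 partitions on a
~9,000-column matrix) and the combinatorial checks at full size
(58,347-column matrices, 360-taxon trees, 78-gene schemes), sizes chosen
so the whole suite completes in minutes on one CPU. Statistical
properties use: 200 replicates for the chi-square type-I calibration
(star tree, 15 taxa × 300 sites, exact binomial 99% acceptance band); 10
replicates for the AICc partition-preference check (5 taxa, 3 genes × 400
sites, strong heterogeneity; the effect is orders of magnitude beyond the
ΔAICc > 10 criterion); 6,000 sites for gamma-shape recovery (±20%).
Likelihood tolerances: pruning vs enumeration 1e-8; optimisation
convergence 1e-4 lnL per round; frequencies bounded away from 0 by the
±6 log-odds box; e-value floor 1e-30.

## Known limitations

- No multiple sequence alignment, tree search, or bootstrap replicate
  generation (out of scope by design; external tools own those steps).
- The trimmer is a gap-fraction census, not a heuristic block filter.
- One empirical AA matrix (WAG); no per-partition AA model selection.
- Exact decisiveness over all trees is limited to ~7 taxa (double
  factorial growth); beyond that only sampled one-sided evidence.
- The chi-square test and the GC regressions ignore phylogenetic
  dependence, deliberately mirroring standard practice.
- The layered simulator's cross-class events ignore subtype state, which
  is what makes RY invariance exact but also means it is not a GTR
  process; parameter-recovery claims use the plain GTR simulator.
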
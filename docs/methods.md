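# Methods

This note documents the models, conventions and numerical choices behind
`musicpipe`, and what the synthetic-data experiments do and do not show.

## Read architecture and demultiplexing

R2 is parsed at fixed offsets: three 14 nt cell barcodes in third,
second, first order, each followed by a constant spacer, then the
modality linker, then the insert.  The exact spacer bases between
barcode blocks are a library-construction detail that varies by reagent
design; the package defines one canonical 7 nt spacer dialect (matching
the 7 nt top-strand overhang of the combinatorial barcodes) and makes it
configurable so a different dialect can be declared for real data.

Linker classification uses the two signatures that share the `CGAGGAG`
prefix: RNA = `CGCTT` + 5 nt UMI + `ATAGCATTGC`, DNA = 5 nt UMI +
`ACAACGCACAGTGTCTAGT`.  Tolerances are ≤1 mismatch per RNA segment and
≤2 over the DNA suffix; a read matching both (or neither) is rejected as
ambiguous rather than guessed.  Whitelist matching allows one
substitution per cell barcode and per GEM barcode and none for I7;
because whitelists are built with minimum pairwise Hamming distance 3, a
single-substitution rescue is always unique, and any sequence within
tolerance of two entries is rejected.  These tolerances are a design
choice of this implementation: the governing principle is that a barcode
is never assigned ambiguously.

Insert trimming: DNA inserts lose a 3′-terminal homopolymer run of A or
G when the run exceeds 20 bp (the poly-A/G artifact of the droplet
barcoding chemistry); RNA inserts are truncated at the first occurrence
of the RNA-linker ssDNA `CGAGGAGCGCTT` (read-through into a downstream
linker).  Both are then 3′ quality-trimmed with the BWA/cutadapt
running-sum rule at Q15 and dropped below 20 bp.  The named parameter is
`-q 15 -m 20`; the running-sum algorithm is the documented behaviour of
that parameter, which is why it is implemented here rather than a naive
per-base cutoff.

## Mapping and duplicate removal

Synthetic genomes are desk-scale (hundreds of kb), so the mapper is an
exact k-mer seed index (k = 20) with full-length verification on both
strands; reads hitting two or more loci are `multi`, and only `unique`
reads proceed.  Real alignments enter through BAM import: primary
records with MAPQ ≥ 30 count as unique (MAPQ 30 is the conventional
proxy for "uniquely mapped"; the tag set B1/B2/B3/BG/QG/QL/BI/MM carries
the barcode stack).

Duplicate marking is a single coordinate-sorted scan.  A read is a PCR
duplicate of an already-retained read when (1) it maps within 8 bp on
the same chromosome and strand, (2) it shares all five barcodes, and
(3) its UMI is within Levenshtein distance 1.  "UMI" here is the 17 nt
concatenation of the 12 nt GEM UMI and the 5 nt linker UMI: the
concatenation keeps both identifiers in play while the <2 threshold
still tolerates a single sequencing error anywhere.  Opposite-strand
reads are never duplicates (they are distinct ligation events).  The
simulator guarantees GEM UMIs within one complex are ≥3 apart in Hamming
distance, so at zero sequencing error the retained count equals the true
molecule count exactly — the property the acceptance suite asserts.

## Cluster decomposition and weights

"All non-overlapping pairs" of a homotypic cluster is read as all
C(N, 2) unordered combinations, each down-weighted by 1/N — the only
reading under which the per-pair factor makes the total (N−1)/2 and is
consistent with the heterotypic "all RNA–DNA pairs" at 1/(M+N)
(SPRITE-style normalisation).  When a genomic region is given, cluster
membership and size are recomputed on region-restricted reads first.

DNA reads inside RNA–DNA clusters feed DNA–DNA analyses through an
explicit `mode="dna_dna"` decomposition (all DNA pairs at 1/cluster-size),
because distance-decay analyses pool DNA reads from both cluster types
while RNA-split analyses keep them separate.  The XIST⁻ set includes
DNA-only clusters by default (configurable).

Census percentages are shares among non-singleton clusters of a type,
reported to two decimals with half-up rounding.

## Distance decay and per-cell profiles

*P*c(*s*) divides 10 bp – 150 Mb into 500,000 equal-width linear bins
(~300 bp each); "equally sized" is taken in linear distance, with log
display left to plotting.  Two aggregation modes exist: per-cell
normalisation to unit mass before summing (`per_cell_then_sum`, the
single-cell default) and pooled histogramming (`pool_all`).  Arm tables
(each synthetic chromosome declares one boundary) optionally restrict
pairs to within-arm distances.

The per-cell log-binned profile uses 150 log2-spaced bins from 5,000 bp
to 1.5×10⁸ bp, generated by the edge formula
2^(log2(5000) + n·(log2(1.5e8)−log2(5000))/150), n = 0..150.  The bin
count follows the formula's index range (n = 1..150), i.e. 150 bins and
151 edges; a stated count of 149 elsewhere is an off-by-one the formula
overrides.  Bin mass is divided by bin width and then normalised to unit
total per cell.

Decay-exponent estimation re-aggregates the linear-bin curve into 50
log-spaced bins, converts mass to density by bin width and fits ordinary
least squares on the log–log scale over non-empty bins; at n = 10⁵
planted power-law pairs this recovers the exponent to ~0.002, well
inside the ±0.1 acceptance band.

Compartment scores are PC1 of the correlation matrix of the
observed/expected map, the expected map being the distance-stratified
mean.  The eigenvector sign is arbitrary; it is oriented by positive
correlation with a caller-supplied reference vector (e.g. gene density),
since no intrinsic orientation rule exists.  Matrices need ≥10
informative bins; degenerate (constant) maps raise instead of returning
noise.

## RNA-side analytics

Pre-mRNA classification demands ≥15 bp same-strand overlap with an
intron of a protein-coding gene.  RAL tracks weight each selected-RNA ×
DNA pair by 1/(M+N), where M counts only the selected RNA reads in the
cluster; clusters above 1,000 members are excluded.  XAL counts distinct
1 Mb chrX bins with any positive XIST RAL — no minimum weight threshold,
since none is established; the threshold is configurable.  XAL
stratification separates the zero group, then cuts the positive cells,
sorted by (XAL, cell id) for determinism, into three contiguous groups
whose sizes differ by at most one.

## Cell-state metrics

The LCS-erosion score takes the ten log-spaced bins with the highest
width-normalised contact frequency (ties resolved toward shorter
distances), and scores the cell as the median of their bin midpoints.
Midpoints are geometric means of the bin edges — the natural centre of a
log-spaced bin — and the median of ten values averages the 5th and 6th
order statistics; "middle point" admits other readings, and this one is
flagged as an interpretation.  Cells with fewer than ten non-empty bins
use all of them and carry a low-confidence flag.  The eroded/preserved
threshold is 3×10⁵ bp.

Transcriptomic age: gene directions are the sign of the correlation
between per-sample mean expression and sample chronological age
(computed globally, not per cell type; a per-type option would be a
straightforward extension), weights are (proportion of cells with raw
count > 0) × direction, and a cell's age is the dot product of its
per-gene expression z-scores with the weights.  "Expressing" means raw
count > 0; "average expression" uses log-normalised values
(ln(1 + 10⁴·x/library)); both conventions are configurable.  Z-scoring
makes the score invariant to per-gene affine rescaling, which the
property suite verifies.

Gene–score association: an "ANOVA" of expression against a continuous
score is implemented as the F-test of a univariate linear regression
(F = t² of the slope, df (1, n−2)) — the only reading that yields both
an F statistic and a Spearman ρ on the same inputs; a grouped
(eroded vs preserved) mode can be obtained by discretising the score
first.  A gene passes with P < 0.01, F > 1 and |ρ| > 0.1; constant genes
are skipped.

## eQTL association

A contact supports an eQTL–target pair when one end overlaps the variant
(treated as a 1 bp interval; input positions are 1-based and converted)
and the other end overlaps the promoter, the closed interval
TSS ± 2,500.  Tables cross contact cell type (rows) × eQTL cell type
(columns); the global test is Pearson's chi-square without continuity
correction (6×6 → df 25).  Per-type 2×2 reductions give OR = ad/bc with
the Wald CI exp(log OR ± 1.96·SE), SE = √(1/a+1/b+1/c+1/d); a zero cell
triggers the Haldane–Anscombe +0.5 correction, flagged in the result.

The calibration simulator plants the odds ratio directly: focal-type
contacts support same-type pairs with probability p₁ where
odds(p₁) = K·odds(p₀), so the planted 2×2 OR is exactly K and CI
coverage is interpretable.  (A 6×6 model with K-fold diagonal enrichment
has per-type ORs of K(K+4)/5 ≠ K, which would conflate model and
estimator.)  Null calibration draws independent contact and pair types
and checks the global p-value against uniformity.

## What the synthetic data emulates — and what it does not

The generator reproduces the structural features the pipeline logic
depends on: the barcode stack and linker architecture, the cluster-size
mixture (singleton fraction 0.25; among non-singletons, size 2 with
p₂ = 0.7226 — the observed pairwise share — and a power law with
exponent 2.5 truncated at 15 for sizes ≥3), power-law intra-complex
distances (exponent 1.2 on 1–80 kb by default, chromosome-wide spreading
for XIST complexes), Poisson PCR duplication, and exact per-read truth
tables.  Base qualities are constant Q30 except for injected low-quality
tails (which deterministically exercise the Q15 trimming path), and RNA
inserts are emitted in transcript-sense orientation so the pipeline is
strand-specific end to end.

Not emulated: realistic sequencing error profiles, chimeric reads,
index hopping, genome repeat structure beyond deliberately planted
repeats, spliced RNA alignment, or real genome scale.  Passing tests
therefore demonstrate the correctness of the algorithms under the
declared generative laws — barcode resolution, exact dedup, weight
accounting, statistical calibration — not robustness to every artifact
of real libraries; real data should enter through the BAM import path
after external alignment.

## Problem sizes and determinism

The test and acceptance runs use desk-scale sizes chosen to make the
statistical checks decisive while staying fast: 120 kb chromosomes,
200 cells / ~55,000 reads for the round trip, 10⁵ pairs for exponent
recovery, 400 cells for LCS classification, 500 cells × 50 genes for
age recovery, and 100/200 replicates for CI coverage and null
calibration.  All randomness flows through `numpy.random.default_rng`
seeds derived from a single `--seed`, and repeated runs are
byte-identical.

## Known limitations

* The exact mapper requires exact matches; substitution noise lowers
  mapping rates rather than producing mismatched alignments.
* The 500,000-bin *P*c(*s*) histogram is memory-proportional to its bin
  count (~4 MB per curve); per-cell curves are accumulated streaming,
  never stored per cell.
* Cell typing assumes cluster labels are supplied (graph clustering and
  embedding are out of scope); scores depend on marker-list quality.
* The GEM whitelist is a synthetic stand-in (default 1,024 barcodes, 3.5
  million in the commercial kit); its size is configurable and does not
  affect any statistic tested here.
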
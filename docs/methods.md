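# Methods

`retromzt` implements the computational analyses used to study
transposable-element (TE) activation across the mouse maternal-to-zygotic
transition (MZT): TE quantification under multi-mapping, chimeric TE–gene
transcript detection from split reads, nine-class time-series expression
labels, TE–gene association statistics, permutation enrichment near TSSs,
and siRNA target scanning. Because embryo RNA-seq at desk scale is not
available, every stage is exercised against a synthetic genome/alignment
generator that plants full ground truth.

## Coordinate and overlap conventions

All intervals are 0-based half-open internally; GTF (1-based closed) and BED
(0-based half-open) are converted at the format boundary only. Overlap is
strand-agnostic throughout — the data are single-end and unstranded — with
strand kept for reporting (TSS orientation). A split read's footprint is the
union of its reference-consuming CIGAR runs (M/D/=/X), with N gaps excluded.

## Synthetic data generator

The generator emulates the structure of single-embryo RNA-seq across three
stages (oocyte, 1-cell, 2-cell) and two genotypes (wild type and a
maternal-factor knockout), with 11 samples per group (66 samples total) by
default.

* **Genome and annotation.** Two 400 kb chromosomes plus a 16 kb
  mitochondrial contig. Five repeat element consensus sequences span three
  RepeatMasker levels: an ERVL-family internal element (`MERVL-int-sim`,
  1.6 kb) and its LTR-like partner (`MT2-sim`, identical to the internal
  element's 5' 300 bp), an ERVK LTR element, a LINE and a SINE. Copies are
  duplicated at 95% identity (configurable). Cross-element sequence sharing
  (MT2 = the ERVL 5' region; shorter shared prefixes for ERVK and the LINE)
  creates the multi-mapping structure: reads that are element-ambiguous but
  family-unambiguous, family-ambiguous but class-unambiguous, and (rarely)
  class-ambiguous. Genes carry 2–3 exons (150–400 bp) with introns.
* **Full-length vs truncated internal elements.** A configurable number
  (default 5 of 10) of internal-element copies keep the full consensus,
  which embeds a gag-like and a pol-like 120 bp region and carries the
  MuERV-L siRNA target site verbatim. Full-length means intact coding, so
  the gag/pol regions and the siRNA site are protected from the per-copy
  mutation process in full-length copies. The remaining copies are
  truncated to the 5' 700 bp and therefore lack the pol region.
* **Expression programs.** Gene counts are negative binomial
  (gamma–Poisson, dispersion 0.1 by default) with group means set by one of
  the nine dynamics classes (per-transition fold change 8 by default;
  per-gene base mean log-normal around 50). In the knockout, a configured
  fraction (0.6) of EU genes has the 2-cell mean multiplied by 0.25
  (dampened zygotic activation) and the same fraction of ED genes retains
  its 1-cell mean at the 2-cell stage (failed maternal decay).
* **Alignments.** 51 bp single-end reads (matching the exon-gap rule, which
  follows the configured read length) are emitted directly — the aligner is
  out of scope. TE read share per library rises from 8% (oocyte) to 30%
  (2-cell), driven by a 2-cell ERVL burst in the per-element stage-activity
  table. A configured fraction (0.25) of TE reads is multi-mapped: all
  alignments are emitted at the same offset of a homologous region, with
  the SAM NH tag set to the multiplicity. Same-element homology dominates
  group choice (weights 0.50/0.40/0.07/0.03 for element, ERVL-cross,
  LTR-cross, class-cross), which yields the qualitative ambiguity pattern
  seen in repeat analysis (class ≈ 98%, family ≈ 95%, element ≈ 69% on the
  default dataset). Planted chimeric junctions run from an internal-element
  copy 3' end to a downstream first-exon start, supported by `kM nN mM`
  split reads; translocated junctions are two soft-clipped pieces of one
  read on different chromosomes. Mitochondrial reads are placed on the
  dedicated contig at a per-sample fraction (default 2%). Read names encode
  kind and true feature for test-time joins, and a per-read origin table is
  returned.

What the generator does **not** emulate: sequencing errors and quality
scores, paired-end structure, batch effects, realistic repeat genealogies,
intronic/intergenic background reads and degradation. Passing tests
therefore demonstrate correctness of the counting, calling and testing
machinery under clean geometry — not robustness to alignment noise in real
embryo data.

## Sample QC

A sample passes iff exon-mapped reads > 500,000 AND the fraction of reads on
mitochondrial contigs < 10%, both strict inequalities. "Exon-mapped" is
approximated as reads whose alignment overlaps any annotated exon.
Mitochondrial reads are recognized by contig name (configurable list), not
by a fixed gene set. On synthetic data the exon floor is rescaled to the
toy library size; the decision rule itself is unchanged.

## TE counting and ambiguity

Two modes: `unique_only` (multiplicity-1 reads) and
`unique_plus_one_random` (one alignment per multi-read, uniform, seeded —
the printed sentence behind this is ambiguous between one-random and
all-alignments counting, so an `all_alignments` variant is exposed without
claiming either is canonical). A retained read is assigned iff its segments
overlap exactly one distinct feature label at the counting level
(element = repName, family, class, or per-genomic-copy rows); reads touching
two or more labels are discarded as ambiguous, mirroring htseq-count.
Reads overlapping both a gene exon and a TE still count toward the TE:
repeats are quantified against their own annotation. Per sample,
assigned + ambiguous + non-TE = retained (a tested conservation law).

The ambiguity report takes multi-reads whose alignments all land in TEs and
asks whether the labels agree at each level; agreement proportions are
necessarily non-increasing from class to family to element.

Normalization: within-sample divides by the sample's TE-mapped total (values
sum to 1 over features), between-sample divides by median-of-ratios size
factors (`factor_s = median_f count_{f,s} / geomean_f`). The TE expression
fraction is TE-assigned over all mapped reads under one-random counting.

## Chimeric transcript calling

Split reads (N-gapped CIGAR, one chromosome) and translocated reads (pieces
on two chromosomes) are extracted after keeping one alignment per
multi-read. A call requires one segment to overlap the exons of exactly one
gene (and no TE) and the other to overlap exactly one TE copy (and no gene
exon); any segment touching both annotations, or two features of a kind,
vetoes the read as ambiguous. Gene overlap uses exons including UTRs because
the junction is a splice onto exonic sequence; a whole-gene-body mode exists
behind a flag. Segments shorter than 8 bp (configurable) are not
overlap-tested, to avoid spurious anchors. Junction identity is exact
coordinates (TE-side end, gene-side start); no fuzzy merging.

## Differential testing and the nine-class scheme

The negative-binomial GLM of standard DE engines is deliberately not
reimplemented; the substitute is a two-sided Wilcoxon rank-sum test on
size-factor-normalized counts (exact for small tie-free samples, otherwise
asymptotic with tie correction), with an optional normal-approximation test
on log2(n+1) counts, and Benjamini–Hochberg adjustment over features passing
a mean-normalized-count ≥ 5 prefilter. The decision rules on top are the
point: DE at adjusted p < 0.05; a stage transition called U or D at adjusted
p < 0.1 with direction from the later- vs earlier-stage mean, E otherwise;
the two transition calls concatenate into the nine classes (EU = zygotically
activated, ED = maternal decay). Under these rules false transition calls on
truly-equal genes occur at the BH-consistent rate (≈ α × discoveries), which
is the dominant error mode; planted ED/EU labels are recovered at ≥ 90% with
8-fold effects and n = 10 per group.

## Co-expression network

Pairwise Pearson correlation ρ on log2(CPM+1), thresholded:
C_ij = ρ_ij if |ρ_ij| ≥ x else 0 (default x = 0.9). The rule is idempotent
and symmetric; zero-variance features are flagged and given no edges rather
than propagating NaN. Anchor-gene neighborhoods report positive (ρ ≥ x) and
negative (ρ ≤ −x) partners separately.

## Category enrichment

Per category: log2((|up∩cat| + c)/(|down∩cat| + c)) with c = 1 only when a
cell is zero (raw counts are reported alongside), and Fisher's exact p on
the [in-category vs not] × [up vs down] table. Categories are user-supplied
maps (e.g. MZT stage-program catalogs); no external ontology is queried.

## TE–gene association

* **Nearest-gene correlation.** TEs within 51 bp (= read length) of any
  exon including UTRs are excluded; the remaining TEs pair with the nearest
  gene by minimal interval-to-interval distance (0 when inside an intron;
  ties to the lower coordinate), capped at 1 Mbp. Spearman's coefficient
  with midranks is computed over the shared samples. TSS-anchored distance
  is used only where the TSS is the stated anchor (the permutation test).
* **DE overlap.** Genes with a DE TE within ±20 kb (window anchored at the
  TE) intersected with DE genes; upper-tail hypergeometric p over the tested
  gene universe.
* **TSS permutation test.** Observed statistic: mean number of
  (exon-overlap-free) depleted TEs within ±10 kb of focus-gene TSSs. Null:
  the same statistic for 10,000 size-matched gene sets drawn without
  replacement from the expressed universe; empirical
  p = (1 + #{null ≥ obs})/(N+1), the add-one convention avoiding p = 0.
* **Maternal/zygotic TEs.** Labels from the substitute test between WT
  oocyte and WT 2-cell at a caller-chosen α (the defining threshold is a
  parameter, not a claimed canonical value). Odds ratios use the sample
  cross-product estimate with Haldane's 0.5 correction on zero cells, and
  Fisher's exact p on the raw table.

## Full-length elements and siRNA scanning

Full-length internal-element copies are those overlapping occurrences of
both the gag and pol query sequences. Occurrences are found by semi-global
(infix) edit-distance alignment (edlib) within each copy interval plus a
50 bp flank, on both strands; a hit requires identity
1 − dist/|query| ≥ 0.9 (default), and infix mode aligns the entire query, so
query coverage is complete by construction.

The siRNA scan slides an ungapped window of siRNA length across both strands
and stratifies windows by Hamming distance 0/1/2. Ungapped matching is the
appropriate model for position-wise siRNA complementarity; gapped aligner
heuristics are not emulated. Hits split into on-target (overlapping a
full-length copy) and off-target; a copy counts at the stratum of its best
overlapping hit. The two study siRNAs ship as constants
(MuERV-L `GAAGAUAUGCCUUUCACCAGCUCUA`, scramble
`UUCCUCUCCACGCGCAGUACAUUUA`); U→T conversion precedes matching.

## Numerical choices and degenerate inputs

Seeded `numpy` generators drive every stochastic step (random alignment
retention, permutation draws, simulation); fixed seed ⇒ byte-identical
generator output. Zero-total samples, zero TE-mapped totals, absent common
nonzero features (size factors), empty focus sets and empty annotation
subsets raise explicit errors; an ambiguity report with no multi-reads is
marked empty rather than zero. Median-of-ratios size factors are
scale-equivariant in ratio (the geometric-mean reference rescales by
c^(1/n), so a doubled duplicate sample yields factors (1/√2, √2)).

## Problem sizes

Tests and the acceptance script run everything at toy scale, chosen so the
full suite stays comfortably under a quarter hour on one CPU: 66-sample
default datasets of ~400k reads for end-to-end runs, ≤10,000-read datasets
for exact brute-force oracle comparisons, 20 × 120-gene simulations for
class-recovery statistics, 500 × 1,000-permutation replications for
calibration, and ~100 kb genomes for exhaustive siRNA scan oracles.

## Known limitations

The substitute DE test has lower power than a parametric NB GLM at very
small n and does not shrink dispersions; study-specific gene lists, network
sizes and real-genome ambiguity percentages are not reproducible here by
design. Chimera calling reports read-level evidence only — no transcript
assembly or splice-motif scoring. The siRNA scan ignores indels and
thermodynamics. The generator's clean geometry (non-overlapping features,
no background noise) makes oracle equalities exact; real data would add
assignment noise that these tests do not measure.
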
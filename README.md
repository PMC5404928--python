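# retromzt

Analysis toolkit for transposable-element (TE) activation across the mouse
maternal-to-zygotic transition (MZT): TE expression quantification under
multi-mapping, chimeric TE–gene transcript detection from split reads,
nine-class time-series expression dynamics, TE–gene association statistics,
permutation enrichment of TEs near transcription start sites, and
genome-wide siRNA target scanning. A synthetic genome/alignment generator
with full ground truth makes every stage testable without any downloads.

It is written for computational biologists working on zygotic genome
activation, endogenous retrovirus (ERV/LTR) expression, or any setting
where repeat-derived reads are quantified from single-end RNA-seq
alignments.

## The core methods

* **TE counting.** Reads are counted against a RepeatMasker-style
  annotation at three hierarchy levels (repName / repFamily / repClass) in
  two modes: uniquely-mapped reads only, or all reads after keeping one
  random genomic alignment per multi-mapped read. A read is assigned iff it
  overlaps exactly one feature label at the counting level; reads touching
  two labels are discarded as ambiguous. The *ambiguity report* measures,
  per level, the fraction of multi-mapped TE reads whose alignments agree
  on the label — non-increasing from class to element. Expression estimates
  are within-sample (count / TE-mapped total) or between-sample
  (median-of-ratios size factors).
* **Chimeric transcripts.** Split (`kM nN mM` CIGAR) and translocated reads
  are resolved into genomic segments; a read supports a TE→gene chimera iff
  one segment overlaps the exons of exactly one gene and the other exactly
  one TE copy, both unambiguously.
* **Expression dynamics.** Each adjacent-stage transition
  (oocyte→1-cell, 1-cell→2-cell) is called U/D at BH-adjusted p < 0.1
  (rank-sum substitute test on size-factor-normalized counts), else E,
  giving nine classes EE…UU; class EU marks zygotically activated genes
  (ZAGs), ED maternal decay. Differential expression uses adjusted
  p < 0.05.
* **Association statistics.** Thresholded Pearson co-expression
  (C_ij = ρ_ij if |ρ_ij| ≥ x else 0 on log2(CPM+1)); nearest-gene Spearman
  correlation with a 51 bp exon-exclusion gap and a 1 Mbp cap;
  hypergeometric DE-set overlap within ±20 kb; and an empirical permutation
  test for depleted TEs within ±10 kb of ZAG TSSs against size-matched
  random gene sets.
* **siRNA targets.** Full-length internal elements are copies overlapping
  alignments of both gag and pol query sequences; the siRNA scan stratifies
  every genomic window (both strands) by Hamming distance 0/1/2 and reports
  target coverage per stratum.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from retromzt import simulate as sim, tequant as tq, chimera as chim
from retromzt import dynamics as dyn, sirna as sir

cfg = sim.SimulationConfig(seed=7)            # 66 samples, 2 genotypes x 3 stages
sequences, ann, truth, counts, alns = sim.simulate_all(cfg)

frac = tq.te_fraction(alns, ann, seed=0)      # TE share of mapped reads
amb = tq.assignment_ambiguity(alns, ann)      # multi-mapping ambiguity by level

splits = chim.extract_split_reads(alns, seed=0)
calls, stats = chim.call_chimeras(splits, ann)

t1 = dyn.differential_test(counts, counts.samples_where("1-cell", "WT"),
                           counts.samples_where("oocyte", "WT"))
t2 = dyn.differential_test(counts, counts.samples_where("2-cell", "WT"),
                           counts.samples_where("1-cell", "WT"))
labels = dyn.classify_dynamics(t1, t2, alpha=0.1)

internal = [t for t in ann.tes.values() if t.rep_name == "MERVL-int-sim"]
full = sir.find_full_length_elements(sequences, internal,
                                     truth.gag_query, truth.pol_query)
report = sir.sirna_scan(sir.MUERVL_SIRNA, sequences, full)
```

Output on this seed:

```
WT oocyte  TE fraction: 0.078
WT 1-cell  TE fraction: 0.120
WT 2-cell  TE fraction: 0.296
ambiguity: {'element': 0.685, 'family': 0.943, 'class': 0.983}
split reads: {'total': 529, 'called': 529, 'ambiguous': 0, 'non_chimeric': 0}
{'DD': 1, 'DE': 9, 'DU': 2, 'ED': 6, 'EE': 11, 'EU': 4, 'UD': 2, 'UE': 3, 'UU': 2}
full-length copies: 5 | perfect-match target coverage: 1.0 | scramble hits <=2 mm: 0
```

The TE fraction rises almost fourfold from oocyte to 2-cell — the planted
ERVL burst at zygotic genome activation. Multi-mapped reads are assignable
to a repeat class 98% of the time but to an individual element only 69% of
the time, which is why element-level analyses use unique counts while
family/class analyses may use multi-mapped counts. Every split read
resolves to its planted TE→gene junction, all five full-length
internal-element copies carry a perfect-match siRNA site, and the scramble
siRNA has no genomic target within two mismatches.

A command-line layer mirrors the library:
`retromzt simulate | qc | te-count | chimera | dynamics | network | sirna`
(see `retromzt --help`).

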
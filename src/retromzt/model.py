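"""Shared data model for annotation, alignments and count matrices.

Coordinate convention: all intervals are 0-based half-open internally.
Conversion to/from the 1-based closed GTF convention and the 0-based
half-open BED convention happens only at format boundaries (see `io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

STAGES = ("oocyte", "1-cell", "2-cell")
GENOTYPES = ("WT", "KO")

# repName -> repFamily -> repClass: the three RepeatMasker hierarchy levels.
TE_LEVELS = ("element", "family", "class")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    exons: tuple[tuple[int, int], ...]  # includes UTR exons

    @property
    def tss(self) -> int:
        """Transcription start site as a 0-based coordinate."""
        return self.start if self.strand != "-" else self.end - 1


@dataclass(frozen=True)
class TERecord:
    te_id: str
    chrom: str
    strand: str
    start: int
    end: int
    rep_name: str
    rep_family: str
    rep_class: str

    def label(self, level: str) -> str:
        if level == "element":
            return self.rep_name
        if level == "family":
            return self.rep_family
        if level == "class":
            return self.rep_class
        raise ValueError(f"unknown TE hierarchy level: {level!r}")


class GenomeAnnotation:
    """Gene models plus repeat (TE) records with interval indexes.

    Parameters
    ----------
    genes : iterable of GeneRecord
    tes : iterable of TERecord
    """

    def __init__(self, genes, tes):
        self.genes: dict[str, GeneRecord] = {g.gene_id: g for g in genes}
        self.tes: dict[str, TERecord] = {t.te_id: t for t in tes}
        for g in self.genes.values():
            for s, e in g.exons:
                if s < g.start or e > g.end:
                    raise ValueError(
                        f"exon [{s},{e}) of {g.gene_id} outside gene interval"
                    )
        self._exon_trees: dict[str, IntervalTree] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        self._te_trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            gt = self._gene_trees.setdefault(g.chrom, IntervalTree())
            gt.addi(g.start, g.end, g.gene_id)
            et = self._exon_trees.setdefault(g.chrom, IntervalTree())
            for s, e in g.exons:
                if e > s:
                    et.addi(s, e, g.gene_id)
        for t in self.tes.values():
            tt = self._te_trees.setdefault(t.chrom, IntervalTree())
            tt.addi(t.start, t.end, t.te_id)

    # -- interval queries (strand-agnostic) --------------------------------
    def overlapping_genes(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._gene_trees.get(chrom)
        return {iv.data for iv in tree.overlap(start, end)} if tree else set()

    def overlapping_exon_genes(self, chrom: str, start: int, end: int) -> set[str]:
        """Gene ids with >=1 exon (incl. UTRs) overlapping [start, end)."""
        tree = self._exon_trees.get(chrom)
        return {iv.data for iv in tree.overlap(start, end)} if tree else set()

    def overlapping_tes(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._te_trees.get(chrom)
        return {iv.data for iv in tree.overlap(start, end)} if tree else set()

    def overlaps_any_exon(self, chrom: str, start: int, end: int, gap: int = 0) -> bool:
        """True if [start,end) lies within `gap` bp of any exon (0 = touch/overlap)."""
        return bool(self.overlapping_exon_genes(chrom, start - gap, end + gap))


@dataclass
class Alignment:
    """One genomic alignment of a read (one SAM line)."""
    chrom: str
    pos: int          # 0-based leftmost
    cigar: str
    segments: tuple[tuple[int, int], ...] = ()  # reference-consuming runs


@dataclass
class ReadAlignments:
    """All alignments of one single-end read in one sample.

    `multiplicity` is the number of genomic alignments (SAM NH tag).  A
    translocated read is a single genomic alignment split across two
    chromosomes and therefore has multiplicity 1 with two pieces.
    """
    read_id: str
    sample_id: str
    alignments: list[Alignment]
    multiplicity: int = 1
    translocated: bool = False


@dataclass
class AlignmentSet:
    reads: list[ReadAlignments]

    @property
    def sample_ids(self) -> list[str]:
        return sorted({r.sample_id for r in self.reads})

    def by_sample(self) -> dict[str, list[ReadAlignments]]:
        out: dict[str, list[ReadAlignments]] = {}
        for r in self.reads:
            out.setdefault(r.sample_id, []).append(r)
        return out


class CountMatrix:
    """Integer features x samples counts with per-sample metadata.

    Metadata must provide `stage` and `genotype` for every sample; `batch`
    is optional and defaults to a single batch.
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame):
        counts = counts.astype(np.int64, copy=False)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in counts.columns if s not in metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        for col in ("stage", "genotype"):
            if col not in metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        metadata = metadata.loc[list(counts.columns)].copy()
        if "batch" not in metadata.columns:
            metadata["batch"] = "batch1"
        self.counts = counts
        self.metadata = metadata

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_where(self, stage=None, genotype=None) -> list[str]:
        m = self.metadata
        mask = pd.Series(True, index=m.index)
        if stage is not None:
            mask &= m["stage"] == stage
        if genotype is not None:
            mask &= m["genotype"] == genotype
        return list(m.index[mask])

    def subset_features(self, ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(ids)], self.metadata)


@dataclass
class QCReport:
    """Per-sample mapping QC: exon-mapped reads and mitochondrial fraction."""
    table: pd.DataFrame  # index: sample; columns: exon_reads, mito_fraction[, pass]

    def __post_init__(self):
        frac = self.table["mito_fraction"]
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("mito_fraction must lie in [0, 1]")
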
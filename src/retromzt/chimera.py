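"""Chimeric TE->gene transcript detection from split and translocated reads.

A split read carries an N gap in its CIGAR and stays on one chromosome; a
translocated read's alignment pieces sit on different chromosomes.  A
chimeric call requires one segment to overlap exactly one gene's exons (and
no TE) and the other to overlap exactly one TE copy (and no gene exon) —
the dual-annotation "unambiguous overlap" rule.  Gene overlap is evaluated
against exons including UTRs because chimeric junctions are splice events
onto exonic sequence; whole-gene-body overlap is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import cigar_segments
from .model import AlignmentSet, GenomeAnnotation, ReadAlignments

DEFAULT_MIN_ANCHOR = 8  # bp; segments shorter than this are not overlap-tested


def segment_coordinates(cigar: str, pos: int, chrom: str):
    """Reference segments of a CIGAR at 1-based leftmost position `pos`.

    Returns a list of (chrom, start, end) with 0-based half-open intervals.
    """
    return [(chrom, s, e) for s, e in cigar_segments(cigar, pos - 1)]


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int


@dataclass
class SplitRead:
    read_id: str
    sample_id: str
    segments: tuple[Segment, ...]
    kind: str  # split_same_chromosome | translocated

    def __post_init__(self):
        if len(self.segments) < 2:
            raise ValueError("a split read needs >= 2 segments")


@dataclass(frozen=True)
class ChimericCall:
    read_id: str
    sample_id: str
    gene_id: str
    te_id: str
    gene_segment: Segment
    te_segment: Segment
    junction: tuple[str, int, str, int]  # (te_chrom, te_end, gene_chrom, gene_start)


def extract_split_reads(alns: AlignmentSet, seed: int = 0) -> list[SplitRead]:
    """Split (N-gapped, same chromosome) and translocated (pieces on
    different chromosomes) reads; one genomic alignment kept per
    multi-mapped read, chosen uniformly at random (seeded)."""
    rng = np.random.default_rng(seed)
    out: list[SplitRead] = []
    for read in alns.reads:
        if read.translocated:
            segs = tuple(Segment(a.chrom, s, e)
                         for a in read.alignments for s, e in a.segments)
            out.append(SplitRead(read.read_id, read.sample_id, segs, "translocated"))
            continue
        if read.multiplicity > 1:
            aln = read.alignments[int(rng.integers(0, len(read.alignments)))]
        else:
            aln = read.alignments[0]
        if len(aln.segments) >= 2:
            segs = tuple(Segment(aln.chrom, s, e) for s, e in aln.segments)
            out.append(SplitRead(read.read_id, read.sample_id, segs,
                                 "split_same_chromosome"))
    return out


def _classify_segment(seg: Segment, ann: GenomeAnnotation, use_exons: bool):
    if use_exons:
        genes = ann.overlapping_exon_genes(seg.chrom, seg.start, seg.end)
    else:
        genes = ann.overlapping_genes(seg.chrom, seg.start, seg.end)
    tes = ann.overlapping_tes(seg.chrom, seg.start, seg.end)
    return genes, tes


def call_chimeras(splits, ann: GenomeAnnotation,
                  min_anchor: int = DEFAULT_MIN_ANCHOR,
                  use_exons: bool = True):
    """Apply the dual-annotation rule to each split read.

    Returns (calls, stats) where stats partitions the input:
    called + ambiguous + non_chimeric = total.
    """
    calls: list[ChimericCall] = []
    stats = {"total": 0, "called": 0, "ambiguous": 0, "non_chimeric": 0}
    for sr in sorted(splits, key=lambda r: r.read_id):
        stats["total"] += 1
        segs = [s for s in sr.segments if s.end - s.start >= min_anchor]
        sides = [_classify_segment(s, ann, use_exons) for s in segs]
        # a segment touching both a gene and a TE makes the read ambiguous
        if any(genes and tes for genes, tes in sides):
            stats["ambiguous"] += 1
            continue
        gene_idx = [i for i, (g, t) in enumerate(sides) if g]
        te_idx = [i for i, (g, t) in enumerate(sides) if t]
        if not gene_idx or not te_idx:
            stats["non_chimeric"] += 1
            continue
        if len(gene_idx) > 1 or len(te_idx) > 1:
            stats["ambiguous"] += 1
            continue
        genes, tes = sides[gene_idx[0]][0], sides[te_idx[0]][1]
        if len(genes) != 1 or len(tes) != 1:
            stats["ambiguous"] += 1
            continue
        gseg, tseg = segs[gene_idx[0]], segs[te_idx[0]]
        calls.append(ChimericCall(
            sr.read_id, sr.sample_id, next(iter(genes)), next(iter(tes)),
            gseg, tseg,
            junction=(tseg.chrom, tseg.end, gseg.chrom, gseg.start)))
        stats["called"] += 1
    return calls, stats


def quantify_chimeras(calls, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read support per (TE copy, gene, junction), per sample and — when
    stage/genotype metadata is given — per group."""
    if not calls:
        return pd.DataFrame(columns=["te_id", "gene_id", "te_chrom", "te_end",
                                     "gene_chrom", "gene_start", "support"])
    rows = [{"te_id": c.te_id, "gene_id": c.gene_id,
             "te_chrom": c.junction[0], "te_end": c.junction[1],
             "gene_chrom": c.junction[2], "gene_start": c.junction[3],
             "sample": c.sample_id} for c in calls]
    df = pd.DataFrame(rows)
    keys = ["te_id", "gene_id", "te_chrom", "te_end", "gene_chrom", "gene_start"]
    per_sample = df.groupby(keys + ["sample"]).size().unstack(fill_value=0)
    out = per_sample.copy()
    out["support"] = per_sample.sum(axis=1)
    if metadata is not None:
        groups = metadata["genotype"].astype(str) + "_" + metadata["stage"].astype(str)
        for grp in sorted(groups.unique()):
            cols = [s for s in per_sample.columns if s in groups.index
                    and groups[s] == grp]
            out[f"group:{grp}"] = per_sample[cols].sum(axis=1) if cols else 0
    return out.reset_index()
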
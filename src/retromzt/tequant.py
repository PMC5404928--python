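"""TE expression quantification under multi-mapping.

Two counting modes mirror the uniquely-mapped and uniquely-plus-multi-mapped
count tables of repeat analysis pipelines:

* ``unique_only`` counts only reads with a single genomic alignment;
* ``unique_plus_one_random`` first keeps one alignment per multi-mapped read,
  chosen uniformly at random (seeded), then counts every retained read.

A retained read is assigned to a repeat feature iff the union of its aligned
segments (CIGAR N gaps excluded) overlaps exactly one distinct feature label
at the counting level; reads touching two or more distinct labels are
discarded as ambiguous, mirroring htseq-count's ambiguous policy.  Reads
overlapping both a gene exon and a TE still count toward the TE: repeats are
counted against the repeat annotation independently of gene models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AlignmentSet, GenomeAnnotation, ReadAlignments, TE_LEVELS

MODES = ("unique_only", "unique_plus_one_random", "all_alignments")


@dataclass
class TECountTable:
    level: str                      # element | family | class | copy
    mode: str
    counts: pd.DataFrame            # features x samples
    mapped_total: pd.Series         # retained reads per sample
    te_mapped_total: pd.Series      # reads assigned to a TE per sample
    ambiguous: pd.Series            # reads discarded as level-ambiguous
    hierarchy: pd.DataFrame         # columns rep_name, rep_family, rep_class

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("TE counts must be non-negative")


@dataclass
class AmbiguityReport:
    """Per-level proportion of multi-mapped TE reads whose alignments agree
    on that level's label.  `empty` marks the no-multi-read case."""
    proportions: dict[str, float] = field(default_factory=dict)
    n_reads: int = 0
    empty: bool = False


def _select_alignments(read: ReadAlignments, mode: str, rng) -> list:
    """Alignments retained for a read under the counting mode, or [] if the
    read is dropped (multi-mapped under unique_only)."""
    if read.multiplicity <= 1:
        return list(read.alignments)
    if mode == "unique_only":
        return []
    if mode == "unique_plus_one_random":
        return [read.alignments[int(rng.integers(0, len(read.alignments)))]]
    if mode == "all_alignments":
        return list(read.alignments)
    raise ValueError(f"unknown counting mode: {mode!r}")


def _te_labels(ann: GenomeAnnotation, alignments, level: str) -> set[str]:
    """Distinct TE labels at `level` overlapped by the aligned segments."""
    ids: set[str] = set()
    for a in alignments:
        for s, e in a.segments:
            ids |= ann.overlapping_tes(a.chrom, s, e)
    if level == "copy":
        return ids
    return {ann.tes[i].label(level) for i in ids}


def _hierarchy_frame(ann: GenomeAnnotation) -> pd.DataFrame:
    rows = [{"copy_id": t.te_id, "rep_name": t.rep_name,
             "rep_family": t.rep_family, "rep_class": t.rep_class}
            for t in ann.tes.values()]
    return pd.DataFrame(rows).set_index("copy_id") if rows else pd.DataFrame(
        columns=["rep_name", "rep_family", "rep_class"])


def count_te(alns: AlignmentSet, ann: GenomeAnnotation,
             mode: str = "unique_only", seed: int = 0,
             level: str = "element") -> TECountTable:
    """Count reads per repeat feature at the requested hierarchy level.

    `level` may be element/family/class (repName/repFamily/repClass labels)
    or "copy" for per-genomic-copy rows.
    """
    if mode not in MODES:
        raise ValueError(f"unknown counting mode: {mode!r}")
    if level not in TE_LEVELS + ("copy",):
        raise ValueError(f"unknown level: {level!r}")
    rng = np.random.default_rng(seed)
    samples = alns.sample_ids
    counts: dict[str, dict[str, int]] = {}
    mapped = {s: 0 for s in samples}
    te_mapped = {s: 0 for s in samples}
    ambiguous = {s: 0 for s in samples}
    for read in alns.reads:
        kept = _select_alignments(read, mode, rng)
        if not kept:
            continue
        s = read.sample_id
        mapped[s] += 1
        labels = _te_labels(ann, kept, level)
        if len(labels) == 1:
            te_mapped[s] += 1
            lab = next(iter(labels))
            counts.setdefault(lab, {})[s] = counts.setdefault(lab, {}).get(s, 0) + 1
        elif len(labels) > 1:
            ambiguous[s] += 1
    df = pd.DataFrame(counts).T.reindex(columns=samples).fillna(0).astype(np.int64)
    df = df.sort_index()
    return TECountTable(level, mode, df,
                        pd.Series(mapped), pd.Series(te_mapped),
                        pd.Series(ambiguous), _hierarchy_frame(ann))


def assignment_ambiguity(alns: AlignmentSet, ann: GenomeAnnotation) -> AmbiguityReport:
    """Fraction of multi-mapped TE reads whose alignments agree on the
    element / family / class label; non-increasing from class to element."""
    n = 0
    consistent = {lvl: 0 for lvl in TE_LEVELS}
    for read in alns.reads:
        if read.multiplicity <= 1:
            continue
        per_aln_ids = []
        for a in read.alignments:
            ids: set[str] = set()
            for s, e in a.segments:
                ids |= ann.overlapping_tes(a.chrom, s, e)
            per_aln_ids.append(ids)
        if not all(per_aln_ids):
            continue  # only reads whose alignments all land in TEs
        n += 1
        for lvl in TE_LEVELS:
            labels = set()
            for ids in per_aln_ids:
                labels |= {ann.tes[i].label(lvl) for i in ids}
            if len(labels) == 1:
                consistent[lvl] += 1
    if n == 0:
        return AmbiguityReport(empty=True)
    return AmbiguityReport({lvl: consistent[lvl] / n for lvl in TE_LEVELS}, n)


def te_fraction(alns: AlignmentSet, ann: GenomeAnnotation,
                seed: int = 0) -> pd.Series:
    """Per-sample fraction of mapped reads assigned to any TE, after keeping
    one random alignment per multi-mapped read."""
    rng = np.random.default_rng(seed)
    mapped: dict[str, int] = {}
    te: dict[str, int] = {}
    for read in alns.reads:
        kept = _select_alignments(read, "unique_plus_one_random", rng)
        s = read.sample_id
        mapped[s] = mapped.get(s, 0) + 1
        hit = any(ann.overlapping_tes(a.chrom, seg[0], seg[1])
                  for a in kept for seg in a.segments)
        te[s] = te.get(s, 0) + int(hit)
    if not mapped or min(mapped.values()) == 0:
        raise ValueError("sample with zero mapped reads")
    return pd.Series({s: te.get(s, 0) / mapped[s] for s in sorted(mapped)},
                     name="te_fraction")


def normalize_te(table: TECountTable, method: str = "within_sample") -> pd.DataFrame:
    """within_sample: divide by the sample's TE-mapped read total (the
    within-sample expression estimate); between_sample: divide by
    median-of-ratios size factors."""
    if method == "within_sample":
        totals = table.te_mapped_total.reindex(table.counts.columns)
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise ValueError(f"zero TE-mapped total for sample(s): {bad}")
        return table.counts / totals
    if method == "between_sample":
        from .io import size_factors
        sf = size_factors(table.counts)
        return table.counts / sf
    raise ValueError(f"unknown normalization method: {method!r}")


def aggregate_hierarchy(table: TECountTable, level: str) -> TECountTable:
    """Sum element-level (repName) counts into family or class totals."""
    if table.level != "element":
        raise ValueError("aggregate_hierarchy expects an element-level table")
    if level not in ("family", "class"):
        raise ValueError(f"cannot aggregate to level {level!r}")
    col = {"family": "rep_family", "class": "rep_class"}[level]
    mapping = (table.hierarchy[["rep_name", col]]
               .drop_duplicates().set_index("rep_name")[col])
    missing = [e for e in table.counts.index if e not in mapping.index]
    if missing:
        raise KeyError(f"element(s) absent from hierarchy map: {missing}")
    agg = table.counts.groupby(mapping.loc[table.counts.index].to_numpy()).sum()
    agg.index.name = None
    return TECountTable(level, table.mode, agg.sort_index(),
                        table.mapped_total, table.te_mapped_total,
                        table.ambiguous, table.hierarchy)
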
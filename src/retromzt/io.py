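"""Readers/writers for FASTA, GTF, BED, SAM and count tables, plus the
sample-QC decision rule and library-size normalization primitives.

GTF coordinates are 1-based closed; BED coordinates 0-based half-open.
Everything is converted to the internal 0-based half-open convention on
the way in and back on the way out.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .model import (
    Alignment,
    AlignmentSet,
    CountMatrix,
    GeneRecord,
    GenomeAnnotation,
    QCReport,
    ReadAlignments,
    TERecord,
)

TE_ATTRS = ("repName", "repFamily", "repClass")
MITO_CHROMS = ("chrM", "chrMT", "MT")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_segments(cigar: str, pos0: int) -> tuple[tuple[int, int], ...]:
    """Maximal reference-consuming runs of a CIGAR as 0-based half-open
    intervals.  M/D/=/X consume reference; N splits segments; I/S/H/P
    consume none of the reference.
    """
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    segments: list[tuple[int, int]] = []
    ref = pos0
    seg_start = None
    for n_str, op in ops:
        n = int(n_str)
        if op in "MD=X":
            if seg_start is None:
                seg_start = ref
            ref += n
        elif op == "N":
            if seg_start is not None:
                segments.append((seg_start, ref))
                seg_start = None
            ref += n
        # I, S, H, P: no reference consumption
    if seg_start is not None:
        segments.append((seg_start, ref))
    if not segments:
        raise ValueError(f"CIGAR consumes no reference bases: {cigar!r}")
    return tuple(segments)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _parse_gtf_attrs(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gene_gtf(path) -> list[GeneRecord]:
    """Read gene models from GTF: `gene` records plus their `exon` children
    (UTR exons are ordinary exon records)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            chrom, _, feature, start, end, _, strand, _, attr_field = f[:9]
            try:
                s, e = int(start) - 1, int(end)  # 1-based closed -> half-open
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from None
            if s < 0 or e <= s:
                raise ValueError(f"{path}:{lineno}: malformed coordinates")
            attrs = _parse_gtf_attrs(attr_field)
            gid = attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id")
            rec = genes.setdefault(
                gid, {"chrom": chrom, "strand": strand, "interval": None, "exons": []}
            )
            if feature == "gene":
                rec["interval"] = (s, e)
            elif feature == "exon":
                rec["exons"].append((s, e))
    out = []
    for gid, rec in genes.items():
        exons = sorted(rec["exons"])
        iv = rec["interval"]
        if iv is None:  # tolerate exon-only GTFs
            iv = (min(s for s, _ in exons), max(e for _, e in exons))
        out.append(GeneRecord(gid, rec["chrom"], rec["strand"], iv[0], iv[1], tuple(exons)))
    return out


def read_te_gtf(path) -> list[TERecord]:
    """Read RepeatMasker-style TE records: one record per genomic copy with
    repName/repFamily/repClass attributes."""
    tes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            chrom, _, _, start, end, _, strand, _, attr_field = f[:9]
            try:
                s, e = int(start) - 1, int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from None
            attrs = _parse_gtf_attrs(attr_field)
            for key in TE_ATTRS:
                if key not in attrs:
                    raise ValueError(f"{path}:{lineno}: TE record missing {key!r}")
            te_id = attrs.get("gene_id", f"{attrs['repName']}|{chrom}:{s}-{e}")
            tes.append(
                TERecord(te_id, chrom, strand, s, e,
                         attrs["repName"], attrs["repFamily"], attrs["repClass"])
            )
    return tes


def read_te_bed(path) -> list[TERecord]:
    """Read TE records from BED6+3: name column holds the copy id and three
    extra columns hold repName, repFamily, repClass."""
    tes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(
                    f"{path}:{lineno}: TE BED needs 9 columns "
                    "(chrom start end id score strand repName repFamily repClass)"
                )
            chrom, start, end, te_id, _, strand = f[:6]
            try:
                s, e = int(start), int(end)  # already half-open
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from None
            tes.append(TERecord(te_id, chrom, strand, s, e, f[6], f[7], f[8]))
    return tes


def read_annotation(gene_gtf=None, te_gtf=None, te_bed=None) -> GenomeAnnotation:
    genes = read_gene_gtf(gene_gtf) if gene_gtf else []
    tes = []
    if te_gtf:
        tes.extend(read_te_gtf(te_gtf))
    if te_bed:
        tes.extend(read_te_bed(te_bed))
    return GenomeAnnotation(genes, tes)


def write_annotation(ann: GenomeAnnotation, gene_gtf, te_gtf) -> None:
    with open(gene_gtf, "w") as fh:
        for g in sorted(ann.genes.values(), key=lambda x: (x.chrom, x.start)):
            attr = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.chrom}\tretromzt\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attr}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tretromzt\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\t{attr}\n")
    with open(te_gtf, "w") as fh:
        for t in sorted(ann.tes.values(), key=lambda x: (x.chrom, x.start)):
            attr = (f'gene_id "{t.te_id}"; repName "{t.rep_name}"; '
                    f'repFamily "{t.rep_family}"; repClass "{t.rep_class}";')
            fh.write(f"{t.chrom}\tretromzt\texon\t{t.start + 1}\t{t.end}\t.\t"
                     f"{t.strand}\t.\t{attr}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif line and name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def write_sam(alns: AlignmentSet, path, chrom_lengths: dict[str, int]) -> None:
    """Write single-end records: one line per genomic alignment, NH set to the
    read's multiplicity, RG naming the sample."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_lengths.items()],
        "RG": [{"ID": s} for s in alns.sample_ids],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {c: i for i, c in enumerate(chrom_lengths)}
        for read in alns.reads:
            for i, a in enumerate(read.alignments):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = read.read_id
                rec.reference_id = tid[a.chrom]
                rec.reference_start = a.pos
                rec.cigarstring = a.cigar
                rec.mapping_quality = 255
                rec.flag = 0 if (i == 0 or read.translocated) else 256
                rec.set_tag("NH", read.multiplicity)
                rec.set_tag("RG", read.sample_id)
                out.write(rec)


def read_sam(path) -> AlignmentSet:
    """Group SAM lines by read name.  Multiplicity comes from NH; a read with
    NH=1 whose lines sit on different chromosomes is a translocated read
    (one alignment split across chromosomes)."""
    grouped: dict[tuple[str, str], list[Alignment]] = {}
    nh: dict[tuple[str, str], int] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            sample = rec.get_tag("RG") if rec.has_tag("RG") else "sample1"
            key = (rec.query_name, sample)
            cigar = rec.cigarstring
            aln = Alignment(
                chrom=rec.reference_name,
                pos=rec.reference_start,
                cigar=cigar,
                segments=cigar_segments(cigar, rec.reference_start),
            )
            grouped.setdefault(key, []).append(aln)
            if rec.has_tag("NH"):
                nh[key] = int(rec.get_tag("NH"))
    reads = []
    for (rid, sample), alignments in grouped.items():
        mult = nh.get((rid, sample), len(alignments))
        transloc = mult == 1 and len({a.chrom for a in alignments}) > 1
        reads.append(ReadAlignments(rid, sample, alignments, mult, transloc))
    return AlignmentSet(reads)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def write_count_matrix(m: CountMatrix, counts_path, metadata_path) -> None:
    m.counts.to_csv(counts_path, sep="\t", index_label="feature")
    m.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def read_count_matrix(counts_path, metadata_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CountMatrix(counts, metadata)


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------

def compute_qc(alns: AlignmentSet, ann: GenomeAnnotation,
               mito_chroms=MITO_CHROMS) -> QCReport:
    """Per-sample exon-mapped read counts and mitochondrial read fraction.

    A read counts toward exons if any alignment's segments overlap any
    annotated exon; mitochondrial reads are identified by contig name.
    """
    mito = set(mito_chroms)
    rows = {}
    for sample, reads in alns.by_sample().items():
        exon = 0
        mito_n = 0
        for r in reads:
            hits_exon = any(
                ann.overlapping_exon_genes(a.chrom, s, e)
                for a in r.alignments for s, e in a.segments
            )
            exon += hits_exon
            if all(a.chrom in mito for a in r.alignments):
                mito_n += 1
        rows[sample] = {"exon_reads": exon,
                        "mito_fraction": mito_n / len(reads) if reads else 0.0}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return QCReport(table)


def qc_filter(report: QCReport, exon_min: int = 500_000,
              mito_max: float = 0.10) -> pd.Series:
    """Sample passes iff exon reads > exon_min AND mito fraction < mito_max
    (both strict)."""
    t = report.table
    passed = (t["exon_reads"] > exon_min) & (t["mito_fraction"] < mito_max)
    report.table = t.assign(**{"pass": passed})
    return passed


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def cpm_log_transform(m: CountMatrix) -> pd.DataFrame:
    """log2(CPM + 1) per entry; CPM = count / sample total x 1e6."""
    counts = m.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = [s for s, t in zip(m.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero-total sample(s): {bad}")
    cpm = counts / totals * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=m.counts.index,
                        columns=m.counts.columns)


def size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors.

    factor_s = median over features (nonzero in every sample) of
    count_{f,s} / geometric_mean_f(count_f).
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no feature has nonzero counts in every sample")
    xp = x[allpos]
    log_geo = np.mean(np.log(xp), axis=1, keepdims=True)
    ratios = np.exp(np.log(xp) - log_geo)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns,
                     name="size_factor")


def normalized_counts(m: CountMatrix) -> pd.DataFrame:
    """Counts divided per sample by the median-of-ratios size factor."""
    sf = size_factors(m)
    return m.counts / sf
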
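"""Synthetic genome, annotation, expression-program and alignment generator.

The generator plants full ground truth for every downstream stage: a toy
genome with gene models and RepeatMasker-style TE copies (three-level
repName/repFamily/repClass hierarchy), stage x genotype negative-binomial
gene expression following nine maternal-to-zygotic dynamics classes,
stage-specific TE activation with a 2-cell burst of ERVL-family elements,
multi-mapped reads across homologous TE copies, split/translocated reads
spanning planted TE->gene chimeric junctions, mitochondrial reads for QC,
and full-length vs truncated internal-element copies carrying gag-like and
pol-like subsequences plus an exact siRNA target site.

Alignments are emitted directly (the aligner is out of scope); multi-mapping
arises from homologous regions shared between copies duplicated at a
configured identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    Alignment,
    AlignmentSet,
    CountMatrix,
    GeneRecord,
    GenomeAnnotation,
    ReadAlignments,
    TERecord,
)

NINE_CLASSES = ("EE", "ED", "EU", "DE", "DD", "DU", "UE", "UD", "UU")
MITO_CHROM = "chrM"

# study siRNA sequences (RNA); the MuERV-L siRNA's DNA form is planted
# verbatim in full-length internal-element copies
MUERVL_SIRNA = "GAAGAUAUGCCUUUCACCAGCUCUA"
SCRAMBLE_SIRNA = "UUCCUCUCCACGCGCAGUACAUUUA"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ElementDef:
    """Consensus definition of one repeat element (repName)."""
    family: str
    te_class: str
    length: int
    n_copies: int


DEFAULT_ELEMENTS: dict[str, ElementDef] = {
    # internal ERVL body: carries gag/pol-like regions and the siRNA site
    "MERVL-int-sim": ElementDef("ERVL", "LTR", 1600, 10),
    # LTR of the same family: identical to the internal element's 5' 300 bp
    "MT2-sim": ElementDef("ERVL", "LTR", 300, 8),
    "ERVK-sim": ElementDef("ERVK", "LTR", 500, 6),
    "L1-sim": ElementDef("L1", "LINE", 900, 8),
    "B1-sim": ElementDef("Alu", "SINE", 150, 8),
}

# per-element relative transcriptional activity by stage (2-cell ERVL burst)
DEFAULT_TE_ACTIVITY: dict[str, dict[str, float]] = {
    "MERVL-int-sim": {"oocyte": 0.3, "1-cell": 1.0, "2-cell": 5.0},
    "MT2-sim": {"oocyte": 0.3, "1-cell": 1.0, "2-cell": 5.0},
    "ERVK-sim": {"oocyte": 1.0, "1-cell": 1.0, "2-cell": 1.5},
    "L1-sim": {"oocyte": 1.0, "1-cell": 1.0, "2-cell": 1.0},
    "B1-sim": {"oocyte": 1.5, "1-cell": 1.0, "2-cell": 0.8},
}

# fraction of a library drawn from TEs, by stage (drives the TE-fraction curve)
DEFAULT_TE_READ_SHARE = {"oocyte": 0.08, "1-cell": 0.12, "2-cell": 0.30}

# gag/pol-like regions and siRNA site inside the internal-element consensus
GAG_REGION = (100, 220)
POL_REGION = (1200, 1320)
SIRNA_SITE = (600, 625)
TRUNCATED_LENGTH = 700  # truncated copies keep the 5' part: gag yes, pol no


class GeometryError(ValueError):
    """Requested features do not fit on the configured chromosomes."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 400_000
    mito_length: int = 16_000
    n_genes: int = 40
    elements: dict[str, ElementDef] = field(default_factory=lambda: dict(DEFAULT_ELEMENTS))
    n_full_length_te: int = 5
    stages: tuple[str, ...] = ("oocyte", "1-cell", "2-cell")
    genotypes: tuple[str, ...] = ("WT", "KO")
    samples_per_group: int = 11  # 2 genotypes x 3 stages x 11 = 66 samples
    mean_library_size: int = 6000
    dispersion: float = 0.1
    class_proportions: dict[str, float] = field(default_factory=lambda: {
        "EE": 0.40, "ED": 0.12, "EU": 0.12, "DE": 0.06, "DD": 0.06,
        "DU": 0.06, "UE": 0.06, "UD": 0.06, "UU": 0.06,
    })
    fold_change: float = 8.0
    base_mean: float = 50.0
    ko_dampening: float = 0.25      # KO 2-cell mean multiplier on affected ZAGs
    ko_affected_fraction: float = 0.6
    n_chimeric_junctions: int = 8
    n_translocated_junctions: int = 2
    junction_base_support: float = 3.0
    multi_map_fraction: float = 0.25
    mito_read_fraction: float | dict[str, float] = 0.02
    read_length: int = 51
    copy_identity: float = 0.95
    te_read_share: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TE_READ_SHARE))
    te_activity: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TE_ACTIVITY.items()})

    def validate(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if set(self.class_proportions) - set(NINE_CLASSES):
            raise ValueError("unknown dynamics class in class_proportions")
        for name, val in (("n_genes", self.n_genes),
                          ("n_full_length_te", self.n_full_length_te),
                          ("n_chimeric_junctions", self.n_chimeric_junctions),
                          ("samples_per_group", self.samples_per_group)):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.multi_map_fraction <= 1:
            raise ValueError("multi_map_fraction must lie in [0, 1]")
        if self.n_translocated_junctions > self.n_chimeric_junctions:
            raise ValueError("n_translocated_junctions exceeds n_chimeric_junctions")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{gt}_{st}_{i + 1}"
                for gt in self.genotypes for st in self.stages
                for i in range(self.samples_per_group)]

    def sample_metadata(self) -> pd.DataFrame:
        rows = []
        for gt in self.genotypes:
            for st in self.stages:
                for i in range(self.samples_per_group):
                    rows.append({"sample": f"{gt}_{st}_{i + 1}",
                                 "stage": st, "genotype": gt, "batch": "batch1"})
        return pd.DataFrame(rows).set_index("sample")

    def mito_fraction_for(self, sample: str) -> float:
        if isinstance(self.mito_read_fraction, dict):
            return self.mito_read_fraction.get(sample, 0.0)
        return float(self.mito_read_fraction)


@dataclass
class Junction:
    junction_id: str
    te_id: str
    gene_id: str
    te_chrom: str
    gene_chrom: str
    te_end: int       # 0-based exclusive end of the TE-side segment
    gene_start: int   # 0-based start of the gene-side (exonic) segment
    kind: str         # "split" | "translocated"
    ko_dampened: bool


@dataclass
class HomologyGroup:
    """TE copies sharing a >= read-length homologous region.

    `members` maps copy id -> offset of the shared region within that copy.
    """
    name: str
    members: dict[str, int]
    region_length: int


@dataclass
class GroundTruth:
    gene_classes: dict[str, str]
    ko_affected_genes: set[str]
    anchor_gene: str
    te_element_of: dict[str, str]          # copy id -> repName
    te_stage_activity: dict[str, dict[str, float]]  # copy id -> stage -> activity
    junctions: list[Junction]
    full_length_ids: list[str]
    homology_groups: list[HomologyGroup]
    gag_query: str
    pol_query: str
    sirna_matches: dict[str, int]          # copy id -> Hamming mismatches at site
    chrom_lengths: dict[str, int]
    read_origins: pd.DataFrame | None = None


def _random_seq(rng, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _mutate(rng, seq: np.ndarray, rate: float,
            protected: list[tuple[int, int]] = ()) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(len(seq)) < rate
    for s, e in protected:
        mask[s:e] = False
    idx = np.nonzero(mask)[0]
    # substitute with a different base
    out[idx] = (out[idx] + rng.integers(1, 4, size=len(idx))) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def _rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def generate_reference(config: SimulationConfig):
    """Build the toy genome, its annotation, and the ground truth.

    Returns (sequences, annotation, truth) where `sequences` maps
    chromosome name -> sequence string.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    elements = config.elements
    if "MERVL-int-sim" in elements:
        n_int = elements["MERVL-int-sim"].n_copies
        if config.n_full_length_te > n_int:
            raise ValueError("n_full_length_te exceeds internal-element copies")

    # --- element consensus sequences (shared prefixes create cross-element
    # homology: MT2 = ERVL 5' LTR-like region; ERVK/L1 share shorter prefixes)
    consensus: dict[str, np.ndarray] = {}
    mervl = _random_seq(rng, elements["MERVL-int-sim"].length) \
        if "MERVL-int-sim" in elements else None
    if mervl is not None:
        sirna_dna = _rna_to_dna(MUERVL_SIRNA)
        site = np.array([("ACGT").index(b) for b in sirna_dna], dtype=np.int8)
        mervl[SIRNA_SITE[0]:SIRNA_SITE[1]] = site
        consensus["MERVL-int-sim"] = mervl
    for name, el in elements.items():
        if name == "MERVL-int-sim":
            continue
        seq = _random_seq(rng, el.length)
        if mervl is not None:
            if name == "MT2-sim":
                seq[:300] = mervl[:300]
            elif name == "ERVK-sim":
                seq[:200] = _mutate(rng, mervl[:200], 1 - config.copy_identity)
            elif name == "L1-sim":
                seq[:100] = _mutate(rng, mervl[:100], 1 - config.copy_identity)
        consensus[name] = seq

    gag_query = _to_str(mervl[GAG_REGION[0]:GAG_REGION[1]]) if mervl is not None else ""
    pol_query = _to_str(mervl[POL_REGION[0]:POL_REGION[1]]) if mervl is not None else ""

    # --- copy sequences
    mut_rate = 1 - config.copy_identity
    copy_defs: list[dict] = []   # name, element, seq, length, full_length
    serial = 0
    for name, el in elements.items():
        for i in range(el.n_copies):
            serial += 1
            cid = f"{name}_c{i + 1}"
            if name == "MERVL-int-sim":
                full = i < config.n_full_length_te
                base = consensus[name] if full else consensus[name][:TRUNCATED_LENGTH]
                # full-length means intact coding: gag/pol and the siRNA
                # site stay at consensus; the rest drifts at copy identity
                protected = [GAG_REGION, POL_REGION, SIRNA_SITE] if full else []
                seq = _mutate(rng, base, mut_rate, protected)
                copy_defs.append(dict(copy_id=cid, element=name, seq=seq,
                                      full_length=full))
            else:
                seq = _mutate(rng, consensus[name], mut_rate)
                copy_defs.append(dict(copy_id=cid, element=name, seq=seq,
                                      full_length=False))

    # --- dynamics classes for genes
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    gene_ids = [f"gene{i + 1:03d}" for i in range(config.n_genes)]
    gene_classes = {g: classes[j] for g, j in
                    zip(gene_ids, rng.choice(len(classes), size=config.n_genes, p=probs))}
    # anchor: a maternal-decay gene if available (maternal-factor-like profile)
    ed_like = [g for g, c in gene_classes.items() if c in ("ED", "DD", "DE")]
    anchor_gene = ed_like[0] if ed_like else gene_ids[0]
    affected = set()
    for cls in ("ED", "EU"):
        members = [g for g, c in gene_classes.items() if c == cls]
        k = int(round(config.ko_affected_fraction * len(members)))
        affected.update(members[:k])

    # --- chimeric junction pairings: an internal-element copy upstream of a gene
    n_same = config.n_chimeric_junctions - config.n_translocated_junctions
    chimera_gene_ids = gene_ids[:config.n_chimeric_junctions]
    same_chrom_pairs = chimera_gene_ids[:n_same]

    # --- placement
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: 1000 for c in chroms}
    sequences = {c: _random_seq(rng, config.chrom_length) for c in chroms}
    genes: list[GeneRecord] = []
    tes: list[TERecord] = []
    te_seq_at: list[tuple[str, int, np.ndarray]] = []
    te_element_of: dict[str, str] = {}
    placed_te: dict[str, tuple[str, int, int]] = {}   # copy -> (chrom, start, end)

    def place(chrom: str, length: int, gap_lo=500, gap_hi=2000) -> int:
        start = cursors[chrom] + int(rng.integers(gap_lo, gap_hi))
        if start + length > config.chrom_length - 500:
            raise GeometryError(
                f"features exceed chromosome length {config.chrom_length} on {chrom}: "
                "reduce n_genes/TE copies or increase chrom_length")
        cursors[chrom] = start + length
        return start

    def place_te(cd: dict, chrom: str, gap_lo=500, gap_hi=2000):
        start = place(chrom, len(cd["seq"]), gap_lo, gap_hi)
        end = start + len(cd["seq"])
        sequences[chrom][start:end] = cd["seq"]
        strand = "+" if rng.random() < 0.5 else "-"
        tes.append(TERecord(cd["copy_id"], chrom, strand, start, end,
                            cd["element"],
                            elements[cd["element"]].family,
                            elements[cd["element"]].te_class))
        te_element_of[cd["copy_id"]] = cd["element"]
        placed_te[cd["copy_id"]] = (chrom, start, end)
        return start, end

    def place_gene(gid: str, chrom: str, gap_lo=500, gap_hi=2000) -> GeneRecord:
        n_ex = int(rng.integers(2, 4))
        ex_lens = rng.integers(150, 400, size=n_ex)
        introns = rng.integers(200, 600, size=n_ex - 1)
        span = int(ex_lens.sum() + introns.sum())
        start = place(chrom, span, gap_lo, gap_hi)
        exons = []
        pos = start
        for i, L in enumerate(ex_lens):
            exons.append((pos, pos + int(L)))
            pos += int(L) + (int(introns[i]) if i < n_ex - 1 else 0)
        strand = "+" if rng.random() < 0.5 else "-"
        rec = GeneRecord(gid, chrom, strand, start, exons[-1][1], tuple(exons))
        genes.append(rec)
        return rec

    # reserve internal-element copies for same-chromosome junctions
    int_copies = [cd for cd in copy_defs if cd["element"] == "MERVL-int-sim"]
    other_copies = [cd for cd in copy_defs if cd["element"] != "MERVL-int-sim"]
    junctions: list[Junction] = []
    jser = 0
    used_int = 0
    for gi, gid in enumerate(gene_ids):
        chrom = chroms[gi % len(chroms)]
        if gid in same_chrom_pairs and used_int < len(int_copies):
            cd = int_copies[used_int]
            used_int += 1
            _, te_end = place_te(cd, chrom)
            gene = place_gene(gid, chrom, gap_lo=200, gap_hi=800)
            jser += 1
            junctions.append(Junction(
                f"jx{jser}", cd["copy_id"], gid, chrom, chrom,
                te_end, gene.exons[0][0], "split",
                ko_dampened=(jser % 2 == 0)))
        else:
            place_gene(gid, chrom)
    # remaining TE copies round-robin
    for i, cd in enumerate(int_copies[used_int:] + other_copies):
        place_te(cd, chroms[i % len(chroms)])

    # translocated junctions: internal-element copy on a different chromosome
    transloc_genes = chimera_gene_ids[n_same:]
    gene_by_id = {g.gene_id: g for g in genes}
    int_ids = [cd["copy_id"] for cd in copy_defs if cd["element"] == "MERVL-int-sim"]
    for gid in transloc_genes:
        gene = gene_by_id[gid]
        partner = next((cid for cid in int_ids
                        if placed_te[cid][0] != gene.chrom), None)
        if partner is None:
            raise GeometryError("no internal-element copy on a different "
                                "chromosome for a translocated junction")
        jser += 1
        junctions.append(Junction(
            f"jx{jser}", partner, gid, placed_te[partner][0], gene.chrom,
            placed_te[partner][2], gene.exons[0][0], "translocated",
            ko_dampened=(jser % 2 == 0)))

    # --- homology groups
    groups: list[HomologyGroup] = []
    for name, el in elements.items():
        ids = [cd["copy_id"] for cd in copy_defs if cd["element"] == name]
        if len(ids) < 2:
            continue
        region = min(TRUNCATED_LENGTH, el.length) if name == "MERVL-int-sim" else el.length
        groups.append(HomologyGroup(f"element:{name}", {i: 0 for i in ids}, region))
    if "MERVL-int-sim" in elements and "MT2-sim" in elements:
        members = {cd["copy_id"]: 0 for cd in copy_defs
                   if cd["element"] in ("MERVL-int-sim", "MT2-sim")}
        groups.append(HomologyGroup("cross:ERVL", members, 300))
        if "ERVK-sim" in elements:
            members = {cd["copy_id"]: 0 for cd in copy_defs
                       if cd["element"] in ("MERVL-int-sim", "ERVK-sim")}
            groups.append(HomologyGroup("cross:LTR", members, 200))
        if "L1-sim" in elements:
            members = {cd["copy_id"]: 0 for cd in copy_defs
                       if cd["element"] in ("MERVL-int-sim", "L1-sim")}
            groups.append(HomologyGroup("cross:classes", members, 100))

    # --- siRNA match truth: Hamming distance at the planted site
    sirna_dna = np.array([("ACGT").index(b) for b in _rna_to_dna(MUERVL_SIRNA)],
                         dtype=np.int8)
    sirna_matches = {}
    for cd in copy_defs:
        if cd["element"] == "MERVL-int-sim" and len(cd["seq"]) >= SIRNA_SITE[1]:
            window = cd["seq"][SIRNA_SITE[0]:SIRNA_SITE[1]]
            sirna_matches[cd["copy_id"]] = int((window != sirna_dna).sum())

    chrom_lengths = {c: config.chrom_length for c in chroms}
    chrom_lengths[MITO_CHROM] = config.mito_length
    sequences[MITO_CHROM] = _random_seq(rng, config.mito_length)

    te_stage_activity = {
        cd["copy_id"]: dict(config.te_activity.get(
            cd["element"], {s: 1.0 for s in config.stages}))
        for cd in copy_defs
    }
    truth = GroundTruth(
        gene_classes=gene_classes,
        ko_affected_genes=affected,
        anchor_gene=anchor_gene,
        te_element_of=te_element_of,
        te_stage_activity=te_stage_activity,
        junctions=junctions,
        full_length_ids=[cd["copy_id"] for cd in copy_defs if cd["full_length"]],
        homology_groups=groups,
        gag_query=gag_query,
        pol_query=pol_query,
        sirna_matches=sirna_matches,
        chrom_lengths=chrom_lengths,
    )
    seq_strings = {c: _to_str(s) for c, s in sequences.items()}
    return seq_strings, GenomeAnnotation(genes, tes), truth


# ---------------------------------------------------------------------------
# expression programs
# ---------------------------------------------------------------------------

def _stage_means(base: float, cls: str, fold: float) -> dict[str, float]:
    means = {"oocyte": base}
    m = base
    for call, stage in zip(cls, ("1-cell", "2-cell")):
        if call == "U":
            m = m * fold
        elif call == "D":
            m = m / fold
        means[stage] = m
    return means


def expected_group_means(config: SimulationConfig, truth: GroundTruth,
                         base_means: dict[str, float]) -> pd.DataFrame:
    """Planted mean expression per gene per (genotype, stage) group."""
    rows = {}
    for gid, cls in truth.gene_classes.items():
        wt = _stage_means(base_means[gid], cls, config.fold_change)
        row = {}
        for st in config.stages:
            row[("WT", st)] = wt[st]
            ko = wt[st]
            if st == "2-cell" and gid in truth.ko_affected_genes:
                if cls == "EU":      # dampened zygotic activation
                    ko = wt[st] * config.ko_dampening
                elif cls == "ED":    # retained maternal transcripts
                    ko = wt["1-cell"]
            row[("KO", st)] = ko
        rows[gid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def _nb_draw(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 1e-12:
        return rng.poisson(mean, size=size).astype(np.int64)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion, size=size)
    return rng.poisson(lam).astype(np.int64)


def simulate_counts(config: SimulationConfig, truth: GroundTruth) -> CountMatrix:
    """Negative-binomial gene counts whose group means follow the planted
    nine-class dynamics, with KO perturbations on the affected subset."""
    rng = np.random.default_rng(config.seed + 1_000_003)
    gene_ids = list(truth.gene_classes)
    base_means = {g: float(np.exp(rng.normal(np.log(config.base_mean), 0.6)))
                  for g in gene_ids}
    means = expected_group_means(config, truth, base_means)
    meta = config.sample_metadata()
    counts = np.zeros((len(gene_ids), len(meta)), dtype=np.int64)
    for j, (sample, row) in enumerate(meta.iterrows()):
        mu = means[(row["genotype"], row["stage"])].to_numpy()
        for i, m in enumerate(mu):
            counts[i, j] = _nb_draw(rng, m, config.dispersion, 1)[0]
    df = pd.DataFrame(counts, index=gene_ids, columns=list(meta.index))
    return CountMatrix(df, meta)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def simulate_alignments(config: SimulationConfig, truth: GroundTruth,
                        ann: GenomeAnnotation) -> AlignmentSet:
    """Emit single-end SAM-style alignments with ground-truth-encoding names.

    Produces unique gene/TE reads, multi-mapped reads across homologous
    copies (NH = number of alignments), split reads with N-containing CIGARs
    across planted same-chromosome junctions, translocated reads as two
    soft-clipped pieces on different chromosomes, and mitochondrial reads.
    Fills ``truth.read_origins``.
    """
    rng = np.random.default_rng(config.seed + 2_000_003)
    L = config.read_length
    meta = config.sample_metadata()
    reads: list[ReadAlignments] = []
    origins: list[dict] = []
    serial = 0

    base_means = {g: float(np.exp(rng.normal(np.log(config.base_mean), 0.6)))
                  for g in truth.gene_classes}
    means = expected_group_means(config, truth, base_means)
    groups_by_copy: dict[str, list[HomologyGroup]] = {}
    for grp in truth.homology_groups:
        for cid in grp.members:
            groups_by_copy.setdefault(cid, []).append(grp)

    def new_read(kind: str, feature: str, sample: str, alignments, mult=1,
                 transloc=False):
        nonlocal serial
        serial += 1
        rid = f"{kind}|{feature}|r{serial:07d}"
        reads.append(ReadAlignments(rid, sample, alignments, mult, transloc))
        origins.append({"read_id": rid, "sample": sample, "kind": kind,
                        "feature_id": feature, "n_alignments": len(alignments)})

    junction_reads_emitted = {j.junction_id: 0 for j in truth.junctions}

    def emit_junction_read(j: Junction, sample: str):
        k = int(rng.integers(12, L - 11))
        m = L - k
        if j.kind == "split":
            gap = j.gene_start - j.te_end
            cigar = f"{k}M{gap}N{m}M"
            aln = Alignment(j.te_chrom, j.te_end - k, cigar,
                            ((j.te_end - k, j.te_end),
                             (j.gene_start, j.gene_start + m)))
            new_read("split", j.junction_id, sample, [aln])
        else:
            a1 = Alignment(j.te_chrom, j.te_end - k, f"{k}M{m}S",
                           ((j.te_end - k, j.te_end),))
            a2 = Alignment(j.gene_chrom, j.gene_start, f"{k}S{m}M",
                           ((j.gene_start, j.gene_start + m),))
            new_read("translocated", j.junction_id, sample, [a1, a2],
                     mult=1, transloc=True)
        junction_reads_emitted[j.junction_id] += 1

    te_by_id = ann.tes
    gene_by_id = ann.genes
    for sample, row in meta.iterrows():
        stage, genotype = row["stage"], row["genotype"]
        n_total = int(rng.poisson(config.mean_library_size))
        n_mito = int(round(config.mito_fraction_for(sample) * n_total))
        # junction support
        for j in truth.junctions:
            factor = {"oocyte": 0.02, "1-cell": 0.2, "2-cell": 1.0}.get(stage, 1.0)
            if j.ko_dampened and genotype == "KO" and stage == "2-cell":
                factor *= config.ko_dampening
            for _ in range(int(rng.poisson(config.junction_base_support * factor))):
                emit_junction_read(j, sample)
        # mitochondrial reads
        mito_len = truth.chrom_lengths[MITO_CHROM]
        for _ in range(n_mito):
            pos = int(rng.integers(0, mito_len - L))
            new_read("mito", MITO_CHROM, sample,
                     [Alignment(MITO_CHROM, pos, f"{L}M", ((pos, pos + L),))])
        # TE vs gene read split
        n_rest = max(n_total - n_mito, 0)
        share = config.te_read_share.get(stage, 0.1)
        n_te = int(rng.binomial(n_rest, share))
        n_gene = n_rest - n_te

        # gene reads: categorical over genes by planted group mean, uniform in exons
        gids = list(truth.gene_classes)
        w = means[(genotype, stage)].to_numpy(dtype=float)
        w = w / w.sum()
        picks = rng.choice(len(gids), size=n_gene, p=w)
        for gi in picks:
            g = gene_by_id[gids[gi]]
            exons = [e for e in g.exons if e[1] - e[0] >= L]
            if not exons:
                continue
            s, e = exons[int(rng.integers(0, len(exons)))]
            pos = int(rng.integers(s, e - L + 1))
            new_read("gene_unique", g.gene_id, sample,
                     [Alignment(g.chrom, pos, f"{L}M", ((pos, pos + L),))])

        # TE reads: categorical over copies by stage activity
        copies = [t for t in te_by_id.values() if t.end - t.start >= L]
        act = np.array([truth.te_stage_activity[t.te_id].get(stage, 1.0)
                        for t in copies], dtype=float)
        act = act / act.sum()
        picks = rng.choice(len(copies), size=n_te, p=act)
        for ci in picks:
            copy = copies[ci]
            multi = rng.random() < config.multi_map_fraction
            grps = [g for g in groups_by_copy.get(copy.te_id, [])
                    if g.region_length >= L]
            if multi and grps:
                # same-element homology dominates; cross-class homology is rare
                gw = np.array([
                    0.5 if g.name.startswith("element:") else
                    0.4 if g.name == "cross:ERVL" else
                    0.07 if g.name == "cross:LTR" else 0.03
                    for g in grps])
                grp = grps[int(rng.choice(len(grps), p=gw / gw.sum()))]
                off = int(rng.integers(0, grp.region_length - L + 1))
                alns = []
                ordered = [copy.te_id] + [c for c in grp.members if c != copy.te_id]
                for cid in ordered:
                    t = te_by_id[cid]
                    pos = t.start + grp.members[cid] + off
                    alns.append(Alignment(t.chrom, pos, f"{L}M", ((pos, pos + L),)))
                new_read("te_multi", copy.te_id, sample, alns, mult=len(alns))
            else:
                pos = int(rng.integers(copy.start, copy.end - L + 1))
                new_read("te_unique", copy.te_id, sample,
                         [Alignment(copy.chrom, pos, f"{L}M", ((pos, pos + L),))])

    # guarantee >=1 supporting read per planted junction
    fallback_sample = next((s for s, r in meta.iterrows()
                            if r["genotype"] == "WT" and r["stage"] == "2-cell"),
                           meta.index[0])
    for j in truth.junctions:
        if junction_reads_emitted[j.junction_id] == 0:
            emit_junction_read(j, fallback_sample)

    truth.read_origins = pd.DataFrame(origins)
    return AlignmentSet(reads)


def simulate_all(config: SimulationConfig):
    """Convenience: reference + counts + alignments in one call."""
    sequences, ann, truth = generate_reference(config)
    counts = simulate_counts(config, truth)
    alns = simulate_alignments(config, truth, ann)
    return sequences, ann, truth, counts, alns
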
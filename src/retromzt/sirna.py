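"""Full-length internal-element discovery and genome-wide siRNA scanning.

A full-length element copy retains complete internal coding sequence: its
genomic interval overlaps occurrences of both the gag-like and the pol-like
query sequence.  Query occurrences are located by semi-global (infix)
alignment with edlib; identity over the aligned query must reach
`min_identity` (the full query aligns in infix mode, so query coverage is
complete by construction).

The siRNA scan slides an ungapped window of siRNA length over both strands
of the genome and stratifies hits by Hamming distance (perfect match, one
mismatch, two mismatches).  Ungapped positional matching is used because
siRNA silencing efficacy is position-wise; indel-tolerant alignment is not
emulated.  U->T conversion is applied to the (RNA) siRNA before matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

# the two study siRNAs, printed 5'->3' (RNA)
MUERVL_SIRNA = "GAAGAUAUGCCUUUCACCAGCUCUA"
SCRAMBLE_SIRNA = "UUCCUCUCCACGCGCAGUACAUUUA"

_COMP = str.maketrans("ACGT", "TGCA")
_ENC = {b: i for i, b in enumerate("ACGT")}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class FullLengthElementSet:
    copy_ids: list[str]
    evidence: dict[str, dict[str, tuple[int, int]]]  # copy -> query -> interval
    intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)


def _find_query_hits(target: str, query: str, max_dist: int):
    """Infix-alignment occurrences of `query` in `target`; 0-based half-open
    target intervals of all non-overlapping best-scoring locations."""
    res = edlib.align(query, target, mode="HW", task="locations", k=max_dist)
    if res["editDistance"] < 0:
        return []
    return [(s, e + 1) for s, e in res["locations"]]


def find_full_length_elements(genome: dict[str, str], te_records,
                              gag_query: str, pol_query: str,
                              min_identity: float = 0.9,
                              flank: int = 50) -> FullLengthElementSet:
    """Internal-element copies whose interval overlaps >= 1 occurrence of
    each of the gag and pol query sequences (searched on both strands)."""
    te_records = list(te_records)
    if not te_records:
        raise ValueError("empty internal-element annotation subset")
    if not gag_query or not pol_query:
        raise ValueError("gag/pol query sequences must be non-empty")
    queries = {"gag": _rna_to_dna(gag_query), "pol": _rna_to_dna(pol_query)}
    ids, evidence, intervals = [], {}, {}
    for te in te_records:
        seq = genome[te.chrom]
        lo = max(te.start - flank, 0)
        target = seq[lo:te.end + flank]
        found = {}
        for name, q in queries.items():
            max_dist = int(np.floor((1 - min_identity) * len(q)))
            hits = _find_query_hits(target, q, max_dist)
            hits += _find_query_hits(target, revcomp(q), max_dist)
            # keep a hit only if it overlaps the copy's own interval
            hits = [(lo + s, lo + e) for s, e in hits
                    if lo + e > te.start and lo + s < te.end]
            if hits:
                found[name] = hits[0]
        if len(found) == len(queries):
            ids.append(te.te_id)
            evidence[te.te_id] = found
            intervals[te.te_id] = (te.chrom, te.start, te.end)
    return FullLengthElementSet(ids, evidence, intervals)


@dataclass
class SiRNAHitReport:
    sirna: str
    hits: pd.DataFrame          # chrom, start, end, strand, mismatches
    on_target: pd.DataFrame
    off_target: pd.DataFrame
    target_best_stratum: dict[str, int]   # copy id -> best (min) distance
    target_fraction: dict[int, float]     # stratum -> fraction of copies whose
                                          # best hit has that distance
    target_fraction_cumulative: dict[int, float]


def _hamming_scan(arr: np.ndarray, query: np.ndarray, max_mismatch: int) -> np.ndarray:
    """Mismatch count of every window of len(query) along `arr` (int8 codes);
    returns positions with count <= max_mismatch and the counts."""
    k = len(query)
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty((0, 2), dtype=np.int64)
    mm = np.zeros(n, dtype=np.int16)
    for j in range(k):
        mm += arr[j:j + n] != query[j]
    pos = np.nonzero(mm <= max_mismatch)[0]
    return np.column_stack([pos, mm[pos].astype(np.int64)])


def sirna_scan(sirna: str, genome: dict[str, str],
               targets: FullLengthElementSet | None = None,
               max_mismatch: int = 2) -> SiRNAHitReport:
    """Scan both strands of the genome for windows within `max_mismatch`
    Hamming distance of the siRNA; split hits into on-target (overlapping a
    full-length copy) and off-target, and report per-stratum target coverage
    (a copy counts at the stratum of its best overlapping hit)."""
    dna = _rna_to_dna(sirna)
    if set(dna) - set("ACGT"):
        raise ValueError(f"siRNA contains non-ACGU characters: {sirna!r}")
    fwd = np.array([_ENC[b] for b in dna], dtype=np.int8)
    rev = np.array([_ENC[b] for b in revcomp(dna)], dtype=np.int8)
    rows = []
    k = len(dna)
    for chrom, seq in genome.items():
        arr = np.array([_ENC.get(b, 4) for b in seq.upper()], dtype=np.int8)
        for strand, q in (("+", fwd), ("-", rev)):
            for pos, mm in _hamming_scan(arr, q, max_mismatch):
                rows.append({"chrom": chrom, "start": int(pos),
                             "end": int(pos) + k, "strand": strand,
                             "mismatches": int(mm)})
    hits = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "mismatches"])
    hits = hits.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)
    if targets is None or not targets.copy_ids:
        empty = hits.iloc[0:0]
        return SiRNAHitReport(sirna, hits, empty, hits.copy(), {}, {}, {})
    on_mask = np.zeros(len(hits), dtype=bool)
    best: dict[str, int] = {}
    for cid in targets.copy_ids:
        chrom, s, e = targets.intervals[cid]
        m = ((hits["chrom"] == chrom) & (hits["start"] < e)
             & (hits["end"] > s)).to_numpy()
        on_mask |= m
        if m.any():
            best[cid] = int(hits.loc[m, "mismatches"].min())
    n_targets = len(targets.copy_ids)
    frac = {s: sum(1 for v in best.values() if v == s) / n_targets
            for s in range(max_mismatch + 1)}
    cum = {s: sum(1 for v in best.values() if v <= s) / n_targets
           for s in range(max_mismatch + 1)}
    return SiRNAHitReport(sirna, hits, hits[on_mask], hits[~on_mask],
                          best, frac, cum)
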
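"""TE-gene association statistics: nearest-gene rank correlation, overlap of
differentially expressed gene and TE sets with a hypergeometric test, the
TSS-window permutation enrichment test, and maternal/zygotic TE labels with
odds-ratio enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import differential_test
from .model import CountMatrix, GenomeAnnotation


def interval_distance(s1: int, e1: int, s2: int, e2: int) -> int:
    """bp gap between two 0-based half-open intervals (0 when overlapping
    or directly adjacent)."""
    if s2 >= e1:
        return s2 - e1
    if s1 >= e2:
        return s1 - e2
    return 0


def _near_any_exon(ann: GenomeAnnotation, chrom, start, end, gap: int) -> bool:
    """True if the interval lies within `gap` bp of any exon (incl. UTRs)."""
    return bool(ann.overlapping_exon_genes(chrom, start - gap - 1, end + gap + 1))


def nearest_gene_correlation(te_counts: pd.DataFrame, gene_counts: pd.DataFrame,
                             ann: GenomeAnnotation,
                             max_distance: int = 1_000_000,
                             exon_gap: int = 51) -> pd.DataFrame:
    """Pair each TE copy with its nearest gene and compute Spearman's rank
    correlation (midranks for ties) over the shared samples.

    TEs whose interval lies within `exon_gap` bp (the read length) of any
    exon are excluded (reason "exon_gap"); TEs farther than `max_distance`
    from every gene are excluded (reason "distance").  Nearest distance is
    interval-to-interval; ties break toward the lower gene coordinate.
    """
    shared = [s for s in te_counts.columns if s in gene_counts.columns]
    if not shared:
        raise ValueError("no samples shared between TE and gene matrices")
    genes_by_chrom: dict[str, list] = {}
    for g in ann.genes.values():
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for te_id in te_counts.index:
        te = ann.tes[te_id]
        if _near_any_exon(ann, te.chrom, te.start, te.end, exon_gap):
            rows.append({"te_id": te_id, "gene_id": None, "distance": np.nan,
                         "spearman": np.nan, "excluded": True,
                         "reason": "exon_gap"})
            continue
        best = None
        for g in sorted(genes_by_chrom.get(te.chrom, []), key=lambda g: g.start):
            d = interval_distance(te.start, te.end, g.start, g.end)
            if best is None or d < best[0]:
                best = (d, g)
        if best is None or best[0] > max_distance:
            rows.append({"te_id": te_id, "gene_id": None, "distance": np.nan,
                         "spearman": np.nan, "excluded": True,
                         "reason": "distance"})
            continue
        d, g = best
        rho = stats.spearmanr(te_counts.loc[te_id, shared],
                              gene_counts.loc[g.gene_id, shared]).statistic
        rows.append({"te_id": te_id, "gene_id": g.gene_id, "distance": d,
                     "spearman": rho, "excluded": False, "reason": ""})
    return pd.DataFrame(rows).set_index("te_id")


@dataclass
class OverlapResult:
    universe: int
    n_de_genes: int
    n_te_neighbor_genes: int
    overlap: int
    pvalue: float  # upper-tail hypergeometric


def de_te_gene_overlap(de_genes: set, de_tes: set, ann: GenomeAnnotation,
                       universe: set, window: int = 20_000) -> OverlapResult:
    """Genes with a DE TE within +/- `window` bp, intersected with DE genes;
    significance from the upper-tail hypergeometric distribution."""
    if not de_genes <= universe:
        raise ValueError("DE genes must be a subset of the gene universe")
    neighbors = set()
    for te_id in de_tes:
        te = ann.tes[te_id]
        hits = ann.overlapping_genes(te.chrom, te.start - window, te.end + window)
        neighbors |= {g for g in hits if g in universe}
    k = len(de_genes & neighbors)
    M, n, N = len(universe), len(de_genes), len(neighbors)
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    return OverlapResult(M, n, N, k, p)


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    pvalue: float
    window: int
    n_perm: int
    seed: int

    def summary(self) -> dict:
        q = np.quantile(self.null, [0.025, 0.5, 0.975])
        return {"observed": self.observed, "pvalue": self.pvalue,
                "n_perm": self.n_perm, "window": self.window,
                "null_q2.5": q[0], "null_median": q[1], "null_q97.5": q[2]}


def tss_neighbor_counts(te_ids, focus_gene_ids, ann: GenomeAnnotation,
                        window: int = 10_000,
                        exclude_exonic: bool = True) -> pd.Series:
    """Per gene: number of the given TEs whose interval overlaps
    TSS +/- window.  TEs overlapping any exon are dropped first."""
    kept = []
    for te_id in te_ids:
        te = ann.tes[te_id]
        if exclude_exonic and ann.overlapping_exon_genes(te.chrom, te.start, te.end):
            continue
        kept.append(te)
    counts = {}
    for gid in focus_gene_ids:
        g = ann.genes[gid]
        lo, hi = g.tss - window, g.tss + window + 1
        counts[gid] = sum(1 for te in kept
                          if te.chrom == g.chrom
                          and interval_distance(te.start, te.end, lo, hi) == 0)
    return pd.Series(counts)


def tss_enrichment_permutation(depleted_tes, focus_genes, all_genes,
                               ann: GenomeAnnotation, window: int = 10_000,
                               n_perm: int = 10_000, seed: int = 0,
                               exclude_exonic: bool = True) -> PermutationResult:
    """Mean number of depleted TEs within +/- window of focus-gene TSSs,
    against a null of size-matched random gene sets drawn without
    replacement; empirical p = (1 + #{null >= observed}) / (n_perm + 1)."""
    focus = list(focus_genes)
    pool = list(all_genes)
    if not focus:
        raise ValueError("focus gene set is empty")
    if len(focus) > len(pool):
        raise ValueError("focus set larger than the gene universe")
    per_gene = tss_neighbor_counts(depleted_tes, pool, ann, window,
                                   exclude_exonic)
    observed = float(per_gene.loc[focus].mean())
    rng = np.random.default_rng(seed)
    vals = per_gene.to_numpy(dtype=float)
    k = len(focus)
    keys = rng.random((n_perm, len(pool)))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null = vals[idx].mean(axis=1)
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return PermutationResult(observed, null, p, window, n_perm, seed)


# ---------------------------------------------------------------------------
# maternal / zygotic TE labels and odds-ratio enrichment
# ---------------------------------------------------------------------------

def maternal_zygotic_te(te_counts: CountMatrix, alpha: float = 0.05,
                        method: str = "ranksum",
                        min_mean: float = 5.0) -> pd.DataFrame:
    """Label TEs maternal (higher in WT oocyte than WT 2-cell), zygotic
    (converse) or neither, via the substitute test + BH at `alpha`."""
    oocyte = te_counts.samples_where(stage="oocyte", genotype="WT")
    twocell = te_counts.samples_where(stage="2-cell", genotype="WT")
    if not oocyte or not twocell:
        raise ValueError("need WT oocyte and WT 2-cell samples")
    res = differential_test(te_counts, oocyte, twocell, method=method,
                            min_mean=min_mean)
    sig = res["padj"] < alpha
    label = np.where(sig & (res["log2_fold_change"] > 0), "maternal",
                     np.where(sig & (res["log2_fold_change"] < 0),
                              "zygotic", "neither"))
    out = res.copy()
    out["label"] = label
    return out


@dataclass
class OddsRatioResult:
    table: tuple  # ((a, b), (c, d))
    odds_ratio: float
    pvalue: float
    haldane: bool


def odds_ratio_enrichment(set_a: set, set_b: set, universe: set) -> OddsRatioResult:
    """Sample (cross-product) odds ratio of the 2x2 membership table over the
    universe, with the Haldane 0.5 correction when a cell is zero, and
    Fisher's exact p on the raw table."""
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    haldane = 0 in (a, b, c, d)
    h = 0.5 if haldane else 0.0
    orr = ((a + h) * (d + h)) / ((b + h) * (c + h))
    _, p = stats.fisher_exact([[a, b], [c, d]])
    return OddsRatioResult(((a, b), (c, d)), float(orr), float(p), haldane)
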
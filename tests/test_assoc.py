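"""Nearest-gene correlation, DE-set overlap, permutation enrichment and
maternal/zygotic TE classification."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retromzt import assoc
from retromzt.model import (CountMatrix, GeneRecord, GenomeAnnotation,
                            TERecord)


def _gene(gid, chrom, start, end, exons=None, strand="+"):
    return GeneRecord(gid, chrom, strand, start, end,
                      tuple(exons or [(start, end)]))


def _te(tid, chrom, start, end):
    return TERecord(tid, chrom, "+", start, end, "MERVL-int", "ERVL", "LTR")


@pytest.fixture()
def linear_ann():
    """One chromosome: gene at 10k-12k, TEs at varying distances."""
    return GenomeAnnotation(
        [_gene("g1", "chr1", 10_000, 12_000, [(10_000, 10_500), (11_500, 12_000)]),
         _gene("g2", "chr1", 60_000, 62_000, [(60_000, 62_000)])],
        [_te("near", "chr1", 13_000, 13_500),       # 1000 bp from g1
         _te("exon_adjacent", "chr1", 12_030, 12_400),  # 30 bp from g1 exon
         _te("far", "chr1", 5_000_000, 5_000_500)],  # > 1 Mbp from everything
    )


def _counts(rows, samples=6):
    cols = [f"s{i}" for i in range(samples)]
    return pd.DataFrame(rows, columns=cols)


def test_nearest_gene_pairing_and_exclusions(linear_ann):
    rng = np.random.default_rng(0)
    profile = rng.poisson(20, size=6).astype(float)
    te_counts = _counts({"near": profile, "exon_adjacent": profile,
                         "far": profile}.values())
    te_counts.index = ["near", "exon_adjacent", "far"]
    gene_counts = _counts([profile, profile[::-1]])
    gene_counts.index = ["g1", "g2"]
    out = assoc.nearest_gene_correlation(te_counts, gene_counts, linear_ann)
    assert out.loc["near", "gene_id"] == "g1"
    assert out.loc["near", "distance"] == 1000  # 13 000 - 12 000
    assert out.loc["near", "spearman"] == pytest.approx(1.0)
    assert out.loc["exon_adjacent", "excluded"] and \
        out.loc["exon_adjacent", "reason"] == "exon_gap"
    assert out.loc["far", "excluded"] and out.loc["far", "reason"] == "distance"


def test_exon_gap_boundary_is_51bp(linear_ann):
    ann = GenomeAnnotation(
        [_gene("g1", "chr1", 10_000, 12_000)],
        [_te("at51", "chr1", 12_051, 12_200),   # gap exactly 51 -> excluded
         _te("at52", "chr1", 12_052, 12_200)])  # gap 52 -> kept
    prof = np.arange(6, dtype=float)
    te_counts = pd.DataFrame([prof, prof], index=["at51", "at52"],
                             columns=[f"s{i}" for i in range(6)])
    gene_counts = pd.DataFrame([prof], index=["g1"],
                               columns=[f"s{i}" for i in range(6)])
    out = assoc.nearest_gene_correlation(te_counts, gene_counts, ann)
    assert out.loc["at51", "reason"] == "exon_gap"
    assert not out.loc["at52", "excluded"]


def test_no_shared_samples_fails(linear_ann):
    te_counts = pd.DataFrame([[1, 2]], index=["near"], columns=["a", "b"])
    gene_counts = pd.DataFrame([[1, 2]], index=["g1"], columns=["c", "d"])
    with pytest.raises(ValueError, match="shared"):
        assoc.nearest_gene_correlation(te_counts, gene_counts, linear_ann)


def test_spearman_matches_midrank_oracle():
    """scipy path vs explicit midrank-then-Pearson, including ties."""
    rng = np.random.default_rng(8)
    for _ in range(20):
        x = rng.integers(0, 6, size=12).astype(float)
        y = rng.integers(0, 6, size=12).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        rx = pd.Series(x).rank().to_numpy()  # midranks
        ry = pd.Series(y).rank().to_numpy()
        rxc, ryc = rx - rx.mean(), ry - ry.mean()
        rho = (rxc @ ryc) / math.sqrt((rxc @ rxc) * (ryc @ ryc))
        assert abs(stats.spearmanr(x, y).statistic - rho) < 1e-12


# ---------------------------------------------------------------------------
# DE gene/TE overlap
# ---------------------------------------------------------------------------

def _hyper_tail_oracle(M, n, N, k):
    """Upper-tail hypergeometric by exact enumeration."""
    return sum(math.comb(n, x) * math.comb(M - n, N - x) / math.comb(M, N)
               for x in range(k, min(n, N) + 1))


def test_overlap_hypergeometric_matches_enumeration():
    genes = [_gene(f"g{i}", "chr1", 100_000 * i + 50_000,
                   100_000 * i + 52_000) for i in range(100)]
    # DE TEs within 20 kb of genes g0..g9 only
    tes = [_te(f"t{i}", "chr1", 100_000 * i + 40_000, 100_000 * i + 41_000)
           for i in range(10)]
    ann = GenomeAnnotation(genes, tes)
    universe = {f"g{i}" for i in range(100)}
    de_genes = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
    res = assoc.de_te_gene_overlap(de_genes, {t.te_id for t in tes}, ann,
                                   universe)
    assert res.n_te_neighbor_genes == 10 and res.overlap == 5
    assert res.pvalue == pytest.approx(_hyper_tail_oracle(100, 10, 10, 5),
                                       rel=1e-9)


def test_overlap_zero_gives_p_near_one():
    genes = [_gene(f"g{i}", "chr1", 100_000 * i, 100_000 * i + 1000)
             for i in range(20)]
    tes = [_te("t0", "chr1", 15_000, 16_000)]
    ann = GenomeAnnotation(genes, tes)
    res = assoc.de_te_gene_overlap({"g5"}, {"t0"}, ann,
                                   {g.gene_id for g in genes})
    assert res.overlap == 0 and res.pvalue == pytest.approx(1.0)


def test_overlap_window_rule():
    genes = [_gene("gin", "chr1", 100_000, 101_000),
             _gene("gout", "chr1", 300_000, 301_000)]
    tes = [_te("t0", "chr1", 85_000, 85_100)]  # 14.9 kb from gin
    ann = GenomeAnnotation(genes, tes)
    res = assoc.de_te_gene_overlap({"gin"}, {"t0"}, ann, {"gin", "gout"},
                                   window=20_000)
    assert res.n_te_neighbor_genes == 1 and res.overlap == 1


def test_overlap_p_monotone_in_overlap():
    ps = [stats.hypergeom.sf(k - 1, 100, 10, 10) for k in range(0, 8)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# TSS permutation test
# ---------------------------------------------------------------------------

def _perm_ann(n_genes=40, te_near=(), spacing=50_000):
    genes, tes = [], []
    for i in range(n_genes):
        s = 20_000 + i * spacing
        genes.append(_gene(f"g{i}", "chr1", s, s + 2000))
    for i in te_near:
        s = 20_000 + i * spacing - 5000
        tes.append(_te(f"t{i}", "chr1", s, s + 500))
    return GenomeAnnotation(genes, tes)


def test_degenerate_equal_neighborhoods_give_p_one():
    ann = _perm_ann(20, te_near=range(20))
    res = assoc.tss_enrichment_permutation(
        [t for t in ann.tes], [f"g{i}" for i in range(5)],
        [f"g{i}" for i in range(20)], ann, n_perm=200, seed=0)
    assert res.pvalue == 1.0


def test_planted_enrichment_gives_minimal_p():
    ann = _perm_ann(40, te_near=range(8))
    res = assoc.tss_enrichment_permutation(
        [t.te_id for t in ann.tes.values()], [f"g{i}" for i in range(8)],
        [f"g{i}" for i in range(40)], ann, n_perm=1000, seed=1)
    assert res.pvalue == pytest.approx(1 / 1001)
    assert res.observed > max(res.null)


def test_exonic_tes_excluded_from_neighborhood_counts():
    genes = [_gene("g0", "chr1", 20_000, 22_000)]
    tes = [_te("inside_exon", "chr1", 20_500, 20_700),
           _te("nearby", "chr1", 15_000, 15_500)]
    ann = GenomeAnnotation(genes, tes)
    counts = assoc.tss_neighbor_counts(["inside_exon", "nearby"], ["g0"], ann)
    assert counts["g0"] == 1


def test_empty_focus_set_fails():
    ann = _perm_ann(5)
    with pytest.raises(ValueError, match="empty"):
        assoc.tss_enrichment_permutation([], [], ["g0"], ann)


# ---------------------------------------------------------------------------
# maternal / zygotic labels and odds ratios
# ---------------------------------------------------------------------------

def _te_matrix(seed=0, n=60):
    rng = np.random.default_rng(seed)
    stages = ["oocyte"] * 4 + ["2-cell"] * 4
    samples = [f"s{i}" for i in range(8)]
    meta = pd.DataFrame({"stage": stages, "genotype": "WT"}, index=samples)
    base = rng.uniform(20, 80, size=n)
    counts = np.empty((n, 8), dtype=np.int64)
    kinds = []
    for i in range(n):
        kind = ("maternal", "zygotic", "flat")[i % 3]
        kinds.append(kind)
        mu_o = base[i] * (8 if kind == "maternal" else 1)
        mu_t = base[i] * (8 if kind == "zygotic" else 1)
        counts[i, :4] = rng.poisson(mu_o, 4)
        counts[i, 4:] = rng.poisson(mu_t, 4)
    idx = [f"te{i}" for i in range(n)]
    return CountMatrix(pd.DataFrame(counts, index=idx, columns=samples),
                       meta), pd.Series(kinds, index=idx)


def test_maternal_zygotic_labels_partition():
    m, kinds = _te_matrix()
    out = assoc.maternal_zygotic_te(m, alpha=0.05)
    assert set(out["label"]) <= {"maternal", "zygotic", "neither"}
    # planted 8-fold stage effects are recovered for most TEs
    for kind in ("maternal", "zygotic"):
        sub = out.loc[kinds[kinds == kind].index, "label"]
        assert (sub == kind).mean() > 0.8
    # no TE is both: labels are single-valued by construction of the rule
    assert out["label"].isin(["maternal", "zygotic", "neither"]).all()


def test_odds_ratio_closed_form():
    universe = set(range(80))
    a = set(range(40))            # 30 overlap with b
    b = set(range(10, 50))
    res = assoc.odds_ratio_enrichment(a, b, universe)
    assert res.table == ((30, 10), (10, 30))
    assert res.odds_ratio == pytest.approx(9.0)


def test_odds_ratio_haldane_on_zero_cell():
    universe = set(range(20))
    res = assoc.odds_ratio_enrichment(set(range(5)), set(range(5, 10)),
                                      universe)
    assert res.haldane and np.isfinite(res.odds_ratio)


def test_independent_sets_log_or_centred_on_zero():
    rng = np.random.default_rng(99)
    logs = []
    universe = set(range(200))
    for _ in range(200):
        a = set(rng.choice(200, 50, replace=False))
        b = set(rng.choice(200, 50, replace=False))
        logs.append(np.log(assoc.odds_ratio_enrichment(a, b, universe)
                           .odds_ratio))
    se = np.std(logs, ddof=1) / np.sqrt(len(logs))
    assert abs(np.mean(logs)) < 2 * se + 0.05
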
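"""TE counting modes, assignment ambiguity and normalization."""

import numpy as np
import pandas as pd
import pytest

from retromzt import tequant as tq
from retromzt.io import cigar_segments
from retromzt.model import (Alignment, AlignmentSet, GenomeAnnotation,
                            ReadAlignments, TERecord)


def _te(te_id, chrom, start, end, name, family, cls):
    return TERecord(te_id, chrom, "+", start, end, name, family, cls)


def _read(rid, chrom, pos, cigar="51M", sample="s1", alns=None, mult=1):
    if alns is None:
        alns = [Alignment(chrom, pos, cigar, cigar_segments(cigar, pos))]
    return ReadAlignments(rid, sample, alns, mult)


def _multi(rid, positions, sample="s1"):
    alns = [Alignment(c, p, "51M", ((p, p + 51),)) for c, p in positions]
    return ReadAlignments(rid, sample, alns, len(alns))


@pytest.fixture()
def two_copy_ann():
    return GenomeAnnotation([], [
        _te("A", "chr1", 1000, 2000, "MERVL-int", "ERVL", "LTR"),
        _te("B", "chr1", 2000, 2500, "MT2", "ERVL", "LTR"),
        _te("C", "chr1", 5000, 6000, "L1Md", "L1", "LINE"),
    ])


def test_unique_counting_rule(two_copy_ann):
    alns = AlignmentSet([
        _read("r1", "chr1", 1100), _read("r2", "chr1", 1200),
        _read("r3", "chr1", 1300),
        _read("r4", "chr1", 9000),  # outside all TEs
    ])
    t = tq.count_te(alns, two_copy_ann, "unique_only", level="copy")
    assert t.counts.loc["A", "s1"] == 3
    assert t.te_mapped_total["s1"] == 3 and t.mapped_total["s1"] == 4


def test_read_spanning_two_copies_dropped_as_ambiguous(two_copy_ann):
    # A ends at 2000 where B begins: a read across the boundary touches both
    alns = AlignmentSet([_read("r1", "chr1", 1975)])
    t = tq.count_te(alns, two_copy_ann, "unique_only", level="element")
    assert t.ambiguous["s1"] == 1 and t.te_mapped_total["s1"] == 0
    # at family level both copies share ERVL: unambiguous
    t2 = tq.count_te(alns, two_copy_ann, "unique_only", level="family")
    assert t2.counts.loc["ERVL", "s1"] == 1


def test_multireads_excluded_from_unique_mode(two_copy_ann):
    alns = AlignmentSet([_multi("m1", [("chr1", 1100), ("chr1", 5100)])])
    t = tq.count_te(alns, two_copy_ann, "unique_only", level="element")
    assert t.mapped_total["s1"] == 0 and t.counts.empty


def test_one_random_mode_expected_split_across_seeds(two_copy_ann):
    """A read multi-mapping to k copies lands on each with probability 1/k:
    over 200 seeds the per-copy assignment rate is binomial around 1/2."""
    alns = AlignmentSet([_multi("m1", [("chr1", 1100), ("chr1", 5100)])])
    hits_a = 0
    for seed in range(200):
        t = tq.count_te(alns, two_copy_ann, "unique_plus_one_random",
                        seed=seed, level="element")
        if "MERVL-int" in t.counts.index and t.counts.loc["MERVL-int", "s1"]:
            hits_a += 1
    # 4 sigma for Binomial(200, 0.5)
    assert abs(hits_a - 100) < 4 * np.sqrt(200 * 0.25)


def _oracle_counts(alns, ann, level):
    """Naive all-pairs interval-overlap counter, unique reads only."""
    tes = list(ann.tes.values())
    counts, mapped, te_mapped, amb = {}, {}, {}, {}
    for read in alns.reads:
        if read.multiplicity > 1:
            continue
        s = read.sample_id
        mapped[s] = mapped.get(s, 0) + 1
        labels = set()
        for a in read.alignments:
            for seg_s, seg_e in a.segments:
                for te in tes:
                    if te.chrom == a.chrom and seg_s < te.end and seg_e > te.start:
                        labels.add(te.te_id if level == "copy"
                                   else te.label(level))
        if len(labels) == 1:
            te_mapped[s] = te_mapped.get(s, 0) + 1
            lab = labels.pop()
            counts.setdefault(lab, {})[s] = counts.get(lab, {}).get(s, 0) + 1
        elif len(labels) > 1:
            amb[s] = amb.get(s, 0) + 1
    return counts, mapped, te_mapped, amb


@pytest.mark.parametrize("level", ["copy", "element", "family", "class"])
def test_counts_match_brute_force_oracle(small_sim, level):
    ann, alns = small_sim["ann"], small_sim["alns"]
    t = tq.count_te(alns, ann, "unique_only", level=level)
    counts, mapped, te_mapped, amb = _oracle_counts(alns, ann, level)
    expected = (pd.DataFrame(counts).T
                .reindex(index=t.counts.index, columns=t.counts.columns)
                .fillna(0).astype(np.int64))
    pd.testing.assert_frame_equal(t.counts.sort_index(), expected.sort_index(),
                                  check_names=False)
    assert dict(t.mapped_total) == mapped
    assert {k: v for k, v in t.te_mapped_total.items() if v} == te_mapped
    assert {k: v for k, v in t.ambiguous.items() if v} == amb


@pytest.mark.parametrize("mode", ["unique_only", "unique_plus_one_random"])
def test_conservation_partition(small_sim, mode):
    """assigned + ambiguous + non-TE = retained reads, per sample."""
    t = tq.count_te(small_sim["alns"], small_sim["ann"], mode, seed=7,
                    level="element")
    non_te = t.mapped_total - t.te_mapped_total - t.ambiguous
    assert (t.counts.sum(axis=0) + t.ambiguous + non_te ==
            t.mapped_total).all()


# ---------------------------------------------------------------------------
# ambiguity report
# ---------------------------------------------------------------------------

def test_ambiguity_label_comparisons(two_copy_ann):
    alns = AlignmentSet([
        # MERVL-int vs MT2: same family+class, different element
        _multi("m1", [("chr1", 1100), ("chr1", 2100)]),
        # MERVL-int vs L1Md: different class entirely
        _multi("m2", [("chr1", 1100), ("chr1", 5100)]),
    ])
    rep = tq.assignment_ambiguity(alns, two_copy_ann)
    assert rep.n_reads == 2
    assert rep.proportions == {"element": 0.0, "family": 0.5, "class": 0.5}


def test_ambiguity_exact_planted_proportions(two_copy_ann):
    """10 multi-reads: 5 element-consistent, 4 family-only, 1 class-only."""
    ann = GenomeAnnotation([], [
        _te("A1", "chr1", 1000, 2000, "MERVL-int", "ERVL", "LTR"),
        _te("A2", "chr1", 3000, 4000, "MERVL-int", "ERVL", "LTR"),
        _te("B", "chr1", 5000, 5500, "MT2", "ERVL", "LTR"),
        _te("D", "chr1", 7000, 7500, "ERVK", "ERVK", "LTR"),
    ])
    reads = []
    for i in range(5):
        reads.append(_multi(f"e{i}", [("chr1", 1100), ("chr1", 3100)]))
    for i in range(4):
        reads.append(_multi(f"f{i}", [("chr1", 1100), ("chr1", 5100)]))
    reads.append(_multi("c0", [("chr1", 1100), ("chr1", 7100)]))
    rep = tq.assignment_ambiguity(AlignmentSet(reads), ann)
    assert rep.proportions == {"element": 0.5, "family": 0.9, "class": 1.0}


def test_ambiguity_hierarchy_monotone(small_sim):
    rep = tq.assignment_ambiguity(small_sim["alns"], small_sim["ann"])
    p = rep.proportions
    assert p["class"] >= p["family"] >= p["element"]


def test_ambiguity_empty_marked_not_zero(two_copy_ann):
    rep = tq.assignment_ambiguity(AlignmentSet([_read("r1", "chr1", 1100)]),
                                  two_copy_ann)
    assert rep.empty and rep.proportions == {}


# ---------------------------------------------------------------------------
# fractions, normalization, aggregation
# ---------------------------------------------------------------------------

def test_te_fraction_simple_ratio(two_copy_ann):
    reads = [_read(f"r{i}", "chr1", 1100) for i in range(40)]
    reads += [_read(f"o{i}", "chr1", 9000) for i in range(60)]
    frac = tq.te_fraction(AlignmentSet(reads), two_copy_ann)
    assert frac["s1"] == pytest.approx(0.4)


def test_te_fraction_no_annotation_is_zero(two_copy_ann):
    empty = GenomeAnnotation([], [])
    frac = tq.te_fraction(AlignmentSet([_read("r1", "chr1", 1100)]), empty)
    assert frac["s1"] == 0.0


def test_te_fraction_two_cell_burst_exceeds_oocyte(small_sim):
    frac = tq.te_fraction(small_sim["alns"], small_sim["ann"], seed=1)
    meta = small_sim["counts"].metadata
    two_cell = frac[[s for s in frac.index if meta.loc[s, "stage"] == "2-cell"]]
    oocyte = frac[[s for s in frac.index if meta.loc[s, "stage"] == "oocyte"]]
    assert two_cell.min() > oocyte.max()


def test_within_sample_normalization(small_sim):
    t = tq.count_te(small_sim["alns"], small_sim["ann"],
                    "unique_plus_one_random", seed=0, level="element")
    norm = tq.normalize_te(t, "within_sample")
    assert np.allclose(norm.sum(axis=0), 1.0)
    # scaling one sample's counts leaves its normalized values unchanged
    t.counts.iloc[:, 0] *= 3
    t.te_mapped_total.iloc[0] *= 3
    norm2 = tq.normalize_te(t, "within_sample")
    assert np.allclose(norm.iloc[:, 0], norm2.iloc[:, 0])


def test_within_sample_zero_total_fails(two_copy_ann):
    t = tq.count_te(AlignmentSet([_read("r1", "chr1", 9000)]), two_copy_ann,
                    "unique_only", level="element")
    with pytest.raises(ValueError, match="zero TE-mapped"):
        tq.normalize_te(t, "within_sample")


def test_aggregate_hierarchy_levels(small_sim):
    t = tq.count_te(small_sim["alns"], small_sim["ann"],
                    "unique_plus_one_random", seed=0, level="element")
    fam = tq.aggregate_hierarchy(t, "family")
    cls = tq.aggregate_hierarchy(t, "class")
    hier = t.hierarchy.drop_duplicates()
    for f in fam.counts.index:
        members = hier.loc[hier["rep_family"] == f, "rep_name"].unique()
        members = [m for m in members if m in t.counts.index]
        assert (fam.counts.loc[f] == t.counts.loc[members].sum(axis=0)).all()
    # class totals equal the sum of family totals within class
    fam_to_cls = hier.set_index("rep_family")["rep_class"].to_dict()
    regroup = fam.counts.groupby(
        [fam_to_cls[f] for f in fam.counts.index]).sum()
    pd.testing.assert_frame_equal(cls.counts.sort_index(),
                                  regroup.sort_index(), check_names=False)


def test_aggregate_unknown_element_fails(small_sim):
    t = tq.count_te(small_sim["alns"], small_sim["ann"], "unique_only",
                    level="element")
    t.counts.loc["made-up-element"] = 0
    with pytest.raises(KeyError, match="made-up-element"):
        tq.aggregate_hierarchy(t, "family")
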
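"""RNA annotation, RAL tracks, XAL and XIST-split distance decay."""

import numpy as np
import pytest
from scipy import stats

from musicpipe.clusters import Cluster
from musicpipe.demux import TaggedRead
from musicpipe.mapdedup import MappedRead
from musicpipe.rnadna import (
    annotate_rna_reads,
    ral_track,
    rna_dna_matrix,
    split_clusters_by_rna,
    stratify_by_xal,
    xal,
    XalRecord,
    xist_split_pc,
)
from musicpipe.synthdata.reference import Gene

MB = 1_000_000


def _read(read_id, modality="DNA", chrom="hs_chrX", start=0, strand="+",
          insert_len=30, cb=(1, 2, 3), gem="G" * 16, i7=1):
    tag = TaggedRead(
        read_id=read_id, cb1=cb[0], cb2=cb[1], cb3=cb[2], gem=gem,
        gem_umi="A" * 12, i7=i7, linker_umi="CCCCC", modality=modality,
        insert="A" * insert_len, quals="?" * insert_len,
    )
    return MappedRead(tag, chrom, start, strand, "unique", "hs")


def _gene(gene_id="G1", chrom="hs_chr1", start=1_000, end=5_000, strand="+",
          biotype="protein_coding", exons=None):
    return Gene(
        gene_id=gene_id, name=gene_id, species="hs", chrom=chrom,
        start=start, end=end, strand=strand, biotype=biotype,
        exons=exons or [(start, start + 1_000), (end - 1_000, end)],
    )


def test_pre_mrna_requires_15bp_same_strand_intron_overlap():
    g = _gene()  # intron spans [2000, 4000)
    inside = _read("a", "RNA", "hs_chr1", 2_500, "+", insert_len=30)
    ann = annotate_rna_reads([inside], [g])
    assert ann["a"].label == "pre-mRNA" and ann["a"].gene_id == "G1"

    # 14 bp of intron overlap only: read ends 14 bases into the intron
    boundary = _read("b", "RNA", "hs_chr1", 2_000 - 16, "+", insert_len=30)
    assert annotate_rna_reads([boundary], [g])["b"].label != "pre-mRNA"
    at15 = _read("c", "RNA", "hs_chr1", 2_000 - 15, "+", insert_len=30)
    assert annotate_rna_reads([at15], [g])["c"].label == "pre-mRNA"


def test_antisense_intron_read_not_pre_mrna():
    g = _gene()
    anti = _read("a", "RNA", "hs_chr1", 2_500, "-", insert_len=30)
    assert annotate_rna_reads([anti], [g])["a"].label == "intergenic"


def test_non_coding_gene_not_pre_mrna():
    g = _gene(biotype="lncRNA")
    r = _read("a", "RNA", "hs_chr1", 2_500, "+", insert_len=30)
    assert annotate_rna_reads([r], [g])["a"].label == "intronic"


def test_exonic_and_missing_annotation():
    g = _gene()
    r = _read("a", "RNA", "hs_chr1", 1_100, "+")
    assert annotate_rna_reads([r], [g])["a"].label == "exonic"
    with pytest.raises(ValueError):
        annotate_rna_reads([r], [])


def _xist_cluster(n_dna_bins, key_i7=1, cb=(1, 2, 3), extra_rna=0, gem="G" * 16):
    cl = Cluster(key=(cb[0], cb[1], cb[2], gem, key_i7))
    cl.rna.append(_read(f"x{key_i7}", "RNA", "hs_chrX", 500, "+"))
    for j, b in enumerate(n_dna_bins):
        cl.dna.append(_read(f"d{key_i7}_{j}", "DNA", "hs_chrX", b * MB + 10))
    for j in range(extra_rna):
        cl.rna.append(_read(f"e{key_i7}_{j}", "RNA", "hs_chrX", 700))
    return cl


def _is_xist(read):
    return read.tag.read_id.startswith("x")


def test_ral_track_weight_rule():
    # 1 XIST RNA + 2 DNA in distinct bins -> each bin +1/3
    cl = _xist_cluster([3, 7])
    track = ral_track([cl], _is_xist)
    assert track.bins[("hs_chrX", 3)] == pytest.approx(1 / 3)
    assert track.bins[("hs_chrX", 7)] == pytest.approx(1 / 3)
    assert track.total == pytest.approx(2 / 3)


def test_ral_conservation_total_equals_pair_weight():
    # M=2 selected RNA, N=3 DNA -> M*N pairs at 1/(M+N): total 6/5
    cl = _xist_cluster([1, 2, 3], extra_rna=1)
    track = ral_track([cl], lambda r: r.tag.modality == "RNA")
    assert track.total == pytest.approx(2 * 3 / 5)


def test_ral_cluster_size_cap():
    cl = Cluster(key=(1, 2, 3, "G" * 16, 1))
    cl.rna.append(_read("x", "RNA", "hs_chrX", 0))
    for j in range(1_200):
        cl.dna.append(_read(f"d{j}", "DNA", "hs_chrX", j))
    assert ral_track([cl], _is_xist).total == 0.0


def test_ral_empty_selector():
    assert ral_track([_xist_cluster([1])], lambda r: False).bins == {}


def test_rna_dna_matrix_single_pair():
    cl = Cluster(key=(1, 2, 3, "G" * 16, 1))
    cl.rna.append(_read("r", "RNA", "hs_chrX", 2 * MB + 5))
    cl.dna.append(_read("d", "DNA", "hs_chrX", 5 * MB + 5))
    m = rna_dna_matrix([cl], "hs_chrX", 10 * MB)
    assert m[2, 5] == pytest.approx(0.5)
    assert m.sum() == pytest.approx(0.5)
    assert m[5, 2] == 0.0  # not symmetric


def test_xal_counts_distinct_bins():
    clusters = [_xist_cluster([3], key_i7=1), _xist_cluster([3, 7], key_i7=2)]
    rec = xal(clusters, _is_xist, "hs_chrX", "cell1")
    assert rec.xal == 2
    assert rec.xist_reads == 2
    assert rec.chrx_dna_reads == 3


def test_xal_invariant_to_dna_only_clusters():
    clusters = [_xist_cluster([3, 7])]
    rec1 = xal(clusters, _is_xist, "hs_chrX", "c")
    extra = Cluster(key=(1, 2, 3, "T" * 16, 5))
    extra.dna = [_read("d1", "DNA", "hs_chrX", 0), _read("d2", "DNA", "hs_chrX", 9 * MB)]
    rec2 = xal(clusters + [extra], _is_xist, "hs_chrX", "c")
    assert rec2.xal == rec1.xal
    assert rec2.chrx_dna_reads == rec1.chrx_dna_reads + 2


def test_xal_zero_without_xist():
    cl = Cluster(key=(1, 2, 3, "G" * 16, 1))
    cl.dna = [_read("d", "DNA", "hs_chrX", 0)]
    assert xal([cl], _is_xist, "hs_chrX", "c").xal == 0


def _recs(xals):
    return [XalRecord(f"c{i}", x, x, 10) for i, x in enumerate(xals)]


def test_stratify_example():
    groups = stratify_by_xal(_recs([0, 0, 1, 2, 3, 4, 5, 6]))
    assert len(groups["zero"]) == 2
    assert [len(groups[g]) for g in ("low", "medium", "high")] == [2, 2, 2]
    assert [r.xal for r in groups["low"]] == [1, 2]
    assert [r.xal for r in groups["high"]] == [5, 6]


def test_stratify_all_zero_and_three_positive():
    groups = stratify_by_xal(_recs([0, 0, 0]))
    assert len(groups["zero"]) == 3
    assert all(not groups[g] for g in ("low", "medium", "high"))
    groups = stratify_by_xal(_recs([0, 4, 2, 9]))
    assert [len(groups[g]) for g in ("low", "medium", "high")] == [1, 1, 1]


def test_stratify_partitions_exactly():
    recs = _recs([0, 1, 1, 2, 5, 5, 5, 8, 9, 11, 13])
    groups = stratify_by_xal(recs)
    ids = [r.cell_id for g in groups.values() for r in g]
    assert sorted(ids) == sorted(r.cell_id for r in recs)
    sizes = [len(groups[g]) for g in ("low", "medium", "high")]
    assert max(sizes) - min(sizes) <= 1


def test_split_clusters_by_rna_sets():
    xist_pos = _xist_cluster([1, 2], key_i7=1)
    rd_neg = Cluster(key=(1, 2, 3, "G" * 16, 2))
    rd_neg.rna.append(_read("o", "RNA", "hs_chrX", 100))
    rd_neg.dna.append(_read("d", "DNA", "hs_chrX", 200))
    dna_only = Cluster(key=(1, 2, 3, "G" * 16, 3))
    dna_only.dna = [_read("e1", "DNA", "hs_chrX", 0), _read("e2", "DNA", "hs_chrX", 50)]
    pos, neg = split_clusters_by_rna([xist_pos, rd_neg, dna_only], _is_xist)
    assert pos == [xist_pos]
    assert set(id(c) for c in neg) == {id(rd_neg), id(dna_only)}
    _, neg2 = split_clusters_by_rna(
        [xist_pos, rd_neg, dna_only], _is_xist, include_dna_only_in_negative=False
    )
    assert neg2 == [rd_neg]


def _planted_clusters(rng, n, alpha, xist=False, chrx_len=100 * MB):
    from musicpipe.synthdata.groundtruth import sample_truncated_powerlaw

    out = []
    for i in range(n):
        cl = Cluster(key=(1, 2, 3, "G" * 16, i + (10_000 if xist else 0)))
        anchor = int(rng.integers(0, chrx_len // 2))
        d = float(sample_truncated_powerlaw(rng, alpha, 1e4, 4e7, 1)[0])
        cl.dna.append(_read(f"d{i}a", "DNA", "hs_chrX", anchor))
        cl.dna.append(_read(f"d{i}b", "DNA", "hs_chrX", anchor + int(d)))
        if xist:
            cl.rna.append(_read(f"x{i}", "RNA", "hs_chrX", 500))
        else:
            cl.rna.append(_read(f"o{i}", "RNA", "hs_chrX", 600))
        out.append(cl)
    return out


def test_xist_split_recovers_planted_generative_difference():
    """XIST+ complexes drawn with a heavier long-range tail separate from
    XIST- complexes below the crossover distance."""
    rng = np.random.default_rng(8)
    pos = _planted_clusters(rng, 2_000, alpha=0.6, xist=True)
    neg = _planted_clusters(rng, 2_000, alpha=1.5, xist=False)
    curves = xist_split_pc(pos + neg, _is_xist, "hs_chrX", 100 * MB, n_bins=500)
    p, q = curves["xist_pos"].freq, curves["xist_neg"].freq
    p, q = p / p.sum(), q / q.sum()
    # short-range mass dominated by the XIST- (steep-decay) set
    short = slice(0, 5)
    assert q[short].sum() > p[short].sum()
    # cumulative curves cross once: beyond the crossover XIST+ dominates
    assert p[50:].sum() > q[50:].sum()


def test_symmetric_simulation_split_is_null():
    """When XIST+ and XIST- complexes share one generative law, their
    contact-distance distributions are statistically indistinguishable."""
    from musicpipe.clusters import decompose_cluster

    rng = np.random.default_rng(9)
    clusters = _planted_clusters(rng, 1_000, alpha=1.2, xist=True) + _planted_clusters(
        rng, 1_000, alpha=1.2, xist=False
    )
    pos, neg = split_clusters_by_rna(clusters, _is_xist)
    dp = np.array([abs(c.a.pos - c.b.pos) for cl in pos
                   for c in decompose_cluster(cl, mode="dna_dna")])
    dq = np.array([abs(c.a.pos - c.b.pos) for cl in neg
                   for c in decompose_cluster(cl, mode="dna_dna")])
    assert stats.ks_2samp(dp, dq).pvalue > 0.05
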
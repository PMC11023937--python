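"""RNA-side analytics: attachment tracks, RNA-DNA maps and XIST metrics.

The RNA attachment level (RAL) of a genomic bin is the summed weight of
RNA-DNA pairs (for a selected RNA class) whose DNA ends fall in that
bin.  Per-cell XIST-chromosome X association is condensed into XAL, the
number of 1 Mb chrX bins with any XIST-attached DNA, and cells are
stratified into a zero-XAL group plus three equal-count groups of
increasing XAL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
from intervaltree import IntervalTree

from .clusters import Cluster, ClusterKey, decompose_cluster
from .contacts import PcCurve, pc_curve
from .mapdedup import MappedRead
from .synthdata.reference import Gene

MB = 1_000_000
PRE_MRNA_MIN_OVERLAP = 15
RAL_MAX_CLUSTER_SIZE = 1_000


def _cluster_pool(clusters) -> list[Cluster]:
    return list(clusters.values() if isinstance(clusters, dict) else clusters)


# ----------------------------------------------------- RNA read annotation

@dataclass
class RnaAnnotation:
    read_id: str
    label: str  # pre-mRNA | exonic | intronic | intergenic
    gene_id: str | None


class GeneIndex:
    """Strand-aware interval index over exons and introns."""

    def __init__(self, genes: list[Gene]):
        self.genes = {g.gene_id: g for g in genes}
        self._exons: dict[tuple[str, str], IntervalTree] = {}
        self._introns: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            ek = self._exons.setdefault((g.chrom, g.strand), IntervalTree())
            for s, e in g.exons:
                ek[s:e] = g.gene_id
            ik = self._introns.setdefault((g.chrom, g.strand), IntervalTree())
            for s, e in g.introns:
                ik[s:e] = g.gene_id

    def _best_overlap(self, tree_map, chrom, strand, start, end):
        tree = tree_map.get((chrom, strand))
        if tree is None:
            return None, 0
        best, best_ov = None, 0
        for iv in tree.overlap(start, end):
            ov = min(end, iv.end) - max(start, iv.begin)
            if ov > best_ov or (ov == best_ov and best is not None and iv.data < best):
                best, best_ov = iv.data, ov
        return best, best_ov


def annotate_rna_reads(
    rna_reads: Iterable[MappedRead], genes: list[Gene]
) -> dict[str, RnaAnnotation]:
    """Classify RNA reads against the annotation (strand-aware).

    A read is pre-mRNA when it overlaps an intron of a protein-coding
    gene by at least 15 bp on the same strand; otherwise exonic /
    intronic / intergenic by its best same-strand overlap.
    """
    if not genes:
        raise ValueError("empty annotation")
    index = GeneIndex(genes)
    out: dict[str, RnaAnnotation] = {}
    for r in rna_reads:
        start, end = r.start, r.start + len(r.tag.insert)
        ig, iov = index._best_overlap(index._introns, r.chrom, r.strand, start, end)
        eg, eov = index._best_overlap(index._exons, r.chrom, r.strand, start, end)
        if (
            ig is not None
            and iov >= PRE_MRNA_MIN_OVERLAP
            and index.genes[ig].biotype == "protein_coding"
        ):
            out[r.tag.read_id] = RnaAnnotation(r.tag.read_id, "pre-mRNA", ig)
        elif eg is not None and eov > 0:
            out[r.tag.read_id] = RnaAnnotation(r.tag.read_id, "exonic", eg)
        elif ig is not None and iov > 0:
            out[r.tag.read_id] = RnaAnnotation(r.tag.read_id, "intronic", ig)
        else:
            out[r.tag.read_id] = RnaAnnotation(r.tag.read_id, "intergenic", None)
    return out


def reads_per_kilobase(
    annotations: dict[str, RnaAnnotation], genes: list[Gene]
) -> dict[str, float]:
    """Gene-level RNA quantification: assigned reads per kb of gene span."""
    counts: dict[str, int] = {}
    for a in annotations.values():
        if a.gene_id is not None:
            counts[a.gene_id] = counts.get(a.gene_id, 0) + 1
    return {
        g.gene_id: counts.get(g.gene_id, 0) / ((g.end - g.start) / 1_000.0)
        for g in genes
    }


# --------------------------------------------------------------- RAL track

@dataclass
class RALTrack:
    bin_size: int
    bins: dict[tuple[str, int], float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.bins.values())

    def on_chrom(self, chrom: str, n_bins: int) -> np.ndarray:
        out = np.zeros(n_bins)
        for (c, b), w in self.bins.items():
            if c == chrom and b < n_bins:
                out[b] += w
        return out

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for (chrom, b), w in sorted(self.bins.items()):
                fh.write(f"{chrom}\t{b * self.bin_size}\t{(b + 1) * self.bin_size}\t{w:.6g}\n")


def ral_track(
    clusters,
    rna_selector: Callable[[MappedRead], bool],
    bin_size: int = MB,
    max_cluster_size: int = RAL_MAX_CLUSTER_SIZE,
) -> RALTrack:
    """RNA attachment level of the selected RNA class per genomic bin.

    A cluster with M selected RNA reads and N DNA reads contributes
    M x N RNA-DNA pairs at weight 1/(M+N); each DNA end deposits its
    pair weights into the bin it maps to.  Clusters larger than the cap
    are excluded.
    """
    track = RALTrack(bin_size=bin_size)
    for cl in _cluster_pool(clusters):
        if cl.size > max_cluster_size or not cl.dna:
            continue
        m = sum(1 for r in cl.rna if rna_selector(r))
        if m == 0:
            continue
        w = 1.0 / (m + len(cl.dna))
        for r in cl.dna:
            key = (r.chrom, r.start // bin_size)
            track.bins[key] = track.bins.get(key, 0.0) + m * w
    return track


def rna_dna_matrix(
    clusters,
    chrom: str,
    chrom_len: int,
    bin_size: int = MB,
) -> np.ndarray:
    """2D RNA-origin x DNA-target map for one chromosome (not symmetric).

    M[i, j] sums the weights of RNA-DNA pairs whose RNA end maps to bin
    i and DNA end to bin j, with membership and size restricted to the
    chromosome.
    """
    n = -(-chrom_len // bin_size)
    m = np.zeros((n, n))
    region = (chrom, 0, chrom_len)
    for cl in _cluster_pool(clusters):
        for c in decompose_cluster(cl, region=region, mode="native"):
            if c.a.modality == "RNA" and c.b.modality == "DNA":
                m[c.a.pos // bin_size, c.b.pos // bin_size] += c.weight
    return m


# -------------------------------------------------------------- XIST / XAL

@dataclass
class XalRecord:
    cell_id: str
    xal: int
    xist_reads: int
    chrx_dna_reads: int
    group: str | None = None  # zero | low | medium | high


def xal(
    cell_clusters,
    xist_selector: Callable[[MappedRead], bool],
    chrx: str,
    cell_id: str,
    bin_size: int = MB,
) -> XalRecord:
    """XIST-chromosome X association level of one cell.

    XAL counts the distinct 1 Mb chrX bins whose XIST RAL is positive;
    adding DNA-only clusters never changes it (they carry no XIST RNA).
    """
    pool = _cluster_pool(cell_clusters)
    track = ral_track(pool, xist_selector, bin_size=bin_size)
    n_bins = sum(1 for (c, _b), w in track.bins.items() if c == chrx and w > 0)
    xist_reads = sum(sum(1 for r in cl.rna if xist_selector(r)) for cl in pool)
    chrx_dna = sum(sum(1 for r in cl.dna if r.chrom == chrx) for cl in pool)
    return XalRecord(cell_id=cell_id, xal=n_bins, xist_reads=xist_reads, chrx_dna_reads=chrx_dna)


def stratify_by_xal(records: list[XalRecord]) -> dict[str, list[XalRecord]]:
    """Partition cells into zero / low / medium / high XAL groups.

    Zero-XAL cells form their own group; the remaining cells are sorted
    by (XAL, cell id) and cut into three contiguous groups whose sizes
    differ by at most one.
    """
    zero = [r for r in records if r.xal == 0]
    positive = sorted((r for r in records if r.xal > 0), key=lambda r: (r.xal, r.cell_id))
    groups: dict[str, list[XalRecord]] = {"zero": zero, "low": [], "medium": [], "high": []}
    for name, chunk in zip(("low", "medium", "high"), np.array_split(positive, 3)):
        groups[name] = list(chunk)
    for name, members in groups.items():
        for r in members:
            r.group = name
    return groups


def split_clusters_by_rna(
    clusters,
    selector: Callable[[MappedRead], bool],
    include_dna_only_in_negative: bool = True,
) -> tuple[list[Cluster], list[Cluster]]:
    """(positive, negative) cluster sets for an RNA class.

    Positive: RNA-DNA clusters with at least one selected RNA read.
    Negative: RNA-DNA clusters without any, plus (by default) DNA-only
    clusters.
    """
    pos: list[Cluster] = []
    neg: list[Cluster] = []
    for cl in _cluster_pool(clusters):
        has = any(selector(r) for r in cl.rna)
        if has:
            if cl.type == "RNA-DNA":
                pos.append(cl)
        elif cl.type == "RNA-DNA" or (include_dna_only_in_negative and cl.type == "DNA-only"):
            neg.append(cl)
    return pos, neg


def xist_split_pc(
    clusters,
    xist_selector: Callable[[MappedRead], bool],
    chrx: str,
    chrx_len: int,
    n_bins: int = 2_000,
    include_dna_only: bool = True,
    mode: str = "pool_all",
) -> dict[str, PcCurve]:
    """chrX P_c(s) for XIST+ vs XIST- cluster sets, with an any-RNA control."""
    region = (chrx, 0, chrx_len)
    out: dict[str, PcCurve] = {}
    splits = {
        ("xist_pos", "xist_neg"): xist_selector,
        ("any_rna_pos", "any_rna_neg"): lambda r: True,
    }
    for (pos_name, neg_name), sel in splits.items():
        pos, neg = split_clusters_by_rna(clusters, sel, include_dna_only)
        for name, subset in ((pos_name, pos), (neg_name, neg)):
            contacts = []
            for cl in subset:
                contacts.extend(decompose_cluster(cl, region=region, mode="dna_dna"))
            out[name] = pc_curve(contacts, n_bins=n_bins, mode=mode)
    return out
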
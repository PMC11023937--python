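"""Cluster assembly, multiplex decomposition and size census.

A *cluster* is the set of uniquely mapped, deduplicated reads sharing
one cell-barcode triple plus one complex barcode (GEM + I7); it is the
sequencing proxy for one crosslinked molecular complex.  Multiplex
clusters are decomposed into pairwise contacts with SPRITE-style
down-weighting: a homotypic cluster of size N yields all C(N, 2)
unordered pairs at weight 1/N (total (N-1)/2), and a heterotypic
cluster with M RNA and N DNA reads yields all M*N RNA-DNA pairs at
weight 1/(M+N) (total MN/(M+N)), so large clusters are not inflated by
their quadratic pair counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .mapdedup import MappedRead

ClusterKey = tuple[int, int, int, str, int]

SIZE_CLASSES = ("1", "2", "3-10", ">10")


def _size_class(n: int) -> str:
    if n == 1:
        return "1"
    if n == 2:
        return "2"
    return "3-10" if n <= 10 else ">10"


@dataclass
class Cluster:
    key: ClusterKey
    dna: list[MappedRead] = field(default_factory=list)
    rna: list[MappedRead] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.dna) + len(self.rna)

    @property
    def type(self) -> str:
        if self.dna and self.rna:
            return "RNA-DNA"
        return "DNA-only" if self.dna else "RNA-only"

    @property
    def is_singleton(self) -> bool:
        return self.size == 1

    @property
    def cell_id(self) -> str:
        return f"{self.key[0]}-{self.key[1]}-{self.key[2]}"


@dataclass(frozen=True)
class ContactEnd:
    chrom: str
    pos: int
    modality: str
    strand: str


@dataclass(frozen=True)
class WeightedContact:
    a: ContactEnd
    b: ContactEnd
    weight: float
    cluster_key: ClusterKey
    cell_id: str
    cluster_size: int  # (region-restricted) size used for the weight


def build_clusters(
    reads: list[MappedRead],
) -> tuple[dict[ClusterKey, Cluster], pd.DataFrame]:
    """Group deduplicated reads by (cb1, cb2, cb3, gem, i7).

    Returns the clusters and a per-cell roster of DNA/RNA read totals
    (cells are distinct cell-barcode triples).
    """
    clusters: dict[ClusterKey, Cluster] = {}
    for r in reads:
        cl = clusters.setdefault(r.cluster_key, Cluster(key=r.cluster_key))
        (cl.dna if r.tag.modality == "DNA" else cl.rna).append(r)
    rows: dict[str, dict[str, int]] = {}
    for cl in clusters.values():
        row = rows.setdefault(
            cl.cell_id, {"n_dna": 0, "n_rna": 0, "n_clusters": 0}
        )
        row["n_dna"] += len(cl.dna)
        row["n_rna"] += len(cl.rna)
        row["n_clusters"] += 1
    roster = pd.DataFrame.from_dict(rows, orient="index").rename_axis("cell_id")
    return clusters, roster


def _in_region(r: MappedRead, region: tuple[str, int, int] | None) -> bool:
    if region is None:
        return True
    chrom, start, end = region
    return r.chrom == chrom and start <= r.start < end


def decompose_cluster(
    cluster: Cluster,
    region: tuple[str, int, int] | None = None,
    mode: str = "native",
) -> list[WeightedContact]:
    """Decompose one cluster into weighted pairwise contacts.

    ``mode="native"``: homotypic clusters give all unordered same-
    modality pairs at weight 1/size; heterotypic clusters give all
    RNA-DNA pairs at weight 1/(M+N).  ``mode="dna_dna"`` gives all
    DNA-DNA pairs from any cluster type, each at 1/size (so DNA reads
    inside RNA-DNA clusters also feed DNA-DNA contact analyses, with
    the same per-cluster normaliser).  With ``region``, membership and
    size are recomputed on region-restricted reads first.
    """
    dna = [r for r in cluster.dna if _in_region(r, region)]
    rna = [r for r in cluster.rna if _in_region(r, region)]
    if mode == "dna_dna":
        members: list[list[MappedRead]] = [dna] if len(dna) >= 2 else []
        size = len(dna) + len(rna)
    elif cluster.type in ("DNA-only", "RNA-only"):
        pool = dna if cluster.type == "DNA-only" else rna
        members = [pool] if len(pool) >= 2 else []
        size = len(pool)
    else:  # heterotypic, native: RNA-DNA pairs only
        members = []
        size = len(dna) + len(rna)

    def end(r: MappedRead) -> ContactEnd:
        return ContactEnd(r.chrom, r.start, r.tag.modality, r.strand)

    out: list[WeightedContact] = []
    if members:
        w = 1.0 / size
        for pool in members:
            # canonical end order -> decomposition is member-order invariant
            ordered = sorted(pool, key=lambda r: (r.chrom, r.start, r.strand))
            for x, y in itertools.combinations(ordered, 2):
                out.append(
                    WeightedContact(end(x), end(y), w, cluster.key, cluster.cell_id, size)
                )
    elif mode == "native" and cluster.type == "RNA-DNA" and dna and rna:
        w = 1.0 / size
        for x in rna:
            for y in dna:
                out.append(
                    WeightedContact(end(x), end(y), w, cluster.key, cluster.cell_id, size)
                )
    return out


def decompose_all(
    clusters: dict[ClusterKey, Cluster] | list[Cluster],
    region: tuple[str, int, int] | None = None,
    mode: str = "native",
) -> list[WeightedContact]:
    pool = clusters.values() if isinstance(clusters, dict) else clusters
    out: list[WeightedContact] = []
    for cl in pool:
        out.extend(decompose_cluster(cl, region=region, mode=mode))
    return out


@dataclass
class ClusterCensus:
    """Counts of clusters and reads by type and size class.

    ``clusters[type][size_class]`` and ``reads[type][size_class]``;
    size classes are "1", "2", "3-10" and ">10".
    """

    clusters: dict[str, dict[str, int]]
    reads: dict[str, dict[str, int]]

    @classmethod
    def from_cluster_counts(cls, counts: dict[str, dict[str, int]]) -> "ClusterCensus":
        """Build a census from externally tabulated cluster counts."""
        return cls(clusters={k: dict(v) for k, v in counts.items()}, reads={})

    def n_clusters(self, type_: str, size_class: str | None = None) -> int:
        table = self.clusters.get(type_, {})
        if size_class is None:
            return sum(table.values())
        if size_class == "3+" and "3+" not in table:
            return table.get("3-10", 0) + table.get(">10", 0)
        return table.get(size_class, 0)

    def n_nonsingleton(self, type_: str) -> int:
        return self.n_clusters(type_) - self.n_clusters(type_, "1")

    def percentage(self, type_: str, size_class: str) -> float | None:
        """Share of ``size_class`` among non-singleton clusters of a type.

        Two decimals, half-up rounding; ``None`` on an empty census.
        """
        total = self.n_nonsingleton(type_)
        if total == 0:
            return None
        pct = Decimal(100 * self.n_clusters(type_, size_class)) / Decimal(total)
        return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    def total_reads(self) -> int:
        return sum(sum(v.values()) for v in self.reads.values())


def census(clusters: dict[ClusterKey, Cluster] | list[Cluster]) -> ClusterCensus:
    pool = clusters.values() if isinstance(clusters, dict) else clusters
    ctab: dict[str, dict[str, int]] = {}
    rtab: dict[str, dict[str, int]] = {}
    for cl in pool:
        sc = _size_class(cl.size)
        ctab.setdefault(cl.type, {}).setdefault(sc, 0)
        ctab[cl.type][sc] += 1
        rtab.setdefault(cl.type, {}).setdefault(sc, 0)
        rtab[cl.type][sc] += cl.size
    return ClusterCensus(clusters=ctab, reads=rtab)


# ------------------------------------------------------------ species QC

def species_qc(
    clusters: dict[ClusterKey, Cluster] | list[Cluster],
    cell_purity: float = 0.95,
    cluster_purity: float = 0.99,
    ambient_max_dna: int = 1_000,
) -> dict:
    """Mixed-species quality control on DNA reads.

    A cell is assigned to a species when at least ``cell_purity`` of its
    DNA reads map to that species; cells with fewer than
    ``ambient_max_dna`` DNA reads are ambient.  A cluster is assigned
    when more than ``cluster_purity`` of its DNA reads come from one
    species.  The collision rate is the mixed fraction of non-ambient
    cells.
    """
    pool = list(clusters.values() if isinstance(clusters, dict) else clusters)
    per_cell: dict[str, dict[str, int]] = {}
    cluster_calls: dict[ClusterKey, str] = {}
    for cl in pool:
        tally: dict[str, int] = {}
        for r in cl.dna:
            sp = r.species or "unknown"
            tally[sp] = tally.get(sp, 0) + 1
            cell = per_cell.setdefault(cl.cell_id, {})
            cell[sp] = cell.get(sp, 0) + 1
        if tally:
            top_sp, top_n = max(tally.items(), key=lambda kv: kv[1])
            frac = top_n / sum(tally.values())
            cluster_calls[cl.key] = top_sp if frac > cluster_purity else "mixed"

    cell_calls: dict[str, str] = {}
    for cell_id, tally in per_cell.items():
        total = sum(tally.values())
        if total < ambient_max_dna:
            cell_calls[cell_id] = "ambient"
            continue
        top_sp, top_n = max(tally.items(), key=lambda kv: kv[1])
        cell_calls[cell_id] = top_sp if top_n / total >= cell_purity else "mixed"

    non_ambient = [v for v in cell_calls.values() if v != "ambient"]
    mixing_rate = (
        sum(1 for v in non_ambient if v == "mixed") / len(non_ambient)
        if non_ambient
        else None
    )
    return {
        "cell_calls": cell_calls,
        "cluster_calls": cluster_calls,
        "mixing_rate": mixing_rate,
    }


def write_contacts_pairs(contacts: list[WeightedContact], path) -> None:
    """Emit contacts in a 4DN .pairs-like text with a weight column."""
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: readID chr1 pos1 chr2 pos2 strand1 strand2 modality1 modality2 weight\n")
        for c in contacts:
            key = "-".join(str(k) for k in c.cluster_key)
            fh.write(
                f"{key}\t{c.a.chrom}\t{c.a.pos}\t{c.b.chrom}\t{c.b.pos}\t"
                f"{c.a.strand}\t{c.b.strand}\t{c.a.modality}\t{c.b.modality}\t{c.weight:.6g}\n"
            )
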
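"""Exact mapping to synthetic references and PCR-duplicate removal.

The built-in mapper is a k-mer seed index with full-length exact
verification, sized for the short synthetic genomes the simulator
emits; externally aligned real data enters through the BAM import path
instead.  Duplicate marking follows a single coordinate-sorted scan: a
read is a duplicate of an already-retained read when it maps within
8 bp on the same chromosome and strand, shares all five barcodes, and
its 17 nt UMI (GEM UMI + linker UMI) is within Levenshtein distance 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import edlib

from .demux import TaggedRead
from .layout import revcomp
from .synthdata.reference import SyntheticReference

MAX_DUP_DISTANCE = 8
MIN_MAPQ_UNIQUE = 30

#: SAM tag names used on export/import of tagged alignments.
SAM_TAGS = {
    "cb1": "B1", "cb2": "B2", "cb3": "B3",
    "gem": "BG", "gem_umi": "QG", "linker_umi": "QL",
    "i7": "BI", "modality": "MM",
}


@dataclass(frozen=True)
class MappedRead:
    """A tagged read with its mapping result."""

    tag: TaggedRead
    chrom: str | None
    start: int  # 0-based 5' mapping coordinate
    strand: str
    mapping: str  # unique | multi | unmapped
    species: str | None = None

    @property
    def umi(self) -> str:
        """17 nt concatenated GEM UMI + linker UMI used for dedup."""
        return self.tag.gem_umi + self.tag.linker_umi

    @property
    def cluster_key(self):
        return self.tag.cluster_key


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit-cost insert/delete/substitute)."""
    return edlib.align(a, b)["editDistance"]


class ExactIndex:
    """Exact-match k-mer index over a synthetic reference.

    Supports lookup of a query's occurrences on both strands; the query
    must match the genome exactly over its full length.
    """

    def __init__(self, ref: SyntheticReference, k: int = 20):
        if k < 1:
            raise ValueError("k must be positive")
        self.ref = ref
        self.k = k
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in ref.sequences.items():
            for pos in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[pos : pos + k], []).append((chrom, pos))

    def _exact_hits(self, query: str) -> list[tuple[str, int]]:
        hits = []
        for chrom, pos in self._seeds.get(query[: self.k], ()):
            seq = self.ref.sequences[chrom]
            if seq[pos : pos + len(query)] == query:
                hits.append((chrom, pos))
        return hits

    def locate(self, query: str) -> list[tuple[str, int, str]]:
        """All (chrom, start, strand) exact occurrences of the query."""
        if len(query) < self.k:
            return []
        fwd = [(c, p, "+") for c, p in self._exact_hits(query)]
        rc = revcomp(query)
        rev = [(c, p, "-") for c, p in self._exact_hits(rc)]
        return fwd + rev


def build_index(ref: SyntheticReference, k: int = 20) -> ExactIndex:
    return ExactIndex(ref, k)


def map_insert(tag: TaggedRead, index: ExactIndex) -> MappedRead:
    hits = index.locate(tag.insert)
    if not hits:
        return MappedRead(tag, None, -1, ".", "unmapped")
    if len(hits) > 1:
        return MappedRead(tag, None, -1, ".", "multi")
    chrom, pos, strand = hits[0]
    return MappedRead(
        tag, chrom, pos, strand, "unique", species=index.ref.species_of.get(chrom)
    )


def map_tagged_reads(
    tagged: list[TaggedRead], index: ExactIndex
) -> tuple[list[MappedRead], dict[str, int]]:
    """Map a batch; returns unique-class reads plus a class census."""
    census = {"unique": 0, "multi": 0, "unmapped": 0}
    unique: list[MappedRead] = []
    for t in tagged:
        m = map_insert(t, index)
        census[m.mapping] += 1
        if m.mapping == "unique":
            unique.append(m)
    return unique, census


def sort_reads(reads: list[MappedRead]) -> list[MappedRead]:
    return sorted(reads, key=lambda r: (r.chrom, r.start, r.tag.read_id))


def deduplicate(reads: list[MappedRead]) -> tuple[list[MappedRead], int]:
    """Remove PCR duplicates from coordinate-sorted unique reads.

    Input must be sorted by (chromosome, start); raises ``ValueError``
    otherwise.  Returns (retained reads, number removed).
    """
    retained: list[MappedRead] = []
    window: list[MappedRead] = []  # retained reads within 8 bp of current
    n_dup = 0
    prev_key: tuple[str, int] | None = None
    for r in reads:
        key = (r.chrom, r.start)
        if prev_key is not None and key < prev_key:
            raise ValueError("deduplicate requires (chromosome, start)-sorted input")
        prev_key = key
        window = [
            w
            for w in window
            if w.chrom == r.chrom and r.start - w.start <= MAX_DUP_DISTANCE
        ]
        is_dup = any(
            w.strand == r.strand
            and w.cluster_key == r.cluster_key
            and edit_distance(w.umi, r.umi) < 2
            for w in window
        )
        if is_dup:
            n_dup += 1
        else:
            retained.append(r)
            window.append(r)
    return retained, n_dup


# ----------------------------------------------------------------- BAM IO

def write_alignments(reads: list[MappedRead], ref: SyntheticReference, path) -> None:
    """Write mapped reads as SAM/BAM with the documented barcode tags."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in ref.sequences.items()],
    }
    mode = "wb" if str(path).endswith(".bam") else "w"
    chrom_ids = {c: i for i, c in enumerate(ref.sequences)}
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for r in sort_reads(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.tag.read_id
            a.query_sequence = r.tag.insert if r.strand == "+" else revcomp(r.tag.insert)
            a.query_qualities = pysam.qualitystring_to_array(
                r.tag.quals if r.strand == "+" else r.tag.quals[::-1]
            )
            a.reference_id = chrom_ids[r.chrom]
            a.reference_start = r.start
            a.cigarstring = f"{len(r.tag.insert)}M"
            a.mapping_quality = 60
            a.flag = 16 if r.strand == "-" else 0
            a.set_tag(SAM_TAGS["cb1"], r.tag.cb1, "i")
            a.set_tag(SAM_TAGS["cb2"], r.tag.cb2, "i")
            a.set_tag(SAM_TAGS["cb3"], r.tag.cb3, "i")
            a.set_tag(SAM_TAGS["gem"], r.tag.gem, "Z")
            a.set_tag(SAM_TAGS["gem_umi"], r.tag.gem_umi, "Z")
            a.set_tag(SAM_TAGS["linker_umi"], r.tag.linker_umi, "Z")
            a.set_tag(SAM_TAGS["i7"], r.tag.i7, "i")
            a.set_tag(SAM_TAGS["modality"], r.tag.modality, "Z")
            out.write(a)


def import_alignments(
    path, species_of: dict[str, str] | None = None
) -> tuple[list[MappedRead], dict[str, int]]:
    """Read externally aligned records carrying the demux tag set.

    Secondary/supplementary records are excluded; a primary alignment
    with MAPQ >= 30 is classed unique.  Records missing any tag are
    rejected and counted.
    """
    import pysam

    reads: list[MappedRead] = []
    counts = {"imported": 0, "secondary": 0, "missing_tag": 0, "low_mapq": 0, "unmapped": 0}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_secondary or a.is_supplementary:
                counts["secondary"] += 1
                continue
            if a.is_unmapped:
                counts["unmapped"] += 1
                continue
            try:
                tag = TaggedRead(
                    read_id=a.query_name,
                    cb1=a.get_tag(SAM_TAGS["cb1"]),
                    cb2=a.get_tag(SAM_TAGS["cb2"]),
                    cb3=a.get_tag(SAM_TAGS["cb3"]),
                    gem=a.get_tag(SAM_TAGS["gem"]),
                    gem_umi=a.get_tag(SAM_TAGS["gem_umi"]),
                    i7=a.get_tag(SAM_TAGS["i7"]),
                    linker_umi=a.get_tag(SAM_TAGS["linker_umi"]),
                    modality=a.get_tag(SAM_TAGS["modality"]),
                    insert=(a.query_sequence or ""),
                    quals="",
                )
            except KeyError:
                counts["missing_tag"] += 1
                continue
            if a.mapping_quality < MIN_MAPQ_UNIQUE:
                counts["low_mapq"] += 1
                continue
            strand = "-" if a.is_reverse else "+"
            insert = tag.insert if strand == "+" else revcomp(tag.insert)
            tag = _dc_replace(tag, insert=insert)
            chrom = a.reference_name
            species = species_of.get(chrom) if species_of else chrom.split("_")[0]
            reads.append(
                MappedRead(tag, chrom, a.reference_start, strand, "unique", species)
            )
            counts["imported"] += 1
    return reads, counts
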
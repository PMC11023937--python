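"""Demultiplexing: read triples -> tagged reads.

Each (R1, I1, R2) triple is parsed into a :class:`TaggedRead` carrying
the three cell barcodes, the GEM barcode and UMI, the I7 index, the
linker UMI, the RNA/DNA modality call and the trimmed insert.  Reads
failing any lookup are rejected with a machine-readable reason and
counted in the demux report.

Mismatch tolerances: one substitution per cell barcode and per GEM
barcode (whitelist rescue), exact match for I7.  Whitelists are built
with minimum pairwise Hamming distance 3, so a single-substitution
rescue can never be ambiguous; a sequence within tolerance of two
entries (possible only for noisier inputs) is rejected as ambiguous
rather than guessed.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .layout import (
    BarcodeTables,
    DNA_LINKER_SUFFIX,
    LINKER_SHARED,
    LINKER_UMI_LEN,
    ReadLayout,
    RNA_LINKER_SSDNA,
    RNA_LINKER_TAG,
    RNA_LINKER_SUFFIX,
)

QUALITY_TRIM_THRESHOLD = 15
MIN_INSERT_LEN = 20


@dataclass(frozen=True)
class TaggedRead:
    read_id: str
    cb1: int
    cb2: int
    cb3: int
    gem: str
    gem_umi: str
    i7: int
    linker_umi: str
    modality: str  # "RNA" | "DNA"
    insert: str
    quals: str

    @property
    def cluster_key(self) -> tuple[int, int, int, str, int]:
        """(cb1, cb2, cb3, gem, i7) — the molecular-complex key."""
        return (self.cb1, self.cb2, self.cb3, self.gem, self.i7)


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # cb1 | cb2 | cb3 | gem | i7 | linker | short_insert | structure


@dataclass
class DemuxReport:
    n_input: int = 0
    n_tagged: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def count_reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "input": self.n_input,
                "barcode_complete": self.n_tagged,
                "rejected": self.rejected,
            },
            indent=2,
        )


class BarcodeMatcher:
    """Whitelist lookup with bounded-mismatch rescue.

    Exact hits resolve through a hash map; otherwise every entry within
    ``max_mismatch`` Hamming distance is considered and the match is
    returned only if unique.
    """

    def __init__(self, table: list[str], max_mismatch: int):
        self.table = table
        self.length = len(table[0])
        self.max_mismatch = max_mismatch
        self._exact = {seq: i + 1 for i, seq in enumerate(table)}

    def match(self, observed: str) -> int | None:
        if len(observed) != self.length:
            return None
        hit = self._exact.get(observed)
        if hit is not None:
            return hit
        if self.max_mismatch == 0:
            return None
        best: int | None = None
        for i, entry in enumerate(self.table):
            d = 0
            for a, b in zip(observed, entry):
                if a != b:
                    d += 1
                    if d > self.max_mismatch:
                        break
            else:
                if best is not None:
                    return None  # ambiguous
                best = i + 1
        return best


def match_barcode(observed: str, table: list[str], max_mismatch: int) -> int | None:
    """One-off whitelist match (1-based id, or None if absent/ambiguous)."""
    return BarcodeMatcher(table, max_mismatch).match(observed)


def _segment_mismatches(observed: str, expected: str) -> int:
    if len(observed) < len(expected):
        return len(expected)
    return sum(a != b for a, b in zip(observed, expected))


def classify_modality(
    r2: str, layout: ReadLayout
) -> tuple[str, str | None]:
    """Classify the linker region of R2 as RNA, DNA or unknown.

    RNA requires <=1 mismatch in each signature segment (shared prefix,
    RNA tag, RNA suffix); DNA requires <=1 mismatch in the shared prefix
    and <=2 in the DNA suffix.  If both match (or neither), the read is
    ``unknown``.  Returns (modality, linker_umi).
    """
    off = layout.linker_offset
    region = r2[off:]
    shared_ok = _segment_mismatches(region, LINKER_SHARED) <= 1
    p = len(LINKER_SHARED)

    rna = (
        shared_ok
        and _segment_mismatches(region[p:], RNA_LINKER_TAG) <= 1
        and _segment_mismatches(
            region[p + len(RNA_LINKER_TAG) + LINKER_UMI_LEN :], RNA_LINKER_SUFFIX
        )
        <= 1
    )
    dna = (
        shared_ok
        and _segment_mismatches(region[p + LINKER_UMI_LEN :], DNA_LINKER_SUFFIX) <= 2
    )
    if rna == dna:
        return "unknown", None
    if rna:
        umi_at = p + len(RNA_LINKER_TAG)
    else:
        umi_at = p
    return ("RNA" if rna else "DNA"), region[umi_at : umi_at + LINKER_UMI_LEN]


def quality_trim_3p(seq: str, quals: str, threshold: int = QUALITY_TRIM_THRESHOLD) -> tuple[str, str]:
    """BWA-style 3' quality trimming (the cutadapt ``-q`` algorithm).

    Trims from the position i that maximises sum_{j>=i}(threshold - q_j)
    when that maximum is positive.
    """
    best = 0.0
    cut = len(seq)
    s = 0.0
    for i in range(len(seq) - 1, -1, -1):
        s += threshold - (ord(quals[i]) - 33)
        if s > best:
            best = s
            cut = i
    return seq[:cut], quals[:cut]


def _terminal_run(seq: str, base: str) -> int:
    n = 0
    for ch in reversed(seq):
        if ch != base:
            break
        n += 1
    return n


def trim_insert(
    insert: str, quals: str, modality: str
) -> tuple[str, str] | None:
    """Artifact and quality trimming; None when the read is dropped.

    DNA: a 3'-terminal homopolymer run of A or of G longer than 20 bp is
    removed.  RNA: the sequence is truncated at the first occurrence of
    the RNA-linker ssDNA (read-through into a downstream linker).  Both
    modalities are then 3' quality-trimmed at Q15 and dropped below
    20 bp.
    """
    if modality == "DNA":
        for base in "AG":
            run = _terminal_run(insert, base)
            if run > 20:
                insert, quals = insert[:-run], quals[:-run]
                break
    else:
        hit = insert.find(RNA_LINKER_SSDNA)
        if hit >= 0:
            insert, quals = insert[:hit], quals[:hit]
    insert, quals = quality_trim_3p(insert, quals)
    if len(insert) < MIN_INSERT_LEN:
        return None
    return insert, quals


def parse_read_pair(
    triple: tuple[tuple[str, str, str], tuple[str, str, str], tuple[str, str, str]],
    tables: BarcodeTables,
    layout: ReadLayout,
    matchers: dict[str, BarcodeMatcher] | None = None,
) -> TaggedRead | Rejection:
    """Parse one ((r1 id, seq, qual), (i1 ...), (r2 ...)) into a TaggedRead.

    Rejection reasons name the first failing component.
    """
    if matchers is None:
        matchers = build_matchers(tables)
    (rid, r1, _q1), (_, i1, _qi), (_, r2, q2) = triple
    if len(r1) < layout.gem_len + layout.gem_umi_len or len(i1) != layout.i7_len:
        return Rejection(rid, "structure")

    gem_id = matchers["gem"].match(r1[: layout.gem_len])
    if gem_id is None:
        return Rejection(rid, "gem")
    gem_umi = r1[layout.gem_len : layout.gem_len + layout.gem_umi_len]

    i7_id = matchers["i7"].match(i1)
    if i7_id is None:
        return Rejection(rid, "i7")

    sl3, sl2, sl1 = layout.barcode_slices()
    cb3 = matchers["cb3"].match(r2[sl3])
    if cb3 is None:
        return Rejection(rid, "cb3")
    cb2 = matchers["cb2"].match(r2[sl2])
    if cb2 is None:
        return Rejection(rid, "cb2")
    cb1 = matchers["cb1"].match(r2[sl1])
    if cb1 is None:
        return Rejection(rid, "cb1")

    modality, linker_umi = classify_modality(r2, layout)
    if modality == "unknown":
        return Rejection(rid, "linker")

    off = layout.rna_insert_offset if modality == "RNA" else layout.dna_insert_offset
    trimmed = trim_insert(r2[off:], q2[off:], modality)
    if trimmed is None:
        return Rejection(rid, "short_insert")
    insert, quals = trimmed

    return TaggedRead(
        read_id=rid, cb1=cb1, cb2=cb2, cb3=cb3,
        gem=tables.gem[gem_id - 1], gem_umi=gem_umi, i7=i7_id,
        linker_umi=linker_umi, modality=modality, insert=insert, quals=quals,
    )


def build_matchers(tables: BarcodeTables) -> dict[str, BarcodeMatcher]:
    return {
        "cb1": BarcodeMatcher(tables.cell[0], 1),
        "cb2": BarcodeMatcher(tables.cell[1], 1),
        "cb3": BarcodeMatcher(tables.cell[2], 1),
        "gem": BarcodeMatcher(tables.gem, 1),
        "i7": BarcodeMatcher(tables.i7, 0),
    }


def _open_maybe_gz(path):
    return gzip.open(path, "rt") if str(path).endswith(".gz") else open(path)


def iter_fastq_triples(r1_path, i1_path, r2_path) -> Iterator[tuple]:
    """Yield synchronised ((id, seq, qual), ...) triples from three FASTQs."""
    with _open_maybe_gz(r1_path) as f1, _open_maybe_gz(i1_path) as fi, _open_maybe_gz(
        r2_path
    ) as f2:
        it1 = FastqGeneralIterator(f1)
        iti = FastqGeneralIterator(fi)
        it2 = FastqGeneralIterator(f2)
        for (t1, s1, q1), (ti, si, qi), (t2, s2, q2) in zip(it1, iti, it2, strict=True):
            rid1, ridi, rid2 = t1.split()[0], ti.split()[0], t2.split()[0]
            if not (rid1 == ridi == rid2):
                raise ValueError(f"read name mismatch: {rid1} / {ridi} / {rid2}")
            yield (rid1, s1, q1), (ridi, si, qi), (rid2, s2, q2)


def demux(
    triples: Iterable[tuple],
    tables: BarcodeTables,
    layout: ReadLayout,
) -> tuple[list[TaggedRead], list[Rejection], DemuxReport]:
    """Run the parser over a stream of read triples with full accounting."""
    matchers = build_matchers(tables)
    tagged: list[TaggedRead] = []
    rejects: list[Rejection] = []
    report = DemuxReport()
    for triple in triples:
        report.n_input += 1
        out = parse_read_pair(triple, tables, layout, matchers)
        if isinstance(out, TaggedRead):
            tagged.append(out)
            report.n_tagged += 1
        else:
            rejects.append(out)
            report.count_reject(out.reason)
    return tagged, rejects, report


def write_tagged_tsv(tagged: Iterable[TaggedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tcb1\tcb2\tcb3\tgem\tgem_umi\ti7\tlinker_umi\tmodality\tinsert\tquals\n"
        )
        for t in tagged:
            fh.write(
                f"{t.read_id}\t{t.cb1}\t{t.cb2}\t{t.cb3}\t{t.gem}\t{t.gem_umi}\t"
                f"{t.i7}\t{t.linker_umi}\t{t.modality}\t{t.insert}\t{t.quals}\n"
            )
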
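"""Emit MUSIC-layout FASTQ triples (R1/I1/R2) from a ground truth.

One read triple is emitted per molecule occurrence (PCR duplicates
included).  R2 is the concatenation of the three cell barcodes (third,
second, first), the constant spacers, the modality linker with its 5 nt
UMI, and finally the insert, truncated to the read length.  Noise
injection covers per-base substitutions, barcode errors, the 3' A/G-tail
artifact on DNA reads, RNA linker read-through and low-quality tails.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np

from ..layout import BarcodeTables, ReadLayout, RNA_LINKER_SSDNA, revcomp
from .groundtruth import GroundTruth, Molecule

_BASES = "ACGT"
_Q30 = chr(30 + 33)
_Q2 = chr(2 + 33)


@dataclass(frozen=True)
class NoiseConfig:
    substitution_rate: float = 0.0    # per base, applied to R2
    barcode_mismatch_rate: float = 0.0  # per read: one substitution in one barcode
    ag_tail_rate: float = 0.0         # DNA reads: 3' poly-A/G artifact
    ag_tail_min: int = 25             # guaranteed visible tail length
    rna_readthrough_rate: float = 0.0  # RNA reads: linker read-through at 3'
    lowq_tail_rate: float = 0.0       # reads with a Q2 3' tail
    lowq_tail_len: int = 30


@dataclass
class EmitResult:
    r1: str
    i1: str
    r2: str
    n_reads: int
    n_skipped: int
    skipped_reads: list[str] = field(default_factory=list)


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = _BASES[(_BASES.index(arr[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def compose_read_triple(
    mol: Molecule,
    cb_seqs: tuple[str, str, str],
    gem_seq: str,
    i7_seq: str,
    ref_seq: str,
    layout: ReadLayout,
    noise: NoiseConfig,
    rng: np.random.Generator,
) -> tuple[str, str, str, str] | None:
    """Build (r1, i1, r2, r2_quals) for one molecule occurrence.

    Returns ``None`` when no insert base would be sequenced (the
    molecule is skipped and logged by the caller).
    """
    insert = ref_seq[mol.start : mol.end]
    if mol.strand == "-":
        insert = revcomp(insert)

    budget = layout.insert_budget(mol.modality)
    tail = ""
    if mol.modality == "DNA" and noise.ag_tail_rate > 0 and rng.random() < noise.ag_tail_rate:
        insert = insert[: max(1, budget - noise.ag_tail_min)]
        tail = ("A" if rng.random() < 0.5 else "G") * (budget - len(insert))
    elif (
        mol.modality == "RNA"
        and noise.rna_readthrough_rate > 0
        and rng.random() < noise.rna_readthrough_rate
    ):
        insert = insert[: max(1, budget - len(RNA_LINKER_SSDNA) - 4)]
        fill = budget - len(insert) - len(RNA_LINKER_SSDNA)
        tail = RNA_LINKER_SSDNA + "".join(
            _BASES[i] for i in rng.integers(0, 4, size=fill)
        )
    insert = insert[:budget]
    if not insert:
        return None

    umi = mol.linker_umi
    linker = layout.rna_linker(umi) if mol.modality == "RNA" else layout.dna_linker(umi)
    cb1, cb2, cb3 = cb_seqs
    sp1, sp2, sp3 = layout.spacers
    r2 = cb3 + sp1 + cb2 + sp2 + cb1 + sp3 + linker + insert + tail
    r2 = r2[: layout.r2_len]
    r2 = _substitute(rng, r2, noise.substitution_rate)

    r1 = gem_seq + mol.gem_umi
    if noise.barcode_mismatch_rate > 0 and rng.random() < noise.barcode_mismatch_rate:
        # corrupt exactly one base of one randomly chosen barcode segment
        def flip_one(seq: str) -> str:
            i = int(rng.integers(0, len(seq)))
            new = _BASES[(_BASES.index(seq[i]) + int(rng.integers(1, 4))) % 4]
            return seq[:i] + new + seq[i + 1 :]

        seg = int(rng.integers(0, 4))
        if seg == 3:
            r1 = flip_one(r1[: layout.gem_len]) + r1[layout.gem_len :]
        else:
            sl = layout.barcode_slices()[seg]
            r2 = r2[: sl.start] + flip_one(r2[sl]) + r2[sl.stop :]

    quals = _Q30 * len(r2)
    if noise.lowq_tail_rate > 0 and rng.random() < noise.lowq_tail_rate:
        k = min(noise.lowq_tail_len, len(r2))
        quals = quals[: len(r2) - k] + _Q2 * k
    return r1, i7_seq, r2, quals


def emit_reads(
    gt: GroundTruth,
    tables: BarcodeTables,
    layout: ReadLayout,
    noise: NoiseConfig,
    seed: int,
    outdir: str,
    prefix: str = "sim",
) -> EmitResult:
    """Write gzipped R1/I1/R2 FASTQ files plus truth tables.

    Read names are the truth read ids, so the truth map in
    ``reads.tsv`` links every FASTQ record back to its molecule, complex
    and cell.
    """
    import os

    rng = np.random.default_rng(seed)
    cells = {c.cell_id: c for c in gt.cells}
    cplx = gt.complex_by_id()
    mols = gt.molecule_by_id()
    paths = {r: os.path.join(outdir, f"{prefix}_{r}.fastq.gz") for r in ("R1", "I1", "R2")}

    n_written = 0
    skipped: list[str] = []
    with gzip.open(paths["R1"], "wt") as f1, gzip.open(paths["I1"], "wt") as fi, gzip.open(
        paths["R2"], "wt"
    ) as f2:
        for occ in gt.reads:
            mol = mols[occ.molecule_id]
            cell = cells[mol.cell_id]
            cx = cplx[mol.complex_id]
            cb_seqs = tuple(tables.cell[i][cell.cb[i] - 1] for i in range(3))
            triple = compose_read_triple(
                mol,
                cb_seqs,
                tables.gem[cx.gem_id - 1],
                tables.i7[cx.i7_id - 1],
                gt.reference.sequences[mol.chrom],
                layout,
                noise,
                rng,
            )
            if triple is None:
                skipped.append(occ.read_id)
                continue
            r1, i1, r2, q2 = triple
            f1.write(f"@{occ.read_id}\n{r1}\n+\n{_Q30 * len(r1)}\n")
            fi.write(f"@{occ.read_id}\n{i1}\n+\n{_Q30 * len(i1)}\n")
            f2.write(f"@{occ.read_id}\n{r2}\n+\n{q2}\n")
            n_written += 1

    gt.write_tsv(outdir)
    tables.to_tsv(os.path.join(outdir, "whitelists.tsv"))
    return EmitResult(
        r1=paths["R1"], i1=paths["I1"], r2=paths["R2"],
        n_reads=n_written, n_skipped=len(skipped), skipped_reads=skipped,
    )
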
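"""Read architecture of the MUSIC sequencing library.

A MUSIC library is sequenced as three reads per insert:

* **R1** (28 bp) — the droplet barcode: a 16 nt GEM barcode followed by a
  12 nt GEM UMI.
* **I1** (8 bp) — the I7 index that, together with the GEM barcode,
  identifies one molecular complex.
* **R2** (150 bp) — three 14 nt combinatorial cell barcodes (read in
  third, second, first order), each followed by a short constant spacer,
  then the RNA or DNA linker (which carries a 5 nt linker UMI), then the
  insert itself.

Each read triple carries exactly one insert, either RNA or DNA; the two
modalities are distinguished by the linker sequence ligated to the
molecule.  The linker signatures share the prefix ``CGAGGAG`` and then
diverge:

* RNA: ``CGAGGAG CGCTT <UMI:5> ATAGCATTGC``
* DNA: ``CGAGGAG <UMI:5> ACAACGCACAGTGTCTAGT``
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

# Linker signature segments, 5' to 3' as they appear in R2.
LINKER_SHARED = "CGAGGAG"
RNA_LINKER_TAG = "CGCTT"          # immediately after the shared prefix
RNA_LINKER_SUFFIX = "ATAGCATTGC"  # after the 5 nt UMI
DNA_LINKER_SUFFIX = "ACAACGCACAGTGTCTAGT"  # after the 5 nt UMI
LINKER_UMI_LEN = 5

# Full ssDNA region of the RNA linker; reads that run through an RNA
# insert into a downstream linker contain this sequence verbatim.
RNA_LINKER_SSDNA = LINKER_SHARED + RNA_LINKER_TAG

CELL_BC_LEN = 14
GEM_BC_LEN = 16
GEM_UMI_LEN = 12
I7_LEN = 8

#: Canonical spacer dialect between R2 barcode blocks (7 nt, matching the
#: top-strand overhang length of the combinatorial barcodes).  Real
#: libraries may use a different dialect; the layout is configurable.
DEFAULT_SPACERS = ("GTCGAAT", "ACCTGTC", "TGGACGA")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def cell_barcode_space(n_rounds: int = 3, n_per_round: int = 96) -> int:
    """Number of distinct cell-barcode combinations from split-pool rounds.

    Three rounds of 96 barcodes give ``96**3 == 884,736`` combinations.
    """
    return n_per_round**n_rounds


@dataclass(frozen=True)
class ReadLayout:
    """Positions of the barcode blocks and linker within R2.

    The R2 prefix is ``cb3 + spacer1 + cb2 + spacer2 + cb1 + spacer3``
    followed by the linker region; the insert starts immediately after
    the linker.  The total prefix (through the longer, DNA, linker) must
    stay below the 150 bp read length so at least part of every insert
    is sequenced.
    """

    cell_bc_len: int = CELL_BC_LEN
    spacers: tuple[str, str, str] = DEFAULT_SPACERS
    gem_len: int = GEM_BC_LEN
    gem_umi_len: int = GEM_UMI_LEN
    i7_len: int = I7_LEN
    r2_len: int = 150

    def __post_init__(self) -> None:
        if self.dna_insert_offset >= self.r2_len:
            raise ValueError("R2 prefix does not fit in the read length")

    @property
    def linker_offset(self) -> int:
        """Offset of the shared linker prefix within R2."""
        return 3 * self.cell_bc_len + sum(len(s) for s in self.spacers)

    @property
    def rna_linker_len(self) -> int:
        return len(LINKER_SHARED) + len(RNA_LINKER_TAG) + LINKER_UMI_LEN + len(RNA_LINKER_SUFFIX)

    @property
    def dna_linker_len(self) -> int:
        return len(LINKER_SHARED) + LINKER_UMI_LEN + len(DNA_LINKER_SUFFIX)

    @property
    def rna_insert_offset(self) -> int:
        return self.linker_offset + self.rna_linker_len

    @property
    def dna_insert_offset(self) -> int:
        return self.linker_offset + self.dna_linker_len

    def insert_budget(self, modality: str) -> int:
        """Maximum number of insert bases visible in a 150 bp R2."""
        off = self.rna_insert_offset if modality == "RNA" else self.dna_insert_offset
        return self.r2_len - off

    def barcode_slices(self) -> tuple[slice, slice, slice]:
        """R2 slices of (cb3, cb2, cb1), in read order."""
        pos = 0
        out = []
        for sp in self.spacers:
            out.append(slice(pos, pos + self.cell_bc_len))
            pos += self.cell_bc_len + len(sp)
        return tuple(out)

    def rna_linker(self, umi: str) -> str:
        return LINKER_SHARED + RNA_LINKER_TAG + umi + RNA_LINKER_SUFFIX

    def dna_linker(self, umi: str) -> str:
        return LINKER_SHARED + umi + DNA_LINKER_SUFFIX


def _random_whitelist(
    rng: np.random.Generator, n: int, length: int, min_dist: int = 3
) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= ``min_dist``."""
    bases = np.array(list("ACGT"))
    out: list[str] = []
    while len(out) < n:
        cand = "".join(bases[rng.integers(0, 4, size=length)])
        if all(hamming(cand, x) >= min_dist for x in out):
            out.append(cand)
    return out


@dataclass
class BarcodeTables:
    """Whitelists for the five barcode lookups.

    ``cell`` holds the three 96-entry cell-barcode sets (indexed 0..2 for
    rounds 1..3); entries within every whitelist are pairwise Hamming
    distance >= 3 apart, so a single substitution is always uniquely
    correctable.  Barcode ids are 1-based, matching well positions.
    """

    cell: tuple[list[str], list[str], list[str]]
    gem: list[str]
    i7: list[str]
    _lookups: list[dict[str, int]] = field(default_factory=list, repr=False)

    @classmethod
    def generate(cls, seed: int = 0, n_gem: int = 1024) -> "BarcodeTables":
        rng = np.random.default_rng(seed)
        cell = tuple(_random_whitelist(rng, 96, CELL_BC_LEN) for _ in range(3))
        gem = _random_whitelist(rng, n_gem, GEM_BC_LEN)
        i7 = _random_whitelist(rng, 8, I7_LEN)
        return cls(cell=cell, gem=gem, i7=i7)

    def exact_lookup(self, which: str) -> dict[str, int]:
        """Map sequence -> 1-based id for one whitelist.

        ``which`` is one of ``cb1``, ``cb2``, ``cb3``, ``gem``, ``i7``.
        """
        table = self._table(which)
        return {seq: i + 1 for i, seq in enumerate(table)}

    def _table(self, which: str) -> list[str]:
        if which.startswith("cb"):
            return self.cell[int(which[2]) - 1]
        return getattr(self, which)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("whitelist\tid\tsequence\n")
            for name in ("cb1", "cb2", "cb3", "gem", "i7"):
                for i, seq in enumerate(self._table(name), start=1):
                    fh.write(f"{name}\t{i}\t{seq}\n")

    @classmethod
    def from_tsv(cls, path) -> "BarcodeTables":
        tables: dict[str, list[str]] = {k: [] for k in ("cb1", "cb2", "cb3", "gem", "i7")}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("whitelist"):
                raise ValueError("missing whitelist header")
            for line in fh:
                name, _i, seq = line.rstrip("\n").split("\t")
                tables[name].append(seq)
        return cls(
            cell=(tables["cb1"], tables["cb2"], tables["cb3"]),
            gem=tables["gem"],
            i7=tables["i7"],
        )

    def validate(self) -> None:
        """Check whitelist invariants (no duplicates, min distance 3)."""
        for name in ("cb1", "cb2", "cb3", "i7"):
            table = self._table(name)
            if len(set(table)) != len(table):
                raise ValueError(f"duplicate entries in {name}")
            for a, b in itertools.combinations(table, 2):
                if hamming(a, b) < 3:
                    raise ValueError(f"{name} entries closer than Hamming 3")
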
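"""Ground-truth nuclei, molecular complexes and molecules.

The generator draws a population of cells, gives every cell a set of
crosslinked molecular complexes, and populates each complex with DNA
fragments and/or RNA molecules.  Cluster sizes follow a configured
mixture law (a singleton fraction; among non-singletons, size 2 with
probability ``p2`` and a truncated power law for sizes >= 3, matching
the observed predominance of pairwise complexes), and intra-complex
genomic distances follow a truncated power law with exponent ``alpha``.
PCR duplication is represented as extra read occurrences per molecule
with explicit duplicate-of links, so deduplication can be scored
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..layout import GEM_UMI_LEN, LINKER_UMI_LEN, hamming
from .reference import Gene, SyntheticReference

_BASES = np.array(list("ACGT"))


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def sample_truncated_powerlaw(
    rng: np.random.Generator, alpha: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Inverse-CDF sample from p(x) ~ x**(-alpha) on [lo, hi]."""
    u = rng.random(size)
    if abs(alpha - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    a = 1.0 - alpha
    return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)


@dataclass(frozen=True)
class SimConfig:
    """Generative law of the simulated experiment.

    ``p2`` is the probability that a non-singleton complex has exactly
    two members (default 0.7226, the observed pairwise fraction among
    non-singleton DNA-only clusters); larger sizes follow a power law
    with exponent ``size_gamma`` truncated at ``max_size``.
    Intra-complex distances are drawn from a power law with exponent
    ``distance_alpha`` on [``d_min``, ``d_max``]; XIST-bearing complexes
    use ``xist_distance_alpha`` (a heavier long-range tail when smaller).
    """

    n_cells: int = 50
    complexes_per_cell: float = 20.0
    singleton_frac: float = 0.25
    p2: float = 0.7226
    size_gamma: float = 2.5
    max_size: int = 15
    rna_only_frac: float = 0.03
    rna_dna_frac: float = 0.12
    distance_alpha: float = 1.2
    d_min: float = 1_000.0
    d_max: float = 80_000.0
    xist_rate: float = 0.0           # mean XIST complexes per female cell
    xist_distance_alpha: float = 0.8
    duplicate_rate: float = 0.0      # mean extra PCR copies per molecule
    frag_len: tuple[int, int] = (24, 50)
    n_gem: int = 1024                # size of the GEM whitelist drawn from
    n_samples: int = 4
    age_range: tuple[float, float] = (60.0, 90.0)

    def validate(self) -> None:
        for name in ("singleton_frac", "p2", "rna_only_frac", "rna_dna_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rna_only_frac + self.rna_dna_frac > 1.0:
            raise ValueError("rna_only_frac + rna_dna_frac > 1")
        if self.duplicate_rate < 0 or self.xist_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class Cell:
    cell_id: str
    species: str
    sex: str
    cell_type: str
    sample: str
    age: float
    ageing_level: float
    cb: tuple[int, int, int]  # 1-based whitelist ids (cb1, cb2, cb3)


@dataclass
class Complex:
    complex_id: str
    cell_id: str
    gem_id: int    # 1-based index into the GEM whitelist
    i7_id: int     # 1-based index into the I7 whitelist
    dna: list[tuple[str, int, int, str]] = field(default_factory=list)
    rna: list[tuple[str, int, int, str, str]] = field(default_factory=list)  # +gene_id
    has_xist: bool = False

    @property
    def size(self) -> int:
        return len(self.dna) + len(self.rna)


@dataclass
class Molecule:
    molecule_id: str
    complex_id: str
    cell_id: str
    modality: str  # "DNA" | "RNA"
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str | None
    gem_umi: str
    linker_umi: str


@dataclass
class ReadOccurrence:
    read_id: str
    molecule_id: str
    duplicate_of: str | None  # read_id of the original occurrence


@dataclass
class GroundTruth:
    reference: SyntheticReference
    config: SimConfig
    cells: list[Cell]
    complexes: list[Complex]
    molecules: list[Molecule]
    reads: list[ReadOccurrence]

    @property
    def n_duplicates(self) -> int:
        return sum(1 for r in self.reads if r.duplicate_of is not None)

    def molecule_by_id(self) -> dict[str, Molecule]:
        return {m.molecule_id: m for m in self.molecules}

    def complex_by_id(self) -> dict[str, Complex]:
        return {c.complex_id: c for c in self.complexes}

    def write_tsv(self, outdir) -> None:
        """Write cells.tsv, complexes.tsv and reads.tsv truth tables."""
        import os

        with open(os.path.join(outdir, "cells.tsv"), "w") as fh:
            fh.write("cell_id\tspecies\tsex\tcell_type\tsample\tage\tageing_level\tcb1\tcb2\tcb3\n")
            for c in self.cells:
                fh.write(
                    f"{c.cell_id}\t{c.species}\t{c.sex}\t{c.cell_type}\t{c.sample}\t"
                    f"{c.age}\t{c.ageing_level:.4f}\t{c.cb[0]}\t{c.cb[1]}\t{c.cb[2]}\n"
                )
        with open(os.path.join(outdir, "complexes.tsv"), "w") as fh:
            fh.write("complex_id\tcell_id\tgem_id\ti7_id\tn_dna\tn_rna\thas_xist\n")
            for x in self.complexes:
                fh.write(
                    f"{x.complex_id}\t{x.cell_id}\t{x.gem_id}\t{x.i7_id}\t"
                    f"{len(x.dna)}\t{len(x.rna)}\t{int(x.has_xist)}\n"
                )
        with open(os.path.join(outdir, "reads.tsv"), "w") as fh:
            fh.write("read_id\tmolecule_id\tcomplex_id\tcell_id\tmodality\tchrom\tstart\tstrand\tduplicate_of\n")
            mol = self.molecule_by_id()
            for r in self.reads:
                m = mol[r.molecule_id]
                fh.write(
                    f"{r.read_id}\t{m.molecule_id}\t{m.complex_id}\t{m.cell_id}\t"
                    f"{m.modality}\t{m.chrom}\t{m.start}\t{m.strand}\t"
                    f"{r.duplicate_of or '.'}\n"
                )


def _draw_size(rng: np.random.Generator, cfg: SimConfig) -> int:
    if rng.random() < cfg.singleton_frac:
        return 1
    if rng.random() < cfg.p2:
        return 2
    sizes = np.arange(3, cfg.max_size + 1)
    p = sizes.astype(float) ** (-cfg.size_gamma)
    return int(rng.choice(sizes, p=p / p.sum()))


def _place_fragments(
    rng: np.random.Generator,
    cfg: SimConfig,
    chrom: str,
    chrom_len: int,
    n: int,
    alpha: float,
    spread_full: bool = False,
) -> list[tuple[str, int, int, str]]:
    """Anchor one fragment uniformly; place the rest at power-law distances.

    ``spread_full`` scatters fragments uniformly over the chromosome
    instead (used for XIST complexes, which coat the whole chromosome).
    """
    lens = rng.integers(cfg.frag_len[0], cfg.frag_len[1] + 1, size=n)
    out = []
    anchor = int(rng.integers(0, chrom_len - int(lens[0])))
    for i in range(n):
        flen = int(lens[i])
        if i == 0:
            pos = anchor
        elif spread_full:
            pos = int(rng.integers(0, chrom_len - flen))
        else:
            d = float(sample_truncated_powerlaw(rng, alpha, cfg.d_min, cfg.d_max, 1)[0])
            pos = int(np.clip(anchor + (1 if rng.random() < 0.5 else -1) * d, 0, chrom_len - flen))
        out.append((chrom, pos, pos + flen, "+" if rng.random() < 0.5 else "-"))
    return out


def _rna_molecule(
    rng: np.random.Generator, cfg: SimConfig, gene: Gene
) -> tuple[str, int, int, str, str]:
    rlen = int(rng.integers(cfg.frag_len[0], cfg.frag_len[1] + 1))
    rlen = min(rlen, gene.end - gene.start)
    start = int(rng.integers(gene.start, gene.end - rlen + 1))
    return (gene.chrom, start, start + rlen, gene.strand, gene.gene_id)


def simulate_ground_truth(
    ref: SyntheticReference, config: SimConfig, seed: int
) -> GroundTruth:
    """Draw cells, complexes, molecules and read occurrences."""
    config.validate()
    rng = np.random.default_rng(seed)

    # -- cells ---------------------------------------------------------
    n96 = 96
    combo_ids = rng.choice(n96**3, size=config.n_cells, replace=False)
    species_ids = list(ref.sex_of)
    sample_ages = np.sort(rng.uniform(*config.age_range, size=config.n_samples))
    cells: list[Cell] = []
    for i in range(config.n_cells):
        c = int(combo_ids[i])
        cb = (c // (n96 * n96) + 1, (c // n96) % n96 + 1, c % n96 + 1)
        sp = species_ids[i % len(species_ids)]
        samp = i % config.n_samples
        age = float(sample_ages[samp])
        lo, hi = config.age_range
        ageing = float(np.clip((age - lo) / (hi - lo) + rng.normal(0, 0.1), 0, 1))
        cells.append(
            Cell(
                cell_id=f"cell{i:04d}",
                species=sp,
                sex=ref.sex_of[sp],
                cell_type=ref.cell_types[i % len(ref.cell_types)],
                sample=f"sample{samp}",
                age=age,
                ageing_level=ageing,
                cb=cb,
            )
        )

    # -- complexes -----------------------------------------------------
    complexes: list[Complex] = []
    n_gem = config.n_gem
    cid = 0
    for cell in cells:
        chroms = ref.chrom_names(cell.species)
        genes_by_chrom = {c: ref.genes_on(c) for c in chroms}
        n_cplx = max(1, int(rng.poisson(config.complexes_per_cell)))
        n_xist = 0
        chrx = ref.chrx(cell.species)
        if cell.sex == "female" and config.xist_rate > 0 and chrx is not None:
            n_xist = int(rng.poisson(config.xist_rate))
        used: set[tuple[int, int]] = set()

        def fresh_barcode() -> tuple[int, int]:
            while True:
                key = (int(rng.integers(1, n_gem + 1)), int(rng.integers(1, 9)))
                if key not in used:
                    used.add(key)
                    return key

        for j in range(n_cplx + n_xist):
            cid += 1
            gem_id, i7_id = fresh_barcode()
            cplx = Complex(
                complex_id=f"cplx{cid:06d}", cell_id=cell.cell_id,
                gem_id=gem_id, i7_id=i7_id,
            )
            if j >= n_cplx:  # XIST complex: 1 XIST RNA + chrX DNA, full spread
                xist = next(g for g in ref.xist_genes if g.species == cell.species)
                cplx.rna.append(_rna_molecule(rng, config, xist))
                n_dna = max(1, _draw_size(rng, config) - 1)
                cplx.dna.extend(
                    _place_fragments(
                        rng, config, chrx, len(ref.sequences[chrx]), n_dna,
                        config.xist_distance_alpha, spread_full=True,
                    )
                )
                cplx.has_xist = True
            else:
                size = _draw_size(rng, config)
                u = rng.random()
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                if u < config.rna_only_frac:
                    pool = genes_by_chrom[chrom] or ref.genes
                    for _ in range(size):
                        g = pool[int(rng.integers(0, len(pool)))]
                        cplx.rna.append(_rna_molecule(rng, config, g))
                elif u < config.rna_only_frac + config.rna_dna_frac and size >= 2:
                    m = 1 + int(rng.binomial(size - 2, 0.3)) if size > 2 else 1
                    pool = genes_by_chrom[chrom] or ref.genes
                    for _ in range(m):
                        g = pool[int(rng.integers(0, len(pool)))]
                        cplx.rna.append(_rna_molecule(rng, config, g))
                    cplx.dna.extend(
                        _place_fragments(
                            rng, config, chrom, len(ref.sequences[chrom]),
                            size - m, config.distance_alpha,
                        )
                    )
                else:
                    cplx.dna.extend(
                        _place_fragments(
                            rng, config, chrom, len(ref.sequences[chrom]),
                            size, config.distance_alpha,
                        )
                    )
            complexes.append(cplx)

    # -- molecules with UMIs -------------------------------------------
    molecules: list[Molecule] = []
    mid = 0
    for cplx in complexes:
        umis: list[str] = []

        def fresh_umi() -> str:
            # within a complex, keep GEM UMIs >= Hamming 3 apart so one
            # sequencing error can never alias two molecules
            while True:
                u = _rand_seq(rng, GEM_UMI_LEN)
                if all(hamming(u, v) >= 3 for v in umis):
                    umis.append(u)
                    return u

        for chrom, s, e, strand in cplx.dna:
            mid += 1
            molecules.append(
                Molecule(
                    molecule_id=f"mol{mid:07d}", complex_id=cplx.complex_id,
                    cell_id=cplx.cell_id, modality="DNA", chrom=chrom,
                    start=s, end=e, strand=strand, gene_id=None,
                    gem_umi=fresh_umi(), linker_umi=_rand_seq(rng, LINKER_UMI_LEN),
                )
            )
        for chrom, s, e, strand, gene_id in cplx.rna:
            mid += 1
            molecules.append(
                Molecule(
                    molecule_id=f"mol{mid:07d}", complex_id=cplx.complex_id,
                    cell_id=cplx.cell_id, modality="RNA", chrom=chrom,
                    start=s, end=e, strand=strand, gene_id=gene_id,
                    gem_umi=fresh_umi(), linker_umi=_rand_seq(rng, LINKER_UMI_LEN),
                )
            )

    # -- read occurrences with PCR duplicates --------------------------
    reads: list[ReadOccurrence] = []
    rid = 0
    for m in molecules:
        rid += 1
        first = f"read{rid:08d}"
        reads.append(ReadOccurrence(first, m.molecule_id, None))
        for _ in range(int(rng.poisson(config.duplicate_rate))):
            rid += 1
            reads.append(ReadOccurrence(f"read{rid:08d}", m.molecule_id, first))

    return GroundTruth(
        reference=ref, config=config, cells=cells,
        complexes=complexes, molecules=molecules, reads=reads,
    )


def with_duplicates(gt: GroundTruth, duplicate_rate: float, seed: int) -> GroundTruth:
    """Re-draw PCR duplication on an existing ground truth."""
    rng = np.random.default_rng(seed)
    reads: list[ReadOccurrence] = []
    rid = 0
    for m in gt.molecules:
        rid += 1
        first = f"read{rid:08d}"
        reads.append(ReadOccurrence(first, m.molecule_id, None))
        for _ in range(int(rng.poisson(duplicate_rate))):
            rid += 1
            reads.append(ReadOccurrence(f"read{rid:08d}", m.molecule_id, first))
    return GroundTruth(
        reference=gt.reference, config=replace(gt.config, duplicate_rate=duplicate_rate),
        cells=gt.cells, complexes=gt.complexes, molecules=gt.molecules, reads=reads,
    )
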
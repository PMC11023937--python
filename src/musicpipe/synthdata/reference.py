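"""Synthetic reference genomes and gene annotation.

A :class:`SyntheticReference` stands in for a real genome build plus its
annotation: a handful of short chromosomes per species (each with a
declared arm boundary), genes with exon/intron structure and strand, and
the special loci the downstream analytics care about — one XIST-like
lncRNA on the female chrX, marker genes per simulated cell type, and
ageing genes with a direction label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length: int
    n_genes: int = 4
    is_x: bool = False


@dataclass(frozen=True)
class SpeciesSpec:
    species_id: str
    sex: str = "female"  # controls whether chrX carries an XIST-like gene
    chromosomes: tuple[ChromSpec, ...] = ()


@dataclass(frozen=True)
class ReferenceConfig:
    species: tuple[SpeciesSpec, ...]
    gene_len_range: tuple[int, int] = (2_000, 6_000)
    exons_per_gene: tuple[int, int] = (2, 4)
    n_cell_types: int = 3
    markers_per_type: int = 4
    n_ageing_genes: int = 10


@dataclass
class Gene:
    gene_id: str
    name: str
    species: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    strand: str
    biotype: str = "protein_coding"
    exons: list[tuple[int, int]] = field(default_factory=list)
    xist_like: bool = False
    marker_of: str | None = None    # cell-type label, if a marker gene
    ageing_direction: int = 0       # +1 / -1 for ageing genes, else 0

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (0-based)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class SyntheticReference:
    """Genome sequences plus annotation for one or more species.

    Chromosome names are prefixed with the species id (``hs_chr1``) so a
    mixed-species run maps into one joint reference, as a barnyard
    experiment does.
    """

    sequences: dict[str, str]                 # chrom -> sequence
    species_of: dict[str, str]                # chrom -> species id
    arm_boundary: dict[str, int]              # chrom -> centromere position
    genes: list[Gene]
    cell_types: list[str]
    sex_of: dict[str, str]                    # species -> sex

    def chrom_names(self, species: str | None = None) -> list[str]:
        if species is None:
            return list(self.sequences)
        return [c for c in self.sequences if self.species_of[c] == species]

    def chrx(self, species: str) -> str | None:
        for c in self.chrom_names(species):
            if c.endswith("chrX"):
                return c
        return None

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    @property
    def xist_genes(self) -> list[Gene]:
        return [g for g in self.genes if g.xist_like]

    def marker_table(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {t: [] for t in self.cell_types}
        for g in self.genes:
            if g.marker_of:
                out[g.marker_of].append(g.name)
        return out

    def ageing_table(self) -> dict[str, int]:
        return {g.name: g.ageing_direction for g in self.genes if g.ageing_direction}

    # ------------------------------------------------------------------ IO
    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name} species={self.species_of[name]}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_gtf(self, path) -> None:
        """Emit the annotation as GTF (1-based, closed intervals)."""
        with open(path, "w") as fh:
            for g in self.genes:
                attrs = (
                    f'gene_id "{g.gene_id}"; gene_name "{g.name}"; '
                    f'gene_biotype "{g.biotype}";'
                )
                if g.xist_like:
                    attrs += ' xist_like "true";'
                if g.marker_of:
                    attrs += f' marker_of "{g.marker_of}";'
                if g.ageing_direction:
                    attrs += f' ageing_direction "{g.ageing_direction:+d}";'
                fh.write(
                    f"{g.chrom}\tsynth\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f'{attrs} exon_number "{i}";\n'
                    )


def _random_gene_structure(
    rng: np.random.Generator, start: int, end: int, n_exons: int
) -> list[tuple[int, int]]:
    """Split [start, end) into alternating exons/introns (exon first/last)."""
    n_parts = 2 * n_exons - 1
    cuts = np.sort(rng.choice(np.arange(start + 1, end), size=n_parts - 1, replace=False))
    bounds = [start, *cuts.tolist(), end]
    return [(bounds[i], bounds[i + 1]) for i in range(0, n_parts, 2)]


def make_reference(config: ReferenceConfig, seed: int) -> SyntheticReference:
    """Build a deterministic synthetic reference from a configuration.

    Raises ``ValueError`` if any chromosome is too short for the largest
    requested gene.
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.gene_len_range
    sequences: dict[str, str] = {}
    species_of: dict[str, str] = {}
    arm_boundary: dict[str, int] = {}
    genes: list[Gene] = []
    cell_types = [f"type{chr(ord('A') + i)}" for i in range(config.n_cell_types)]
    sex_of = {}

    gid = 0
    for sp in config.species:
        sex_of[sp.species_id] = sp.sex
        for chrom in sp.chromosomes:
            if chrom.length <= hi:
                raise ValueError(
                    f"chromosome {chrom.name} ({chrom.length} bp) shorter than "
                    f"the largest requested gene ({hi} bp)"
                )
            full = f"{sp.species_id}_{chrom.name}"
            seq = "".join(_BASES[rng.integers(0, 4, size=chrom.length)])
            sequences[full] = seq
            species_of[full] = sp.species_id
            # arm boundary near (not at) the middle, like a real centromere
            arm_boundary[full] = int(chrom.length * rng.uniform(0.4, 0.6))

            # non-overlapping gene placement on a regular grid with jitter
            slots = np.linspace(0, chrom.length - hi - 1, max(chrom.n_genes, 1))
            for j in range(chrom.n_genes):
                glen = int(rng.integers(lo, hi + 1))
                gstart = int(slots[j]) + int(rng.integers(0, max(hi - glen, 1)))
                gend = gstart + glen
                n_ex = int(rng.integers(*config.exons_per_gene, endpoint=True))
                gid += 1
                genes.append(
                    Gene(
                        gene_id=f"G{gid:05d}",
                        name=f"{sp.species_id.upper()}GENE{gid}",
                        species=sp.species_id,
                        chrom=full,
                        start=gstart,
                        end=gend,
                        strand="+" if rng.random() < 0.5 else "-",
                        exons=_random_gene_structure(rng, gstart, gend, n_ex),
                    )
                )
            if chrom.is_x and sp.sex == "female":
                g = genes[-chrom.n_genes]  # first gene on this chrX
                g.xist_like = True
                g.biotype = "lncRNA"
                g.name = f"{sp.species_id.upper()}_XIST"

    # assign marker and ageing roles among protein-coding, non-chrX genes
    pool = [g for g in genes if g.biotype == "protein_coding" and not g.xist_like]
    rng.shuffle(pool)
    need = config.n_cell_types * config.markers_per_type + config.n_ageing_genes
    if len(pool) < need:
        raise ValueError(f"not enough genes ({len(pool)}) for {need} special roles")
    k = 0
    for t in cell_types:
        for _ in range(config.markers_per_type):
            pool[k].marker_of = t
            k += 1
    for _ in range(config.n_ageing_genes):
        pool[k].ageing_direction = 1 if rng.random() < 0.5 else -1
        k += 1

    return SyntheticReference(
        sequences=sequences,
        species_of=species_of,
        arm_boundary=arm_boundary,
        genes=genes,
        cell_types=cell_types,
        sex_of=sex_of,
    )


def default_config(
    species: str = "hs", n_chroms: int = 2, chrom_len: int = 120_000, sex: str = "female"
) -> ReferenceConfig:
    """Small single-species reference with autosomes plus a chrX."""
    chroms = [ChromSpec(f"chr{i + 1}", chrom_len, n_genes=10) for i in range(n_chroms)]
    chroms.append(ChromSpec("chrX", chrom_len, n_genes=10, is_x=True))
    return ReferenceConfig(
        species=(SpeciesSpec(species_id=species, sex=sex, chromosomes=tuple(chroms)),)
    )
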
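"""Synthetic data with the statistical structure the pooled scan assumes.

Generates reference genomes, gene models, EMS-style variants (C->T / G->A
biased, one causal missense SNP in a protein-motif context), F2 cohorts
under two crossing designs, phenotype-selected pools and pooled read
counts.

The primary design is the selfed-heterozygote one: a plant heterozygous at
the causal locus and at every background EMS SNP (all mutant alleles in
coupling phase, as expected when they derive from one mutagenised genome)
is selfed, and the two sequencing pools are built from the extreme
phenotype classes of its progeny. A separate biparental cross (two
homozygous parents with opposite alleles) feeds recombinant fine mapping.

Recombination follows Haldane's model: crossover counts per gamete are
Poisson with mean equal to the chromosome's genetic length in Morgans, and
crossover positions are uniform, so the recombination fraction between two
loci at distance d Morgans is r = (1 - exp(-2d)) / 2 with no interference.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .exceptions import ConfigurationError, GenerationError
from .fine_mapping import Marker, MarkerMap
from .io_formats import (
    GeneModel,
    GenomeSequenceSet,
    VariantSite,
    write_fasta,
    write_gff3,
    write_pooled_vcf,
)
from .variant_annotation import genomic_position, translate_gene

MODES = ("semi-dominant", "dominant", "recessive")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in _STANDARD_TABLE.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
_STOP_CODONS = list(_STANDARD_TABLE.stop_codons)
_AMINO_ACIDS = sorted(_CODONS_BY_AA)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_EMS_PARTNER = {"C": "T", "G": "A"}


# ---------------------------------------------------------------------------
# configuration and cohort container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults mirror the pooled design the scan targets: two pools of 20
    extreme-phenotype plants from a selfed-heterozygote population, mean
    pooled depth 38x, a semi-dominant single-locus trait, EMS-biased
    background SNPs and a 4 cM/Mb genetic map.
    """

    chromosomes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000}
    )
    n_snps: int = 2000
    n_genes: int = 60
    motif: str = "GWPPV"
    mode: str = "semi-dominant"
    ems_bias: float = 0.98
    cohort_size: int = 200
    pool_size: int = 20
    depth: float = 38.0
    error_rate: float = 0.005
    cm_per_mb: float = 4.0
    finemap_size: int = 185
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ConfigurationError("at least one chromosome is required")
        if any(length <= 0 for length in self.chromosomes.values()):
            raise ConfigurationError("chromosome lengths must be positive")
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown inheritance mode {self.mode!r}")
        if self.depth <= 0:
            raise ConfigurationError("depth must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ConfigurationError("error rate must be in [0, 0.5)")
        if not 0 <= self.ems_bias <= 1:
            raise ConfigurationError("ems_bias must be in [0, 1]")
        if self.pool_size <= 0 or self.pool_size * 2 > self.cohort_size:
            raise ConfigurationError(
                "pool_size must be positive and 2*pool_size <= cohort_size"
            )
        if self.cm_per_mb <= 0:
            raise ConfigurationError("cm_per_mb must be positive")
        object.__setattr__(self, "chromosomes", dict(self.chromosomes))

    def morgans(self, chrom: str) -> float:
        """Genetic length of a chromosome in Morgans."""
        return self.chromosomes[chrom] / 1e6 * self.cm_per_mb / 100.0


@dataclass(frozen=True)
class VariantTemplate:
    """A planted SNP: genomic plus-strand ref/alt and whether it is causal."""

    chrom: str
    pos: int
    ref: str
    alt: str
    causal: bool = False


@dataclass
class F2Cohort:
    """Simulated F2 individuals with per-locus genotypes and phenotypes.

    Genotypes are stored as integers counting mutant alleles (0 = A,
    1 = H, 2 = B); :meth:`genotype_codes` returns the letter codes.
    """

    loci: dict[str, np.ndarray]
    genotypes: dict[str, np.ndarray]
    phenotypes: np.ndarray
    causal: tuple[str, int]
    mode: str

    _CODES = np.array(["A", "H", "B"])

    @property
    def n(self) -> int:
        return int(self.phenotypes.size)

    def causal_index(self) -> tuple[str, int]:
        chrom, pos = self.causal
        idx = int(np.searchsorted(self.loci[chrom], pos))
        if idx >= self.loci[chrom].size or self.loci[chrom][idx] != pos:
            raise ConfigurationError("causal position is not among the loci")
        return chrom, idx

    def causal_genotypes(self) -> np.ndarray:
        chrom, idx = self.causal_index()
        return self.genotypes[chrom][:, idx]

    def genotype_codes(self, chrom: str) -> np.ndarray:
        return self._CODES[self.genotypes[chrom]]

    def phenotype_counts(self) -> dict[str, int]:
        values, counts = np.unique(self.phenotypes, return_counts=True)
        return {str(v): int(c) for v, c in zip(values, counts)}


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------


def _random_chromosome(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(_BASE_BYTES[rng.integers(0, 4, size=length)].tobytes())


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in protein]
    codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def simulate_reference_and_genes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequenceSet, list[GeneModel]]:
    """Random genome plus non-overlapping gene models (2-6 CDS segments).

    Every gene encodes a clean ORF (ATG start, no internal stop, stop codon
    last); exactly one gene's translation contains ``config.motif``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chrom_arrays = {
        chrom: _random_chromosome(rng, length)
        for chrom, length in config.chromosomes.items()
    }
    chrom_names = list(config.chromosomes)
    chrom_lengths = np.array([config.chromosomes[c] for c in chrom_names], dtype=float)
    chrom_weights = chrom_lengths / chrom_lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    motif_gene_index = int(rng.integers(config.n_genes))
    raw_genes = []
    for gi in range(config.n_genes):
        n_codons = int(rng.integers(100, 401))
        n_aa = n_codons - 1  # last codon is the stop
        cds_len = 3 * n_codons
        n_seg = int(rng.integers(2, 7))
        seg_lens = rng.multinomial(cds_len - 10 * n_seg, [1.0 / n_seg] * n_seg) + 10
        introns = rng.integers(80, 801, size=n_seg - 1)
        extent = cds_len + int(introns.sum())
        for _ in range(200):
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_weights)]
            limit = config.chromosomes[chrom] - extent
            if limit < 1:
                continue
            start = int(rng.integers(1, limit + 1))
            end = start + extent - 1
            if all(e < start - 1 or s > end + 1 for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                break
        else:
            raise GenerationError(
                f"could not place gene {gi} (extent {extent} bp); genome too crowded"
            )
        segments = []
        cursor = start
        for k, seg_len in enumerate(seg_lens):
            segments.append((cursor, cursor + int(seg_len) - 1))
            cursor += int(seg_len)
            if k < n_seg - 1:
                cursor += int(introns[k])
        strand = "+" if rng.random() < 0.5 else "-"
        protein = "M" + "".join(
            np.asarray(_AMINO_ACIDS)[rng.integers(len(_AMINO_ACIDS), size=n_aa - 1)]
        )
        if gi == motif_gene_index:
            if len(config.motif) > n_aa - 4:
                raise GenerationError(
                    f"motif {config.motif!r} does not fit in a {n_aa}-residue protein"
                )
            ins = int(rng.integers(2, n_aa - len(config.motif)))
            protein = (
                protein[:ins] + config.motif + protein[ins + len(config.motif) :]
            )
        nt = _back_translate(protein, rng)
        genomic = nt if strand == "+" else _revcomp(nt)
        arr = chrom_arrays[chrom]
        offset = 0
        for a, b in segments:
            chunk = genomic[offset : offset + (b - a + 1)]
            arr[a - 1 : b] = chunk.encode()
            offset += b - a + 1
        raw_genes.append((chrom, strand, tuple(segments)))
    raw_genes.sort(key=lambda g: (g[0], g[2][0][0]))
    genes = [
        GeneModel(
            gene_id=f"g{i + 1:03d}",
            chrom=chrom,
            strand=strand,
            cds_segments=segments,
            protein_id=f"g{i + 1:03d}.t1",
        )
        for i, (chrom, strand, segments) in enumerate(raw_genes)
    ]
    genome = GenomeSequenceSet(
        {c: chrom_arrays[c].decode() for c in chrom_names}
    )
    if find_motif_gene(genes, genome, config.motif) is None:
        raise GenerationError(f"motif {config.motif!r} absent from every gene")
    return genome, genes


def find_motif_gene(
    genes: Sequence[GeneModel], genome: GenomeSequenceSet, motif: str
) -> tuple[GeneModel, int] | None:
    """First gene whose translation contains ``motif``; returns
    ``(gene, 0-based residue index of the occurrence)``."""
    for gene in genes:
        if not gene.translatable:
            continue
        protein = translate_gene(gene, genome)
        idx = protein.find(motif)
        if idx >= 0:
            return gene, idx
    return None


# ---------------------------------------------------------------------------
# EMS variants
# ---------------------------------------------------------------------------


def simulate_ems_variants(
    config: SimulationConfig,
    genome: GenomeSequenceSet,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> list[VariantTemplate]:
    """Background EMS SNPs plus exactly one causal motif-disrupting SNP.

    Background SNPs are C->T or G->A transitions with probability
    ``config.ems_bias`` (the alternative branch draws a non-transition
    change, so the realised transition fraction is exactly the bias in
    expectation). The causal SNP is a coding-strand C->T at the second base
    of a proline codon (CCx -> CTx, Pro->Leu) inside the motif-bearing gene
    — at the motif's first proline when the motif contains one.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    found = find_motif_gene(genes, genome, config.motif)
    if found is None:
        raise GenerationError(f"no gene carries motif {config.motif!r}")
    gene, motif_idx = found
    protein = translate_gene(gene, genome)
    if "P" in config.motif:
        residue_idx = motif_idx + config.motif.index("P")
    else:
        residue_idx = protein.find("P")
        if residue_idx < 0:
            raise GenerationError(
                f"no proline codon available in motif gene {gene.gene_id}"
            )
    causal_offset = residue_idx * 3 + 1  # second base of the proline codon
    causal_pos = genomic_position(gene, causal_offset)
    ref = genome.base(gene.chrom, causal_pos)
    if ref not in ("C", "G"):
        raise GenerationError("proline codon second base is not C/G; generator bug")
    causal = VariantTemplate(
        chrom=gene.chrom, pos=causal_pos, ref=ref, alt=_EMS_PARTNER[ref], causal=True
    )

    chrom_names = list(config.chromosomes)
    lengths = np.array([config.chromosomes[c] for c in chrom_names], dtype=float)
    weights = lengths / lengths.sum()
    seqs = {c: np.frombuffer(genome[c].encode(), dtype=np.uint8) for c in chrom_names}
    taken = {(causal.chrom, causal.pos)}
    templates = [causal]
    for _ in range(config.n_snps):
        transition = rng.random() < config.ems_bias
        for _attempt in range(10_000):
            chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
            pos = int(rng.integers(1, config.chromosomes[chrom] + 1))
            if (chrom, pos) in taken:
                continue
            base = chr(seqs[chrom][pos - 1])
            if transition:
                if base not in _EMS_PARTNER:
                    continue
                alt = _EMS_PARTNER[base]
            else:
                # exclude the canonical transition partner so the realised
                # transition fraction equals the configured bias
                options = [b for b in "ACGT" if b != base and b != _EMS_PARTNER.get(base)]
                alt = options[rng.integers(len(options))]
            taken.add((chrom, pos))
            templates.append(VariantTemplate(chrom, pos, base, alt))
            break
        else:
            raise GenerationError("could not place a background SNP after 10000 tries")
    templates.sort(key=lambda t: (t.chrom, t.pos))
    return templates


# ---------------------------------------------------------------------------
# meiosis and cohorts
# ---------------------------------------------------------------------------


def simulate_gametes(
    rng: np.random.Generator,
    morgans: float,
    length_bp: int,
    positions_bp: np.ndarray,
    n_gametes: int,
) -> np.ndarray:
    """Gamete haplotypes at the given loci under Haldane's crossover model.

    Each gamete draws its crossover count from Poisson(``morgans``) with
    uniform crossover positions, and starts from a random parental phase.
    Returns an ``(n_gametes, n_loci)`` array of 0/1 parental-origin labels.
    """
    positions = np.asarray(positions_bp, dtype=float)
    out = np.empty((n_gametes, positions.size), dtype=np.int8)
    n_xovers = rng.poisson(morgans, size=n_gametes)
    phases = rng.integers(0, 2, size=n_gametes)
    for g in range(n_gametes):
        if n_xovers[g] == 0:
            out[g] = phases[g]
            continue
        cuts = np.sort(rng.uniform(0, length_bp, size=n_xovers[g]))
        below = np.searchsorted(cuts, positions)
        out[g] = (phases[g] + below) % 2
    return out


def phenotype_from_genotype(genotype, mode: str) -> str:
    """Phenotype class for a causal genotype under an inheritance mode.

    Genotype may be a letter code (A/H/B) or a mutant-allele count (0/1/2).
    Semi-dominant: A->WT, H->INT, B->MUT; dominant: {H,B}->MUT;
    recessive: only B->MUT.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown inheritance mode {mode!r}")
    code = {0: "A", 1: "H", 2: "B"}.get(genotype, genotype)
    if code not in ("A", "H", "B"):
        raise ConfigurationError(f"unknown genotype code {genotype!r}")
    if mode == "semi-dominant":
        return {"A": "WT", "H": "INT", "B": "MUT"}[code]
    if mode == "dominant":
        return "WT" if code == "A" else "MUT"
    return "MUT" if code == "B" else "WT"


def simulate_f2_cohort(
    config: SimulationConfig,
    loci: Mapping[str, np.ndarray],
    causal: tuple[str, int],
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> F2Cohort:
    """Self a plant heterozygous at every locus (mutant alleles in coupling).

    Each individual is the union of two independent gametes; the biparental
    F2 of two opposite homozygous parents produces the same genotype
    distribution, so this routine also backs the fine-mapping cross.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.cohort_size if n is None else n
    genotypes: dict[str, np.ndarray] = {}
    sorted_loci: dict[str, np.ndarray] = {}
    for chrom, positions in loci.items():
        positions = np.asarray(positions, dtype=np.int64)
        if np.any(np.diff(positions) < 0):
            raise ConfigurationError(f"{chrom}: loci must be sorted")
        sorted_loci[chrom] = positions
        morgans = config.morgans(chrom)
        length = config.chromosomes[chrom]
        g1 = simulate_gametes(rng, morgans, length, positions, n)
        g2 = simulate_gametes(rng, morgans, length, positions, n)
        genotypes[chrom] = (g1 + g2).astype(np.int8)
    cohort = F2Cohort(
        loci=sorted_loci,
        genotypes=genotypes,
        phenotypes=np.empty(n, dtype=object),
        causal=causal,
        mode=config.mode,
    )
    causal_geno = cohort.causal_genotypes()
    cohort.phenotypes = np.array(
        [phenotype_from_genotype(int(g), config.mode) for g in causal_geno],
        dtype=object,
    )
    return cohort


# ---------------------------------------------------------------------------
# pooling and pooled reads
# ---------------------------------------------------------------------------


def build_pools_and_reads(
    cohort: F2Cohort,
    variants: Sequence[VariantTemplate],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[VariantSite]:
    """Pooled read counts for phenotype-selected mutant and wild-type pools.

    ``pool_size`` individuals of class MUT and of class WT are drawn; at
    each variant the pool's alt-allele frequency f is the planted-allele
    count over ``2 * pool_size`` chromosomes, site depth is
    Poisson(``depth``) per pool, and reads land on bases with
    P(alt) = f(1-e) + (1-f)e/3, P(ref) = (1-f)(1-e) + f e/3 and e/3 for each
    other base. Zero-depth sites are emitted with zero counts (removed later
    by QC).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mut_idx = np.flatnonzero(cohort.phenotypes == "MUT")
    wt_idx = np.flatnonzero(cohort.phenotypes == "WT")
    if mut_idx.size < config.pool_size or wt_idx.size < config.pool_size:
        raise GenerationError(
            f"not enough individuals for pools of {config.pool_size}: "
            f"MUT={mut_idx.size}, WT={wt_idx.size}"
        )
    pools = {
        "mut": rng.choice(mut_idx, size=config.pool_size, replace=False),
        "wt": rng.choice(wt_idx, size=config.pool_size, replace=False),
    }
    col_index = {
        (chrom, int(pos)): i
        for chrom, positions in cohort.loci.items()
        for i, pos in enumerate(positions)
    }
    e = config.error_rate
    n_chroms = 2 * config.pool_size
    base_order = "ACGT"
    sites = []
    for var in variants:
        key = (var.chrom, var.pos)
        if key not in col_index:
            raise ConfigurationError(f"variant {key} has no locus in the cohort")
        col = col_index[key]
        counts = {}
        for pool in ("mut", "wt"):
            f = float(cohort.genotypes[var.chrom][pools[pool], col].sum()) / n_chroms
            depth = int(rng.poisson(config.depth))
            if depth == 0:
                counts[pool] = {b: 0 for b in base_order}
                continue
            probs = np.full(4, e / 3.0)
            probs[base_order.index(var.ref)] = (1 - f) * (1 - e) + f * e / 3.0
            probs[base_order.index(var.alt)] = f * (1 - e) + (1 - f) * e / 3.0
            draw = rng.multinomial(depth, probs)
            counts[pool] = {b: int(c) for b, c in zip(base_order, draw)}
        sites.append(
            VariantSite(
                chrom=var.chrom,
                pos=var.pos,
                ref=var.ref,
                alt=var.alt,
                mut_counts=counts["mut"],
                wt_counts=counts["wt"],
            )
        )
    return sites


# ---------------------------------------------------------------------------
# whole experiments
# ---------------------------------------------------------------------------


@dataclass
class MutmapDataset:
    """Everything one simulated pooled-mapping experiment produced."""

    config: SimulationConfig
    genome: GenomeSequenceSet
    genes: list[GeneModel]
    variants: list[VariantTemplate]
    causal: VariantTemplate
    causal_gene_id: str
    cohort: F2Cohort
    sites: list[VariantSite]


def simulate_mutmap_experiment(config: SimulationConfig) -> MutmapDataset:
    """Simulate the full selfed-heterozygote pooled experiment.

    Deterministic in ``config`` (including its seed). The cohort is
    re-simulated (up to ``config.max_retries`` times) if a phenotype class
    is too small to fill its pool.
    """
    ss = np.random.SeedSequence(config.seed)
    r_genome, r_var, r_cohort, r_reads = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    genome, genes = simulate_reference_and_genes(config, r_genome)
    variants = simulate_ems_variants(config, genome, genes, r_var)
    causal = next(v for v in variants if v.causal)
    gene, _ = find_motif_gene(genes, genome, config.motif)
    loci = {}
    for var in variants:
        loci.setdefault(var.chrom, []).append(var.pos)
    loci = {c: np.array(sorted(p), dtype=np.int64) for c, p in loci.items()}
    last_counts: dict[str, int] = {}
    for _ in range(config.max_retries):
        cohort = simulate_f2_cohort(
            config, loci, causal=(causal.chrom, causal.pos), rng=r_cohort
        )
        counts = cohort.phenotype_counts()
        if (
            counts.get("MUT", 0) >= config.pool_size
            and counts.get("WT", 0) >= config.pool_size
        ):
            break
        last_counts = counts
    else:
        raise GenerationError(
            f"phenotype classes too small for pools of {config.pool_size} after "
            f"{config.max_retries} tries: {last_counts}"
        )
    sites = build_pools_and_reads(cohort, variants, config, r_reads)
    return MutmapDataset(
        config=config,
        genome=genome,
        genes=genes,
        variants=variants,
        causal=causal,
        causal_gene_id=gene.gene_id,
        cohort=cohort,
        sites=sites,
    )


#: Default fine-mapping marker layout (offsets in bp from the first marker).
#: Thirteen markers over ~1.83 Mb — two outer anchors plus eleven interior
#: markers — with the causal locus inside a 91 kb gap between markers 7 and 8.
FINEMAP_MARKER_OFFSETS = (
    0,
    200_000,
    450_000,
    680_000,
    850_000,
    985_000,
    1_076_000,
    1_167_000,
    1_280_000,
    1_420_000,
    1_600_000,
    1_720_000,
    1_830_000,
)
FINEMAP_CAUSAL_OFFSET = 1_120_000


def simulate_finemap_cross(
    config: SimulationConfig,
    marker_positions: Sequence[int] | None = None,
    causal_pos: int | None = None,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MarkerMap, F2Cohort]:
    """Biparental F2 cross genotyped at ordered markers for fine mapping.

    Both parents are homozygous with opposite alleles; the F1 is
    heterozygous everywhere, so F2 genotypes come from the same gamete
    process as the selfed design. The causal position must lie strictly
    between two markers.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.finemap_size if n is None else n
    chrom = next(iter(config.chromosomes))
    length = config.chromosomes[chrom]
    if marker_positions is None:
        span = FINEMAP_MARKER_OFFSETS[-1]
        # shrink the default layout proportionally on short chromosomes
        scale = min(1.0, 0.6 * length / span)
        offsets = [int(off * scale) for off in FINEMAP_MARKER_OFFSETS]
        if len(set(offsets)) != len(offsets):
            raise ConfigurationError(
                f"chromosome {chrom} ({length} bp) too short for the marker layout"
            )
        anchor = (length - offsets[-1]) // 2
        marker_positions = [anchor + off for off in offsets]
        if causal_pos is None:
            causal_pos = anchor + int(FINEMAP_CAUSAL_OFFSET * scale)
    marker_positions = sorted(int(p) for p in marker_positions)
    if causal_pos is None:
        raise ConfigurationError("causal_pos is required with explicit markers")
    causal_pos = int(causal_pos)
    if not marker_positions[0] < causal_pos < marker_positions[-1]:
        raise ConfigurationError("causal position must lie inside the marker span")
    if causal_pos in marker_positions:
        raise ConfigurationError("causal position must lie strictly between markers")
    marker_map = MarkerMap(
        tuple(
            Marker(id=f"mk{i + 1:02d}", chrom=chrom, pos=pos)
            for i, pos in enumerate(marker_positions)
        )
    )
    loci = {chrom: np.array(sorted([*marker_positions, causal_pos]), dtype=np.int64)}
    cohort = simulate_f2_cohort(config, loci, causal=(chrom, causal_pos), n=n, rng=rng)
    return marker_map, cohort


def marker_genotype_codes(cohort: F2Cohort, marker_map: MarkerMap) -> np.ndarray:
    """(n_individuals, n_markers) array of A/H/B codes at the map's markers."""
    columns = []
    for marker in marker_map.markers:
        positions = cohort.loci[marker.chrom]
        idx = int(np.searchsorted(positions, marker.pos))
        if idx >= positions.size or positions[idx] != marker.pos:
            raise ConfigurationError(f"marker {marker.id} has no genotyped locus")
        columns.append(cohort.genotype_codes(marker.chrom)[:, idx])
    return np.stack(columns, axis=1)


def add_genotyping_errors(
    codes: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Replace each genotype call with one of the two other codes w.p. ``rate``."""
    out = codes.copy()
    if rate <= 0:
        return out
    flip = rng.random(out.shape) < rate
    all_codes = np.array(["A", "H", "B"])
    for i, j in zip(*np.nonzero(flip)):
        others = all_codes[all_codes != out[i, j]]
        out[i, j] = others[rng.integers(2)]
    return out


# ---------------------------------------------------------------------------
# file outputs
# ---------------------------------------------------------------------------


def write_dataset(dataset: MutmapDataset, outdir) -> dict[str, Path]:
    """Write FASTA / GFF3 / pooled VCF / truth TSV for a simulated experiment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fasta",
        "gff3": outdir / "genes.gff3",
        "vcf": outdir / "pooled.vcf",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(dataset.genome, paths["fasta"])
    write_gff3(dataset.genes, paths["gff3"])
    write_pooled_vcf(
        dataset.sites, paths["vcf"], contig_lengths=dataset.genome.lengths
    )
    truth = pd.DataFrame(
        [
            {
                "chrom": dataset.causal.chrom,
                "pos": dataset.causal.pos,
                "ref": dataset.causal.ref,
                "alt": dataset.causal.alt,
                "causal_gene": dataset.causal_gene_id,
                "motif": dataset.config.motif,
            }
        ]
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def write_finemap_tsvs(
    marker_map: MarkerMap, cohort: F2Cohort, outdir
) -> dict[str, Path]:
    """Write the marker map and individual genotype/phenotype tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "marker_map": outdir / "marker_map.tsv",
        "genotypes": outdir / "finemap_genotypes.tsv",
    }
    pd.DataFrame(
        [
            {"marker_id": m.id, "chrom": m.chrom, "pos_bp": m.pos}
            for m in marker_map.markers
        ]
    ).to_csv(paths["marker_map"], sep="\t", index=False)
    codes = marker_genotype_codes(cohort, marker_map)
    table = pd.DataFrame(codes, columns=[m.id for m in marker_map.markers])
    table.insert(0, "phenotype", cohort.phenotypes)
    table.insert(0, "individual_id", [f"ind{i + 1:04d}" for i in range(cohort.n)])
    table.to_csv(paths["genotypes"], sep="\t", index=False)
    return paths
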
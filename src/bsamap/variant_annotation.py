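"""Codon-level effect prediction of SNPs against gene models.

Classifies variants as intergenic / intronic / synonymous / missense /
nonsense / stop_loss / start_loss using the standard nuclear codon table,
filters genes carrying nonsynonymous variants, and checks whether an
affected residue falls inside a protein motif (e.g. the Aux/IAA degron
GWPPV, whose first proline is the canonical gain-of-function target).

Gene span is taken as the CDS extent; UTRs are not modelled, so a genic
variant outside every CDS segment is called intronic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .exceptions import ConfigurationError, ConsistencyError, FormatError
from .io_formats import GeneModel, GenomeSequenceSet, VariantSite

log = logging.getLogger(__name__)

EFFECT_INTERGENIC = "intergenic"
EFFECT_INTRONIC = "intronic"
EFFECT_SYNONYMOUS = "synonymous"
EFFECT_MISSENSE = "missense"
EFFECT_NONSENSE = "nonsense"
EFFECT_STOP_LOSS = "stop_loss"
EFFECT_START_LOSS = "start_loss"
EFFECT_NON_TRANSLATABLE = "non_translatable"

#: Effects that change the encoded protein.
NONSYNONYMOUS_EFFECTS = frozenset(
    {EFFECT_MISSENSE, EFFECT_NONSENSE, EFFECT_STOP_LOSS, EFFECT_START_LOSS}
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant with its predicted effect on one gene (or none)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    effect: str
    gene_id: str | None = None
    codon_ref: str | None = None
    codon_alt: str | None = None
    protein_pos: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    motif_hit: bool = False
    motif_offset: int | None = None

    @property
    def protein_change(self) -> str | None:
        """Compact protein notation such as ``"P160L"``."""
        if self.protein_pos is None:
            return None
        return f"{self.aa_ref}{self.protein_pos}{self.aa_alt}"


@dataclass(frozen=True)
class CodingChange:
    codon_ref: str
    codon_alt: str
    protein_pos: int
    aa_ref: str
    aa_alt: str
    effect: str


# ---------------------------------------------------------------------------
# coding coordinates
# ---------------------------------------------------------------------------


def coding_sequence(gene: GeneModel, genome: GenomeSequenceSet) -> str:
    """The gene's CDS in coding order (minus strand: reverse-complemented)."""
    seq = genome[gene.chrom]
    joined = "".join(seq[a - 1 : b] for a, b in gene.cds_segments)
    if gene.strand == "-":
        joined = str(Seq(joined).reverse_complement())
    return joined


def translate_gene(gene: GeneModel, genome: GenomeSequenceSet) -> str:
    """Protein sequence including the terminal ``*`` if a stop is encoded."""
    if not gene.translatable:
        raise FormatError(f"gene {gene.gene_id}: CDS length not divisible by 3")
    return str(Seq(coding_sequence(gene, genome)).translate())


def coding_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of a genomic position within the coding sequence."""
    if gene.strand == "+":
        cum = 0
        for a, b in gene.cds_segments:
            if a <= pos <= b:
                return cum + (pos - a)
            cum += b - a + 1
    else:
        cum = 0
        for a, b in reversed(gene.cds_segments):
            if a <= pos <= b:
                return cum + (b - pos)
            cum += b - a + 1
    raise ValueError(f"position {pos} not inside a CDS segment of {gene.gene_id}")


def genomic_position(gene: GeneModel, offset: int) -> int:
    """Inverse of :func:`coding_offset`: genomic 1-based position of a
    0-based coding offset."""
    if not 0 <= offset < gene.cds_length:
        raise ValueError(f"coding offset {offset} outside CDS of {gene.gene_id}")
    segments = (
        gene.cds_segments if gene.strand == "+" else tuple(reversed(gene.cds_segments))
    )
    cum = 0
    for a, b in segments:
        length = b - a + 1
        if offset < cum + length:
            within = offset - cum
            return a + within if gene.strand == "+" else b - within
        cum += length
    raise AssertionError("unreachable")


def coding_change(
    gene: GeneModel,
    pos: int,
    ref: str,
    alt: str,
    genome: GenomeSequenceSet,
) -> CodingChange:
    """Codon-level consequence of a SNP inside a CDS segment.

    ``ref``/``alt`` are on the genomic plus strand; on minus-strand genes
    they are complemented into coding-strand bases before the codon is
    rebuilt and translated.
    """
    if not gene.translatable:
        raise FormatError(f"gene {gene.gene_id}: CDS length not divisible by 3")
    offset = coding_offset(gene, pos)
    cds = coding_sequence(gene, genome)
    if gene.strand == "+":
        ref_c, alt_c = ref, alt
    else:
        ref_c, alt_c = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
    if cds[offset] != ref_c:
        raise ConsistencyError(
            f"{gene.chrom}:{pos}: coding base {cds[offset]!r} does not match "
            f"expected ref {ref_c!r} for gene {gene.gene_id}"
        )
    codon_index = offset // 3
    within = offset % 3
    codon_ref = cds[3 * codon_index : 3 * codon_index + 3]
    codon_alt = codon_ref[:within] + alt_c + codon_ref[within + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    if aa_ref == aa_alt:
        effect = EFFECT_SYNONYMOUS
    elif aa_alt == "*":
        effect = EFFECT_NONSENSE
    elif aa_ref == "*":
        effect = EFFECT_STOP_LOSS
    elif codon_index == 0:
        effect = EFFECT_START_LOSS
    else:
        effect = EFFECT_MISSENSE
    return CodingChange(
        codon_ref=codon_ref,
        codon_alt=codon_alt,
        protein_pos=codon_index + 1,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        effect=effect,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_variant(
    site: VariantSite,
    genes: Iterable[GeneModel],
    genome: GenomeSequenceSet,
) -> list[AnnotatedVariant]:
    """Annotate one SNP against every overlapping gene.

    Returns one record per overlapping gene (or a single intergenic record).
    The genome base at the site must match the variant's ref allele; an 'N'
    reference base skips the variant with a warning (empty list).
    """
    genome_base = genome.base(site.chrom, site.pos)
    if genome_base == "N":
        log.warning("%s:%d: reference base is N; variant skipped", site.chrom, site.pos)
        return []
    if genome_base != site.ref:
        raise ConsistencyError(
            f"{site.chrom}:{site.pos}: VCF ref {site.ref!r} does not match "
            f"genome base {genome_base!r}"
        )
    hits = [g for g in genes if g.chrom == site.chrom and g.contains(site.pos)]
    if not hits:
        return [
            AnnotatedVariant(
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                alt=site.alt,
                effect=EFFECT_INTERGENIC,
            )
        ]
    out = []
    for gene in hits:
        if not gene.in_cds(site.pos):
            out.append(
                AnnotatedVariant(
                    chrom=site.chrom,
                    pos=site.pos,
                    ref=site.ref,
                    alt=site.alt,
                    effect=EFFECT_INTRONIC,
                    gene_id=gene.gene_id,
                )
            )
            continue
        if not gene.translatable:
            log.warning(
                "%s:%d: gene %s is non-translatable; coding effect not assigned",
                site.chrom,
                site.pos,
                gene.gene_id,
            )
            out.append(
                AnnotatedVariant(
                    chrom=site.chrom,
                    pos=site.pos,
                    ref=site.ref,
                    alt=site.alt,
                    effect=EFFECT_NON_TRANSLATABLE,
                    gene_id=gene.gene_id,
                )
            )
            continue
        cc = coding_change(gene, site.pos, site.ref, site.alt, genome)
        out.append(
            AnnotatedVariant(
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                alt=site.alt,
                effect=cc.effect,
                gene_id=gene.gene_id,
                codon_ref=cc.codon_ref,
                codon_alt=cc.codon_alt,
                protein_pos=cc.protein_pos,
                aa_ref=cc.aa_ref,
                aa_alt=cc.aa_alt,
            )
        )
    return out


def motif_hit(
    annotated: AnnotatedVariant,
    genes: Iterable[GeneModel],
    genome: GenomeSequenceSet,
    motif: str,
) -> tuple[bool, int | None]:
    """Does the affected residue fall inside an exact occurrence of ``motif``?

    Returns ``(hit, offset)`` where ``offset`` is the 1-based position of the
    affected residue within the motif occurrence.
    """
    if not motif:
        raise ConfigurationError("motif must be non-empty")
    if annotated.protein_pos is None or annotated.gene_id is None:
        raise ConfigurationError("motif_hit requires a coding variant")
    gene = next((g for g in genes if g.gene_id == annotated.gene_id), None)
    if gene is None:
        raise ConfigurationError(f"gene {annotated.gene_id!r} not found")
    protein = translate_gene(gene, genome).rstrip("*")
    start = 0
    while True:
        idx = protein.find(motif, start)
        if idx < 0:
            return False, None
        if idx + 1 <= annotated.protein_pos <= idx + len(motif):
            return True, annotated.protein_pos - idx
        start = idx + 1


def annotate_sites(
    sites: Sequence[VariantSite],
    genes: Sequence[GeneModel],
    genome: GenomeSequenceSet,
    motif: str | None = None,
) -> list[AnnotatedVariant]:
    """Annotate many sites; optionally mark motif hits on coding variants."""
    out: list[AnnotatedVariant] = []
    for site in sites:
        for av in classify_variant(site, genes, genome):
            if motif and av.protein_pos is not None:
                hit, off = motif_hit(av, genes, genome, motif)
                av = replace(av, motif_hit=hit, motif_offset=off)
            out.append(av)
    return out


def nonsyn_filter(
    intervals,
    annotated: Sequence[AnnotatedVariant],
) -> list[tuple[str, list[AnnotatedVariant]]]:
    """Genes inside the candidate intervals that carry >= 1 protein-changing
    variant, each with its qualifying variants, sorted by chromosome and
    position."""
    allowed: set[str] = set()
    for iv in intervals:
        allowed.update(iv.genes)
    grouped: dict[str, list[AnnotatedVariant]] = {}
    for av in annotated:
        if av.effect in NONSYNONYMOUS_EFFECTS and av.gene_id in allowed:
            grouped.setdefault(av.gene_id, []).append(av)
    def sort_key(item):
        gene_id, variants = item
        first = min(variants, key=lambda v: (v.chrom, v.pos))
        return (first.chrom, first.pos, gene_id)
    return sorted(grouped.items(), key=sort_key)
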
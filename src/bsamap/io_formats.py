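"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 1-based inclusive throughout (the VCF/GFF3
convention). Conversion to 0-based half-open happens only at the BED
boundary, in :func:`write_intervals_bed`.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pysam
from Bio import SeqIO

from .exceptions import ConfigurationError, FormatError

log = logging.getLogger(__name__)

#: Canonical base order used for all per-pool count/frequency vectors.
BASES = ("A", "C", "G", "T")

_SEQ_ALPHABET = frozenset("ACGTN")
_POOLS = ("mut", "wt")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequenceSet:
    """Reference sequences keyed by chromosome id.

    Sequences are uppercase strings over ``{A, C, G, T, N}``; the reported
    length of each chromosome is the string length.
    """

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"chromosome {chrom!r} has an empty sequence")
            bad = set(seq) - _SEQ_ALPHABET
            if bad:
                raise FormatError(
                    f"chromosome {chrom!r} contains illegal characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self):
        return iter(self.sequences)

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self.sequences[chrom]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} outside {chrom} (length {len(seq)})")
        return seq[pos - 1]


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with ordered CDS segments (1-based inclusive).

    Segments are stored in genomic order, non-overlapping and sorted by
    start; on the minus strand the *coding* order is the reverse. A model
    whose total CDS length is not divisible by 3 is flagged non-translatable
    rather than rejected.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    protein_id: str | None = None
    translatable: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        segs = tuple((int(a), int(b)) for a, b in self.cds_segments)
        object.__setattr__(self, "cds_segments", segs)
        if not segs:
            raise FormatError(f"gene {self.gene_id}: no CDS segments")
        prev_end = 0
        for a, b in segs:
            if a < 1 or a > b:
                raise FormatError(f"gene {self.gene_id}: bad segment ({a}, {b})")
            if a <= prev_end:
                raise FormatError(
                    f"gene {self.gene_id}: CDS segments overlap or are unsorted"
                )
            prev_end = b
        if self.cds_length % 3 != 0:
            object.__setattr__(self, "translatable", False)

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        """(min CDS start, max CDS end)."""
        return (self.cds_segments[0][0], self.cds_segments[-1][1])

    def contains(self, pos: int) -> bool:
        a, b = self.span
        return a <= pos <= b

    def in_cds(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.cds_segments)


def _normalise_counts(counts: Mapping[str, int], label: str) -> dict[str, int]:
    extra = set(counts) - set(BASES)
    if extra:
        raise FormatError(f"{label}: unknown bases in counts: {sorted(extra)}")
    out = {}
    for b in BASES:
        v = int(counts.get(b, 0))
        if v < 0:
            raise FormatError(f"{label}: negative count for base {b}")
        out[b] = v
    return out


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP with per-pool base-level read counts.

    ``mut_counts`` / ``wt_counts`` map each of A/C/G/T to a non-negative
    read count for the mutant-phenotype and wild-type-phenotype pool.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    mut_counts: Mapping[str, int]
    wt_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise FormatError(f"{self.chrom}:{self.pos}: ref/alt must be A/C/G/T")
        if self.ref == self.alt:
            raise FormatError(f"{self.chrom}:{self.pos}: ref equals alt")
        if self.pos < 1:
            raise FormatError(f"{self.chrom}:{self.pos}: position must be >= 1")
        label = f"{self.chrom}:{self.pos}"
        object.__setattr__(self, "mut_counts", _normalise_counts(self.mut_counts, label))
        object.__setattr__(self, "wt_counts", _normalise_counts(self.wt_counts, label))

    def counts(self, pool: str) -> dict[str, int]:
        if pool not in _POOLS:
            raise ConfigurationError(f"unknown pool {pool!r}; expected 'mut' or 'wt'")
        return dict(self.mut_counts if pool == "mut" else self.wt_counts)

    def depth(self, pool: str) -> int:
        return sum(self.counts(pool).values())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _locate_bad_line(path: Path, bad: set[str]) -> int:
    bad_lower = {c.lower() for c in bad} | bad
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip()) & bad_lower:
                return i
    return 0


def read_fasta(path) -> GenomeSequenceSet:
    """Read a FASTA file into a :class:`GenomeSequenceSet` (uppercased)."""
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FASTA: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found (malformed header at line 1?)")
    seqs: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - _SEQ_ALPHABET
        if bad:
            line = _locate_bad_line(path, bad)
            raise FormatError(
                f"{path}: illegal sequence character(s) {sorted(bad)} near line {line}"
            )
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
        seqs[rec.id] = seq
    return GenomeSequenceSet(seqs)


def write_fasta(genome: GenomeSequenceSet, path, width: int = 60) -> None:
    """Write FASTA with fixed-width (default 60-column) wrapping."""
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path) -> list[GeneModel]:
    """Read gene models (gene/mRNA/CDS with ID/Parent attributes).

    Returns one :class:`GeneModel` per mRNA. A model whose CDS length is not
    divisible by 3 triggers a warning and is flagged non-translatable; a CDS
    feature without a Parent attribute is a format error.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        sort_attribute_values=True,
    )
    for cds in db.features_of_type("CDS"):
        if "Parent" not in cds.attributes:
            raise FormatError(f"{path}: CDS feature at {cds.seqid}:{cds.start} lacks Parent")
    models: list[GeneModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        cds_list = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds_list:
            log.warning("mRNA %s has no CDS features; skipped", mrna.id)
            continue
        segments = tuple((c.start, c.end) for c in cds_list)
        parents = mrna.attributes.get("Parent", [])
        gene_id = parents[0] if parents else mrna.id
        model = GeneModel(
            gene_id=gene_id,
            chrom=mrna.seqid,
            strand=mrna.strand,
            cds_segments=segments,
            protein_id=mrna.id,
        )
        if not model.translatable:
            warnings.warn(
                f"{path}: gene {gene_id} CDS length {model.cds_length} not divisible "
                "by 3; flagged non-translatable",
                stacklevel=2,
            )
        models.append(model)
    return models


def _cds_phases(gene: GeneModel) -> list[int]:
    """GFF3 phase column per segment, in genomic order."""
    segs = list(gene.cds_segments)
    order = segs if gene.strand == "+" else list(reversed(segs))
    phases = {}
    cum = 0
    for seg in order:
        phases[seg] = (3 - cum % 3) % 3
        cum += seg[1] - seg[0] + 1
    return [phases[s] for s in segs]


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    """Write gene/mRNA/CDS features for the given models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(genes, key=lambda g: (g.chrom, g.span[0])):
            start, end = gene.span
            mrna_id = gene.protein_id or f"{gene.gene_id}.t1"
            fh.write(
                f"{gene.chrom}\tbsamap\tgene\t{start}\t{end}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            fh.write(
                f"{gene.chrom}\tbsamap\tmRNA\t{start}\t{end}\t.\t{gene.strand}\t.\t"
                f"ID={mrna_id};Parent={gene.gene_id}\n"
            )
            for (a, b), phase in zip(gene.cds_segments, _cds_phases(gene)):
                fh.write(
                    f"{gene.chrom}\tbsamap\tCDS\t{a}\t{b}\t.\t{gene.strand}\t{phase}\t"
                    f"ID={mrna_id}.cds;Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# VCF with per-sample AD
# ---------------------------------------------------------------------------


def read_pooled_vcf(path, mut_sample: str, wt_sample: str):
    """Read biallelic SNPs with per-sample allele depths.

    The AD FORMAT field of the two named samples is parsed as
    ``(ref_count, alt_count)`` and mapped onto base-count vectors.
    Multiallelic records, indels and records without AD are skipped and
    counted.

    Returns ``(sites, skipped)`` where ``skipped`` maps a reason
    (``multiallelic``/``indel``/``non_acgt``/``missing_ad``) to a count.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for name in (mut_sample, wt_sample):
            if name not in samples:
                raise ConfigurationError(
                    f"{path}: sample {name!r} not in VCF (samples: {samples})"
                )
        skipped = {"multiallelic": 0, "indel": 0, "non_acgt": 0, "missing_ad": 0}
        sites: list[VariantSite] = []
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                skipped["multiallelic"] += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1:
                skipped["indel"] += 1
                continue
            if ref not in BASES or alt not in BASES:
                skipped["non_acgt"] += 1
                continue
            ad_mut = rec.samples[mut_sample].get("AD")
            ad_wt = rec.samples[wt_sample].get("AD")
            if (
                ad_mut is None
                or ad_wt is None
                or len(ad_mut) < 2
                or len(ad_wt) < 2
                or any(v is None for v in (*ad_mut[:2], *ad_wt[:2]))
            ):
                skipped["missing_ad"] += 1
                continue
            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    mut_counts={ref: int(ad_mut[0]), alt: int(ad_mut[1])},
                    wt_counts={ref: int(ad_wt[0]), alt: int(ad_wt[1])},
                )
            )
    n_skipped = sum(skipped.values())
    if n_skipped:
        log.info("read_pooled_vcf: skipped %d records: %s", n_skipped, skipped)
    return sites, skipped


def write_pooled_vcf(
    sites: Sequence[VariantSite],
    path,
    mut_sample: str = "mut_pool",
    wt_sample: str = "wt_pool",
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write sites as a VCF 4.2 file with per-sample AD (ref, alt) depths."""
    chroms: list[str] = []
    for s in sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsamap\n")
        for chrom in chroms:
            if contig_lengths and chrom in contig_lengths:
                fh.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{mut_sample}\t{wt_sample}\n"
        )
        for s in sites:
            ad_m = f"{s.mut_counts[s.ref]},{s.mut_counts[s.alt]}"
            ad_w = f"{s.wt_counts[s.ref]},{s.wt_counts[s.alt]}"
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t.\tAD\t{ad_m}\t{ad_w}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)
_BED_HEADER = "#chrom\tchromStart\tchromEnd\tname\tscore\tstrand\n"


def write_intervals_bed(intervals, path) -> None:
    """Write candidate intervals as BED6 (0-based half-open).

    The score column is the interval's peak fitted ED scaled onto
    ``[0, 1000]`` (1000 corresponds to the biallelic maximum sqrt(2)).
    Intervals are sorted by chromosome then start. Duck-typed: any object
    with ``chrom``/``start``/``end``/``peak_value`` attributes works.
    """
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start))
    with open(path, "w") as fh:
        fh.write(_BED_HEADER)
        for iv in rows:
            score = int(round(1000 * min(max(iv.peak_value, 0.0), _SQRT2) / _SQRT2))
            name = f"{iv.chrom}:{iv.start}-{iv.end}"
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t{score}\t.\n")


def read_intervals_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED file back to 1-based inclusive (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: malformed BED line: {line!r}")
            out.append((fields[0], int(fields[1]) + 1, int(fields[2])))
    return out
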
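import numpy as np
import pytest

from bsamap.io_formats import GeneModel, GenomeSequenceSet
from bsamap.synthetic_data import (
    SimulationConfig,
    simulate_mutmap_experiment,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down pooled experiment used by unit tests (fast)."""
    return SimulationConfig(
        chromosomes={"chr1": 1_000_000},
        n_snps=300,
        n_genes=12,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_mutmap_experiment(small_config)


def make_single_exon_gene(protein: str, codon_overrides=None, strand: str = "+",
                          chrom: str = "chrT", cds_start: int = 101):
    """Build a (genome, gene) pair encoding ``protein`` in one CDS segment.

    ``codon_overrides`` maps a 1-based protein position to a specific codon.
    Deterministic: always uses the lexicographically first codon per residue
    unless overridden. Returns (GenomeSequenceSet, GeneModel).
    """
    from Bio.Data import CodonTable
    from Bio.Seq import Seq

    table = CodonTable.unambiguous_dna_by_name["Standard"]
    by_aa = {}
    for codon, aa in sorted(table.forward_table.items()):
        by_aa.setdefault(aa, codon)
    codons = [by_aa[aa] for aa in protein]
    for pos_1based, codon in (codon_overrides or {}).items():
        codons[pos_1based - 1] = codon
    codons.append("TAA")
    cds = "".join(codons)
    genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
    flank = "A" * (cds_start - 1)
    seq = flank + genomic + "A" * 100
    genome = GenomeSequenceSet({chrom: seq})
    gene = GeneModel(
        gene_id="gTEST",
        chrom=chrom,
        strand=strand,
        cds_segments=((cds_start, cds_start + len(cds) - 1),),
    )
    return genome, gene
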
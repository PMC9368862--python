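import math

import numpy as np
import pytest

from bsamap import synthetic_data as sd
from bsamap.exceptions import ConfigurationError, GenerationError
from bsamap.variant_annotation import coding_change, translate_gene


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def test_config_validation():
    with pytest.raises(ConfigurationError):
        sd.SimulationConfig(depth=0)
    with pytest.raises(ConfigurationError):
        sd.SimulationConfig(error_rate=0.5)
    with pytest.raises(ConfigurationError):
        sd.SimulationConfig(mode="codominant")
    with pytest.raises(ConfigurationError):
        sd.SimulationConfig(pool_size=150, cohort_size=200)


# ---------------------------------------------------------------------------
# genome and genes
# ---------------------------------------------------------------------------


def test_reference_and_genes_invariants(small_dataset, small_config):
    genome, genes = small_dataset.genome, small_dataset.genes
    assert set(genome.lengths) == set(small_config.chromosomes)
    spans = sorted(g.span for g in genes)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 < s2, "genes overlap"
    for gene in genes:
        assert gene.cds_length % 3 == 0
        assert 2 <= len(gene.cds_segments) <= 6
        protein = translate_gene(gene, genome)
        assert protein.startswith("M")
        assert protein.endswith("*") and "*" not in protein[:-1]
    motif_carriers = [
        g for g in genes if small_config.motif in translate_gene(g, genome)
    ]
    assert len(motif_carriers) == 1


def test_simulation_deterministic_under_seed(small_config):
    a = sd.simulate_mutmap_experiment(small_config)
    b = sd.simulate_mutmap_experiment(small_config)
    assert a.genome.sequences == b.genome.sequences
    assert a.variants == b.variants
    assert all(
        np.array_equal(a.cohort.genotypes[c], b.cohort.genotypes[c])
        for c in a.cohort.genotypes
    )
    assert [s.mut_counts for s in a.sites] == [s.mut_counts for s in b.sites]


# ---------------------------------------------------------------------------
# EMS variants
# ---------------------------------------------------------------------------


def test_causal_snp_is_pro_to_leu(small_dataset):
    """The planted causal change is CCx->CTx (Pro->Leu) in the motif gene."""
    ds = small_dataset
    gene = next(g for g in ds.genes if g.gene_id == ds.causal_gene_id)
    cc = coding_change(gene, ds.causal.pos, ds.causal.ref, ds.causal.alt, ds.genome)
    assert cc.aa_ref == "P" and cc.aa_alt == "L"
    assert cc.codon_ref.startswith("CC") and cc.codon_alt[1] == "T"
    assert cc.effect == "missense"


def test_ems_bias_one_all_transitions():
    cfg = sd.SimulationConfig(
        chromosomes={"chr1": 300_000}, n_snps=200, n_genes=6, ems_bias=1.0, seed=2
    )
    rng = np.random.default_rng(2)
    genome, genes = sd.simulate_reference_and_genes(cfg, rng)
    variants = sd.simulate_ems_variants(cfg, genome, genes, rng)
    assert all((v.ref, v.alt) in {("C", "T"), ("G", "A")} for v in variants)
    assert sum(v.causal for v in variants) == 1


def test_ems_bias_fraction_within_three_binomial_sd():
    n = 10_000
    bias = 0.9
    cfg = sd.SimulationConfig(
        chromosomes={"chr1": 2_000_000}, n_snps=n, n_genes=6, ems_bias=bias, seed=3
    )
    rng = np.random.default_rng(3)
    genome, genes = sd.simulate_reference_and_genes(cfg, rng)
    variants = [v for v in sd.simulate_ems_variants(cfg, genome, genes, rng) if not v.causal]
    frac = sum((v.ref, v.alt) in {("C", "T"), ("G", "A")} for v in variants) / n
    tol = 3 * math.sqrt(bias * (1 - bias) / n)
    assert abs(frac - bias) <= tol


# ---------------------------------------------------------------------------
# phenotype mapping
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "genotype,mode,expected",
    [
        ("A", "semi-dominant", "WT"),
        ("H", "semi-dominant", "INT"),
        ("B", "semi-dominant", "MUT"),
        ("A", "dominant", "WT"),
        ("H", "dominant", "MUT"),
        ("B", "dominant", "MUT"),
        ("A", "recessive", "WT"),
        ("H", "recessive", "WT"),
        ("B", "recessive", "MUT"),
        (1, "semi-dominant", "INT"),
    ],
)
def test_phenotype_from_genotype(genotype, mode, expected):
    assert sd.phenotype_from_genotype(genotype, mode) == expected


def test_phenotype_unknown_mode():
    with pytest.raises(ConfigurationError):
        sd.phenotype_from_genotype("A", "overdominant")


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def test_causal_genotypes_fit_1_2_1_over_large_cohort():
    cfg = sd.SimulationConfig(chromosomes={"c": 1_000_000}, seed=4)
    loci = {"c": np.array([500_000])}
    cohort = sd.simulate_f2_cohort(cfg, loci, causal=("c", 500_000), n=10_000)
    counts = np.bincount(cohort.causal_genotypes(), minlength=3)
    n = counts.sum()
    for observed, p in zip(counts, (0.25, 0.5, 0.25)):
        tol = 3 * math.sqrt(p * (1 - p) * n)
        assert abs(observed - n * p) <= tol


def test_zero_distance_loci_completely_linked():
    cfg = sd.SimulationConfig(chromosomes={"c": 1_000_000}, seed=5)
    loci = {"c": np.array([400_000, 400_001])}  # ~4e-9 Morgans apart
    cohort = sd.simulate_f2_cohort(cfg, loci, causal=("c", 400_000), n=2000)
    g = cohort.genotypes["c"]
    assert np.array_equal(g[:, 0], g[:, 1])


def test_haldane_recombination_fraction_at_half_morgan():
    """Two loci 0.5 Morgans apart: gametic recombination fraction should be
    (1 - e^-1)/2 ~ 0.3161 within Monte-Carlo error."""
    rng = np.random.default_rng(6)
    d = 0.5
    length_bp = 20_000_000
    morgans_total = 0.8  # chromosome longer than the inter-locus distance
    positions = np.array([0.0, d / morgans_total * length_bp])
    n = 40_000
    gametes = sd.simulate_gametes(rng, morgans_total, length_bp, positions, n)
    r_hat = np.mean(gametes[:, 0] != gametes[:, 1])
    r_exp = (1 - math.exp(-2 * d)) / 2
    tol = 3 * math.sqrt(r_exp * (1 - r_exp) / n)
    assert abs(r_hat - r_exp) <= tol


# ---------------------------------------------------------------------------
# pools and reads
# ---------------------------------------------------------------------------


def test_pools_error_free_causal_site_is_fixed():
    cfg = sd.SimulationConfig(
        chromosomes={"c": 1_000_000}, error_rate=0.0, seed=7, cohort_size=200
    )
    loci = {"c": np.array([500_000])}
    cohort = sd.simulate_f2_cohort(cfg, loci, causal=("c", 500_000))
    variants = [sd.VariantTemplate("c", 500_000, "C", "T", causal=True)]
    (site,) = sd.build_pools_and_reads(cohort, variants, cfg)
    assert site.mut_counts["T"] == site.depth("mut") > 0
    assert site.wt_counts["C"] == site.depth("wt") > 0


def test_pools_unlinked_site_mean_frequency_half():
    """At a freely segregating unlinked site both pools' expected alt
    frequency is 0.5 (checked as a mean over seeds)."""
    freqs = []
    for seed in range(30):
        cfg = sd.SimulationConfig(
            chromosomes={"c1": 1_000_000, "c2": 1_000_000},
            error_rate=0.0,
            depth=100,
            seed=seed,
            cohort_size=200,
        )
        loci = {"c1": np.array([500_000]), "c2": np.array([500_000])}
        cohort = sd.simulate_f2_cohort(cfg, loci, causal=("c1", 500_000))
        variants = [
            sd.VariantTemplate("c1", 500_000, "C", "T", causal=True),
            sd.VariantTemplate("c2", 500_000, "G", "A"),
        ]
        sites = sd.build_pools_and_reads(cohort, variants, cfg)
        unlinked = sites[1] if sites[1].chrom == "c2" else sites[0]
        for pool in ("mut", "wt"):
            counts = unlinked.counts(pool)
            freqs.append(counts["A"] / sum(counts.values()))
    assert abs(np.mean(freqs) - 0.5) < 0.05


def test_insufficient_pool_class_raises_with_counts():
    cfg = sd.SimulationConfig(chromosomes={"c": 1_000_000}, seed=8, cohort_size=40)
    loci = {"c": np.array([500_000])}
    cohort = sd.simulate_f2_cohort(cfg, loci, causal=("c", 500_000), n=4)
    with pytest.raises(GenerationError, match="MUT="):
        sd.build_pools_and_reads(
            cohort, [sd.VariantTemplate("c", 500_000, "C", "T")], cfg
        )


def test_zero_depth_site_emitted_with_zero_counts():
    cfg = sd.SimulationConfig(
        chromosomes={"c": 1_000_000}, depth=0.0001, seed=9, cohort_size=200
    )
    loci = {"c": np.array([500_000])}
    cohort = sd.simulate_f2_cohort(cfg, loci, causal=("c", 500_000))
    (site,) = sd.build_pools_and_reads(
        cohort, [sd.VariantTemplate("c", 500_000, "C", "T", causal=True)], cfg
    )
    assert site.depth("mut") == 0 and site.depth("wt") == 0


# ---------------------------------------------------------------------------
# fine-mapping cross
# ---------------------------------------------------------------------------


def test_finemap_cross_deterministic_and_sized():
    cfg = sd.SimulationConfig(seed=10)
    mm1, c1 = sd.simulate_finemap_cross(cfg)
    mm2, c2 = sd.simulate_finemap_cross(cfg)
    assert c1.n == cfg.finemap_size == 185
    assert len(mm1) == 13
    assert np.array_equal(
        sd.marker_genotype_codes(c1, mm1), sd.marker_genotype_codes(c2, mm2)
    )


def test_finemap_cross_phenotypes_fit_1_2_1():
    from bsamap.genetics import chi_square_gof

    cfg = sd.SimulationConfig(seed=12)
    _, cohort = sd.simulate_finemap_cross(cfg)
    counts = cohort.phenotype_counts()
    res = chi_square_gof(
        [counts["WT"], counts["INT"], counts["MUT"]], [1, 2, 1]
    )
    assert res.decision == "fits"


def test_finemap_markers_flanking_causal_tightly_show_no_recombinants():
    from bsamap.fine_mapping import find_recombinants

    cfg = sd.SimulationConfig(seed=13)
    chrom = "chr1"
    causal = 5_000_000
    mm, cohort = sd.simulate_finemap_cross(
        cfg, marker_positions=[causal - 1, causal + 1, causal + 200_000],
        causal_pos=causal,
    )
    codes = sd.marker_genotype_codes(cohort, mm)
    recombinants = find_recombinants(
        codes[:, :2], list(cohort.phenotypes), cfg.mode
    )
    assert recombinants == []


def test_finemap_causal_outside_span_is_error():
    cfg = sd.SimulationConfig(seed=14)
    with pytest.raises(ConfigurationError):
        sd.simulate_finemap_cross(
            cfg, marker_positions=[1000, 2000, 3000], causal_pos=5000
        )
    with pytest.raises(ConfigurationError):
        sd.simulate_finemap_cross(
            cfg, marker_positions=[1000, 2000, 3000], causal_pos=2000
        )
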
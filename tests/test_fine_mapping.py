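import numpy as np
import pytest

from bsamap import fine_mapping as fm
from bsamap import synthetic_data as sd
from bsamap.exceptions import (
    ConfigurationError,
    FineMapInconsistencyError,
    FormatError,
)


def _map5():
    return fm.MarkerMap(
        tuple(
            fm.Marker(f"M{i + 1}", "chr1", pos)
            for i, pos in enumerate([10_000, 20_000, 30_000, 40_000, 50_000])
        )
    )


# ---------------------------------------------------------------------------
# compatibility sets
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "phenotype,mode,expected",
    [
        ("WT", "semi-dominant", {"A"}),
        ("INT", "semi-dominant", {"H"}),
        ("MUT", "semi-dominant", {"B"}),
        ("WT", "dominant", {"A"}),
        ("MUT", "dominant", {"H", "B"}),
        ("WT", "recessive", {"A", "H"}),
        ("MUT", "recessive", {"B"}),
    ],
)
def test_expected_causal_genotypes(phenotype, mode, expected):
    assert fm.expected_causal_genotypes(phenotype, mode) == frozenset(expected)


def test_int_phenotype_invalid_under_dominant():
    with pytest.raises(ConfigurationError):
        fm.expected_causal_genotypes("INT", "dominant")


# ---------------------------------------------------------------------------
# recombinant detection at two flanking markers
# ---------------------------------------------------------------------------


def test_find_recombinants_rules():
    genotypes = np.array(
        [
            ["B", "H"],   # MUT: markers disagree -> recombinant
            ["B", "B"],   # MUT: fully concordant -> not
            ["A", "NA"],  # WT: missing is non-informative -> not
            ["H", "H"],   # WT expects A -> recombinant
        ],
        dtype=object,
    )
    phenotypes = ["MUT", "MUT", "WT", "WT"]
    ids = ["i1", "i2", "i3", "i4"]
    assert fm.find_recombinants(genotypes, phenotypes, "semi-dominant", ids) == [
        "i1",
        "i4",
    ]


def test_find_recombinants_rejects_bad_codes():
    genotypes = np.array([["B", "X"]], dtype=object)
    with pytest.raises(FormatError):
        fm.find_recombinants(genotypes, ["MUT"], "semi-dominant")


# ---------------------------------------------------------------------------
# interval narrowing
# ---------------------------------------------------------------------------


def _concordant_cohort(n, phenotype="MUT"):
    """n individuals fully concordant at 5 markers."""
    code = {"MUT": "B", "WT": "A", "INT": "H"}[phenotype]
    return np.full((n, 5), code, dtype=object), [phenotype] * n


def test_narrow_interval_hand_example():
    """ind1 (MUT) A,B,B,B,B and ind2 (WT) A,A,A,B,B exclude M1 and M4/M5;
    core = {M2, M3}; open interval (10 kb, 40 kb)."""
    geno, phen = _concordant_cohort(3)
    geno = np.vstack(
        [
            np.array([["A", "B", "B", "B", "B"]], dtype=object),
            np.array([["A", "A", "A", "B", "B"]], dtype=object),
            geno,
        ]
    )
    phen = ["MUT", "WT"] + phen
    res = fm.narrow_interval(_map5(), geno, phen, "semi-dominant")
    assert res.interval == (10_000, 40_000)
    assert res.left_marker == "M1" and res.right_marker == "M4"
    assert res.core_markers == ("M2", "M3")
    assert set(res.recombinants) == {"0", "1"}
    assert res.recombinants["1"] == ("M4", "M5")


def test_no_recombinants_returns_full_range():
    geno, phen = _concordant_cohort(10)
    res = fm.narrow_interval(
        _map5(), geno, phen, "semi-dominant", chrom_start=1, chrom_end=100_000
    )
    assert res.interval == (1, 100_000)
    assert res.core_markers == ("M1", "M2", "M3", "M4", "M5")
    assert res.recombinants == {}


def test_fully_discordant_individual_is_inconsistency():
    geno, phen = _concordant_cohort(3)
    geno[0] = ["A", "A", "A", "A", "A"]  # MUT phenotype but all-wild genotypes
    with pytest.raises(FineMapInconsistencyError):
        fm.narrow_interval(_map5(), geno, phen, "semi-dominant")


def test_single_marker_puncture_does_not_split_interval():
    """An individual discordant at one interior marker only (double
    crossover around it) excludes that point, not the flanking gaps."""
    geno, phen = _concordant_cohort(4)
    geno[0] = ["B", "B", "A", "B", "B"]  # MUT, discordant only at M3
    res = fm.narrow_interval(
        _map5(), geno, phen, "semi-dominant", chrom_start=1, chrom_end=100_000
    )
    assert res.interval == (1, 100_000)
    assert "M3" not in res.core_markers


def test_min_discordant_masks_single_noisy_call():
    geno, phen = _concordant_cohort(5)
    geno[0][0] = "A"  # one stray discordance at M1
    strict = fm.narrow_interval(
        _map5(), geno, phen, "semi-dominant", chrom_start=1, chrom_end=100_000
    )
    lenient = fm.narrow_interval(
        _map5(),
        geno,
        phen,
        "semi-dominant",
        chrom_start=1,
        chrom_end=100_000,
        min_discordant=2,
    )
    assert strict.interval == (10_000, 100_000)
    assert lenient.interval == (1, 100_000)


def test_monotone_narrowing_as_individuals_accumulate():
    cfg = sd.SimulationConfig(seed=21)
    marker_map, cohort = sd.simulate_finemap_cross(cfg)
    codes = sd.marker_genotype_codes(cohort, marker_map)
    chrom = marker_map.single_chromosome()
    bounds = dict(chrom_start=1, chrom_end=cfg.chromosomes[chrom])
    prev_measure = float("inf")
    for n in (20, 60, 100, 150, 185):
        regions = fm.feasible_regions(
            marker_map, codes[:n], list(cohort.phenotypes[:n]), cfg.mode, **bounds
        )
        measure = sum(hi - lo for lo, hi in regions)
        assert measure <= prev_measure
        prev_measure = measure


def test_failure_rate_grows_with_genotyping_error():
    """With zero genotyping error the causal is always recovered; injected
    errors can only make things worse (coverage failures or inconsistency)."""
    failures = {}
    for eps in (0.0, 0.01, 0.05):
        n_fail = 0
        for seed in range(15):
            cfg = sd.SimulationConfig(seed=seed)
            marker_map, cohort = sd.simulate_finemap_cross(cfg)
            codes = sd.marker_genotype_codes(cohort, marker_map)
            rng = np.random.default_rng(1000 + seed)
            codes = sd.add_genotyping_errors(codes, eps, rng)
            chrom, causal_pos = cohort.causal
            try:
                res = fm.narrow_interval(
                    marker_map,
                    codes,
                    list(cohort.phenotypes),
                    cfg.mode,
                    chrom_start=1,
                    chrom_end=cfg.chromosomes[chrom],
                )
                if not res.interval[0] < causal_pos < res.interval[1]:
                    n_fail += 1
            except (FineMapInconsistencyError, fm.FineMapAmbiguityError):
                n_fail += 1
        failures[eps] = n_fail
    assert failures[0.0] == 0
    assert failures[0.0] <= failures[0.01] <= failures[0.05]


# ---------------------------------------------------------------------------
# intersection with the BSA interval
# ---------------------------------------------------------------------------


def test_intersect_with_bsa_cases():
    finemap = ("chr1", 10_000, 40_000)
    assert fm.intersect_with_bsa(finemap, [("chr1", 5_000, 25_000)]) == [
        ("chr1", 10_000, 25_000)
    ]
    assert fm.intersect_with_bsa(finemap, [("chr1", 60_000, 90_000)]) == []
    assert fm.intersect_with_bsa(finemap, [("chr1", 1, 1_000_000)]) == [
        ("chr1", 10_000, 40_000)
    ]
    assert fm.intersect_with_bsa(finemap, [("chr2", 5_000, 25_000)]) == []


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------


def test_marker_and_genotype_tsv_round_trip(tmp_path):
    cfg = sd.SimulationConfig(seed=22)
    marker_map, cohort = sd.simulate_finemap_cross(cfg)
    paths = sd.write_finemap_tsvs(marker_map, cohort, tmp_path)
    mm2 = fm.read_marker_map_tsv(paths["marker_map"])
    assert mm2.ids == marker_map.ids
    assert np.array_equal(mm2.positions, marker_map.positions)
    ids, phenotypes, genotypes = fm.read_genotypes_tsv(paths["genotypes"], mm2)
    assert len(ids) == cohort.n
    assert phenotypes == list(cohort.phenotypes)
    assert np.array_equal(genotypes, sd.marker_genotype_codes(cohort, marker_map))
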
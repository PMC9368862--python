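"""Recombinant-breakpoint fine mapping from ordered marker genotypes.

Under a single-locus model, an individual's phenotype implies a set of
compatible genotypes at the causal locus (semi-dominant phenotypes imply
the genotype uniquely). A marker where an individual's genotype falls
outside that set is *discordant* for that individual: a crossover separates
the marker from the causal locus, so the causal locus cannot sit at the
marker itself. The interval is OPEN at discordant markers — a breakpoint
excludes the causal locus AT the marker but says nothing beyond it.

For each individual the feasible region is therefore the union of open
intervals around its runs of concordant markers, bounded by the nearest
discordant marker on each side (or the chromosome end). The fine-mapped
interval is the intersection of these regions across all individuals; its
bounds are the facing left- and right-side discordant markers, and its
*core* is the markers strictly inside, at which no individual is
discordant. Missing genotypes are non-informative.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    FineMapAmbiguityError,
    FineMapInconsistencyError,
    FormatError,
)

log = logging.getLogger(__name__)

GENOTYPE_CODES = ("A", "H", "B")
MISSING_CODES = ("NA", "N", ".", "", "-")

_COMPATIBILITY = {
    "semi-dominant": {"WT": frozenset("A"), "INT": frozenset("H"), "MUT": frozenset("B")},
    "dominant": {"WT": frozenset("A"), "MUT": frozenset("HB")},
    "recessive": {"WT": frozenset("AH"), "MUT": frozenset("B")},
}


@dataclass(frozen=True)
class Marker:
    id: str
    chrom: str
    pos: int


@dataclass(frozen=True)
class MarkerMap:
    """Ordered markers with unique ids and strictly increasing positions."""

    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise FormatError("marker ids are not unique")
        by_chrom: dict[str, int] = {}
        for m in self.markers:
            if m.chrom in by_chrom and m.pos <= by_chrom[m.chrom]:
                raise FormatError(
                    f"marker positions not strictly increasing on {m.chrom}"
                )
            by_chrom[m.chrom] = m.pos

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.markers]

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.pos for m in self.markers], dtype=np.int64)

    def single_chromosome(self) -> str:
        chroms = {m.chrom for m in self.markers}
        if len(chroms) != 1:
            raise ConfigurationError(
                f"expected markers on one chromosome, got {sorted(chroms)}"
            )
        return chroms.pop()


@dataclass(frozen=True)
class FineMapResult:
    """Bounding markers, consistent core, and the recombinants behind them.

    ``interval`` is the open interval (left bound position, right bound
    position); an unbounded side is ``-inf`` / ``+inf`` unless chromosome
    bounds were supplied.
    """

    chrom: str
    interval: tuple[float, float]
    left_marker: str | None
    right_marker: str | None
    core_markers: tuple[str, ...]
    recombinants: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if not self.interval[0] < self.interval[1]:
            raise ConfigurationError("left bound must be below right bound")

    @property
    def width(self) -> float:
        return self.interval[1] - self.interval[0]


# ---------------------------------------------------------------------------
# genotype/phenotype compatibility
# ---------------------------------------------------------------------------


def expected_causal_genotypes(phenotype: str, mode: str) -> frozenset[str]:
    """Genotype codes at the causal locus compatible with a phenotype class."""
    if mode not in _COMPATIBILITY:
        raise ConfigurationError(f"unknown inheritance mode {mode!r}")
    table = _COMPATIBILITY[mode]
    if phenotype not in table:
        raise ConfigurationError(
            f"phenotype {phenotype!r} is not valid under {mode} inheritance"
        )
    return table[phenotype]


def _discordance_matrix(
    genotypes: np.ndarray, phenotypes: Sequence[str], mode: str
) -> np.ndarray:
    geno = np.asarray(genotypes, dtype=object)
    if geno.ndim != 2:
        raise ConfigurationError("genotype matrix must be 2-D (individuals x markers)")
    n, m = geno.shape
    if len(phenotypes) != n:
        raise ConfigurationError("phenotypes do not match the genotype matrix rows")
    out = np.zeros((n, m), dtype=bool)
    for i, phen in enumerate(phenotypes):
        compat = expected_causal_genotypes(phen, mode)
        for j in range(m):
            g = str(geno[i, j]).upper()
            if g in MISSING_CODES:
                continue
            if g not in GENOTYPE_CODES:
                raise FormatError(f"unknown genotype code {geno[i, j]!r}")
            out[i, j] = g not in compat
    return out


def find_recombinants(
    genotypes: np.ndarray,
    phenotypes: Sequence[str],
    mode: str,
    ids: Sequence[str] | None = None,
) -> list[str]:
    """Individuals recombinant with respect to two flanking markers.

    An individual is a recombinant iff its genotype at either marker falls
    outside its phenotype's compatibility set, or the two (non-missing)
    marker genotypes differ from each other. Missing genotypes never
    trigger.
    """
    geno = np.asarray(genotypes, dtype=object)
    if geno.ndim != 2 or geno.shape[1] != 2:
        raise ConfigurationError("expected a genotype matrix with two marker columns")
    ids = list(ids) if ids is not None else [str(i) for i in range(geno.shape[0])]
    disc = _discordance_matrix(geno, phenotypes, mode)
    out = []
    for i in range(geno.shape[0]):
        g1, g2 = (str(geno[i, j]).upper() for j in (0, 1))
        differ = (
            g1 not in MISSING_CODES and g2 not in MISSING_CODES and g1 != g2
        )
        if disc[i].any() or differ:
            out.append(ids[i])
    return out


# ---------------------------------------------------------------------------
# interval narrowing
# ---------------------------------------------------------------------------


def _individual_feasible(
    discordant_row: np.ndarray, positions: np.ndarray, lo: float, hi: float
) -> list[tuple[float, float]]:
    """Open feasible intervals for one individual: one per maximal run of
    concordant markers, bounded by the flanking discordant markers."""
    m = positions.size
    concordant = ~discordant_row
    intervals = []
    j = 0
    while j < m:
        if not concordant[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and concordant[k + 1]:
            k += 1
        left = float(positions[j - 1]) if j > 0 else lo
        right = float(positions[k + 1]) if k + 1 < m else hi
        intervals.append((left, right))
        j = k + 1
    return intervals


def _intersect_unions(
    a: list[tuple[float, float]], b: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    out = []
    for lo1, hi1 in a:
        for lo2, hi2 in b:
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            if lo < hi:
                out.append((lo, hi))
    out.sort()
    return out


def _merge_punctured(regions: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge components that abut at a single marker position.

    An individual discordant at one marker but concordant on both sides (a
    double crossover around that marker) excludes the causal locus only AT
    that zero-width point; the surrounding interval stays one region.
    Components separated by a positive-length infeasible gap are kept
    apart — that is genuine ambiguity.
    """
    if not regions:
        return regions
    merged = [regions[0]]
    for lo, hi in regions[1:]:
        prev_lo, prev_hi = merged[-1]
        if lo <= prev_hi:
            merged[-1] = (prev_lo, max(prev_hi, hi))
        else:
            merged.append((lo, hi))
    return merged


def feasible_regions(
    marker_map: MarkerMap,
    genotypes: np.ndarray,
    phenotypes: Sequence[str],
    mode: str,
    *,
    chrom_start: float | None = None,
    chrom_end: float | None = None,
    min_discordant: int = 1,
) -> list[tuple[float, float]]:
    """All open regions where the causal locus may lie, given every
    individual's marker discordance pattern. Empty when the data are
    internally inconsistent."""
    positions = marker_map.positions
    lo = float(chrom_start) if chrom_start is not None else -math.inf
    hi = float(chrom_end) if chrom_end is not None else math.inf
    disc = _discordance_matrix(genotypes, phenotypes, mode)
    if min_discordant > 1:
        # treat rarely-discordant markers as genotyping noise
        noisy = disc.sum(axis=0) < min_discordant
        disc[:, noisy] = False
    regions = [(lo, hi)]
    for i in range(disc.shape[0]):
        indiv = _individual_feasible(disc[i], positions, lo, hi)
        regions = _intersect_unions(regions, indiv)
        if not regions:
            return []
    return _merge_punctured(regions)


def narrow_interval(
    marker_map: MarkerMap,
    genotypes: np.ndarray,
    phenotypes: Sequence[str],
    mode: str,
    *,
    ids: Sequence[str] | None = None,
    chrom_start: float | None = None,
    chrom_end: float | None = None,
    min_discordant: int = 1,
) -> FineMapResult:
    """Narrow the causal interval by intersecting per-individual feasible
    regions.

    Raises :class:`FineMapInconsistencyError` when no region survives
    (phenotyping/genotyping error or wrong inheritance mode) and
    :class:`FineMapAmbiguityError` when more than one disjoint region does.
    """
    if len(marker_map) < 3:
        raise ConfigurationError("need at least 3 ordered markers")
    chrom = marker_map.single_chromosome()
    geno = np.asarray(genotypes, dtype=object)
    ids = list(ids) if ids is not None else [str(i) for i in range(geno.shape[0])]
    regions = feasible_regions(
        marker_map,
        geno,
        phenotypes,
        mode,
        chrom_start=chrom_start,
        chrom_end=chrom_end,
        min_discordant=min_discordant,
    )
    if not regions:
        raise FineMapInconsistencyError(
            "every candidate region is excluded; check phenotypes, genotypes "
            f"or the inheritance mode ({mode})"
        )
    if len(regions) > 1:
        raise FineMapAmbiguityError(regions)
    lo, hi = regions[0]
    by_pos = {m.pos: m.id for m in marker_map.markers}
    disc = _discordance_matrix(geno, phenotypes, mode)
    excluded_cols = disc.any(axis=0)
    core = tuple(
        m.id
        for j, m in enumerate(marker_map.markers)
        if lo < m.pos < hi and not excluded_cols[j]
    )
    recombinants = {
        ids[i]: tuple(
            marker_map.ids[j] for j in np.flatnonzero(disc[i])
        )
        for i in range(disc.shape[0])
        if disc[i].any()
    }
    return FineMapResult(
        chrom=chrom,
        interval=(lo, hi),
        left_marker=by_pos.get(lo),
        right_marker=by_pos.get(hi),
        core_markers=core,
        recombinants=recombinants,
    )


def intersect_with_bsa(
    finemap: FineMapResult | tuple[str, float, float],
    bsa_intervals,
) -> list[tuple[str, float, float]]:
    """Intersect the fine-mapped open interval with BSA candidate intervals.

    ``bsa_intervals`` may be :class:`~bsamap.ed_scan.CandidateInterval`
    objects or ``(chrom, start, end)`` tuples (1-based inclusive). An empty
    result is allowed and logged.
    """
    if isinstance(finemap, FineMapResult):
        chrom, (lo, hi) = finemap.chrom, finemap.interval
    else:
        chrom, lo, hi = finemap
    out = []
    for iv in bsa_intervals:
        if isinstance(iv, tuple):
            iv_chrom, start, end = iv
        else:
            iv_chrom, start, end = iv.chrom, iv.start, iv.end
        if iv_chrom != chrom:
            continue
        new_lo, new_hi = max(lo, float(start)), min(hi, float(end))
        if new_lo < new_hi:
            out.append((chrom, new_lo, new_hi))
    if not out:
        log.warning(
            "fine-map interval %s:(%s, %s) does not intersect any BSA interval",
            chrom,
            lo,
            hi,
        )
    return out


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_marker_map_tsv(path) -> MarkerMap:
    """Columns: marker_id, chrom, pos_bp."""
    df = pd.read_csv(path, sep="\t")
    required = {"marker_id", "chrom", "pos_bp"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    return MarkerMap(
        tuple(
            Marker(id=str(r.marker_id), chrom=str(r.chrom), pos=int(r.pos_bp))
            for r in df.itertuples()
        )
    )


def read_genotypes_tsv(path, marker_map: MarkerMap):
    """Columns: individual_id, phenotype, then one A/H/B/NA column per marker.

    Returns ``(ids, phenotypes, genotype matrix)`` with marker columns in
    map order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("individual_id", "phenotype") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    absent = [m for m in marker_map.ids if m not in df.columns]
    if absent:
        raise FormatError(f"{path}: missing marker columns {absent}")
    genotypes = df[marker_map.ids].fillna("NA").to_numpy(dtype=object)
    return (
        df["individual_id"].tolist(),
        df["phenotype"].tolist(),
        genotypes,
    )
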
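"""The core genome scan.

Per-site allele frequencies, read-support QC, the Euclidean-distance (ED)
allele-frequency statistic, local tricube-weighted fitting, threshold
computation and candidate interval/peak calling.

The ED statistic at a site is the Euclidean distance between the two pools'
allele-frequency vectors over the four bases,

    ED = sqrt( sum_b (f_mut(b) - f_wt(b))^2 ),   b in {A, C, G, T},

which for a biallelic site equals ``sqrt(2) * |f_mut(alt) - f_wt(alt)|`` and
is bounded by ``sqrt(2)``. Sites tightly linked to the causal locus in a
phenotype-selected pool design show large ED; unlinked sites fluctuate
around 0.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .exceptions import ConfigurationError, ZeroDepthError
from .io_formats import BASES, GeneModel, VariantSite

SQRT2 = math.sqrt(2.0)

THRESHOLD_METHODS = ("fixed", "quantile_permutation", "median_plus_k_sd")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EDProfile:
    """Raw and fitted ED values for one chromosome, plus the threshold used."""

    chrom: str
    positions: np.ndarray
    ed_raw: np.ndarray
    ed_fitted: np.ndarray
    threshold: float
    power: int = 1

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ConfigurationError(f"{self.chrom}: positions not strictly increasing")
        if self.threshold < 0:
            raise ConfigurationError("threshold must be >= 0")


@dataclass(frozen=True)
class CandidateInterval:
    """A super-threshold run of sites (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_value: float
    n_sites: int
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start <= self.peak_pos <= self.end:
            raise ConfigurationError("peak position outside interval")


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------


def _count_vector(site: VariantSite, pool: str) -> np.ndarray:
    counts = site.mut_counts if pool == "mut" else site.wt_counts
    return np.array([counts[b] for b in BASES], dtype=float)


def allele_frequencies(site: VariantSite, pool: str) -> np.ndarray:
    """Frequency vector over (A, C, G, T) for one pool; entries sum to 1."""
    if pool not in ("mut", "wt"):
        raise ConfigurationError(f"unknown pool {pool!r}")
    vec = _count_vector(site, pool)
    total = vec.sum()
    if total <= 0:
        raise ZeroDepthError(
            f"{site.chrom}:{site.pos}: zero depth in {pool} pool; "
            "filter low-depth sites before computing frequencies"
        )
    return vec / total


def euclidean_distance(site: VariantSite, power: int = 1) -> float:
    """ED between the two pools' allele-frequency vectors, raised to ``power``."""
    fm = allele_frequencies(site, "mut")
    fw = allele_frequencies(site, "wt")
    ed = float(np.sqrt(np.sum((fm - fw) ** 2)))
    return ed**power


def filter_sites(
    sites: Sequence[VariantSite], min_reads: int = 4
) -> tuple[list[VariantSite], dict[str, int]]:
    """Remove sites with total depth below ``min_reads`` in either pool.

    A site is retained iff both pools have depth >= ``min_reads``. Returns
    the retained sites and a removal log keyed by reason.
    """
    retained: list[VariantSite] = []
    log = {
        "n_input": len(sites),
        "n_retained": 0,
        "n_removed": 0,
        "low_depth_mut": 0,
        "low_depth_wt": 0,
        "low_depth_both": 0,
    }
    for site in sites:
        low_mut = site.depth("mut") < min_reads
        low_wt = site.depth("wt") < min_reads
        if low_mut and low_wt:
            log["low_depth_both"] += 1
        elif low_mut:
            log["low_depth_mut"] += 1
        elif low_wt:
            log["low_depth_wt"] += 1
        else:
            retained.append(site)
    log["n_retained"] = len(retained)
    log["n_removed"] = log["n_input"] - log["n_retained"]
    return retained, log


# ---------------------------------------------------------------------------
# local fitting
# ---------------------------------------------------------------------------


def _tricube_matrix(positions: np.ndarray, window_bp: float) -> sparse.csr_matrix:
    """Row-normalised tricube weight matrix over a physical window.

    Row i holds weights ``w(u) = (1 - |u|^3)^3`` with
    ``u = (pos_j - pos_i) / (window_bp / 2)`` for the sites within
    ``window_bp / 2`` of site i.
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.size
    h = window_bp / 2.0
    lo = np.searchsorted(pos, pos - h, side="left")
    hi = np.searchsorted(pos, pos + h, side="right")
    rows, cols, vals = [], [], []
    for i in range(n):
        j0, j1 = int(lo[i]), int(hi[i])
        u = np.abs(pos[j0:j1] - pos[i]) / h
        w = np.clip(1.0 - u**3, 0.0, None) ** 3
        w /= w.sum()  # self-weight is 1, so the sum is always positive
        rows.append(np.full(j1 - j0, i, dtype=np.int64))
        cols.append(np.arange(j0, j1, dtype=np.int64))
        vals.append(w)
    if not rows:
        return sparse.csr_matrix((0, 0))
    return sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def fit_profile(
    positions: Sequence[int], values: np.ndarray, window_bp: float = 1_000_000
) -> np.ndarray:
    """Tricube-weighted local mean of ED values over a physical window.

    ``values`` may be 1-D (one series) or 2-D with shape ``(B, n)`` (B series
    over the same positions, fitted in one pass). Each fitted value is a
    convex combination of raw values in its window, hence lies within their
    range.
    """
    pos = np.asarray(positions, dtype=float)
    vals = np.asarray(values, dtype=float)
    if window_bp <= 0:
        raise ConfigurationError("window_bp must be positive")
    if pos.size == 0:
        return np.empty(vals.shape[:-1] + (0,))
    if pos.size != vals.shape[-1]:
        raise ConfigurationError("positions and values are not aligned")
    if np.any(np.diff(pos) < 0):
        raise ConfigurationError("positions must be sorted")
    weights = _tricube_matrix(pos, window_bp)
    if vals.ndim == 1:
        return weights @ vals
    return (weights @ vals.T).T


# ---------------------------------------------------------------------------
# threshold
# ---------------------------------------------------------------------------


def _null_ed_matrix(
    sites: Sequence[VariantSite],
    n_permutations: int,
    rng: np.random.Generator,
    power: int = 1,
    pool_size: int | None = None,
) -> np.ndarray:
    """Null ED values with no true allele-frequency difference between pools.

    With ``pool_size`` given (the number of individuals per pool), the null
    for each site draws both pools' allele compositions from the combined
    allele frequency — alt-chromosome counts Binomial(2*pool_size, f0) per
    pool, then reads Binomial(depth, f*) — which reproduces the finite-pool
    sampling noise an unlinked segregating site shows. Without it, the reads
    of both pools are merely re-partitioned at the observed depths (a
    multivariate hypergeometric draw), a narrower null that only reflects
    read sampling. Returns an ``(n_permutations, n_sites)`` array.
    """
    if pool_size is not None:
        ref_m = np.array([s.mut_counts[s.ref] for s in sites], dtype=np.int64)
        alt_m = np.array([s.mut_counts[s.alt] for s in sites], dtype=np.int64)
        ref_w = np.array([s.wt_counts[s.ref] for s in sites], dtype=np.int64)
        alt_w = np.array([s.wt_counts[s.alt] for s in sites], dtype=np.int64)
        dm = ref_m + alt_m
        dw = ref_w + alt_w
        if np.any(dm <= 0) or np.any(dw <= 0):
            raise ZeroDepthError("null model requires ref+alt reads in both pools")
        f0 = (alt_m + alt_w) / (dm + dw)
        two_n = 2 * pool_size
        out = np.empty((n_permutations, len(sites)))
        for b in range(n_permutations):
            fm = rng.binomial(two_n, f0) / two_n
            fw = rng.binomial(two_n, f0) / two_n
            fm_hat = rng.binomial(dm, fm) / dm
            fw_hat = rng.binomial(dw, fw) / dw
            out[b] = (SQRT2 * np.abs(fm_hat - fw_hat)) ** power
        return out
    mut = np.array([[s.mut_counts[b] for b in BASES] for s in sites], dtype=np.int64)
    wt = np.array([[s.wt_counts[b] for b in BASES] for s in sites], dtype=np.int64)
    total = mut + wt
    dm = mut.sum(axis=1)
    dw = wt.sum(axis=1)
    if np.any(dm <= 0) or np.any(dw <= 0):
        raise ZeroDepthError("permutation null requires positive depth in both pools")
    out = np.empty((n_permutations, len(sites)))
    for b in range(n_permutations):
        remaining = dm.copy()
        pool_rem = total.sum(axis=1)
        new_mut = np.empty_like(mut)
        for base in range(4):
            good = total[:, base]
            bad = pool_rem - good
            draw = rng.hypergeometric(good, bad, remaining) if np.any(remaining) else np.zeros_like(remaining)
            draw = np.where(remaining > 0, draw, 0)
            new_mut[:, base] = draw
            remaining = remaining - draw
            pool_rem = pool_rem - good
        new_wt = total - new_mut
        fm = new_mut / dm[:, None]
        fw = new_wt / dw[:, None]
        out[b] = np.sqrt(((fm - fw) ** 2).sum(axis=1)) ** power
    return out


def compute_threshold(
    fitted: Sequence[float],
    method: str = "fixed",
    *,
    value: float = 0.05,
    quantile: float = 0.995,
    n_permutations: int = 200,
    k_sd: float = 3.0,
    window_bp: float = 1_000_000,
    power: int = 1,
    chrom_sites: Sequence[tuple[np.ndarray, Sequence[VariantSite]]] | None = None,
    pool_size: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> float:
    """Threshold above which fitted ED values are called significant.

    ``fixed``
        returns ``value`` (0.05 reproduces a literature-style fixed cutoff).
    ``median_plus_k_sd``
        median + ``k_sd`` * SD of the supplied fitted values.
    ``quantile_permutation``
        the ``quantile`` of ``n_permutations`` fitted null profiles drawn
        per site under the no-linkage null (see :func:`_null_ed_matrix`;
        pass ``pool_size`` so the null includes finite-pool composition
        noise). Requires ``chrom_sites``: one ``(positions, sites)`` pair
        per chromosome.
    """
    if method == "fixed":
        return float(value)
    arr = np.asarray(fitted, dtype=float)
    if method == "median_plus_k_sd":
        if arr.size == 0:
            raise ConfigurationError("no fitted values supplied")
        return float(np.median(arr) + k_sd * np.std(arr))
    if method == "quantile_permutation":
        if not chrom_sites:
            raise ConfigurationError(
                "quantile_permutation needs chrom_sites=[(positions, sites), ...]"
            )
        rng = np.random.default_rng(seed)
        null_fitted = []
        for positions, sites in chrom_sites:
            null_ed = _null_ed_matrix(
                sites, n_permutations, rng, power=power, pool_size=pool_size
            )
            null_fitted.append(fit_profile(positions, null_ed, window_bp).ravel())
        return float(np.quantile(np.concatenate(null_fitted), quantile))
    raise ConfigurationError(
        f"unknown threshold method {method!r}; expected one of {THRESHOLD_METHODS}"
    )


# ---------------------------------------------------------------------------
# interval calling
# ---------------------------------------------------------------------------


def call_intervals(
    chrom: str,
    positions: Sequence[int],
    fitted: Sequence[float],
    threshold: float,
    merge_gap_bp: int = 0,
) -> list[CandidateInterval]:
    """Maximal runs of consecutive sites with fitted ED strictly above threshold.

    Runs whose facing boundary sites are within ``merge_gap_bp`` of each
    other are merged. The peak is the member site with the largest fitted
    value (leftmost on ties); the interval span runs from the first to the
    last member site.
    """
    pos = np.asarray(positions)
    fit = np.asarray(fitted, dtype=float)
    if pos.size != fit.size:
        raise ConfigurationError("positions and fitted values are not aligned")
    above = fit > threshold
    if not above.any():
        return []
    # maximal runs of consecutive super-threshold sites, as index pairs
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = [0] if above[0] else []
    starts += [int(e) + 1 for e in edges if above[e + 1]]
    ends = [int(e) for e in edges if above[e]]
    if above[-1]:
        ends.append(int(pos.size - 1))
    runs = list(zip(starts, ends))
    # merge runs separated by at most merge_gap_bp
    merged: list[list[tuple[int, int]]] = [[runs[0]]]
    for run in runs[1:]:
        prev = merged[-1][-1]
        if pos[run[0]] - pos[prev[1]] <= merge_gap_bp:
            merged[-1].append(run)
        else:
            merged.append([run])
    intervals = []
    for group in merged:
        members = np.concatenate([np.arange(a, b + 1) for a, b in group])
        peak_local = members[int(np.argmax(fit[members]))]
        intervals.append(
            CandidateInterval(
                chrom=chrom,
                start=int(pos[group[0][0]]),
                end=int(pos[group[-1][1]]),
                peak_pos=int(pos[peak_local]),
                peak_value=float(fit[peak_local]),
                n_sites=int(members.size),
            )
        )
    return intervals


def genes_in_intervals(
    intervals: Iterable[CandidateInterval], genes: Iterable[GeneModel]
) -> list[CandidateInterval]:
    """Fill each interval's gene list: a gene belongs iff its span overlaps
    the interval by at least 1 bp."""
    genes = list(genes)
    out = []
    for iv in intervals:
        hits = [
            g.gene_id
            for g in genes
            if g.chrom == iv.chrom
            and not (g.span[1] < iv.start or g.span[0] > iv.end)
        ]
        out.append(dataclasses.replace(iv, genes=tuple(hits)))
    return out


# ---------------------------------------------------------------------------
# whole-scan convenience
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """Everything the ED scan produces for one pooled dataset."""

    profiles: dict[str, EDProfile]
    intervals: list[CandidateInterval]
    threshold: float
    removal_log: dict[str, int] = field(default_factory=dict)

    @property
    def global_peak(self) -> tuple[str, int, float] | None:
        """(chrom, position, fitted ED) of the genome-wide fitted maximum."""
        best = None
        for chrom, prof in self.profiles.items():
            if prof.ed_fitted.size == 0:
                continue
            i = int(np.argmax(prof.ed_fitted))
            cand = (chrom, int(prof.positions[i]), float(prof.ed_fitted[i]))
            if best is None or cand[2] > best[2]:
                best = cand
        return best


def run_scan(
    sites: Sequence[VariantSite],
    *,
    min_reads: int = 4,
    window_bp: float = 1_000_000,
    power: int = 1,
    threshold_method: str = "quantile_permutation",
    threshold_value: float = 0.05,
    quantile: float = 0.995,
    n_permutations: int = 200,
    k_sd: float = 3.0,
    merge_gap_bp: int = 0,
    pool_size: int | None = 20,
    seed: int | np.random.SeedSequence | None = None,
) -> ScanResult:
    """Run QC, ED, fitting, a single genome-wide threshold and interval calls.

    ``pool_size`` (individuals per pool) parameterises the permutation null;
    the default matches the 20+20 pooled design.
    """
    retained, removal_log = filter_sites(sites, min_reads=min_reads)
    by_chrom: dict[str, list[VariantSite]] = {}
    for site in retained:
        by_chrom.setdefault(site.chrom, []).append(site)
    chrom_data = []
    for chrom in sorted(by_chrom):
        chrom_sites = sorted(by_chrom[chrom], key=lambda s: s.pos)
        positions = np.array([s.pos for s in chrom_sites], dtype=np.int64)
        raw = np.array([euclidean_distance(s, power=power) for s in chrom_sites])
        fitted = fit_profile(positions, raw, window_bp)
        chrom_data.append((chrom, positions, chrom_sites, raw, fitted))
    all_fitted = (
        np.concatenate([c[4] for c in chrom_data]) if chrom_data else np.empty(0)
    )
    threshold = compute_threshold(
        all_fitted,
        threshold_method,
        value=threshold_value,
        quantile=quantile,
        n_permutations=n_permutations,
        k_sd=k_sd,
        window_bp=window_bp,
        power=power,
        chrom_sites=[(c[1], c[2]) for c in chrom_data],
        pool_size=pool_size,
        seed=seed,
    )
    profiles = {}
    intervals: list[CandidateInterval] = []
    for chrom, positions, _, raw, fitted in chrom_data:
        profiles[chrom] = EDProfile(
            chrom=chrom,
            positions=positions,
            ed_raw=raw,
            ed_fitted=fitted,
            threshold=threshold,
            power=power,
        )
        intervals.extend(
            call_intervals(chrom, positions, fitted, threshold, merge_gap_bp)
        )
    return ScanResult(
        profiles=profiles,
        intervals=intervals,
        threshold=threshold,
        removal_log=removal_log,
    )


def plot_profile(profile: EDProfile, path, intervals=None) -> None:
    """Scatter the raw ED values with the fitted curve and threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.5))
    mb = profile.positions / 1e6
    ax.plot(mb, profile.ed_raw, ".", ms=2, color="0.7", label="raw ED")
    ax.plot(mb, profile.ed_fitted, "-", color="C0", lw=1.5, label="fitted ED")
    ax.axhline(profile.threshold, color="C3", ls="--", lw=1, label="threshold")
    if intervals:
        for iv in intervals:
            if iv.chrom == profile.chrom:
                ax.axvspan(iv.start / 1e6, iv.end / 1e6, color="C1", alpha=0.15)
    ax.set_xlabel(f"{profile.chrom} position (Mb)")
    ax.set_ylabel(f"ED^{profile.power}" if profile.power != 1 else "ED")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
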
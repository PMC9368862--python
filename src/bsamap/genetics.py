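"""Mendelian segregation-ratio testing and inheritance-mode classification.

The chi-square goodness-of-fit statistic here is the plain Pearson statistic
(optionally with Yates continuity correction); p-values and critical values
come from :mod:`scipy.stats`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError

#: Candidate Mendelian F2 ratios for two observed phenotype classes.
TWO_CLASS_RATIOS: tuple[tuple[int, ...], ...] = ((3, 1), (15, 1), (13, 3), (9, 7))
#: Candidate ratios for three observed phenotype classes.
THREE_CLASS_RATIOS: tuple[tuple[int, ...], ...] = ((1, 2, 1),)


@dataclass(frozen=True)
class SegregationResult:
    """Outcome of a chi-square goodness-of-fit test against a fixed ratio."""

    observed: tuple[int, ...]
    ratio: tuple[int, ...]
    expected: tuple[float, ...]
    statistic: float
    df: int
    alpha: float
    critical_value: float
    p_value: float

    @property
    def decision(self) -> str:
        """``"fits"`` iff the statistic does not exceed the critical value."""
        return "fits" if self.statistic <= self.critical_value else "rejected"


def chi_square_gof(
    observed: Sequence[int],
    ratio: Sequence[int],
    alpha: float = 0.05,
    yates: bool = False,
) -> SegregationResult:
    """Test observed class counts against an expected Mendelian ratio.

    Expected counts are ``N * ratio_i / sum(ratio)``; the statistic is
    ``sum((O_i - E_i)^2 / E_i)`` with ``df = k - 1`` (Yates correction
    subtracts 0.5 from each |O-E| when requested).
    """
    obs = tuple(int(v) for v in observed)
    rat = tuple(int(v) for v in ratio)
    if len(obs) < 2:
        raise ConfigurationError("need at least 2 phenotype classes")
    if len(obs) != len(rat):
        raise ConfigurationError(
            f"ratio length {len(rat)} does not match class count {len(obs)}"
        )
    if any(v < 0 for v in obs):
        raise ConfigurationError("observed counts must be non-negative")
    total = sum(obs)
    if total <= 0:
        raise ConfigurationError("total observed count must be positive")
    if any(r <= 0 for r in rat):
        raise ConfigurationError("ratio classes must have positive weight")
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    expected = tuple(total * r / sum(rat) for r in rat)
    diffs = np.abs(np.asarray(obs, dtype=float) - np.asarray(expected))
    if yates:
        diffs = np.maximum(diffs - 0.5, 0.0)
    statistic = float(np.sum(diffs**2 / np.asarray(expected)))
    df = len(obs) - 1
    return SegregationResult(
        observed=obs,
        ratio=rat,
        expected=expected,
        statistic=statistic,
        df=df,
        alpha=alpha,
        critical_value=float(stats.chi2.ppf(1 - alpha, df)),
        p_value=float(stats.chi2.sf(statistic, df)),
    )


def classify_inheritance(
    observed: Sequence[int],
    alpha: float = 0.05,
    candidate_ratios: Sequence[Sequence[int]] | None = None,
    yates: bool = False,
) -> tuple[tuple[int, ...] | None, list[SegregationResult]]:
    """Pick the best-fitting Mendelian ratio for the observed class counts.

    Tests every applicable candidate ratio (3-class ratios only when three
    classes are observed) and returns ``(best_ratio, results)`` where
    ``best_ratio`` is the non-rejected ratio with the largest p-value, or
    ``None`` when every candidate is rejected at ``alpha``.
    """
    obs = tuple(int(v) for v in observed)
    if len(obs) not in (2, 3):
        raise ConfigurationError("expected 2 or 3 phenotype classes")
    if candidate_ratios is None:
        candidate_ratios = TWO_CLASS_RATIOS if len(obs) == 2 else THREE_CLASS_RATIOS
    applicable = [tuple(int(v) for v in r) for r in candidate_ratios if len(r) == len(obs)]
    results = [chi_square_gof(obs, r, alpha=alpha, yates=yates) for r in applicable]
    fitting = [r for r in results if r.decision == "fits"]
    if not fitting:
        return None, results
    best = max(fitting, key=lambda r: r.p_value)
    return best.ratio, results
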
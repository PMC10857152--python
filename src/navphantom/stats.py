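"""Cohort-level statistics: descriptive demographics, non-parametric group
comparisons with Bonferroni-corrected post hocs, Spearman correlations, and
median-split subgroup analysis.

The inferential layer mirrors a standard small-cohort accuracy study:
Kruskal–Wallis across surgical positions as the omnibus test, pairwise
Mann–Whitney U post hocs at a Bonferroni-adjusted alpha (0.05 / number of
pairs), two-sided throughout, and tie-corrected Spearman rank correlations
between accuracy metrics and lesion characteristics.  Mann–Whitney p-values
use the exact null distribution when the combined sample is small (<= 20 and
tie-free), the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "MedianSplitResult",
    "demographics_summary",
    "compare_positions",
    "correlate",
    "median_split",
]

ALPHA = 0.05
EXACT_MWU_MAX_N = 20


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus + post hoc comparison of one metric across groups."""

    metric: str
    groups: dict[str, tuple[float, float, int]]  # name -> (mean, sd, n)
    omnibus_p: float
    pairwise: tuple[tuple[str, str, float], ...]
    alpha_adjusted: float

    @property
    def significant(self) -> bool:
        return self.omnibus_p < ALPHA


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation between a metric and a characteristic."""

    pair: str
    rho: float
    p_value: float


@dataclass(frozen=True)
class MedianSplitResult:
    """Metric compared between >median and <=median characteristic groups."""

    characteristic: str
    metric: str
    above: tuple[float, float, int]  # mean, sd, n of metric where char > median
    below: tuple[float, float, int]  # ... where char <= median
    p_value: float


def _mean_sd(values: np.ndarray) -> tuple[float, float, int]:
    v = np.asarray(values, dtype=float)
    sd = float(v.std(ddof=1)) if len(v) > 1 else float("nan")
    return float(v.mean()), sd, len(v)


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann–Whitney U p-value; exact for small tie-free samples."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MWU_MAX_N and not ties) else "asymptotic"
    return float(
        sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def demographics_summary(table: pd.DataFrame) -> dict:
    """Descriptive summary of a cohort table (sex, age, pathology, position).

    Age is reported as mean +/- sample SD (n-1); a single-row table has no
    defined SD and reports NaN for it.
    """
    required = {"sex", "age", "pathology", "position"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    ages = table["age"].astype(float)
    return {
        "n": len(table),
        "age_mean": float(ages.mean()),
        "age_sd": float(ages.std(ddof=1)) if len(ages) > 1 else float("nan"),
        "sex_counts": table["sex"].value_counts().to_dict(),
        "pathology_counts": table["pathology"].value_counts().to_dict(),
        "position_counts": table["position"].value_counts().to_dict(),
    }


def compare_positions(
    grouped: dict[str, np.ndarray],
    metric: str = "",
    *,
    post_hoc: bool = True,
) -> GroupComparison:
    """Kruskal–Wallis omnibus across groups, optional Mann–Whitney post hocs.

    ``grouped`` maps group name (e.g. surgical position) to that group's
    metric values.  Post hoc tests run over all pairs at the
    Bonferroni-adjusted alpha = 0.05 / (number of pairs).
    """
    if len(grouped) < 2:
        raise ValueError("need at least two groups to compare")
    for name, values in grouped.items():
        if len(np.asarray(values)) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    samples = {k: np.asarray(v, dtype=float) for k, v in grouped.items()}
    omnibus = sps.kruskal(*samples.values())
    pairs = list(itertools.combinations(samples, 2))
    alpha_adjusted = ALPHA / len(pairs)
    pairwise: tuple[tuple[str, str, float], ...] = ()
    if post_hoc:
        pairwise = tuple(
            (a, b, _mannwhitney_p(samples[a], samples[b])) for a, b in pairs
        )
    return GroupComparison(
        metric=metric,
        groups={k: _mean_sd(v) for k, v in samples.items()},
        omnibus_p=float(omnibus.pvalue),
        pairwise=pairwise,
        alpha_adjusted=alpha_adjusted,
    )


def correlate(x, y, pair: str = "") -> CorrelationResult:
    """Tie-corrected Spearman rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(pair=pair, rho=float(rho), p_value=float(p))


def median_split(
    metric_values,
    characteristic_values,
    *,
    characteristic: str = "",
    metric: str = "",
) -> MedianSplitResult:
    """Compare a metric between observations above vs at-or-below the median
    of a characteristic (ties go to the <= median group), Mann–Whitney U.
    """
    m = np.asarray(metric_values, dtype=float)
    c = np.asarray(characteristic_values, dtype=float)
    if len(m) != len(c) or len(m) < 4:
        raise ValueError("median split needs matched vectors with n >= 4")
    if np.ptp(c) == 0:
        raise ValueError("all characteristic values identical; split undefined")
    med = float(np.median(c))
    above = m[c > med]
    below = m[c <= med]
    if len(above) == 0:
        raise ValueError("no observations above the median; split undefined")
    return MedianSplitResult(
        characteristic=characteristic,
        metric=metric,
        above=_mean_sd(above),
        below=_mean_sd(below),
        p_value=_mannwhitney_p(above, below),
    )
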
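"""Stratified disparity statistics for access surfaces.

Implements the summary machinery used to compare access across rural/urban
and deprivation strata: per-stratum medians, differences in medians versus a
reference stratum (reference median minus stratum median, so a positive
difference means the stratum is worse off than the reference), two-sided
Wilcoxon-Mann-Whitney rank-sum tests, a two-part zero-inflated rank-sum
variant for semicontinuous distributions with excess zeros, and per-area
percent change between two periods.

The zero-inflated test follows the standard two-part construction for
semicontinuous data: a two-proportion z statistic compares the zero
frequencies, a rank-sum z statistic compares the strictly positive values,
and the sum of the squared z's is referred to a chi-square distribution with
one degree of freedom per informative part.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, IntegrityError
from .types import AccessSurface, AreaUnit

__all__ = [
    "TestResult",
    "rank_sum_test",
    "zero_inflated_rank_sum",
    "PercentChange",
    "percent_change",
    "StratumRow",
    "StratifiedComparison",
    "stratum_medians",
    "ReportConfig",
    "disparity_report",
]

logger = logging.getLogger(__name__)

#: Combined sample size up to which the exact rank-sum distribution is used
#: (when the pooled sample has no ties).
EXACT_RANKSUM_MAX_N = 12

#: Canonical display order for the rural/urban stratum variable.
RURAL_URBAN_ORDER = ("metropolitan", "micropolitan", "small town", "rural")


@dataclass(frozen=True)
class TestResult:
    """Statistic and two-sided p-value of a location/comparison test."""

    statistic: float
    p_value: float
    method: str
    df: int | None = None
    degenerate: bool = False


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    Uses the exact null distribution when the combined sample size is at most
    ``EXACT_RANKSUM_MAX_N`` and there are no ties, and the normal
    approximation with midrank tie handling and continuity correction
    otherwise.  Empty samples are an error.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigurationError("rank_sum_test requires two nonempty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= EXACT_RANKSUM_MAX_N and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "rank-sum-exact"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=True)
        method = "rank-sum-normal"
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), method)


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Standard-normal Mann-Whitney z with midrank tie correction, no continuity."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 0.0
    return (u1 - mu) / math.sqrt(var)


def zero_inflated_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-part test for samples with excess zeros.

    Part (a) compares the proportions of zeros between the groups with a
    pooled two-proportion z statistic; part (b) compares the nonzero values
    (the strictly positive part, for nonnegative access data) with a
    rank-sum z statistic (midrank ties, no continuity correction).  The
    statistic is the sum of the squared informative z's, referred to
    chi-square with as many degrees of freedom as informative parts.  With
    no informative part (for example both samples entirely zero) the result
    is p = 1 with the degeneracy flag set.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConfigurationError("zero_inflated_rank_sum requires two nonempty samples")

    n1, n2 = x.size, y.size
    z_parts: list[float] = []

    m1, m2 = int((x == 0).sum()), int((y == 0).sum())
    pooled_zero = (m1 + m2) / (n1 + n2)
    if 0.0 < pooled_zero < 1.0:
        se = math.sqrt(pooled_zero * (1 - pooled_zero) * (1 / n1 + 1 / n2))
        z_parts.append((m1 / n1 - m2 / n2) / se)

    xp, yp = x[x != 0], y[y != 0]
    if xp.size > 0 and yp.size > 0:
        z_parts.append(_ranksum_z(xp, yp))

    if not z_parts:
        return TestResult(0.0, 1.0, "zero-inflated-rank-sum", df=0, degenerate=True)
    chi2 = float(sum(z * z for z in z_parts))
    df = len(z_parts)
    p = float(sps.chi2.sf(chi2, df))
    return TestResult(chi2, p, "zero-inflated-rank-sum", df=df)


@dataclass
class PercentChange:
    """Per-area percent change between two periods of one surface.

    ``values`` holds 100*(A_t2 - A_t1)/A_t1, with 0 where both periods are
    zero; areas going from zero to positive access have no defined percent
    change — they are NaN in ``values``, excluded from medians, and listed in
    ``undefined_ids``.
    """

    values: pd.Series
    undefined_ids: list[str] = field(default_factory=list)

    @property
    def n_undefined(self) -> int:
        return len(self.undefined_ids)

    @property
    def defined(self) -> pd.Series:
        return self.values.dropna()


def percent_change(surface_t1: AccessSurface, surface_t2: AccessSurface) -> PercentChange:
    """Per-area percent change from ``surface_t1`` to ``surface_t2``."""
    if surface_t1.mode != surface_t2.mode or surface_t1.classification != surface_t2.classification:
        raise IntegrityError("percent change requires matching mode and classification")
    if set(surface_t1.area_ids) != set(surface_t2.area_ids):
        raise IntegrityError("percent change requires identical area sets")
    a1 = surface_t1.values
    a2 = surface_t2.values.reindex(a1.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (a2 - a1) / a1
    pct = pct.where(a1 > 0)
    both_zero = (a1 == 0) & (a2 == 0)
    pct[both_zero] = 0.0
    undefined = list(a1.index[(a1 == 0) & (a2 > 0)])
    if undefined:
        logger.info("%d areas moved from zero to positive access; percent change undefined",
                    len(undefined))
    pct.name = "percent_change"
    return PercentChange(values=pct, undefined_ids=undefined)


@dataclass(frozen=True)
class StratumRow:
    """One stratum's summary: size, median, difference vs reference, test."""

    stratum: str
    n: int
    median: float
    diff_vs_ref: float | None  # None for the reference row
    p_value: float | None
    test: str | None

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise ConfigurationError("p-values must lie in [0, 1]")


@dataclass
class StratifiedComparison:
    """A block of stratum rows for one classification x metric x stratum variable."""

    classification: str
    metric: str  # "access" or "percent_change"
    stratum_variable: str
    reference: str
    rows: list[StratumRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "classification": self.classification,
                "metric": self.metric,
                "stratum_variable": self.stratum_variable,
                "stratum": [r.stratum for r in self.rows],
                "n": [r.n for r in self.rows],
                "median": [r.median for r in self.rows],
                "diff_vs_ref": [r.diff_vs_ref for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
                "test": [r.test for r in self.rows],
            }
        )

    def row(self, stratum: str) -> StratumRow:
        for r in self.rows:
            if r.stratum == stratum:
                return r
        raise KeyError(stratum)


def _stratum_order(labels: set[str], stratum_variable: str, reference: str) -> list[str]:
    if stratum_variable == "rural_urban_class":
        ordered = [s for s in RURAL_URBAN_ORDER if s in labels]
        ordered += sorted(labels - set(ordered))
    else:
        ordered = sorted(labels)
    return [reference] + [s for s in ordered if s != reference]


def _group_values(
    values: pd.Series, areas: Sequence[AreaUnit], stratum_variable: str
) -> dict[str, np.ndarray]:
    label_of = {a.area_id: getattr(a, stratum_variable) for a in areas}
    missing = [i for i in values.index if i not in label_of]
    if missing:
        raise IntegrityError(f"areas missing from table for surface IDs {missing[:5]}")
    groups: dict[str, list[float]] = {}
    for area_id, v in values.items():
        if not np.isnan(v):
            groups.setdefault(label_of[area_id], []).append(float(v))
    return {k: np.asarray(v) for k, v in groups.items()}


def stratum_medians(
    surface: AccessSurface,
    areas: Sequence[AreaUnit],
    stratum_variable: str,
    reference_label: str,
) -> StratifiedComparison:
    """Per-stratum medians and differences versus the reference stratum.

    The difference is reference median minus stratum median.  Strata with no
    areas are omitted with a logged warning.  No p-values are attached here;
    :func:`disparity_report` adds them with the appropriate test.
    """
    groups = _group_values(surface.values, areas, stratum_variable)
    if reference_label not in groups:
        raise IntegrityError(f"reference stratum {reference_label!r} has no areas")
    all_labels = {getattr(a, stratum_variable) for a in areas}
    for label in sorted(all_labels - set(groups)):
        logger.warning("stratum %r has no values; omitted", label)
    ref_median = float(np.median(groups[reference_label]))
    rows = []
    for label in _stratum_order(set(groups), stratum_variable, reference_label):
        med = float(np.median(groups[label]))
        rows.append(StratumRow(
            stratum=label, n=len(groups[label]), median=med,
            diff_vs_ref=None if label == reference_label else ref_median - med,
            p_value=None, test=None,
        ))
    return StratifiedComparison(surface.classification, "access", stratum_variable,
                                reference_label, rows)


@dataclass(frozen=True)
class ReportConfig:
    """Disparity-report settings.

    ``zero_excess_threshold`` picks the zero-inflated test whenever either
    group's zero fraction exceeds it; otherwise the plain rank-sum is used.
    """

    stratum_variables: tuple[str, ...] = ("rural_urban_class", "deprivation_quartile")
    references: Mapping[str, str] = field(
        default_factory=lambda: {"rural_urban_class": "metropolitan",
                                 "deprivation_quartile": "Q1"}
    )
    zero_excess_threshold: float = 0.25
    change_periods: tuple[str, str] | None = None  # default: first and last


def _choose_test(ref: np.ndarray, grp: np.ndarray, threshold: float) -> TestResult:
    zf_ref = float((ref == 0).mean())
    zf_grp = float((grp == 0).mean())
    if max(zf_ref, zf_grp) > threshold:
        return zero_inflated_rank_sum(grp, ref)
    return rank_sum_test(grp, ref)


def _compare(
    values: pd.Series,
    areas: Sequence[AreaUnit],
    classification: str,
    metric: str,
    stratum_variable: str,
    reference: str,
    threshold: float,
) -> StratifiedComparison:
    groups = _group_values(values, areas, stratum_variable)
    if reference not in groups:
        raise IntegrityError(f"reference stratum {reference!r} has no values")
    ref_vals = groups[reference]
    ref_median = float(np.median(ref_vals))
    rows = []
    for label in _stratum_order(set(groups), stratum_variable, reference):
        vals = groups[label]
        if label == reference:
            rows.append(StratumRow(label, len(vals), ref_median, None, None, None))
            continue
        if np.all(vals == 0) and np.all(ref_vals == 0):
            result = TestResult(0.0, 1.0, "degenerate-all-zero", degenerate=True)
        else:
            result = _choose_test(ref_vals, vals, threshold)
        rows.append(StratumRow(
            stratum=label, n=len(vals), median=float(np.median(vals)),
            diff_vs_ref=ref_median - float(np.median(vals)),
            p_value=result.p_value, test=result.method,
        ))
    return StratifiedComparison(classification, metric, stratum_variable, reference, rows)


def disparity_report(
    surfaces_by_period: Mapping[str, AccessSurface],
    areas: Sequence[AreaUnit],
    config: ReportConfig | None = None,
) -> list[StratifiedComparison]:
    """Stratified comparison blocks for access levels and percent change.

    ``surfaces_by_period`` maps ordered period labels to surfaces of one mode
    and classification.  Access levels are summarised for the first change
    period; percent change between the configured (default first and last)
    periods is added when at least two periods are present.  The test for
    each stratum-vs-reference contrast is the zero-inflated variant when
    either group's zero fraction exceeds the configured threshold, else the
    plain rank-sum; the choice is recorded per row.
    """
    config = config or ReportConfig()
    if not surfaces_by_period:
        raise ConfigurationError("disparity_report needs at least one period")
    periods = list(surfaces_by_period)
    if config.change_periods is not None:
        t1, t2 = config.change_periods
        if t1 not in surfaces_by_period or t2 not in surfaces_by_period:
            raise ConfigurationError(f"change_periods {config.change_periods} not all present")
    else:
        t1, t2 = periods[0], periods[-1]
    base = surfaces_by_period[t1]

    out: list[StratifiedComparison] = []
    for var in config.stratum_variables:
        ref = config.references[var]
        out.append(_compare(base.values, areas, base.classification, "access", var, ref,
                            config.zero_excess_threshold))
    if len(periods) >= 2 and t1 != t2:
        change = percent_change(surfaces_by_period[t1], surfaces_by_period[t2])
        for var in config.stratum_variables:
            ref = config.references[var]
            out.append(_compare(change.values, areas, base.classification, "percent_change",
                                var, ref, config.zero_excess_threshold))
    return out
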
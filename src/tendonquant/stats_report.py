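"""Group comparisons and reporting conventions.

Two-group comparisons use either the Mann-Whitney-Wilcoxon rank-sum test
(exact null distribution for small untied samples, normal approximation
with tie correction otherwise) or the pooled-variance Student's t-test.
Summaries follow the figure conventions of the quantification scheme:
type-7 quantiles, boxplot hinges at the quartiles with whiskers at the
most extreme data points within 1.5x IQR, values reported as median (IQR),
and normalization of treatment groups to the control-group median (the
control's own median maps to 100% by construction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "BoxplotSummary",
    "MedianIQR",
    "mann_whitney",
    "students_t",
    "boxplot_summary",
    "normalize_to_control_median",
    "report_medians",
    "write_manifest",
]

_ALTERNATIVES = {"two_sided": "two-sided", "two-sided": "two-sided", "less": "less", "greater": "greater"}


def _summary(values: np.ndarray) -> dict:
    q1, q3 = np.percentile(values, [25, 75])
    return {
        "n": int(values.size),
        "median": float(np.median(values)),
        "iqr": float(q3 - q1),
        "mean": float(values.mean()),
        "sem": float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0,
    }


@dataclass
class GroupComparison:
    test: str
    alternative: str
    statistic: float
    pvalue: float
    method: str  # "exact" or "asymptotic" (Mann-Whitney); "pooled" (t)
    summaries: dict = field(default_factory=dict)


def mann_whitney(a, b, alternative: str = "two_sided") -> GroupComparison:
    """Mann-Whitney-Wilcoxon rank-sum test.

    Uses the exact null distribution when n_a * n_b <= 400 and the data are
    untied, otherwise the normal approximation with tie correction and
    continuity correction.  Two completely identical groups give p = 1 by
    convention (the statistic carries no information).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    alt = _ALTERNATIVES.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    use_exact = (a.size * b.size <= 400) and not has_ties
    if np.ptp(combined) == 0:
        # fully degenerate: all observations equal in both groups
        return GroupComparison(
            test="mann_whitney",
            alternative=alt,
            statistic=float(a.size * b.size / 2),
            pvalue=1.0,
            method="asymptotic",
            summaries={"a": _summary(a), "b": _summary(b)},
        )
    res = stats.mannwhitneyu(
        a, b, alternative=alt, method="exact" if use_exact else "asymptotic"
    )
    return GroupComparison(
        test="mann_whitney",
        alternative=alt,
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        method="exact" if use_exact else "asymptotic",
        summaries={"a": _summary(a), "b": _summary(b)},
    )


def students_t(a, b, alternative: str = "two_sided") -> GroupComparison:
    """Pooled-variance two-sample Student's t-test, df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if pooled == 0:
        raise ValueError("zero pooled variance: t-statistic undefined")
    alt = _ALTERNATIVES.get(alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    res = stats.ttest_ind(a, b, equal_var=True, alternative=alt)
    return GroupComparison(
        test="students_t",
        alternative=alt,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method="pooled",
        summaries={"a": _summary(a), "b": _summary(b)},
    )


@dataclass
class BoxplotSummary:
    """Boxplot fields: hinges at the quartiles (type-7), whiskers at the most
    extreme data points within 1.5x IQR of the hinges, the rest outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def boxplot_summary(values) -> BoxplotSummary:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # type-7 interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(values[(values < lo_fence) | (values > hi_fence)]),
    )


def normalize_to_control_median(values, control_values) -> np.ndarray:
    """Express values as percent of the control-group median."""
    values = np.asarray(values, dtype=float)
    control_median = float(np.median(np.asarray(control_values, dtype=float)))
    if control_median == 0:
        raise ValueError("control median is zero: normalization undefined")
    return 100.0 * values / control_median


@dataclass
class MedianIQR:
    median: float
    iqr: float

    def __str__(self) -> str:
        return f"{self.median:g} ({self.iqr:g})"


def report_medians(values) -> MedianIQR:
    """Median and IQR (q3 - q1, type-7 quantiles) for table-style reporting."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return MedianIQR(median=float(med), iqr=float(q3 - q1))


def write_manifest(path: str | Path, config: dict, seed: int | None = None) -> None:
    """Write a run manifest (config echo, package version, seed) next to outputs."""
    from . import __version__

    manifest = {"package": "tendonquant", "version": __version__, "seed": seed, "config": config}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
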
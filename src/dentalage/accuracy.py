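"""Stratified accuracy of dental-age estimates against chronological age.

For each age-sex stratum the estimated dental ages (EDA) are compared with
the chronological ages (CA) by an independent-samples t-test on the two
columns (pooled-variance Student's t by default, mirroring the classical
reporting style for this design; Welch and paired variants are available).
p-values are bucketed into the conventional significance categories, and the
overall bias is summarized by an OLS regression of the per-child difference
EDA - CA on CA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .cohort import AgeGroup
from .errors import DegenerateDataError, InsufficientDataError

NON_SIGNIFICANT = "non-significant"
SIGNIFICANT = "significant"
HIGHLY_SIGNIFICANT = "highly significant"
VERY_HIGHLY_SIGNIFICANT = "very highly significant"


def classify_p(p: float) -> str:
    """Bucket a p-value: >=0.05 ns; <0.05 / <0.01 / <0.001 increasingly strong.

    The most extreme applicable label is returned; the 0.05 boundary itself
    is non-significant.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return VERY_HIGHLY_SIGNIFICANT
    if p < 0.01:
        return HIGHLY_SIGNIFICANT
    if p < 0.05:
        return SIGNIFICANT
    return NON_SIGNIFICANT


class SummaryComparison(NamedTuple):
    mean_diff: float
    t_stat: float
    p_value: float
    degenerate: bool = False


def compare_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    *,
    welch: bool = False,
) -> SummaryComparison:
    """Two-sample t-test from summary statistics (sample SDs, n-1 denominator).

    Returns ``(mean_diff, t, p)`` with ``mean_diff = mean2 - mean1`` and a
    two-sided p.  Default is the pooled-variance Student's t with
    df = n1+n2-2; ``welch=True`` uses Welch's unequal-variance t.

    Degenerate convention: with both SDs zero, equal means give (0, 0, 1) and
    unequal means give (diff, inf, 0) — both flagged ``degenerate``.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(f"need n>=2 in both samples, got {n1} and {n2}")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    diff = mean2 - mean1
    if sd1 == 0.0 and sd2 == 0.0:
        if diff == 0.0:
            return SummaryComparison(0.0, 0.0, 1.0, degenerate=True)
        return SummaryComparison(diff, math.copysign(math.inf, diff), 0.0, degenerate=True)
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return SummaryComparison(diff, t, min(p, 1.0))


@dataclass(frozen=True)
class GroupSummary:
    """One stratum's EDA-vs-CA comparison (a validation-report row)."""

    group: AgeGroup | None
    sex: str | None
    n: int
    ca_mean: float
    ca_sd: float
    eda_mean: float
    eda_sd: float
    mean_diff: float
    t_stat: float | None
    p_value: float | None
    category: str | None

    @property
    def label(self) -> str:
        return self.group.label if self.group is not None else "total"


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    return float(np.mean(values)), float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def compare_group(
    ca_values: Sequence[float],
    eda_values: Sequence[float],
    *,
    group: AgeGroup | None = None,
    sex: str | None = None,
    welch: bool = False,
    paired: bool = False,
) -> GroupSummary:
    """Compare one stratum's EDA column against its CA column.

    Means and sample SDs (n-1) are computed per column; the test is the
    unpaired two-sample t of :func:`compare_from_summary` on the identical
    summary statistics (``paired=True`` switches to a paired t on the
    per-child differences, requiring equal lengths).
    """
    ca = np.asarray(ca_values, dtype=float)
    eda = np.asarray(eda_values, dtype=float)
    if len(ca) == 0 or len(eda) == 0:
        raise InsufficientDataError("empty sample")
    if len(ca) < 2 or len(eda) < 2:
        raise InsufficientDataError("need at least 2 values per column for the t-test")
    ca_mean, ca_sd = _mean_sd(ca)
    eda_mean, eda_sd = _mean_sd(eda)
    if paired:
        if len(ca) != len(eda):
            raise InsufficientDataError("paired test requires equal-length columns")
        d = eda - ca
        sd_d = float(np.std(d, ddof=1))
        if sd_d == 0.0:
            cmp_ = SummaryComparison(
                float(np.mean(d)),
                0.0 if np.mean(d) == 0 else math.copysign(math.inf, float(np.mean(d))),
                1.0 if np.mean(d) == 0 else 0.0,
                degenerate=True,
            )
        else:
            t = float(np.mean(d)) / (sd_d / math.sqrt(len(d)))
            p = 2.0 * stats.t.sf(abs(t), len(d) - 1)
            cmp_ = SummaryComparison(float(np.mean(d)), t, min(p, 1.0))
    else:
        cmp_ = compare_from_summary(
            ca_mean, ca_sd, len(ca), eda_mean, eda_sd, len(eda), welch=welch
        )
    return GroupSummary(
        group=group,
        sex=sex,
        n=len(ca),
        ca_mean=ca_mean,
        ca_sd=ca_sd,
        eda_mean=eda_mean,
        eda_sd=eda_sd,
        mean_diff=cmp_.mean_diff,
        t_stat=cmp_.t_stat,
        p_value=cmp_.p_value,
        category=classify_p(cmp_.p_value),
    )


def descriptive_group(
    ca_values: Sequence[float],
    eda_values: Sequence[float],
    *,
    group: AgeGroup | None = None,
    sex: str | None = None,
) -> GroupSummary:
    """Descriptive-only stratum row (used when n < 2 makes the t undefined)."""
    ca = np.asarray(ca_values, dtype=float)
    eda = np.asarray(eda_values, dtype=float)
    ca_mean, ca_sd = _mean_sd(ca)
    eda_mean, eda_sd = _mean_sd(eda)
    return GroupSummary(
        group=group, sex=sex, n=len(ca), ca_mean=ca_mean, ca_sd=ca_sd,
        eda_mean=eda_mean, eda_sd=eda_sd, mean_diff=eda_mean - ca_mean,
        t_stat=None, p_value=None, category=None,
    )


@dataclass(frozen=True)
class BiasFit:
    """OLS fit of the difference EDA - CA on CA, plus overall bias summary."""

    slope: float
    intercept: float
    overall_mean_diff: float
    overall_sd: float
    n: int


def bias_regression(ca_values: Sequence[float], diffs: Sequence[float]) -> BiasFit:
    """Least-squares line of (EDA - CA) differences against chronological age."""
    ca = np.asarray(ca_values, dtype=float)
    d = np.asarray(diffs, dtype=float)
    if len(ca) != len(d) or len(ca) < 2:
        raise InsufficientDataError("need equal-length arrays with at least 2 points")
    if np.ptp(ca) == 0.0:
        raise DegenerateDataError("all chronological ages identical: slope undefined")
    slope, intercept = np.polyfit(ca, d, 1)
    return BiasFit(
        slope=float(slope),
        intercept=float(intercept),
        overall_mean_diff=float(np.mean(d)),
        overall_sd=float(np.std(d, ddof=1)),
        n=len(d),
    )


def plot_bias(ca_values, diffs, path, title: str = "EDA - CA vs CA") -> None:
    """Scatter of differences vs CA with the fitted regression line (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = bias_regression(ca_values, diffs)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ca_values, diffs, s=14, alpha=0.7)
    xs = np.linspace(min(ca_values), max(ca_values), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="C3")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("chronological age (years)")
    ax.set_ylabel("EDA - CA (years)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
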
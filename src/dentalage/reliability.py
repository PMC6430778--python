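"""Test-retest reliability of stage ratings.

A fixed fraction (default 20%) of a cohort is re-scored after an interval;
agreement between the two rating passes is summarized by percent exact
agreement with counts of one-stage-ahead / one-stage-behind offsets,
unweighted Cohen's kappa (with a large-sample z-test against kappa = 0), and
the Pearson correlation between the test and retest maturity scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError
from .staging import LEFT_MANDIBULAR_TEETH, ScoreTable, Stage, compute_dms, resolve_stage


def select_retest_subsample(cohort: Sequence, fraction: float = 0.20, seed=None) -> list:
    """Simple random subsample without replacement of round(fraction * n) records.

    ``round`` is half-up, so 20% of 160 selects exactly 32.  ``seed`` may be
    an int or a ``numpy.random.Generator``; order follows the draw.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    n = len(cohort)
    k = int(math.floor(fraction * n + 0.5))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    return [cohort[i] for i in idx]


class AgreementResult(NamedTuple):
    percent: float
    n_ahead: int
    n_behind: int


def percent_agreement(ratings1: Sequence[Stage], ratings2: Sequence[Stage]) -> AgreementResult:
    """Percent of exactly matching stages, plus one-stage offset counts.

    ``n_ahead`` counts items where the retest (``ratings2``) is one stage
    later than the test, ``n_behind`` one stage earlier.
    """
    if len(ratings1) != len(ratings2):
        raise InsufficientDataError("rating sequences differ in length")
    if len(ratings1) == 0:
        raise InsufficientDataError("empty rating sequences")
    deltas = [int(b) - int(a) for a, b in zip(ratings1, ratings2)]
    matches = sum(d == 0 for d in deltas)
    return AgreementResult(
        percent=100.0 * matches / len(deltas),
        n_ahead=sum(d == 1 for d in deltas),
        n_behind=sum(d == -1 for d in deltas),
    )


class KappaResult(NamedTuple):
    kappa: float
    p_value: float
    degenerate: bool = False


def cohens_kappa(ratings1: Sequence, ratings2: Sequence) -> KappaResult:
    """Unweighted Cohen's kappa with a large-sample z-test against kappa = 0.

    kappa = (p_o - p_e)/(1 - p_e), with chance agreement p_e from the product
    of the two raters' marginal proportions; the null standard error is the
    Fleiss large-sample form.  When both raters are constant and identical
    (p_e = 1) kappa is undefined and is reported as 1 with ``degenerate`` set.
    """
    if len(ratings1) != len(ratings2):
        raise InsufficientDataError("rating sequences differ in length")
    n = len(ratings1)
    if n < 2:
        raise InsufficientDataError("need >= 2 paired ratings")
    labels = sorted(set(ratings1) | set(ratings2))
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    conf = np.zeros((k, k))
    for a, b in zip(ratings1, ratings2):
        conf[index[a], index[b]] += 1
    conf /= n
    p_o = float(np.trace(conf))
    row = conf.sum(axis=1)
    col = conf.sum(axis=0)
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        return KappaResult(1.0, float("nan"), degenerate=True)
    kappa = (p_o - p_e) / (1.0 - p_e)
    # Fleiss null-hypothesis SE for testing kappa = 0
    se0_num = p_e + p_e**2 - float(np.sum(row * col * (row + col)))
    se0 = math.sqrt(max(se0_num, 0.0)) / ((1.0 - p_e) * math.sqrt(n))
    if se0 == 0.0:
        return KappaResult(kappa, float("nan"), degenerate=True)
    z = kappa / se0
    return KappaResult(kappa, float(2.0 * stats.norm.sf(abs(z))))


def pearson_testretest(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r between test and retest scores, with two-sided t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("need >= 3 paired scores")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateDataError("zero variance in a score sequence")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ReliabilityResult:
    """Pooled test-retest agreement over all seven teeth of a subsample."""

    n_items: int
    percent_agreement: float
    n_ahead: int
    n_behind: int
    kappa: float
    kappa_p: float
    pearson_r: float
    pearson_p: float
    per_tooth: dict[int, AgreementResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_items": self.n_items,
            "percent_agreement": self.percent_agreement,
            "n_ahead": self.n_ahead,
            "n_behind": self.n_behind,
            "kappa": self.kappa,
            "kappa_p": self.kappa_p,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "per_tooth": {
                str(t): {"percent": r.percent, "n_ahead": r.n_ahead, "n_behind": r.n_behind}
                for t, r in self.per_tooth.items()
            },
        }


def assess_reliability(
    records: Sequence,
    retest_stages: Mapping[str, Mapping[int, Stage]],
    table: ScoreTable,
) -> ReliabilityResult:
    """Compare a subsample's original resolved stages against a retest pass.

    Stage labels are pooled across all seven teeth for percent agreement and
    kappa (a per-tooth agreement breakdown is also reported); the Pearson
    correlation is computed on the per-child maturity scores of the two
    passes.
    """
    r1, r2 = [], []
    by_tooth: dict[int, tuple[list, list]] = {t: ([], []) for t in LEFT_MANDIBULAR_TEETH}
    dms1, dms2 = [], []
    for rec in records:
        retest = retest_stages[rec.child_id]
        score2 = 0.0
        for tooth in LEFT_MANDIBULAR_TEETH:
            s1 = resolve_stage(rec, tooth)
            s2 = retest[tooth]
            r1.append(s1)
            r2.append(s2)
            by_tooth[tooth][0].append(s1)
            by_tooth[tooth][1].append(s2)
            score2 += table.score(rec.sex, tooth, s2)
        dms1.append(compute_dms(rec, table))
        dms2.append(score2)
    agree = percent_agreement(r1, r2)
    kap = cohens_kappa(r1, r2)
    r, p = pearson_testretest(dms1, dms2)
    return ReliabilityResult(
        n_items=len(r1),
        percent_agreement=agree.percent,
        n_ahead=agree.n_ahead,
        n_behind=agree.n_behind,
        kappa=kap.kappa,
        kappa_p=kap.p_value,
        pearson_r=r,
        pearson_p=p,
        per_tooth={t: percent_agreement(a, b) for t, (a, b) in by_tooth.items()},
    )
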
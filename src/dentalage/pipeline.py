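"""Full study orchestration: simulate/score/estimate/validate/calibrate/reliability.

:func:`run_study` executes the stages in the study's order — maturity
scoring, dental-age estimation, exclusion of estimates below the study
range, yearly age grouping, per-stratum accuracy testing, growth-curve
calibration, and a test-retest reliability pass — and assembles everything
into a serializable :class:`StudyReport`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import accuracy, calibration, reliability
from .cohort import (
    AGE_GROUPS,
    ChildRecord,
    Exclusion,
    assign_age_group,
    exclude_below_min_age,
)
from .conversion import ConversionTable, dms_to_age, packaged_conversion_table
from .errors import DentalAgeError, UnscorableToothError
from .staging import SEXES, ScoreTable, compute_dms, packaged_score_table
from .synthetic import GeneratorConfig, generate_cohort, generate_retest

logger = logging.getLogger(__name__)


@dataclass
class StudyReport:
    """Everything a study reproduction produces, in one serializable object."""

    counts: dict[str, dict[str, int]]
    group_summaries: list[accuracy.GroupSummary]
    overall_summaries: list[accuracy.GroupSummary]
    bias_fits: dict[str, accuracy.BiasFit]
    calibrations: dict[str, calibration.CalibrationResult]
    reliability: reliability.ReliabilityResult | None
    exclusions: list[Exclusion]
    provenance: dict = field(default_factory=dict)

    @property
    def total_n(self) -> int:
        return sum(sum(by_group.values()) for by_group in self.counts.values())

    def to_dict(self) -> dict:
        def summary_row(s: accuracy.GroupSummary) -> dict:
            return {
                "group": s.label,
                "sex": s.sex,
                "n": s.n,
                "ca_mean": s.ca_mean,
                "ca_sd": s.ca_sd,
                "eda_mean": s.eda_mean,
                "eda_sd": s.eda_sd,
                "mean_diff": s.mean_diff,
                "t": s.t_stat,
                "p": s.p_value,
                "category": s.category,
            }

        return {
            "counts": self.counts,
            "groups": [summary_row(s) for s in self.group_summaries],
            "overall": [summary_row(s) for s in self.overall_summaries],
            "bias": {
                sex: {
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "overall_mean_diff": f.overall_mean_diff,
                    "overall_sd": f.overall_sd,
                    "n": f.n,
                }
                for sex, f in self.bias_fits.items()
            },
            "calibration": {
                sex: {
                    "a": r.model.a,
                    "b": r.model.b,
                    "c": r.model.c,
                    "r_squared": r.r_squared,
                    "spearman_rho": r.spearman_rho,
                    "fit_method": r.fit_method,
                    "n": r.n,
                    "converged": r.converged,
                }
                for sex, r in self.calibrations.items()
            },
            "reliability": self.reliability.to_dict() if self.reliability else None,
            "exclusions": [e._asdict() for e in self.exclusions],
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def table2_frame(self) -> pd.DataFrame:
        """Validation report mirroring the classical per-stratum table layout."""
        rows = [
            {
                "group": s.label,
                "sex": s.sex,
                "n": s.n,
                "ca_mean": round(s.ca_mean, 2),
                "ca_sd": round(s.ca_sd, 2),
                "eda_mean": round(s.eda_mean, 2),
                "eda_sd": round(s.eda_sd, 2),
                "mean_diff": round(s.mean_diff, 2),
                "t": None if s.t_stat is None else round(s.t_stat, 3),
                "p": None if s.p_value is None else round(s.p_value, 4),
                "category": s.category,
            }
            for s in self.group_summaries + self.overall_summaries
        ]
        return pd.DataFrame(rows)


def _config_hash(config: GeneratorConfig) -> str:
    payload = json.dumps(
        {
            "group_sizes": sorted((f"{k[0]}{k[1]}", v) for k, v in config.group_sizes.items()),
            "bias": sorted((f"{k[0]}{k[1]}", v) for k, v in config.bias_by_group.items()),
            "dms_noise_sd": config.dms_noise_sd,
            "missing_left_rate": config.missing_left_rate,
            "missing_both_rate": config.missing_both_rate,
            "rater_flip_rate": config.rater_flip_rate,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_study(
    cohort: Sequence[ChildRecord] | None = None,
    *,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    score_table: ScoreTable | None = None,
    conversion_table: ConversionTable | None = None,
    min_eda: float = 2.5,
    retest_fraction: float = 0.20,
    rater_flip_rate: float | None = None,
    calibration_asymptote: float | str = 12.0,
) -> StudyReport:
    """Run the full pipeline and return a :class:`StudyReport`.

    Give either an existing ``cohort`` or a generator ``config`` (``seed``
    overrides the config's seed); stages run in the study's order: score ->
    estimate -> exclude EDA < ``min_eda`` -> group -> compare -> calibrate ->
    reliability.  Deterministic for a fixed seed: cohort generation, retest
    subsampling and rating jitter each draw from an independent stream
    derived from it.
    """
    score_table = score_table or packaged_score_table()
    conversion_table = conversion_table or packaged_conversion_table()
    if cohort is None:
        config = config or GeneratorConfig()
        if seed is not None:
            config = config.with_seed(seed)
        cohort = generate_cohort(config, score_table)
    root_seed = config.seed if config is not None else (seed if seed is not None else 0)
    flip_rate = rater_flip_rate
    if flip_rate is None:
        flip_rate = config.rater_flip_rate if config is not None else 0.107

    exclusions: list[Exclusion] = []

    # stage 1: maturity scoring (records with an unscorable tooth are excluded,
    # mirroring the radiograph-quality criterion)
    scored: list[ChildRecord] = []
    for rec in cohort:
        try:
            rec.dms = compute_dms(rec, score_table)
        except UnscorableToothError as exc:
            exclusions.append(Exclusion(rec.child_id, "unscorable tooth", float(exc.tooth)))
            continue
        scored.append(rec)
    logger.info("score: %d in, %d scorable", len(cohort), len(scored))

    # stage 2: dental-age estimation via the conversion table
    for rec in scored:
        rec.eda = dms_to_age(rec.dms, rec.sex, conversion_table, policy="clamp")

    # stage 3: study-range exclusion
    retained, _, log = exclude_below_min_age(scored, min_eda=min_eda)
    exclusions.extend(log)
    logger.info("exclude: %d in, %d retained", len(scored), len(retained))

    # stage 4: grouping + per-stratum comparison
    counts: dict[str, dict[str, int]] = {s: {} for s in SEXES}
    group_summaries: list[accuracy.GroupSummary] = []
    overall: list[accuracy.GroupSummary] = []
    in_range = [r for r in retained if 3.0 <= r.ca < 11.0]
    for sex in SEXES:
        sex_records = [r for r in in_range if r.sex == sex]
        for group in AGE_GROUPS:
            members = [r for r in sex_records if assign_age_group(r.ca) == group]
            if not members:
                continue
            counts[sex][group.label] = len(members)
            ca = [r.ca for r in members]
            eda = [r.eda for r in members]
            if len(members) >= 2:
                group_summaries.append(
                    accuracy.compare_group(ca, eda, group=group, sex=sex)
                )
            else:
                group_summaries.append(
                    accuracy.descriptive_group(ca, eda, group=group, sex=sex)
                )
        if len(sex_records) >= 2:
            overall.append(
                accuracy.compare_group(
                    [r.ca for r in sex_records], [r.eda for r in sex_records], sex=sex
                )
            )

    # stage 5: overall bias regression per sex
    bias_fits = {}
    for sex in SEXES:
        sex_records = [r for r in in_range if r.sex == sex]
        if len(sex_records) >= 2 and len({r.ca for r in sex_records}) > 1:
            bias_fits[sex] = accuracy.bias_regression(
                [r.ca for r in sex_records], [r.eda - r.ca for r in sex_records]
            )

    # stage 6: growth-curve calibration per sex
    calibrations = {}
    for sex in SEXES:
        sex_records = [r for r in in_range if r.sex == sex]
        if len(sex_records) >= 3:
            try:
                calibrations[sex] = calibration.fit_logistic_growth(
                    [r.dms for r in sex_records],
                    [r.ca for r in sex_records],
                    sex=sex,
                    asymptote=calibration_asymptote,
                )
            except DentalAgeError as exc:
                logger.warning("calibration (%s) skipped: %s", sex, exc)

    # stage 7: test-retest reliability on a random subsample
    rel = None
    if retained and retest_fraction > 0:
        sub = reliability.select_retest_subsample(
            retained, retest_fraction, seed=np.random.default_rng([1, root_seed])
        )
        if sub:
            retest = generate_retest(
                sub, score_table, flip_rate, seed=np.random.default_rng([2, root_seed])
            )
            try:
                rel = reliability.assess_reliability(sub, retest, score_table)
            except DentalAgeError as exc:
                logger.warning("reliability skipped: %s", exc)

    provenance = {
        "seed": root_seed,
        "score_table": score_table.name,
        "conversion_table": conversion_table.name,
        "generator_config": _config_hash(config) if config is not None else None,
        "min_eda": min_eda,
        "retest_fraction": retest_fraction,
    }
    return StudyReport(
        counts=counts,
        group_summaries=group_summaries,
        overall_summaries=overall,
        bias_fits=bias_fits,
        calibrations=calibrations,
        reliability=rel,
        exclusions=exclusions,
        provenance=provenance,
    )
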
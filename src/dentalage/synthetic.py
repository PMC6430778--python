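"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a cross-sectional pediatric radiograph study: children
in yearly age-sex cells (default cell counts reproduce a 160-child cohort of
74 boys and 86 girls aged 3 to <11), a per-cell systematic bias of the
estimated dental age relative to the chronological age, year-scale Gaussian
noise on the latent dental age, occasional missing left teeth with the
contralateral available, and a stage-flip retest process for reliability
studies.

The latent dental age is mapped to a maturity score by inverting a monotone
DMS -> age map (by default the packaged conversion table, whose top end —
like the classical percentile tables — extends well beyond age 11 so that
the oldest cells remain representable), and the score is realized as
per-tooth stages.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cohort import ChildRecord, compute_chronological_age
from .conversion import (
    ConversionTable,
    PredictionModel,
    SexConversion,
    packaged_conversion_table,
)
from .errors import ConfigError
from .staging import (
    LEFT_MANDIBULAR_TEETH,
    ScoreTable,
    Stage,
    contralateral,
    packaged_score_table,
)

#: Default cell counts (sex, group lower bound) -> children; 74 M + 86 F = 160.
DEFAULT_GROUP_SIZES: Mapping[tuple[str, int], int] = {
    ("M", 3): 10, ("M", 4): 10, ("M", 5): 11, ("M", 6): 5,
    ("M", 7): 10, ("M", 8): 10, ("M", 9): 8, ("M", 10): 10,
    ("F", 3): 8, ("F", 4): 9, ("F", 5): 15, ("F", 6): 10,
    ("F", 7): 10, ("F", 8): 10, ("F", 9): 12, ("F", 10): 12,
}

#: Default per-cell mean EDA - CA offsets (years): systematic overestimation
#: in most cells, mild underestimation in the oldest ones.
DEFAULT_BIAS: Mapping[tuple[str, int], float] = {
    ("M", 3): 1.19, ("M", 4): 0.25, ("M", 5): 0.90, ("M", 6): 0.18,
    ("M", 7): 0.58, ("M", 8): 0.25, ("M", 9): -0.60, ("M", 10): 0.57,
    ("F", 3): 0.87, ("F", 4): 0.60, ("F", 5): 0.60, ("F", 6): 0.44,
    ("F", 7): 0.23, ("F", 8): 0.08, ("F", 9): -0.06, ("F", 10): -0.008,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for :func:`generate_cohort`.

    ``age_map`` is the invertible DMS <-> dental-age map (a
    :class:`ConversionTable` or per-sex :class:`PredictionModel` mapping);
    ``None`` selects the packaged conversion table.  ``dms_noise_sd`` is the
    SD (years) of the Gaussian noise added to the latent dental age before
    inversion.  ``rater_flip_rate`` is the per-tooth probability that a
    retest rating moves one stage (chosen to emulate ~89% retest agreement).
    """

    group_sizes: Mapping[tuple[str, int], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    bias_by_group: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_BIAS)
    )
    age_map: ConversionTable | Mapping[str, PredictionModel] | None = None
    dms_noise_sd: float = 0.30
    missing_left_rate: float = 0.05
    missing_both_rate: float = 0.0
    rater_flip_rate: float = 0.107
    seed: int = 0

    def __post_init__(self):
        if any(n < 0 for n in self.group_sizes.values()):
            raise ConfigError("group sizes must be non-negative")
        for name in ("missing_left_rate", "missing_both_rate", "rater_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.dms_noise_sd < 0:
            raise ConfigError("dms_noise_sd must be >= 0")

    def sex_map(self, sex: str):
        """The AgeMap (age()/dms()/age_range()) for one sex."""
        amap = self.age_map
        if amap is None:
            amap = packaged_conversion_table()
        if isinstance(amap, ConversionTable):
            return SexConversion(amap, sex)
        return amap[sex]

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def assign_stages_from_dms(dms: float, table: ScoreTable, sex: str) -> dict[int, Stage]:
    """Deterministic per-tooth stage assignment realizing (at most) ``dms``.

    Each tooth first takes the largest stage whose score does not exceed the
    tooth's proportional share (dms/100) * score(tooth, H); the leftover
    score mass is then packed greedily, promoting whichever single-stage step
    still fits (smallest first).  The realized score re-computed from the
    stages never exceeds ``dms``, and at termination no further promotion
    fits, so the shortfall is below the smallest available stage step — in
    particular at most the table's largest single-stage increment.
    """
    if not 0.0 <= dms <= 100.0:
        raise ValueError(f"dms {dms} outside [0, 100]")
    stages = {}
    for tooth in LEFT_MANDIBULAR_TEETH:
        share = (dms / 100.0) * table.max_score(sex, tooth)
        stage = Stage.S0
        for s in range(1, 9):
            if table.score(sex, tooth, Stage(s)) <= share:
                stage = Stage(s)
            else:
                break
        stages[tooth] = stage
    # greedy refill of the per-tooth rounding losses
    realized = _realized_dms(stages, table, sex)
    while True:
        best_tooth, best_inc = None, None
        for tooth in LEFT_MANDIBULAR_TEETH:
            s = stages[tooth]
            if s == Stage.H:
                continue
            inc = table.score(sex, tooth, Stage(s + 1)) - table.score(sex, tooth, s)
            if realized + inc <= dms + 1e-9 and (best_inc is None or inc < best_inc):
                best_tooth, best_inc = tooth, inc
        if best_tooth is None:
            return stages
        stages[best_tooth] = Stage(stages[best_tooth] + 1)
        realized += best_inc


def _realized_dms(stages: Mapping[int, Stage], table: ScoreTable, sex: str) -> float:
    return float(sum(table.score(sex, t, stages[t]) for t in LEFT_MANDIBULAR_TEETH))


def _assign_stages_nearest(dms: float, table: ScoreTable, sex: str) -> dict[int, Stage]:
    """Packed assignment refined by greedy single-stage promotions.

    :func:`assign_stages_from_dms` never overshoots, so a cohort built with
    it alone would carry a small systematic negative score offset.  Promoting
    one further stage wherever that shrinks |realized - dms| keeps the
    realized score approximately centred on the latent one.
    """
    stages = assign_stages_from_dms(dms, table, sex)
    gap = dms - _realized_dms(stages, table, sex)
    while True:
        best_tooth, best_gap = None, gap
        for tooth in LEFT_MANDIBULAR_TEETH:
            s = stages[tooth]
            if s == Stage.H:
                continue
            delta = table.score(sex, tooth, Stage(s + 1)) - table.score(sex, tooth, s)
            if abs(gap - delta) < abs(best_gap) - 1e-12:
                best_tooth, best_gap = tooth, gap - delta
        if best_tooth is None:
            return stages
        stages[best_tooth] = Stage(stages[best_tooth] + 1)
        gap = best_gap


def perturb_ratings(
    stages: Mapping[int, Stage], rater_flip_rate: float, rng
) -> dict[int, Stage]:
    """Independent one-stage rating jitter, clamped at the S0/H ends.

    Each tooth's stage moves one step up or down (equal probability) with
    probability ``rater_flip_rate``; a move past an end stays at the end.
    """
    if not 0.0 <= rater_flip_rate <= 1.0:
        raise ValueError(f"rate {rater_flip_rate} outside [0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = {}
    for tooth in sorted(stages):
        s = int(stages[tooth])
        if rng.random() < rater_flip_rate:
            s = min(8, max(0, s + (1 if rng.random() < 0.5 else -1)))
        out[tooth] = Stage(s)
    return out


def generate_cohort(
    config: GeneratorConfig | None = None, table: ScoreTable | None = None
) -> list[ChildRecord]:
    """Draw a synthetic cohort under ``config`` (byte-reproducible per seed).

    Per cell: CA is uniform on the yearly interval; the latent dental age is
    CA + cell bias + Gaussian(0, dms_noise_sd), clipped just inside the age
    map's representable span; the latent maturity score is the map's inverse
    at that age, realized as per-tooth stages.  Birth dates sit on a
    first-of-month grid and the radiograph date is derived from the CA.  With
    probability ``missing_left_rate`` a tooth's stage is recorded only on the
    contralateral side; with ``missing_both_rate`` both sides are absent
    (making the record unscorable downstream).
    """
    config = config or GeneratorConfig()
    table = table or packaged_score_table()
    rng = np.random.default_rng(config.seed)
    records = []
    for (sex, lower), count in sorted(config.group_sizes.items()):
        amap = config.sex_map(sex)
        age_lo, age_hi = amap.age_range()
        lo_clip, hi_clip = age_lo + 1e-6, age_hi - 1e-6
        if lo_clip >= hi_clip or lower + 1 <= lo_clip or lower >= hi_clip:
            raise ConfigError(
                f"cell (sex={sex}, group={lower} to <{lower + 1}) lies outside the "
                f"age map's representable span ({age_lo:.2f}, {age_hi:.2f})"
            )
        bias = config.bias_by_group.get((sex, lower), 0.0)
        for i in range(count):
            ca_target = rng.uniform(lower + 0.01, lower + 0.99)
            dob = dt.date(2007 + (lower % 2), (i % 12) + 1, 1)
            dor = dob + dt.timedelta(days=round(ca_target * 365.25))
            ca = compute_chronological_age(dob, dor)
            target_da = ca + bias + rng.normal(0.0, config.dms_noise_sd)
            target_da = min(max(target_da, lo_clip), hi_clip)
            latent = amap.dms(target_da)
            latent = min(max(latent, 0.0), 100.0)
            stages7 = _assign_stages_nearest(latent, table, sex)
            stages: dict[int, Stage] = {}
            for tooth, stage in stages7.items():
                u = rng.random()
                if u < config.missing_both_rate:
                    continue
                if u < config.missing_both_rate + config.missing_left_rate:
                    stages[contralateral(tooth)] = stage
                else:
                    stages[tooth] = stage
            records.append(
                ChildRecord(
                    child_id=f"{sex}{lower:02d}-{i:03d}",
                    sex=sex,
                    dob=dob,
                    dor=dor,
                    stages=stages,
                )
            )
    return records


def generate_retest(
    records: Sequence[ChildRecord],
    table: ScoreTable | None = None,
    rater_flip_rate: float = 0.107,
    seed=None,
) -> dict[str, dict[int, Stage]]:
    """Second rating pass: each child's resolved stages with rating jitter."""
    from .staging import resolve_stage

    table = table or packaged_score_table()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for rec in records:
        resolved = {t: resolve_stage(rec, t) for t in LEFT_MANDIBULAR_TEETH}
        out[rec.child_id] = perturb_ratings(resolved, rater_flip_rate, rng)
    return out


def generate_calibration_pairs(
    model: PredictionModel,
    n: int,
    noise_sd: float = 0.30,
    age_range: tuple[float, float] = (3.0, 10.0),
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """(dms, ca) pairs from a known growth model with Gaussian age noise.

    True ages are uniform on ``age_range`` so the scores span the curve; the
    observed CA is the true age plus N(0, noise_sd) noise.  Used for
    parameter-recovery checks of the calibration fit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    true_age = rng.uniform(age_range[0], age_range[1], size=n)
    dms = np.array([model.dms(a) for a in true_age])
    ca = true_age + rng.normal(0.0, noise_sd, size=n)
    ca = np.clip(ca, 0.05, None)  # ages must stay positive for the fit
    return dms, ca
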
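"""Demirjian tooth-development staging and maturity scoring.

A permanent tooth is staged radiographically through eight crown/root
development stages A..H (initial cusp calcification through apical closure),
preceded by a pre-calcification state (``S0``, serialized ``"0"``).  Each
(sex, tooth, stage) carries a self-weighted score; the dental maturity score
(DMS) of a child is the sum over the seven left permanent mandibular teeth
(FDI 31..37), scaled so that full maturity (all teeth at H) scores 100.

When a left tooth is missing or unreadable its contralateral right-side
counterpart (41..47) is scored instead; a tooth with neither side readable
makes the record unscorable.
"""

from __future__ import annotations

import csv
import enum
import functools
from dataclasses import dataclass
from importlib import resources
from typing import TYPE_CHECKING, Mapping

from .errors import ConfigError, UnscorableToothError

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import ChildRecord

#: The seven left permanent mandibular teeth scored by the method (FDI codes).
LEFT_MANDIBULAR_TEETH = (31, 32, 33, 34, 35, 36, 37)
#: Right-side counterparts usable for contralateral substitution.
RIGHT_MANDIBULAR_TEETH = (41, 42, 43, 44, 45, 46, 47)
SEXES = ("M", "F")

_SUM_TOL = 1e-9


class Stage(enum.IntEnum):
    """Tooth development stage with the total order S0 < A < ... < H."""

    S0 = 0
    A = 1
    B = 2
    C = 3
    D = 4
    E = 5
    F = 6
    G = 7
    H = 8

    @property
    def code(self) -> str:
        """Serialized one-character code: ``"0"`` for S0, else the letter."""
        return "0" if self is Stage.S0 else self.name

    @classmethod
    def from_code(cls, code: str) -> "Stage":
        code = code.strip().upper()
        if code == "0" or code == "S0":
            return cls.S0
        try:
            return cls[code]
        except KeyError:
            raise ValueError(f"unknown stage code {code!r} (expected 0 or A..H)") from None


def contralateral(tooth: int) -> int:
    """FDI code of the mirror-image mandibular tooth (31<->41 ... 37<->47)."""
    if 31 <= tooth <= 37:
        return tooth + 10
    if 41 <= tooth <= 47:
        return tooth - 10
    raise ValueError(f"tooth {tooth} is not a mandibular FDI code in 31..37/41..47")


@dataclass(frozen=True)
class ScoreTable:
    """Sex-specific self-weighted stage scores for the seven-tooth method.

    ``scores`` maps ``(sex, tooth, stage)`` to points.  A valid table covers
    both sexes, all seven teeth and all nine stages, scores 0 at S0, is
    non-decreasing in stage, and sums to exactly 100 over the seven H-stage
    scores of each sex.
    """

    scores: Mapping[tuple[str, int, Stage], float]
    name: str = "unnamed"

    def score(self, sex: str, tooth: int, stage: Stage) -> float:
        return self.scores[(sex, tooth, stage)]

    def max_score(self, sex: str, tooth: int) -> float:
        return self.scores[(sex, tooth, Stage.H)]

    def max_increment(self, sex: str) -> float:
        """Largest single-stage score step anywhere in the table for ``sex``."""
        return max(
            self.scores[(sex, t, Stage(s + 1))] - self.scores[(sex, t, Stage(s))]
            for t in LEFT_MANDIBULAR_TEETH
            for s in range(8)
        )


def _validate_score_table(scores, name):
    for sex in SEXES:
        for tooth in LEFT_MANDIBULAR_TEETH:
            for stage in Stage:
                if (sex, tooth, stage) not in scores:
                    raise ConfigError(
                        f"score table {name!r}: missing cell (sex={sex}, "
                        f"tooth={tooth}, stage={stage.code})"
                    )
            if scores[(sex, tooth, Stage.S0)] != 0.0:
                raise ConfigError(
                    f"score table {name!r}: S0 score must be 0 for (sex={sex}, tooth={tooth})"
                )
            for s in range(8):
                lo, hi = scores[(sex, tooth, Stage(s))], scores[(sex, tooth, Stage(s + 1))]
                if hi < lo:
                    raise ConfigError(
                        f"score table {name!r}: scores decrease from stage "
                        f"{Stage(s).code} to {Stage(s + 1).code} at (sex={sex}, tooth={tooth})"
                    )
        total = sum(scores[(sex, t, Stage.H)] for t in LEFT_MANDIBULAR_TEETH)
        if abs(total - 100.0) > _SUM_TOL:
            raise ConfigError(
                f"score table {name!r}: full-maturity scores for sex={sex} sum to "
                f"{total!r}, expected 100"
            )


def score_table_from_mapping(scores, name="unnamed") -> ScoreTable:
    """Build and validate a :class:`ScoreTable` from a plain mapping."""
    scores = dict(scores)
    _validate_score_table(scores, name)
    return ScoreTable(scores=scores, name=name)


def load_score_table(path, name: str | None = None) -> ScoreTable:
    """Load a score table from a CSV with columns sex, tooth, stage, score.

    The load fails loudly (:class:`ConfigError`) on any missing cell,
    non-monotone stage scores, or a full-maturity sum differing from 100.
    """
    name = name or str(path)
    scores = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                key = (row["sex"].strip(), int(row["tooth"]), Stage.from_code(row["stage"]))
                scores[key] = float(row["score"])
            except (KeyError, ValueError, TypeError) as exc:
                raise ConfigError(f"score table {name!r}, line {i}: {exc}") from exc
    _validate_score_table(scores, name)
    return ScoreTable(scores=scores, name=name)


@functools.cache
def packaged_score_table() -> ScoreTable:
    """The packaged seven-tooth score table.

    This is a *synthetic* stand-in with the structure of the classical
    sex-specific self-weighted tables (monotone stages, staggered tooth
    maturation, H-scores summing to 100), not the published reference values;
    swap in a real edition with :func:`load_score_table` for production use.
    """
    ref = resources.files("dentalage.data") / "score_table_synthetic.csv"
    with resources.as_file(ref) as path:
        return load_score_table(path, name="synthetic-v1")


def resolve_stage(record: "ChildRecord", tooth: int) -> Stage:
    """Stage used for scoring ``tooth``: the left tooth, else its contralateral.

    Raises :class:`UnscorableToothError` when both sides are absent (a tooth
    recorded as unreadable is treated identically to absent).
    """
    if tooth not in LEFT_MANDIBULAR_TEETH:
        raise ValueError(f"tooth {tooth} is not one of the seven left mandibular teeth")
    stage = record.stages.get(tooth)
    if stage is None:
        stage = record.stages.get(contralateral(tooth))
    if stage is None:
        raise UnscorableToothError(record.child_id, tooth)
    return stage


def compute_dms(record: "ChildRecord", table: ScoreTable) -> float:
    """Dental maturity score: sum of stage scores over the seven teeth.

    Contralateral substitution is applied per tooth; any unscorable tooth
    propagates :class:`UnscorableToothError` (such records are excluded
    upstream, mirroring the radiograph-quality exclusion criterion).
    """
    return float(
        sum(
            table.score(record.sex, tooth, resolve_stage(record, tooth))
            for tooth in LEFT_MANDIBULAR_TEETH
        )
    )
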
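"""Maturity-score to dental-age conversion.

Two routes are supported:

* a :class:`ConversionTable` of monotone (DMS, age) knots — the classical
  50th-percentile lookup, interpolated linearly between knots; and
* a :class:`PredictionModel`, the population-specific logistic growth curve

      age(DMS) = 1 / (a + b * c**DMS),        a,b > 0,  0 < c < 1,

  a bounded strictly increasing curve with lower asymptote 1/(a+b) and upper
  asymptote 1/a (= u, the adult-age ceiling).  The packaged default models
  carry reference coefficients fitted on an Egyptian pediatric cohort aged
  3-10: male (a, b, c) = (0.083, 0.351, 0.969), female (0.083, 0.350, 0.970).
"""

from __future__ import annotations

import csv
import functools
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

from .errors import ConfigError, NonInvertibleError, OutOfTableError
from .staging import SEXES

__all__ = [
    "PredictionModel",
    "ConversionTable",
    "DEFAULT_MODELS",
    "predict_age",
    "invert_prediction",
    "dms_to_age",
    "age_to_dms",
    "load_conversion_table",
    "packaged_conversion_table",
    "load_model",
    "save_model",
]


@dataclass(frozen=True)
class PredictionModel:
    """Logistic growth prediction model age = 1/(a + b*c**dms) for one sex.

    ``a`` is the inverse upper asymptote (1/years), ``b`` a scale (1/years)
    and ``c`` the dimensionless per-score decay base.  Predicted age increases
    strictly with DMS and is confined to the open interval (1/(a+b), 1/a).
    """

    sex: str
    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ConfigError(f"model sex must be one of {SEXES}, got {self.sex!r}")
        if not (self.a > 0 and self.b > 0 and 0 < self.c < 1):
            raise ConfigError(
                f"invalid model coefficients a={self.a}, b={self.b}, c={self.c}: "
                "require a>0, b>0, 0<c<1"
            )

    @property
    def age_floor(self) -> float:
        """Predicted age at DMS=0 — the infimum of attainable predictions."""
        return 1.0 / (self.a + self.b)

    @property
    def age_ceiling(self) -> float:
        """Upper asymptote 1/a, approached as DMS grows without bound."""
        return 1.0 / self.a

    # AgeMap protocol -------------------------------------------------
    def age(self, dms):
        return predict_age(dms, self)

    def dms(self, age):
        return invert_prediction(age, self)

    def age_range(self) -> tuple[float, float]:
        """(age at DMS=0, age at DMS=100): the span representable by stages."""
        return (predict_age(0.0, self), predict_age(100.0, self))


#: Reference coefficients (printed at 3-decimal precision) per sex.
DEFAULT_MODELS: Mapping[str, PredictionModel] = {
    "M": PredictionModel("M", 0.083, 0.351, 0.969),
    "F": PredictionModel("F", 0.083, 0.350, 0.970),
}


def predict_age(dms, model: PredictionModel):
    """Evaluate the logistic growth curve at ``dms`` (scalar or array)."""
    dms = np.asarray(dms, dtype=float)
    age = 1.0 / (model.a + model.b * model.c**dms)
    return float(age) if age.ndim == 0 else age


#: Half a 2-decimal presentation ulp: ages printed at 2 dp may round to just
#: below the curve's value at DMS=0 and must still invert (to ~0).
_FLOOR_TOL = 0.005


def invert_prediction(age: float, model: PredictionModel) -> float:
    """Maturity score whose predicted age equals ``age`` (exact algebraic inverse).

    Defined between the asymptotes 1/(a+b) and 1/a; ages outside raise
    :class:`NonInvertibleError`.  Ages within half a 2-dp rounding step below
    the DMS=0 value are accepted (they arise from presentation rounding) and
    return a value marginally below zero.
    """
    if not model.age_floor - _FLOOR_TOL <= age < model.age_ceiling:
        raise NonInvertibleError(
            f"age {age} outside the invertible open range "
            f"({model.age_floor:.4f}, {model.age_ceiling:.4f}) years"
        )
    return math.log((1.0 / age - model.a) / model.b) / math.log(model.c)


@dataclass(frozen=True)
class ConversionTable:
    """Per-sex ordered (dms, age) knots for 50th-percentile age lookup.

    Knots must be strictly increasing in DMS and non-decreasing in age, with
    at least two knots per sex and a minimum age knot below 2.5 years (ages
    under the study range must be representable so that the downstream
    exclusion filter can see them).
    """

    knots: Mapping[str, tuple[np.ndarray, np.ndarray]]
    name: str = "unnamed"

    def __post_init__(self):
        for sex in SEXES:
            if sex not in self.knots:
                raise ConfigError(f"conversion table {self.name!r}: missing sex {sex}")
            d, a = self.knots[sex]
            if len(d) < 2:
                raise ConfigError(f"conversion table {self.name!r}: <2 knots for sex {sex}")
            if not np.all(np.diff(d) > 0):
                raise ConfigError(
                    f"conversion table {self.name!r}: dms knots not strictly increasing ({sex})"
                )
            if not np.all(np.diff(a) >= 0):
                raise ConfigError(
                    f"conversion table {self.name!r}: age knots decrease ({sex})"
                )
            if a[0] >= 2.5:
                raise ConfigError(
                    f"conversion table {self.name!r}: minimum age knot {a[0]} not < 2.5 ({sex})"
                )

    def for_sex(self, sex: str) -> "SexConversion":
        return SexConversion(self, sex)

    def dms_span(self, sex: str) -> tuple[float, float]:
        d, _ = self.knots[sex]
        return float(d[0]), float(d[-1])

    def age_span(self, sex: str) -> tuple[float, float]:
        _, a = self.knots[sex]
        return float(a[0]), float(a[-1])


@dataclass(frozen=True)
class SexConversion:
    """One sex's slice of a conversion table, exposing the AgeMap protocol."""

    table: ConversionTable
    sex: str

    def age(self, dms):
        return dms_to_age(dms, self.sex, self.table)

    def dms(self, age):
        return age_to_dms(age, self.sex, self.table)

    def age_range(self) -> tuple[float, float]:
        return self.table.age_span(self.sex)


def dms_to_age(dms: float, sex: str, table: ConversionTable, policy: str = "error") -> float:
    """Estimated dental age by piecewise-linear interpolation between knots.

    Exact at knots.  A score outside [first knot, last knot] raises
    :class:`OutOfTableError` under the default ``policy="error"``; with
    ``policy="clamp"`` it is clamped to the boundary knot's age.
    """
    d, a = table.knots[sex]
    if dms < d[0] or dms > d[-1]:
        if policy == "error":
            raise OutOfTableError(
                f"dms {dms} outside conversion-table span [{d[0]}, {d[-1]}] for sex {sex}"
            )
        if policy != "clamp":
            raise ValueError(f"unknown out-of-table policy {policy!r}")
    return float(np.interp(dms, d, a))


def age_to_dms(age: float, sex: str, table: ConversionTable, policy: str = "error") -> float:
    """Inverse lookup: the maturity score whose table age equals ``age``.

    Requires the table's ages to be strictly increasing for ``sex``.
    """
    d, a = table.knots[sex]
    if not np.all(np.diff(a) > 0):
        raise ConfigError(f"conversion table {table.name!r} not invertible for sex {sex}")
    if age < a[0] or age > a[-1]:
        if policy == "error":
            raise OutOfTableError(
                f"age {age} outside conversion-table span [{a[0]}, {a[-1]}] for sex {sex}"
            )
        if policy != "clamp":
            raise ValueError(f"unknown out-of-table policy {policy!r}")
    return float(np.interp(age, a, d))


def load_conversion_table(path, name: str | None = None) -> ConversionTable:
    """Load a conversion table from a CSV with columns sex, dms, age."""
    name = name or str(path)
    rows: dict[str, list[tuple[float, float]]] = {s: [] for s in SEXES}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                rows[row["sex"].strip()].append((float(row["dms"]), float(row["age"])))
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"conversion table {name!r}, line {i}: {exc}") from exc
    knots = {}
    for sex, pairs in rows.items():
        pairs.sort()
        knots[sex] = (
            np.array([p[0] for p in pairs]),
            np.array([p[1] for p in pairs]),
        )
    return ConversionTable(knots=knots, name=name)


@functools.cache
def packaged_conversion_table() -> ConversionTable:
    """The packaged DMS -> age table.

    A *synthetic* stand-in for the classical 50th-percentile conversion
    tables: a smooth monotone logistic-shaped map from DMS 0 (age 2.0) to
    DMS 100 (age ~12-12.4), strictly increasing and therefore invertible.
    Swap in a real edition with :func:`load_conversion_table`.
    """
    ref = resources.files("dentalage.data") / "conversion_table_synthetic.csv"
    with resources.as_file(ref) as path:
        return load_conversion_table(path, name="synthetic-v1")


def load_model(path) -> PredictionModel:
    """Read a model JSON ``{"sex":..., "a":..., "b":..., "c":...}``."""
    with open(path) as fh:
        obj = json.load(fh)
    try:
        return PredictionModel(obj["sex"], float(obj["a"]), float(obj["b"]), float(obj["c"]))
    except KeyError as exc:
        raise ConfigError(f"model file {path}: missing field {exc}") from exc


def save_model(model: PredictionModel, path) -> None:
    with open(path, "w") as fh:
        json.dump({"sex": model.sex, "a": model.a, "b": model.b, "c": model.c}, fh, indent=2)
        fh.write("\n")
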
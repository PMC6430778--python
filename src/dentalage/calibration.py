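"""Calibration of the logistic growth curve CA = 1/(a + b*c**DMS).

"Logistic regression" in the growth-curve-estimation sense: the response is
a continuous age, not a binary outcome.  Two fitting routes are provided:

* *linearized, fixed asymptote*: with the upper asymptote u (= 1/a) fixed,
  ln(1/CA - 1/u) = ln(b) + DMS*ln(c) is linear in DMS and is fitted by OLS;
* *free asymptote*: nonlinear least squares over (a, b, c), initialized from
  the linearized fit at u0 = 1.05 * max(CA).

Fit quality is reported as R^2 on the age scale (1 - SSE/SST) together with
Spearman's rank correlation between DMS and CA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .conversion import PredictionModel, predict_age
from .errors import ConfigError, DegenerateDataError, InsufficientDataError

LINEARIZED = "linearized-fixed-asymptote"
FREE_NLS = "free-asymptote-nls"


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted model with fit-quality diagnostics."""

    model: PredictionModel
    r_squared: float
    spearman_rho: float
    fit_method: str
    n: int
    converged: bool
    message: str = ""


def spearman(x, y) -> float:
    """Spearman rank correlation with mid-rank ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise InsufficientDataError("need >= 2 pairs for a rank correlation")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise DegenerateDataError("zero variance in a rank vector: correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def r_squared(model: PredictionModel, dms, ca) -> float:
    """Coefficient of determination 1 - SSE/SST of the model on (dms, ca)."""
    dms = np.asarray(dms, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if len(dms) != len(ca) or len(ca) < 2:
        raise InsufficientDataError("need >= 2 pairs")
    sst = float(np.sum((ca - ca.mean()) ** 2))
    if sst == 0.0:
        raise DegenerateDataError("constant response: SST = 0")
    sse = float(np.sum((ca - predict_age(dms, model)) ** 2))
    return 1.0 - sse / sst


def _linearized_fit(dms, ca, u):
    if np.any(ca >= u):
        raise ConfigError(f"fixed asymptote u={u} not above every observed age")
    y = np.log(1.0 / ca - 1.0 / u)
    slope, intercept = np.polyfit(dms, y, 1)
    return 1.0 / u, float(np.exp(intercept)), float(np.exp(slope))


def _validate_pairs(dms, ca):
    dms = np.asarray(dms, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if len(dms) != len(ca):
        raise InsufficientDataError("dms and ca must have equal length")
    if len(np.unique(dms)) < 3:
        raise InsufficientDataError("need >= 3 pairs with >= 3 distinct maturity scores")
    if np.any(ca <= 0):
        raise ConfigError("all chronological ages must be positive")
    if np.ptp(ca) == 0.0:
        raise DegenerateDataError("constant response: SST = 0")
    return dms, ca


def fit_logistic_growth(
    dms,
    ca,
    *,
    sex: str = "M",
    asymptote: float | str = 12.0,
) -> CalibrationResult:
    """Fit age = 1/(a + b*c**dms) to observed (dms, ca) pairs.

    ``asymptote`` is either a fixed adult-age ceiling u in years (the
    linearized route with a = 1/u; default 12) or ``"free"`` for the full
    three-parameter nonlinear least squares.  Inputs may be individual
    children or per-group mean points — both are supported.
    """
    dms, ca = _validate_pairs(dms, ca)

    if asymptote != "free":
        u = float(asymptote)
        a, b, c = _linearized_fit(dms, ca, u)
        if not 0 < c < 1:
            raise ConfigError(
                f"linearized fit produced c={c:.4f} outside (0,1): "
                "ages do not increase with maturity score"
            )
        model = PredictionModel(sex, a, b, c)
        return CalibrationResult(
            model=model,
            r_squared=r_squared(model, dms, ca),
            spearman_rho=spearman(dms, ca),
            fit_method=LINEARIZED,
            n=len(ca),
            converged=True,
        )

    u0 = 1.05 * float(np.max(ca))
    a0, b0, c0 = _linearized_fit(dms, ca, u0)
    c0 = min(max(c0, 1e-6), 1 - 1e-6)

    def f(x, a, b, c):
        return 1.0 / (a + b * c**x)

    converged, message = True, ""
    try:
        popt, _ = optimize.curve_fit(
            f, dms, ca, p0=[a0, b0, c0], method="lm", maxfev=20000
        )
        a, b, c = (float(v) for v in popt)
        if not (a > 0 and b > 0 and 0 < c < 1):
            raise RuntimeError(f"unconstrained optimum invalid (a={a}, b={b}, c={c})")
    except RuntimeError as exc:
        message = str(exc)
        try:
            popt, _ = optimize.curve_fit(
                f,
                dms,
                ca,
                p0=[a0, b0, c0],
                method="trf",
                bounds=([1e-9, 1e-12, 1e-9], [10.0, 100.0, 1 - 1e-12]),
                maxfev=20000,
            )
            a, b, c = (float(v) for v in popt)
        except RuntimeError as exc2:  # pragma: no cover - pathological data
            return CalibrationResult(
                model=PredictionModel(sex, a0, b0, c0),
                r_squared=float("nan"),
                spearman_rho=spearman(dms, ca),
                fit_method=FREE_NLS,
                n=len(ca),
                converged=False,
                message=f"{message}; {exc2}",
            )
    model = PredictionModel(sex, a, b, c)
    return CalibrationResult(
        model=model,
        r_squared=r_squared(model, dms, ca),
        spearman_rho=spearman(dms, ca),
        fit_method=FREE_NLS,
        n=len(ca),
        converged=converged,
        message=message,
    )
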
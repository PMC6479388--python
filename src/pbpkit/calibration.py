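"""Bioanalytical calibration-curve regression and QC statistics.

Implements the weighted quadratic calibration model used for LC-MS/MS
quantification: the instrument response (analyte/internal-standard peak-area
ratio) y is regressed on nominal concentration x as

    y = a x^2 + b x + c,   weights 1/x^2,

concentrations are back-calculated by inverting the quadratic, and
quality-control replicates are summarized as %accuracy (100 mean/nominal)
and %CV (100 sd/mean, sample sd).  Curve acceptance uses r >= 0.99 and QC
acceptance uses |%Acc - 100| <= 25 and %CV <= 25.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    InsufficientPointsError,
    InvalidWeightError,
    NoDataError,
    NonInvertibleResponseError,
)

__all__ = [
    "CalibrationCurve",
    "QCStatistics",
    "BackCalcResult",
    "fit_weighted_quadratic",
    "back_calculate",
    "qc_stats",
]

#: default curve-acceptance threshold on r
R_ACCEPT = 0.99
#: default QC acceptance band, percent
QC_ACCEPT_PCT = 25.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted weighted quadratic calibration curve.

    ``r`` is the square root of the weighted R^2 (reported alongside
    ``r_squared`` because conventions differ on which one is quoted);
    ``lloq``/``uloq`` bound the validated range in ng/mL.
    """

    a: float
    b: float
    c: float
    r: float
    r_squared: float
    lloq: float
    uloq: float

    @property
    def accepted(self) -> bool:
        return self.r >= R_ACCEPT

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        """Forward-evaluate the curve (response from concentration)."""
        return self.a * np.asarray(x, dtype=float) ** 2 + self.b * np.asarray(
            x, dtype=float
        ) + self.c

    def __post_init__(self) -> None:
        if not self.lloq < self.uloq:
            raise InvalidWeightError("lloq must be < uloq")


@dataclass(frozen=True)
class BackCalcResult:
    """Back-calculated concentration with quantification-range flag."""

    conc: float  # ng/mL
    flag: str  # "ok", "blq" (below LLOQ) or "alq" (above ULOQ)


@dataclass(frozen=True)
class QCStatistics:
    """Accuracy/precision summary of quality-control replicates."""

    nominal: float  # ng/mL
    mean: float  # ng/mL
    n: int
    acc: float  # percent, 100 * mean / nominal
    cv: float  # percent, 100 * sd / mean (sample sd); NaN when n == 1

    @property
    def passed(self) -> bool:
        ok_acc = abs(self.acc - 100.0) <= QC_ACCEPT_PCT
        ok_cv = math.isnan(self.cv) or self.cv <= QC_ACCEPT_PCT
        return ok_acc and ok_cv


def fit_weighted_quadratic(
    concentrations: Sequence[float], responses: Sequence[float]
) -> CalibrationCurve:
    """Fit y = a x^2 + b x + c by 1/x^2-weighted least squares.

    Parameters
    ----------
    concentrations, responses
        Paired standard concentrations (ng/mL, all > 0) and peak-area
        ratios.  Replicate standards may repeat a concentration; at least
        four *distinct* concentrations are required to support a quadratic.

    Returns
    -------
    CalibrationCurve
        With ``r``/``r_squared`` computed on the weighted fit and the
        calibration range set to [min(x), max(x)].
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientPointsError("concentrations and responses must be 1-D and paired")
    if np.any(x <= 0):
        raise InvalidWeightError("1/x^2 weighting requires all concentrations > 0")
    if len(np.unique(x)) < 4:
        raise InsufficientPointsError(
            "at least 4 distinct concentrations are required for a quadratic fit"
        )

    # np.polyfit applies w to the residuals, so w = 1/x gives least-squares
    # weights w^2 = 1/x^2.
    w = 1.0 / x
    a, b, c = np.polyfit(x, y, 2, w=w)

    resid = y - (a * x**2 + b * x + c)
    w2 = w**2
    ybar = np.sum(w2 * y) / np.sum(w2)
    ss_res = float(np.sum(w2 * resid**2))
    ss_tot = float(np.sum(w2 * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r = math.sqrt(max(r2, 0.0))

    return CalibrationCurve(
        a=float(a),
        b=float(b),
        c=float(c),
        r=r,
        r_squared=r2,
        lloq=float(x.min()),
        uloq=float(x.max()),
    )


def back_calculate(curve: CalibrationCurve, response: float) -> BackCalcResult:
    """Invert the calibration curve: concentration from observed response.

    The quadratic is solved for x; the root lying inside the calibration
    range wins, otherwise the root nearest the range.  Concentrations below
    LLOQ are flagged ``"blq"``, above ULOQ ``"alq"``.

    Raises
    ------
    NonInvertibleResponseError
        If no real root exists.
    """
    a, b, c = curve.a, curve.b, curve.c
    cc = c - response
    if a == 0.0:
        if b == 0:
            raise NonInvertibleResponseError("degenerate flat curve")
        roots = [-cc / b]
    else:
        disc = b * b - 4.0 * a * cc
        if disc < 0:
            raise NonInvertibleResponseError(
                f"response {response!r} has no real inverse on this curve"
            )
        # cancellation-safe form: for near-linear curves (a ~ 0 from the
        # least-squares fit) the naive formula loses the finite root
        sq = math.sqrt(disc)
        q = -0.5 * (b + math.copysign(sq, b if b != 0 else 1.0))
        roots = [q / a]
        if q != 0.0:
            roots.append(cc / q)
        roots = [r for r in roots if math.isfinite(r)]
        if not roots:
            raise NonInvertibleResponseError("no finite root")

    mid = 0.5 * (curve.lloq + curve.uloq)
    in_range = [r for r in roots if curve.lloq <= r <= curve.uloq]
    if len(in_range) == 2:
        warnings.warn(
            "both quadratic roots fall inside the calibration range; "
            "taking the one nearest the range midpoint",
            stacklevel=2,
        )
        conc = min(in_range, key=lambda r: abs(r - mid))
    elif len(in_range) == 1:
        conc = in_range[0]
    else:
        # neither root in range: nearest to the range (prefer non-negative)
        nonneg = [r for r in roots if r >= 0] or roots
        conc = min(nonneg, key=lambda r: min(abs(r - curve.lloq), abs(r - curve.uloq)))

    if conc < curve.lloq:
        flag = "blq"
    elif conc > curve.uloq:
        flag = "alq"
    else:
        flag = "ok"
    return BackCalcResult(conc=float(conc), flag=flag)


def qc_stats(nominal: float, measured: Sequence[float]) -> QCStatistics:
    """Summarize QC replicates as mean, %accuracy and %CV.

    %Acc = 100 * mean / nominal; %CV = 100 * sd / mean with the sample
    (n - 1) standard deviation.  With a single replicate %CV is NaN.
    """
    vals = np.asarray(measured, dtype=float)
    if vals.size == 0:
        raise NoDataError("qc_stats requires at least one measured value")
    mean = float(vals.mean())
    n = int(vals.size)
    acc = 100.0 * mean / nominal
    cv = 100.0 * float(vals.std(ddof=1)) / mean if n > 1 else float("nan")
    return QCStatistics(nominal=float(nominal), mean=mean, n=n, acc=acc, cv=cv)
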
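"""Linear calibration of dynamic range against capture-antibody concentration.

The working range of a sandwich assay widens as more capture antibody is
deposited at the test line, because antigen excess sets in later.  Over
the tested range that relationship is well described by a straight line

    DR(ab) = DR_nonspecific + M * ab

where ``DR_nonspecific`` is the intercept (the range observed for a
blank experiment with no antibody) and ``M`` is the sensitivity of the
dynamic range to the antibody concentration (ug/mL per mg/mL).  The fit
is ordinary least squares with 95% t-based confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .exceptions import DomainError, InsufficientDataError, ValidationError

__all__ = ["DRLine", "fit_dr_line", "predict_dynamic_range"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DRLine:
    """OLS calibration of dynamic range vs antibody concentration."""

    dr_nonspecific: float
    M: float
    intercept_ci: Tuple[float, float]
    slope_ci: Tuple[float, float]
    r_squared: float
    max_fitted_conc: float = float("nan")

    def __post_init__(self) -> None:
        lo, hi = self.intercept_ci
        if not (lo <= self.dr_nonspecific <= hi):
            raise ValidationError("intercept CI must bracket the intercept")
        lo, hi = self.slope_ci
        if not (lo <= self.M <= hi):
            raise ValidationError("slope CI must bracket the slope")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValidationError("r_squared must lie in [0, 1]")


def fit_dr_line(points: Sequence[Tuple[float, float]]) -> DRLine:
    """Fit DR = DR_nonspecific + M * ab_conc by OLS with 95% CIs.

    ``points`` are (antibody_conc mg/mL, dynamic_range ug/mL) pairs; at
    least three points with distinct antibody concentrations are needed
    for a t-based interval.  Deterministic for fixed input.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise InsufficientDataError("linear calibration needs >= 3 points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.unique(x).size < 2:
        raise InsufficientDataError("antibody concentrations are all identical")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return DRLine(
        dr_nonspecific=float(model.params[0]),
        M=float(model.params[1]),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        r_squared=float(np.clip(model.rsquared, 0.0, 1.0)),
        max_fitted_conc=float(np.max(x)),
    )


def predict_dynamic_range(line: DRLine, antibody_conc: float) -> float:
    """Predicted dynamic range (ug/mL) at a given capture-antibody level.

    At 0 mg/mL this returns the blank-experiment range.  Predictions
    above the largest fitted concentration are extrapolations and are
    logged as such.
    """
    if not (np.isfinite(antibody_conc) and antibody_conc >= 0):
        raise DomainError("antibody_conc must be non-negative")
    if np.isfinite(line.max_fitted_conc) and antibody_conc > line.max_fitted_conc:
        logger.warning(
            "predicting at %.3g mg/mL, above the fitted range (max %.3g mg/mL)",
            antibody_conc, line.max_fitted_conc,
        )
    return float(line.dr_nonspecific + line.M * antibody_conc)
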
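"""Closed-form response percentiles, dynamic range and hook-onset metrics.

For the asymmetric sigmoid with inflection point ``C`` and steepness
``n`` (symmetric case, Q = 1), the concentration giving a p% response is

    C_p = C * (p / (100 - p))**(1/n)

so C_50 = C, and with n = 1 the working range runs from C_10 = C/9 to
C_90 = 9C.  The dynamic range is the arithmetic difference C_90 - C_10.

When the hook arrives before the sigmoid saturates, the fitted plateau is
extrapolation and the closed-form C_90 is unreliable; that situation is
betrayed by a large spread of the inflection point across replicate
fits, in which case the dose of maximal observed intensity is reported
as C_90 instead (flagged anomalous).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .curve_fitting import DoseResponseDataset, FitResult
from .exceptions import DomainError, InsufficientDataError, OrderingError
from .response_models import AsymParams

__all__ = [
    "DerivedMetrics",
    "concentration_at_response",
    "dynamic_range",
    "resolve_c90_anomalous",
    "prozone_onset",
    "derive_metrics",
]


def concentration_at_response(C: float, n: float, p: float) -> float:
    """Concentration at which the sensor reaches p% of its span.

    Parameters are the inflection point ``C`` (> 0, ug/mL), steepness
    ``n`` (nonzero) and the response level ``p`` in percent, open
    interval (0, 100).  p = 50 returns C exactly.
    """
    if not (np.isfinite(C) and C > 0):
        raise DomainError("C must be a positive finite concentration")
    if not (np.isfinite(n) and n != 0):
        raise DomainError("n must be finite and nonzero")
    if not (np.isfinite(p) and 0 < p < 100):
        raise DomainError("p must lie strictly between 0 and 100")
    if p == 50:
        return float(C)
    return float(C * (p / (100.0 - p)) ** (1.0 / n))


def dynamic_range(C10: float, C90: float) -> float:
    """Working range of the assay: the difference C90 - C10 (ug/mL)."""
    if not (C10 > 0 and np.isfinite(C10) and np.isfinite(C90)):
        raise DomainError("C10 and C90 must be positive finite concentrations")
    if C90 < C10:
        raise OrderingError(f"C90 ({C90}) must be >= C10 ({C10})")
    return float(C90 - C10)


def prozone_onset(data: DoseResponseDataset) -> float:
    """Dose of maximal replicate-mean intensity: the last pre-hook dose.

    Reported on the measured grid (not interpolated); equals the last
    dose when no hook is present.
    """
    pos = data.positive_subset()
    if pos.n_doses < 3:
        raise InsufficientDataError("need at least 3 positive doses")
    means = pos.mean_intensities()
    return float(pos.doses[int(np.argmax(means))])


def resolve_c90_anomalous(
    fit: FitResult,
    data: DoseResponseDataset,
    cv_threshold: float = 0.5,
) -> Tuple[float, bool]:
    """C90 with the anomalous-saturation fallback.

    If the coefficient of variation of the inflection point across the
    per-replicate fits exceeds ``cv_threshold``, the sigmoid plateau was
    never reached experimentally and the dose of maximal mean intensity
    is returned as C90 (flagged anomalous); otherwise the closed form
    ``concentration_at_response(C, n, 90)`` applies.
    """
    if fit.n_replicate_fits < 2 or len(fit.replicate_params) < 2:
        raise InsufficientDataError("anomaly rule needs >= 2 per-replicate inflection estimates")
    if not isinstance(fit.params, AsymParams):
        raise DomainError("anomaly rule applies to the asymmetric (pre-hook) fit")
    reps = fit.replicate_values("C")
    mean = float(np.mean(reps))
    cv = float(np.std(reps, ddof=0) / mean) if mean != 0 else float("inf")
    if cv > cv_threshold:
        return prozone_onset(data), True
    return concentration_at_response(fit.params.C, fit.params.n, 90.0), False


@dataclass(frozen=True)
class DerivedMetrics:
    """Inflection point, working-range bounds and hook diagnostics.

    Intervals on C10/C90 are the C interval scaled by the same closed-form
    factor, matching how replicate SEM propagates through C_p = C * k(p).
    ``dynamic_range_log10`` is the decades-of-concentration variant,
    provided alongside the default arithmetic difference.
    """

    C: float
    C_interval: Tuple[float, float]
    C10: float
    C10_interval: Tuple[float, float]
    C90: float
    C90_interval: Tuple[float, float]
    dynamic_range: float
    anomalous: bool
    onset_conc: float
    dynamic_range_log10: float = float("nan")


def derive_metrics(
    fit: FitResult,
    data: DoseResponseDataset,
    cv_threshold: float = 0.5,
) -> DerivedMetrics:
    """Full working-range summary for one assay condition."""
    params = fit.params
    if not isinstance(params, AsymParams):
        raise DomainError("derived metrics require an asymmetric-fit result")
    C = params.C
    n = params.n
    c_int = fit.param_interval.get("C", (float("nan"), float("nan")))
    k10 = concentration_at_response(C, n, 10.0) / C
    k90 = concentration_at_response(C, n, 90.0) / C
    c10 = C * k10
    c90, anomalous = resolve_c90_anomalous(fit, data, cv_threshold)
    c90_int = (c_int[0] * k90, c_int[1] * k90) if not anomalous else (c90, c90)
    dr = dynamic_range(c10, c90)
    return DerivedMetrics(
        C=C,
        C_interval=tuple(c_int),
        C10=c10,
        C10_interval=(c_int[0] * k10, c_int[1] * k10),
        C90=c90,
        C90_interval=c90_int,
        dynamic_range=dr,
        anomalous=anomalous,
        onset_conc=prozone_onset(data),
        dynamic_range_log10=float(np.log10(c90 / c10)),
    )
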
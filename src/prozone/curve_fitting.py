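"""Nonlinear least-squares estimation of the dose-response curves.

The bell curve is fitted to replicate-mean intensities over the full
dose grid; the asymmetric sigmoid is fitted to the pre-hook subset
obtained with :func:`truncate_preprozone`.  Uncertainty follows the
replicate-refit scheme used for lateral-flow experiments run in
triplicate: each replicate series is refitted on its own and the SEM of
every parameter is the standard deviation of those per-replicate
estimates divided by sqrt(k).

Fits use SciPy's bounded trust-region reflective least squares on a
deterministic, data-driven start, so repeated runs on the same dataset
give identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .exceptions import InsufficientDataError, ValidationError
from .response_models import AsymParams, BellParams, asym_intensity, bell_intensity

__all__ = [
    "DoseResponseDataset",
    "FitResult",
    "truncate_preprozone",
    "fit_bell",
    "fit_asymmetric",
]


@dataclass(frozen=True)
class DoseResponseDataset:
    """One assay condition: a dose grid with replicate intensities.

    capture_ab_conc : capture-antibody concentration at the test line (mg/mL)
    doses           : strictly increasing analyte concentrations (ug/mL);
                      a leading 0 (blank) is allowed but excluded from fits
    intensities     : per-dose tuples of replicate intensities (a.u.,
                      background-subtracted); replicate counts may vary
    """

    capture_ab_conc: float
    doses: tuple
    intensities: tuple
    label: str = ""

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        intens = tuple(tuple(float(v) for v in row) for row in self.intensities)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "intensities", intens)
        if not (isinstance(self.capture_ab_conc, (int, float)) and self.capture_ab_conc > 0):
            raise ValidationError("capture_ab_conc must be positive")
        if len(doses) == 0 or len(doses) != len(intens):
            raise ValidationError("doses and intensities must be non-empty and aligned")
        arr = np.asarray(doses)
        if np.any(arr < 0) or np.any(np.diff(arr) <= 0):
            raise ValidationError("doses must be non-negative and strictly increasing")
        if any(len(row) == 0 for row in intens):
            raise ValidationError("every dose needs at least one replicate")

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    @property
    def max_replicates(self) -> int:
        return max(len(row) for row in self.intensities)

    def mean_intensities(self) -> np.ndarray:
        return np.array([np.mean(row) for row in self.intensities])

    def positive_subset(self) -> "DoseResponseDataset":
        """Drop the blank (dose 0) if present; models are undefined there."""
        if self.doses[0] > 0:
            return self
        return replace(self, doses=self.doses[1:], intensities=self.intensities[1:])

    def replicate_series(self, r: int):
        """(doses, values) for replicate index ``r``, skipping doses without it."""
        d, v = [], []
        for dose, row in zip(self.doses, self.intensities):
            if r < len(row):
                d.append(dose)
                v.append(row[r])
        return np.asarray(d), np.asarray(v)


@dataclass(frozen=True)
class FitResult:
    """Point estimates plus replicate-based and covariance-based uncertainty.

    param_sem      : SEM per parameter from k per-replicate refits (NaN when
                     fewer than two replicate fits succeeded)
    param_interval : (estimate - SEM, estimate + SEM) per parameter; falls
                     back to the optimiser-covariance standard error when
                     no replicate SEM is available
    param_se_cov   : standard errors from the Jacobian covariance at the
                     solution (the classical asymptotic alternative)
    replicate_params : per-replicate parameter objects (successful refits)
    decreasing     : fitted curve decreases over the dose range (e.g. the
                     n = -1 interpretation of an inhibitory response)
    """

    params: Union[BellParams, AsymParams]
    param_sem: dict
    param_interval: dict
    residual_ss: float
    converged: bool
    n_replicate_fits: int
    param_se_cov: dict = field(default_factory=dict)
    replicate_params: tuple = ()
    decreasing: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        if self.residual_ss < 0:
            raise ValidationError("residual_ss cannot be negative")
        for name, (lo, hi) in self.param_interval.items():
            est = getattr(self.params, name)
            if not (lo <= est <= hi or math.isnan(lo) or math.isnan(hi)):
                raise ValidationError(f"interval for {name} does not bracket the estimate")

    def replicate_values(self, name: str) -> np.ndarray:
        return np.array([getattr(p, name) for p in self.replicate_params])


def truncate_preprozone(data: DoseResponseDataset) -> DoseResponseDataset:
    """Keep doses up to (and including) the replicate-mean maximum.

    This isolates the stimulatory section just before the hook: from the
    smallest positive dose through the dose of maximal mean intensity.
    On a tie the lower dose wins, which keeps inhibition-phase points out
    of the retained window.  With no hook (monotone means) the dataset is
    returned unchanged apart from blank removal.
    """
    pos = data.positive_subset()
    if pos.n_doses < 3:
        raise InsufficientDataError("need at least 3 positive doses to locate the hook")
    means = pos.mean_intensities()
    peak = int(np.argmax(means))  # first occurrence -> lower dose on ties
    return replace(pos, doses=pos.doses[: peak + 1], intensities=pos.intensities[: peak + 1])


# ---------------------------------------------------------------------------
# shared machinery

def _solve(residual_fn, x0, bounds):
    return least_squares(residual_fn, x0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)


def _cov_se(res) -> np.ndarray:
    """Asymptotic standard errors from the Jacobian at the solution."""
    m, p = res.jac.shape
    dof = m - p
    if dof <= 0:
        return np.full(p, np.nan)
    try:
        cov = np.linalg.pinv(res.jac.T @ res.jac) * (2.0 * res.cost / dof)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def _uncertainty(names, estimate_vec, replicate_vecs, cov_se):
    """Assemble SEM / interval dictionaries from per-replicate estimates."""
    k = len(replicate_vecs)
    sem = {}
    interval = {}
    se_cov = {n: float(s) for n, s in zip(names, cov_se)}
    if k >= 2:
        mat = np.vstack(replicate_vecs)
        sd = np.std(mat, axis=0, ddof=1)
        sem_vec = sd / math.sqrt(k)
    else:
        sem_vec = np.full(len(names), np.nan)
    for i, n in enumerate(names):
        s = sem_vec[i] if np.isfinite(sem_vec[i]) else cov_se[i]
        sem[n] = float(sem_vec[i])
        if np.isfinite(s):
            interval[n] = (float(estimate_vec[i] - s), float(estimate_vec[i] + s))
        else:
            interval[n] = (float("nan"), float("nan"))
    return sem, interval, se_cov


def _half_crossing(doses, means, lo_level, hi_level):
    """Dose nearest the half-way level between two plateaus (log grid)."""
    half = 0.5 * (lo_level + hi_level)
    return float(doses[int(np.argmin(np.abs(means - half)))])


def _mean_weights(data: DoseResponseDataset, weights: str) -> Optional[np.ndarray]:
    """Per-dose residual weights (sqrt of inverse replicate variance)."""
    if weights == "none":
        return None
    if weights != "inverse_variance":
        raise ValidationError(f"unknown weighting scheme: {weights!r}")
    variances = np.array(
        [np.var(row, ddof=1) if len(row) > 1 else np.nan for row in data.intensities]
    )
    fallback = np.nanmean(variances) if np.isfinite(variances).any() else 1.0
    variances = np.where(np.isfinite(variances) & (variances > 0), variances, fallback)
    if not np.all(variances > 0):
        return None
    return np.sqrt(1.0 / variances)


# ---------------------------------------------------------------------------
# bell fit

_BELL_NAMES = ("Ic", "Ib", "D", "Cs", "Ci", "n1", "n2")


def _bell_setup(doses, means):
    span = float(np.ptp(means)) or 1.0
    lo_i, hi_i = float(np.min(means)) - span, float(np.max(means)) + span
    dmin, dmax = float(doses[0]), float(doses[-1])
    peak = int(np.argmax(means))
    ic0 = float(means[0])
    d0 = float(np.max(means))
    ib0 = float(means[-1])
    cs0 = _half_crossing(doses[: peak + 1], means[: peak + 1], ic0, d0)
    if peak < len(doses) - 1:
        ci0 = _half_crossing(doses[peak:], means[peak:], d0, ib0)
    else:
        ci0 = dmax
    cs0 = float(np.clip(cs0, dmin, dmax))
    ci0 = float(np.clip(max(ci0, cs0 * 1.5), dmin, dmax))
    x0 = np.array([ic0, ib0, d0, cs0, ci0, 1.0, 1.0])
    lb = np.array([lo_i, lo_i, lo_i, dmin / 10, dmin / 10, 0.1, 0.1])
    ub = np.array([hi_i, hi_i, hi_i, dmax * 10, dmax * 10, 10.0, 10.0])
    return x0, (lb, ub)


def _fit_bell_vector(doses, values, w=None):
    x0, bounds = _bell_setup(doses, values)

    def resid(v):
        r = bell_intensity(doses, BellParams(*v)) - values
        return r if w is None else w * r

    res = _solve(resid, x0, bounds)
    return res


def fit_bell(data: DoseResponseDataset, pooled: bool = False, weights: str = "none") -> FitResult:
    """Fit the seven-parameter bell curve over the full (positive) dose grid.

    By default the fit targets replicate means; ``pooled=True`` stacks all
    replicates as individual residuals instead, and
    ``weights="inverse_variance"`` weights each dose's mean residual by
    its replicate precision.  Per-replicate refits (where a replicate
    covers >= 7 doses) supply the SEM of each parameter.  Optimiser
    failure is reported via ``converged`` rather than raised.
    """
    pos = data.positive_subset()
    if pos.n_doses < 7:
        raise InsufficientDataError("bell fit needs >= 7 distinct positive doses (7 parameters)")
    doses = np.asarray(pos.doses)
    if pooled:
        xs = np.concatenate([np.full(len(row), d) for d, row in zip(doses, pos.intensities)])
        ys = np.concatenate([np.asarray(row) for row in pos.intensities])
        w = None
    else:
        xs, ys = doses, pos.mean_intensities()
        w = _mean_weights(pos, weights)
    try:
        res = _fit_bell_vector(xs, ys, w)
        params = BellParams(*res.x)
        converged = bool(res.success)
        message = res.status and str(res.message) or ""
    except (ValidationError, np.linalg.LinAlgError) as exc:  # pragma: no cover - defensive
        return FitResult(
            params=BellParams(0.0, 0.0, 0.0, 1.0, 2.0, 1.0, 1.0),
            param_sem={n: float("nan") for n in _BELL_NAMES},
            param_interval={n: (float("nan"), float("nan")) for n in _BELL_NAMES},
            residual_ss=float("inf"), converged=False, n_replicate_fits=0,
            message=f"optimizer failure: {exc}",
        )

    rep_vecs, rep_params = [], []
    for r in range(pos.max_replicates):
        rd, rv = pos.replicate_series(r)
        if len(rd) < 7:
            continue
        rres = _fit_bell_vector(rd, rv)
        if rres.success:
            rep_vecs.append(rres.x)
            rep_params.append(BellParams(*rres.x))
    sem, interval, se_cov = _uncertainty(_BELL_NAMES, res.x, rep_vecs, _cov_se(res))
    return FitResult(
        params=params, param_sem=sem, param_interval=interval,
        residual_ss=float(2.0 * res.cost), converged=converged,
        n_replicate_fits=len(rep_params), param_se_cov=se_cov,
        replicate_params=tuple(rep_params), message=message,
    )


# ---------------------------------------------------------------------------
# asymmetric fit

_ASYM_NAMES = ("Io", "Im", "C", "Q", "n")


def _asym_setup(doses, values, fix_n):
    span = float(np.ptp(values)) or 1.0
    lo_i, hi_i = float(np.min(values)) - span, float(np.max(values)) + span
    dmin, dmax = float(doses[0]), float(doses[-1])
    if fix_n is not None and fix_n < 0:
        io0, im0 = float(values[-1]), float(values[0])
    else:
        io0, im0 = float(values[0]), float(np.max(values))
    c0 = float(np.clip(_half_crossing(doses, values, io0, im0), dmin, dmax))
    x0 = [io0, im0, c0, 1.0]
    lb = [lo_i, lo_i, dmin / 10, 0.1]
    ub = [hi_i, hi_i, dmax * 10, 10.0]
    if fix_n is None:
        x0.append(1.0)
        lb.append(0.1)
        ub.append(10.0)
    return np.array(x0), (np.array(lb), np.array(ub))


def _fit_asym_vector(doses, values, fix_n, w=None):
    x0, bounds = _asym_setup(doses, values, fix_n)

    def make(v):
        if fix_n is None:
            return AsymParams(v[0], v[1], v[2], v[3], v[4])
        return AsymParams(v[0], v[1], v[2], v[3], fix_n)

    def resid(v):
        r = asym_intensity(doses, make(v)) - values
        return r if w is None else w * r

    res = _solve(resid, x0, bounds)
    return res, make(res.x)


def fit_asymmetric(
    data: DoseResponseDataset,
    fix_n: Optional[float] = 1.0,
    pooled: bool = False,
    weights: str = "none",
) -> FitResult:
    """Fit the asymmetric sigmoid to a pre-hook (truncated) dataset.

    ``fix_n`` pins the steepness (default 1, the standard increasing
    response; use -1 for a decreasing one; ``None`` frees it, which needs
    an extra dose).  ``weights="inverse_variance"`` weights each dose's
    mean residual by its replicate precision.  The SEM of the inflection
    point C comes from refitting each replicate series separately.
    """
    pos = data.positive_subset()
    n_free = 4 if fix_n is not None else 5
    if pos.n_doses < n_free:
        raise InsufficientDataError(f"asymmetric fit needs >= {n_free} distinct positive doses")
    if fix_n == 0:
        raise ValidationError("fix_n must be nonzero")
    doses = np.asarray(pos.doses)
    if pooled:
        xs = np.concatenate([np.full(len(row), d) for d, row in zip(doses, pos.intensities)])
        ys = np.concatenate([np.asarray(row) for row in pos.intensities])
        w = None
    else:
        xs, ys = doses, pos.mean_intensities()
        w = _mean_weights(pos, weights)
    res, params = _fit_asym_vector(xs, ys, fix_n, w)

    rep_vecs, rep_params = [], []
    for r in range(pos.max_replicates):
        rd, rv = pos.replicate_series(r)
        if len(rd) < n_free:
            continue
        rres, rp = _fit_asym_vector(rd, rv, fix_n)
        if rres.success:
            vec = rp.as_array() if fix_n is None else rp.as_array()[:4]
            rep_vecs.append(vec)
            rep_params.append(rp)

    names = _ASYM_NAMES if fix_n is None else _ASYM_NAMES[:4]
    est_vec = params.as_array() if fix_n is None else params.as_array()[:4]
    sem, interval, se_cov = _uncertainty(names, est_vec, rep_vecs, _cov_se(res))
    if fix_n is not None:
        sem["n"] = 0.0
        interval["n"] = (fix_n, fix_n)
        se_cov["n"] = 0.0
    curve_lo = asym_intensity(float(doses[0]), params)
    curve_hi = asym_intensity(float(doses[-1]), params)
    return FitResult(
        params=params, param_sem=sem, param_interval=interval,
        residual_ss=float(2.0 * res.cost), converged=bool(res.success),
        n_replicate_fits=len(rep_params), param_se_cov=se_cov,
        replicate_params=tuple(rep_params), decreasing=bool(curve_hi < curve_lo),
        message=str(res.message),
    )
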
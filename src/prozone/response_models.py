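"""Parametric dose-response curves for sandwich-assay lateral-flow sensors.

Two shapes are modelled.  The full dose range of a hook-affected sandwich
assay is biphasic: signal rises with analyte (stimulation) until antigen
excess saturates the antibodies, after which it falls (inhibition).  That
bell shape is the sum of two logistic sections sharing a middle plateau.
The pre-hook portion alone is an asymmetric sigmoid (a power-of-logistic,
i.e. 5PL-type curve) whose inflection point ``C`` is the analyte
concentration giving 50% of the maximal response when the asymmetry
factor ``Q`` equals 1.

Intensities are background-subtracted colorimetric test-line readings in
arbitrary units; concentrations are in ug/mL.  Both forms involve ``C/x``,
so a blank (x = 0) is outside the model domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .exceptions import DomainError, ValidationError

__all__ = ["BellParams", "AsymParams", "bell_intensity", "asym_intensity"]


def _require_finite(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not (isinstance(v, (int, float)) and math.isfinite(v)):
            raise ValidationError(f"{type(obj).__name__}.{f.name} must be a finite number, got {v!r}")


@dataclass(frozen=True)
class BellParams:
    """Biphasic bell-shaped curve parameters.

    Ic, Ib : left / right plateau intensities (a.u.)
    D      : middle-plateau intensity (a.u.); the hook maximum for a
             prozone-shaped curve
    Cs, Ci : half-maximal stimulatory / inhibitory concentrations (ug/mL)
    n1, n2 : Hill slopes of the stimulatory / inhibitory sections
    """

    Ic: float
    Ib: float
    D: float
    Cs: float
    Ci: float
    n1: float
    n2: float

    def __post_init__(self) -> None:
        _require_finite(self)
        if self.Cs <= 0 or self.Ci <= 0:
            raise ValidationError("Cs and Ci must be positive concentrations")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValidationError("Hill slopes n1 and n2 must be positive")

    @property
    def is_prozone_shaped(self) -> bool:
        """Middle plateau dominates and stimulation precedes inhibition."""
        return self.D >= self.Ic and self.D >= self.Ib and self.Cs < self.Ci

    def as_array(self) -> np.ndarray:
        return np.array([self.Ic, self.Ib, self.D, self.Cs, self.Ci, self.n1, self.n2])


@dataclass(frozen=True)
class AsymParams:
    """Asymmetric sigmoid (pre-hook) parameters.

    Io, Im : initial / maximal intensity (a.u.)
    C      : inflection-point concentration (ug/mL); the 50%-response
             concentration when Q = 1
    Q      : asymmetry factor (dimensionless)
    n      : steepness (Hill slope); 1 for an increasing response,
             -1 models a decreasing one
    """

    Io: float
    Im: float
    C: float
    Q: float
    n: float

    def __post_init__(self) -> None:
        _require_finite(self)
        if self.C <= 0:
            raise ValidationError("inflection point C must be positive")
        if self.Q <= 0:
            raise ValidationError("asymmetry factor Q must be positive")
        if self.n == 0:
            raise ValidationError("steepness n must be nonzero")

    def as_array(self) -> np.ndarray:
        return np.array([self.Io, self.Im, self.C, self.Q, self.n])


def _check_positive(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise DomainError("empty concentration input")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError("concentrations must be finite and strictly positive")
    return arr


def bell_intensity(x, params: BellParams):
    """Evaluate the biphasic bell curve at concentration ``x`` (> 0).

    I(x) = Ic + (D - Ic) / (1 + (Cs/x)^n1) + (Ib - D) / (1 + (Ci/x)^n2)

    The limits are Ic as x -> 0+ and Ib as x -> inf; the stimulatory
    section is half-complete at x = Cs and the inhibitory one at x = Ci.
    Accepts scalars or arrays; returns the matching shape.
    """
    arr = _check_positive(x)
    p = params
    stim = (p.D - p.Ic) / (1.0 + (p.Cs / arr) ** p.n1)
    inhib = (p.Ib - p.D) / (1.0 + (p.Ci / arr) ** p.n2)
    out = p.Ic + stim + inhib
    return out if out.ndim else float(out)


def asym_intensity(x, params: AsymParams):
    """Evaluate the asymmetric sigmoid at concentration ``x`` (> 0).

    I(x) = Io + (Im - Io) / (1 + (C/x)^n)^Q

    Monotone increasing in x for n > 0, with limits Io (x -> 0+) and
    Im (x -> inf); at x = C with Q = 1 it returns (Io + Im)/2 exactly.
    """
    arr = _check_positive(x)
    p = params
    out = p.Io + (p.Im - p.Io) / (1.0 + (p.C / arr) ** p.n) ** p.Q
    return out if out.ndim else float(out)
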
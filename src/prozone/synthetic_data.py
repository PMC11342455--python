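"""Synthetic dose-response generator emulating a hook-affected LFD assay.

Datasets mimic a CRP sandwich lateral-flow experiment: analyte doses on
a 9-point log grid spanning 0.01-200 ug/mL, triplicate test-line
intensities, and a biphasic stimulation-inhibition (hook) truth curve.
Noise is additive i.i.d. Gaussian on intensity, parameterised as a
fraction of the noiseless curve span so tests stay scale-free; 2% of
span approximates the replicate scatter of a well-run strip reader.

The default truth places the stimulatory inflection near 1.1 ug/mL (a
mid-range capture-antibody condition), the hook inflection at 40 ug/mL
with a steep collapse (n2 = 4), and equal baseline/terminal plateaus,
so the observed hook onset lands in the 5-20 ug/mL window typical of
these assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .curve_fitting import DoseResponseDataset
from .exceptions import ConfigurationError, ValidationError
from .response_models import BellParams, bell_intensity

__all__ = [
    "SimulationConfig",
    "default_truth",
    "default_doses",
    "crp_panel_inflection_points",
    "simulate_dataset",
    "simulate_antibody_panel",
    "truth_implied_asym_params",
]


def default_doses(n: int = 9, lo: float = 0.01, hi: float = 200.0) -> np.ndarray:
    """Log-spaced analyte grid, by default 9 points over 0.01-200 ug/mL."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def default_truth() -> BellParams:
    """Reference hook-shaped truth curve (see module docstring)."""
    return BellParams(Ic=0.5, Ib=0.5, D=10.0, Cs=1.1, Ci=40.0, n1=1.0, n2=4.0)


def crp_panel_inflection_points() -> Dict[float, float]:
    """Observed inflection points (ug/mL) per capture-antibody level (mg/mL).

    These are the experimentally reported 50%-response concentrations for
    the five-condition CRP panel; they serve as the panel scaling when
    emulating that experiment end to end.
    """
    return {0.1: 2.286, 0.5: 1.105, 1.0: 0.981, 1.5: 0.873, 2.0: 0.620}


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated assay condition.

    noise_sigma is interpreted as a fraction of the noiseless curve span
    when ``noise_as_fraction`` (default), otherwise as absolute a.u.
    """

    truth: BellParams
    doses: Optional[Sequence[float]] = None
    replicates: int = 3
    noise_sigma: float = 0.02
    noise_as_fraction: bool = True
    capture_ab_conc: float = 1.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not (np.isfinite(self.noise_sigma) and self.noise_sigma >= 0):
            raise ValidationError("noise_sigma must be >= 0")
        if self.capture_ab_conc <= 0:
            raise ValidationError("capture_ab_conc must be positive")
        doses = default_doses() if self.doses is None else np.asarray(self.doses, dtype=float)
        if doses.ndim != 1 or doses.size == 0 or np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
            raise ValidationError("doses must be strictly increasing positive concentrations")
        object.__setattr__(self, "doses", tuple(float(d) for d in doses))


def simulate_dataset(config: SimulationConfig) -> DoseResponseDataset:
    """Draw one dataset: truth curve plus i.i.d. Gaussian replicate noise.

    The same seed always yields the identical dataset; zero noise yields
    the exact model values at every replicate.
    """
    doses = np.asarray(config.doses)
    means = bell_intensity(doses, config.truth)
    span = float(np.ptp(means))
    sigma = config.noise_sigma * span if config.noise_as_fraction else config.noise_sigma
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, sigma, size=(len(doses), config.replicates)) if sigma > 0 else np.zeros(
        (len(doses), config.replicates)
    )
    intensities = tuple(tuple(means[i] + noise[i]) for i in range(len(doses)))
    return DoseResponseDataset(
        capture_ab_conc=config.capture_ab_conc,
        doses=tuple(doses),
        intensities=intensities,
        label=config.label or f"sim(ab={config.capture_ab_conc} mg/mL)",
    )


def truth_implied_asym_params(
    truth: BellParams,
    doses: Optional[Sequence[float]] = None,
    fix_n: Optional[float] = 1.0,
):
    """Asymmetric-sigmoid parameters implied by a bell truth on a dose grid.

    Runs the noiseless pipeline (simulate at sigma = 0, truncate at the
    hook, fit) and returns the resulting parameters.  This is the
    plug-in estimand that noisy fits converge to: when the hook sits
    close to the stimulatory section it can differ from the generating
    Cs, because the retained saturation points are slightly depressed by
    incipient inhibition.  Recovery tests compare against this value, not
    the raw Cs, so they measure noise sensitivity rather than the
    deliberate contamination built into the truth curve.
    """
    from .curve_fitting import fit_asymmetric, truncate_preprozone

    cfg = SimulationConfig(truth=truth, doses=doses, replicates=1, noise_sigma=0.0)
    pre = truncate_preprozone(simulate_dataset(cfg))
    return fit_asymmetric(pre, fix_n=fix_n).params


def simulate_antibody_panel(
    base_truth: BellParams,
    antibody_concs: Sequence[float],
    c_scaling: Mapping[float, float],
    seed: int = 0,
    ci_scaling: Optional[Mapping[float, float]] = None,
    doses: Optional[Sequence[float]] = None,
    replicates: int = 3,
    noise_sigma: float = 0.02,
) -> list:
    """One dataset per capture-antibody concentration.

    ``c_scaling`` maps each antibody concentration to the stimulatory
    inflection Cs (ug/mL) of that panel's truth curve (e.g. the observed
    CRP panel values from :func:`crp_panel_inflection_points`);
    ``ci_scaling`` optionally rescales the hook inflection likewise.
    Every panel is drawn with the same base seed, so panels sharing a
    truth are identical — determinism is per (seed, truth), not per
    position in the list.
    """
    if len(antibody_concs) == 0:
        raise ConfigurationError("antibody_concs must be non-empty")
    if any(a <= 0 for a in antibody_concs):
        raise ConfigurationError("antibody concentrations must be positive")
    out = []
    for ab in antibody_concs:
        if ab not in c_scaling:
            raise ConfigurationError(f"c_scaling has no entry for antibody concentration {ab}")
        truth = replace(base_truth, Cs=float(c_scaling[ab]))
        if ci_scaling is not None:
            if ab not in ci_scaling:
                raise ConfigurationError(f"ci_scaling has no entry for antibody concentration {ab}")
            truth = replace(truth, Ci=float(ci_scaling[ab]))
        cfg = SimulationConfig(
            truth=truth,
            doses=doses,
            replicates=replicates,
            noise_sigma=noise_sigma,
            capture_ab_conc=float(ab),
            seed=seed,
            label=f"panel(ab={ab} mg/mL)",
        )
        out.append(simulate_dataset(cfg))
    return out
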
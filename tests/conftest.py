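import numpy as np
import pytest

from prozone import (
    AsymParams,
    BellParams,
    DoseResponseDataset,
    SimulationConfig,
    asym_intensity,
    default_truth,
    simulate_dataset,
)


def dataset_from_means(doses, means, capture_ab_conc=1.0):
    """Single-replicate dataset with exactly the given mean intensities."""
    return DoseResponseDataset(
        capture_ab_conc=capture_ab_conc,
        doses=tuple(doses),
        intensities=tuple((float(m),) for m in means),
    )


def noisy_asym_dataset(truth: AsymParams, doses, seed, sigma_frac=0.02, replicates=3):
    """Triplicate data from an asymmetric-sigmoid truth plus Gaussian noise."""
    doses = np.asarray(doses, dtype=float)
    means = asym_intensity(doses, truth)
    sigma = sigma_frac * float(np.ptp(means))
    rng = np.random.default_rng(seed)
    intens = tuple(
        tuple(means[i] + rng.normal(0.0, sigma, replicates)) for i in range(len(doses))
    )
    return DoseResponseDataset(1.0, tuple(doses), intens)


def invert_sigmoid_numerically(par: AsymParams, p: float) -> float:
    """Brute-force oracle: root-find the concentration giving a p% response.

    Expands the bracket around C until it straddles the target, so it
    stays valid for shallow slopes where the percent point sits many
    decades from the inflection.
    """
    from scipy.optimize import brentq

    target = par.Io + (p / 100.0) * (par.Im - par.Io)
    lo, hi = par.C / 2.0, par.C * 2.0
    while asym_intensity(lo, par) > target:
        lo /= 10.0
    while asym_intensity(hi, par) < target:
        hi *= 10.0
    return brentq(lambda x: asym_intensity(x, par) - target, lo, hi, xtol=1e-15, rtol=1e-14)


@pytest.fixture
def hook_truth() -> BellParams:
    return default_truth()

@pytest.fixture
def noiseless_hook_dataset(hook_truth):
    return simulate_dataset(SimulationConfig(truth=hook_truth, noise_sigma=0.0))
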
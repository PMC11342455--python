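"""Truncation and nonlinear least-squares estimation of both curve shapes."""

from dataclasses import replace

import numpy as np
import pytest

from prozone import (
    AsymParams,
    BellParams,
    DoseResponseDataset,
    SimulationConfig,
    asym_intensity,
    bell_intensity,
    fit_asymmetric,
    fit_bell,
    simulate_dataset,
    truncate_preprozone,
)
from prozone.exceptions import InsufficientDataError, ValidationError

from conftest import dataset_from_means, noisy_asym_dataset


class TestDataset:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            DoseResponseDataset(1.0, (1.0, 0.5), ((1.0,), (2.0,)))  # not increasing
        with pytest.raises(ValidationError):
            DoseResponseDataset(0.0, (1.0,), ((1.0,),))  # non-positive antibody
        with pytest.raises(ValidationError):
            DoseResponseDataset(1.0, (1.0, 2.0), ((1.0,), ()))  # empty replicate row

    def test_blank_removed_from_positive_subset(self):
        ds = DoseResponseDataset(1.0, (0.0, 1.0, 2.0), ((0.1,), (1.0,), (2.0,)))
        assert ds.positive_subset().doses == (1.0, 2.0)

    def test_replicate_series_skips_missing(self):
        ds = DoseResponseDataset(1.0, (1.0, 2.0), ((1.0, 1.1), (2.0,)))
        d, v = ds.replicate_series(1)
        assert list(d) == [1.0] and list(v) == [1.1]


class TestTruncation:
    def test_cuts_at_interior_maximum(self):
        ds = dataset_from_means([0.1, 1, 10, 50, 200], [1, 4, 9, 7, 2])
        assert truncate_preprozone(ds).doses == (0.1, 1.0, 10.0)

    def test_monotone_means_kept_whole(self):
        ds = dataset_from_means([0.1, 1, 10, 50, 200], [1, 2, 3, 4, 5])
        assert truncate_preprozone(ds).doses == ds.doses

    def test_tie_breaks_to_lower_dose(self):
        ds = dataset_from_means([0.1, 1, 10, 50, 200], [1, 4, 9, 9, 2])
        assert truncate_preprozone(ds).doses[-1] == 10.0

    def test_requires_three_positive_doses(self):
        ds = dataset_from_means([0.0, 1.0, 2.0], [0, 1, 2])
        with pytest.raises(InsufficientDataError):
            truncate_preprozone(ds)

    @pytest.mark.parametrize("cs,ci,n2", [(0.9, 30.0, 2.0), (1.5, 20.0, 4.0), (0.5, 60.0, 3.0)])
    def test_never_retains_inhibition_phase_points(self, cs, ci, n2):
        # brute-force oracle: the analytic bell peak on a dense grid bounds
        # the retained window; every dropped neighbour lies past the peak
        truth = BellParams(Ic=0.5, Ib=0.5, D=10.0, Cs=cs, Ci=ci, n1=1.0, n2=n2)
        grid = np.logspace(-2, np.log10(200), 9)
        dense = np.logspace(-2, np.log10(200), 20001)
        peak = dense[int(np.argmax(bell_intensity(dense, truth)))]
        ds = dataset_from_means(grid, bell_intensity(grid, truth))
        kept = truncate_preprozone(ds).doses
        dropped = [d for d in ds.doses if d not in kept]
        assert all(d > peak for d in dropped)


class TestBellFit:
    TRUTH = BellParams(Ic=0.8, Ib=0.6, D=9.5, Cs=0.9, Ci=35.0, n1=1.1, n2=2.2)

    def _noiseless(self, truth, n=12):
        doses = np.logspace(-2, np.log10(200), n)
        return dataset_from_means(doses, bell_intensity(doses, truth))

    def test_noiseless_round_trip(self):
        fit = fit_bell(self._noiseless(self.TRUTH))
        assert fit.converged
        for name in ("Ic", "Ib", "D", "Cs", "Ci", "n1", "n2"):
            got, want = getattr(fit.params, name), getattr(self.TRUTH, name)
            assert got == pytest.approx(want, rel=1e-4), name

    def test_degenerate_no_inhibition_truth(self):
        # when the truth has no hook (Ib = D) the fitted right plateau and
        # middle plateau must coincide; under noise the split between them
        # (and Ci, n2) is unidentifiable, so the check runs noiseless
        truth = replace(self.TRUTH, Ib=self.TRUTH.D)
        fit = fit_bell(self._noiseless(truth))
        span = truth.D - truth.Ic
        assert abs(fit.params.Ib - fit.params.D) <= 1e-6 * span

    def test_underdetermined_grid_rejected(self):
        doses = np.logspace(-2, 2, 6)
        ds = dataset_from_means(doses, bell_intensity(doses, self.TRUTH))
        with pytest.raises(InsufficientDataError):
            fit_bell(ds)

    def test_replicate_refits_populate_sem(self):
        ds = simulate_dataset(SimulationConfig(truth=self.TRUTH, noise_sigma=0.02, seed=7))
        fit = fit_bell(ds)
        assert fit.n_replicate_fits == 3
        assert fit.param_sem["Cs"] > 0


class TestAsymFit:
    TRUTH = AsymParams(Io=0.5, Im=10.0, C=1.105, Q=1.0, n=1.0)
    DOSES = np.logspace(np.log10(0.01), 1, 10)

    def test_noiseless_round_trip(self):
        ds = dataset_from_means(self.DOSES, asym_intensity(self.DOSES, self.TRUTH))
        fit = fit_asymmetric(ds)
        assert fit.converged and not fit.decreasing
        assert fit.params.C == pytest.approx(self.TRUTH.C, rel=1e-4)
        assert fit.params.Q == pytest.approx(1.0, rel=1e-3)

    def test_free_steepness_round_trip(self):
        truth = replace(self.TRUTH, n=1.6)
        ds = dataset_from_means(self.DOSES, asym_intensity(self.DOSES, truth))
        fit = fit_asymmetric(ds, fix_n=None)
        assert fit.params.n == pytest.approx(1.6, rel=1e-3)

    def test_monte_carlo_mean_recovery_and_sem(self):
        # replicate-refit SEM procedure: across seeds the mean estimate is
        # close to truth and every SEM is strictly positive
        cs, sems = [], []
        for seed in range(200):
            fit = fit_asymmetric(noisy_asym_dataset(self.TRUTH, self.DOSES, seed))
            cs.append(fit.params.C)
            sems.append(fit.param_sem["C"])
        assert np.mean(cs) == pytest.approx(self.TRUTH.C, rel=0.05)
        assert np.all(np.array(sems) > 0)

    def test_sem_shrinks_with_noise(self):
        sem_at = {}
        for sigma in (0.01, 0.05):
            sems = [
                fit_asymmetric(noisy_asym_dataset(self.TRUTH, self.DOSES, s, sigma_frac=sigma)).param_sem["C"]
                for s in range(100)
            ]
            sem_at[sigma] = np.mean(sems)
        assert sem_at[0.01] < sem_at[0.05]

    def test_decreasing_response_with_negative_steepness(self):
        down = AsymParams(Io=9.0, Im=1.0, C=1.0, Q=1.0, n=1.0)  # decreasing shape
        means = down.Io + (down.Im - down.Io) / (1.0 + down.C / self.DOSES)
        ds = dataset_from_means(self.DOSES, means)
        fit = fit_asymmetric(ds, fix_n=-1.0)
        assert fit.converged
        assert fit.decreasing

    def test_intensity_rescaling_leaves_c_invariant(self):
        ds = noisy_asym_dataset(self.TRUTH, self.DOSES, seed=3)
        scaled = DoseResponseDataset(
            ds.capture_ab_conc,
            ds.doses,
            tuple(tuple(37.5 * v for v in row) for row in ds.intensities),
        )
        f1, f2 = fit_asymmetric(ds), fit_asymmetric(scaled)
        assert f2.params.C == pytest.approx(f1.params.C, rel=1e-8)
        assert f2.params.Im == pytest.approx(37.5 * f1.params.Im, rel=1e-6)

    def test_inverse_variance_weighting(self):
        ds = noisy_asym_dataset(self.TRUTH, self.DOSES, seed=21)
        fit = fit_asymmetric(ds, weights="inverse_variance")
        assert fit.converged
        # triplicate variance weights are noisy, so judge the fit by its
        # 50%-response concentration (stable), not the raw C parameter
        half = fit.params.C / (2.0 ** (1.0 / fit.params.Q) - 1.0)
        assert half == pytest.approx(self.TRUTH.C, rel=0.25)
        with pytest.raises(ValidationError):
            fit_asymmetric(ds, weights="bogus")

    def test_too_few_doses_rejected(self):
        ds = dataset_from_means([0.1, 1.0, 10.0], [1.0, 5.0, 9.0])
        with pytest.raises(InsufficientDataError):
            fit_asymmetric(ds)
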
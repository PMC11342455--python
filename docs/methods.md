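# Methods

## Dose–response model

A hook-affected sandwich assay produces a biphasic dose response: signal
grows with analyte until antigen excess saturates the capture/detection
antibodies, then falls. We model the replicate-mean test-line intensity as
the sum of two logistic sections,

    I(x) = Ic + (D − Ic)/(1 + (Cs/x)^n1) + (Ib − D)/(1 + (Ci/x)^n2),

with plateaus `Ic` (baseline), `D` (hook maximum) and `Ib` (terminal),
half-maximal stimulatory/inhibitory concentrations `Cs`, `Ci` (µg/mL) and
Hill slopes `n1`, `n2`. Intensities are background-subtracted arbitrary
units; both sections involve `C/x`, so blanks (x = 0) are kept in datasets
but excluded from evaluation and fitting. A prozone-shaped parameter set has
`D ≥ Ic`, `D ≥ Ib` and `Cs < Ci`; this is exposed as a predicate
(`BellParams.is_prozone_shaped`) rather than enforced at construction,
because fits to degenerate (hook-free) data legitimately violate it.

The pre-hook subset — doses from the smallest positive dose through the dose
of maximal replicate-mean intensity — is described by the power-of-logistic
(5PL-type) sigmoid

    I(x) = Io + (Im − Io)/(1 + (C/x)^n)^Q.

When `Q = 1` the curve is symmetric about `C` on the log-dose axis and `C`
is exactly the 50%-response concentration; the steepness `n` is fixed to 1
by default (−1 models a decreasing response; the fitted curve's direction is
reported via a `decreasing` flag).

Truncation tie-break: if two doses tie for the maximal mean, the lower one
ends the retained window, which provably (and by enumeration in the tests)
keeps inhibition-phase points out.

## Closed-form working range

For the symmetric case the response level p ∈ (0, 100) % inverts in closed
form: `C_p = C·(p/(100−p))^(1/n)`. This gives the identities
`C_p · C_{100−p} = C²` and `C90/C10 = 81^(1/n)` (exactly 81 at n = 1), both
enforced as property-based tests and cross-checked against numeric root
finding of the sigmoid. The dynamic range is the arithmetic difference
`DR = C90 − C10`, as the working-range definition states; because C10 and
C90 are proportional to C, this difference *shrinks* when potency improves
(C decreases), so a logarithmic variant `dynamic_range_log10 = log10(C90/C10)`
(constant `log10 81 ≈ 1.908` at n = 1 unless the anomaly rule replaces C90)
is reported alongside but is not the default.

## Anomalous-C90 rule

If the signal drops before the fitted plateau is reached, `Im` — and hence
the closed-form C90 — is extrapolated. The symptom is instability of `C`
across replicates: we refit each replicate series separately and compute the
coefficient of variation (population SD over mean) of the per-replicate `C`
estimates. Above a threshold (default 0.5, exposed as `--cv-threshold`) the
dose of maximal mean intensity — which is inside the observed linear range —
is reported as C90 and the condition is flagged anomalous. The default of
0.5 separates tight triplicates (CV of a few percent) from fits whose
replicate inflection points scatter over several-fold ranges.

## Fitting and uncertainty

Both curves are estimated by bounded trust-region-reflective least squares
(SciPy `least_squares`) on replicate means (an option pools replicates as
individual residuals instead). Bounds: concentration parameters within
[min dose/10, max dose·10]; slopes and Q within [0.1, 10]; plateaus within
one observed span of the observed intensity range. Starts are deterministic
and data-driven (baseline/maximum/terminal means; the dose nearest the
half-max crossing for `Cs`/`C`; post-peak half-max for `Ci`; slopes and Q
at 1), so identical data give identical fits. Optimizer failure is reported
through a `converged` flag, never an exception.

Uncertainty follows the replicate-refit scheme: with k replicate series, the
SEM of each parameter is the SD (ddof = 1) of the per-replicate estimates
over √k, and the reported interval is estimate ± SEM — symmetric, matching
how such panel tables are usually printed. The asymptotic
Jacobian-covariance standard errors are exposed separately
(`param_se_cov`). Intervals on C10/C90 scale the C interval by the same
closed-form factor.

The dynamic-range calibration `DR = DR_nonspecific + M·ab` is ordinary least
squares (statsmodels) with 95% t-based confidence intervals; its coverage is
verified by simulation (500 seeds, nominal 95%, observed within [93%, 97%]).
Predictions above the largest fitted antibody concentration are logged as
extrapolations.

## Synthetic data generator

`simulate_dataset` draws replicate intensities as the bell-curve truth plus
i.i.d. additive Gaussian noise, parameterised as a fraction of the noiseless
curve span (default 2%, roughly the replicate scatter of a strip reader);
the default design is 9 log-spaced doses over 0.01–200 µg/mL in triplicate.
The default truth (`Ic = Ib = 0.5`, `D = 10`, `Cs = 1.1`, `Ci = 40` µg/mL,
`n1 = 1`, `n2 = 4`) puts the stimulatory inflection near a mid-range
capture-antibody condition and the hook onset near 17 µg/mL on the default
grid, i.e. inside the 5–20 µg/mL window where such assays typically hook;
the steep inhibitory slope reflects the rapid collapse seen once antigen
excess dominates. `simulate_antibody_panel` emulates a multi-condition
experiment by rescaling `Cs` (and optionally `Ci`) per capture-antibody
concentration; all panels share the base seed, so determinism is per
(seed, truth).

What the generator does **not** emulate: strip-to-strip variation,
reader optics, flow kinetics, heteroscedastic noise, or dose-grid
irregularities of real experiments. Passing recovery tests therefore shows
the estimator handles the idealised noise structure at the stated design,
not that real LFD data will fit this well.

### The truth-implied estimand

When the hook sits close to the stimulatory section, the retained
"saturation" points are slightly depressed by incipient inhibition, so the
asymmetric fit's large-sample limit differs from the generating `Cs`
(about 20% under the default geometry). Recovery tests therefore compare
against the *truth-implied* parameters — the noiseless-pipeline fit,
`truth_implied_asym_params` — which is the estimand the noisy estimator
actually targets. A further numerical fact, measured in the test suite: on
7–10-point log grids the raw `C` parameter trades off strongly against the
asymmetry factor `Q` (per-seed relative spread ~12% even for data generated
exactly from the sigmoid), while the 50%-response concentration
`C/(2^(1/Q) − 1)` is stable to a few percent. Aggregate checks therefore
test the median estimate across seeds (robust bias), and the end-to-end
panel test compares 50%-response concentrations.

## Problem sizes

Monte-Carlo checks use 100 seeds (200 for the SEM calibration, 500 for CI
coverage) at the default 9-dose × 3-replicate design; each fit is a 4–7
parameter least squares on ≤ 12 points, so the full suite runs in well under
a minute on one core.

## Known limitations

- The arithmetic dynamic range inherits the proportionality of C10/C90 to C;
  comparing working ranges across conditions whose response spans differ is
  better done on the log ratio (see above).
- The bell fit on a 9-point grid is weakly identified in its inhibitory
  section (Ci, n2, Ib) when the terminal plateau is not well sampled;
  degenerate hook-free data leave the Ib/D split unidentifiable under noise.
- The anomaly rule's CV threshold is a heuristic; its specificity (≤ 5% false
  alarms at 2% noise on plateau-reaching hooks) is verified by simulation,
  but sensitivity depends on how starved the truncated grid actually is.
- Fits assume homoscedastic noise across doses; inverse-variance weighting is
  available but unweighted means are the default.
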
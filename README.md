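# prozone

Modelling the prozone (hook) effect and the dynamic range of
sandwich-immunoassay lateral-flow devices (LFDs).

In a sandwich assay, test-line signal rises with analyte concentration until
the analyte saturates the antibodies; beyond that point the signal *falls*,
producing falsely low readings at high concentrations (the prozone or hook
effect). This package is for assay developers who need to quantify that
behaviour from dose–response data — e.g. a C-reactive protein (CRP) LFD read
colorimetrically — and to choose a capture-antibody concentration that gives
the working range they need.

## The model

The full dose response is biphasic (stimulation then inhibition), the sum of
two logistic sections:

    I(x) = Ic + (D − Ic) / (1 + (Cs/x)^n1) + (Ib − D) / (1 + (Ci/x)^n2)

with left/middle/right plateaus `Ic`, `D`, `Ib`, half-maximal stimulatory and
inhibitory concentrations `Cs < Ci`, and Hill slopes `n1`, `n2`.

The pre-hook portion (doses up to the intensity maximum) is an asymmetric
sigmoid:

    I(x) = Io + (Im − Io) / (1 + (C/x)^n)^Q

whose inflection point `C` is the concentration at 50% response when the
asymmetry factor `Q = 1`. From a fitted `C` the concentration at any response
level `p` follows in closed form:

    C_p = C · (p / (100 − p))^(1/n)

so with `n = 1`, `C10 = C/9` and `C90 = 9C`, and the **dynamic range** is
`DR = C90 − C10`. When the signal drops before the sigmoid plateau is reached,
the closed-form `C90` extrapolates; that situation is detected by a large
coefficient of variation of `C` across per-replicate fits, and the dose of
maximal observed intensity is reported as `C90` instead (flagged anomalous).
Across capture-antibody concentrations the dynamic range is calibrated
linearly:

    DR(ab) = DR_nonspecific + M · ab

by ordinary least squares with 95% confidence intervals.

## Worked example

Simulate a five-condition capture-antibody panel (triplicates, 9 log-spaced
doses from 0.01 to 200 µg/mL, 1% replicate noise) and analyse it:

```sh
prozone simulate --out demo.csv --seed 7 --noise-sigma 0.01
prozone report demo.csv --out demo_report.json
```

Summarising `demo_report.json` per condition:

```
ab= 0.1 mg/mL  C=1.740  C10=0.193  C90=15.663  DR=15.470  onset=16.8  anomalous=False
ab= 0.5 mg/mL  C=0.841  C10=0.093  C90=7.566   DR=7.473   onset=16.8  anomalous=False
ab= 1.0 mg/mL  C=0.744  C10=0.083  C90=6.696   DR=6.613   onset=16.8  anomalous=False
ab= 1.5 mg/mL  C=0.659  C10=0.073  C90=5.935   DR=5.862   onset=16.8  anomalous=False
ab= 2.0 mg/mL  C=0.461  C10=0.051  C90=4.152   DR=4.101   onset=16.8  anomalous=False
DR line: intercept=12.950  M=-4.947  r2=0.727
```

Reading the numbers: `C` (µg/mL) is the 50%-response concentration — it falls
as the capture-antibody concentration rises, i.e. more antibody makes the
assay more potent. `C10`/`C90` bound the quasi-linear working range,
`onset` is the dose where the hook begins (here ~17 µg/mL on the simulated
grid), and no condition triggered the anomalous-C90 fallback at this noise
level. Because `C10` and `C90` are both proportional to `C`, the arithmetic
range `C90 − C10` shrinks together with `C` in this emulation, which is why
the fitted calibration slope is negative here; see `docs/methods.md` for the
discussion of arithmetic versus logarithmic range (a `dynamic_range_log10`
field is also reported).

The same pipeline is available from Python:

```python
import prozone as pz
from prozone.io_cli import read_dose_response_csv

datasets = read_dose_response_csv("demo.csv")
pre = pz.truncate_preprozone(datasets[0])
fit = pz.fit_asymmetric(pre)                      # n fixed to 1
c10 = pz.concentration_at_response(fit.params.C, 1.0, 10.0)
c90, anomalous = pz.resolve_c90_anomalous(fit, datasets[0])
print(fit.params.C, c10, c90, pz.dynamic_range(c10, c90))
```

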
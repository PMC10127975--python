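# radgrowth

Tumour-growth modelling with radiotherapy, in ordinary and Caputo-fractional
form. The package implements:

- three growth laws (exponential, logistic, exponential-linear) with a
  **continuous radiation death-rate term**: each 2 Gy fraction removes the
  linear-quadratic (LQ) predicted cell kill, spread over a short treatment
  window and switched by a smooth tanh step so the right-hand side stays
  continuous — the prerequisite for well-posed Caputo dynamics;
- a fixed-step **Adams–Bashforth–Moulton predictor–corrector** for Caputo
  fractional ODEs (order `0 < mu <= 1`; at `mu = 1` it collapses to the
  classical AB/AM pair), plus an impulsive stop/restart comparator and a
  Mittag–Leffler series oracle for validation;
- **SSR fitting** with bounded multistart L-BFGS-B under the standard fixed
  assumptions (`alpha/beta = 10` Gy, `K = 2 v0`, `psi = 20`, 15-minute
  windows);
- **model selection**: AICc, BIC, criterion differences, Akaike weights,
  tie-averaged rankings, cohort tallies, and residual-normality checks
  (Shapiro–Wilk and a seeded Monte-Carlo Lilliefors test);
- dynamic **relative-sensitivity** curves (±1% one-sided perturbations);
- a **synthetic cohort generator** that emulates the structure of a
  radiotherapy head-and-neck dataset (66–70 Gy in 2 Gy weekday fractions,
  planning scan, pre-treatment scan, weekly scans, final scan on the last
  treatment day), so everything is testable with no external data;
- a repeated-fit **benchmark harness** comparing smooth-window,
  hard-window and impulsive kill representations.

## CLI

```sh
radgrowth cohort --n-patients 19 --sigma 0.05 --seed 1 --out cohort/
radgrowth fit --data cohort/patient_01.csv --protocol cohort/protocol_01.yaml \
              --model exp --starts 20 --seed 1 --out fit_exp.json
radgrowth fit --data cohort/patient_01.csv --protocol cohort/protocol_01.yaml \
              --model exp --fractional --seed 1 --out fit_fexp.json
radgrowth compare --fits fit_exp.json --fits fit_fexp.json --out table.csv
radgrowth sensitivity --fit fit_exp.json --protocol cohort/protocol_01.yaml \
              --param alpha --direction -1 --out curve.csv
radgrowth simulate --fit fit_exp.json --protocol cohort/protocol_01.yaml \
              --t-end 51 --out traj.csv
radgrowth benchmark --data cohort/patient_01.csv --protocol cohort/protocol_01.yaml \
              -m 10 --out bench.json
```

Models: `exp`, `log`, `explin`; add `--fractional` to fit the Caputo order
`mu` as well. All commands are deterministic given `--seed`.

## Layout

```
src/radgrowth/
  models.py       growth laws, LQ kill, smooth windows, fractionation
  solver.py       Caputo ABM, impulsive comparator, Mittag-Leffler
  _kernels.py     numba hot loops (BLAS-dot history sums)
  fitting.py      SSR objective, multistart bounded fits
  selection.py    AICc/BIC, weights, rankings, normality tests
  sensitivity.py  relative-sensitivity curves
  cohort.py       synthetic patient generator
  benchmark.py    repeated-fit timing harness
  io.py, cli.py   plain-text formats and the click CLI
```

Units: time in days (nondimensionalized by 1 day), volumes in cm^3, doses
in Gy; the default treatment window is 15 minutes = 1/96 day and the
default solver step is 5 minutes = 1/288 day.
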
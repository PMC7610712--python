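# isostim

Phase-space optimization of pulsatile stimulation in stochastic
Wilson–Cowan tremor models.

The package builds two kinds of scalar amplitude fields over the (E, I)
phase plane of a two-population neural mass with a stable focus:

* **isostable amplitude** — computed by flowing the deterministic system
  for several linear periods and reading off two linear observables of the
  endpoint (exact exponential decay along trajectories);
* **Hilbert amplitude** — Monte-Carlo averages of the analytic-signal
  envelope of the excitatory activity over many stochastic trajectories,
  with mean- or fixed-point-centering.

From either field it derives the **instantaneous response field**
`gamma0(X) = Omega(X + (dE, 0)) - Omega(X)` (negative = a pulse reduces
amplitude) and an **augmented field** `gamma(i, j, k)` sampling `gamma0`
along deterministic trajectories over one oscillation period.  A
closed-loop controller then decides at every integration step whether to
pulse now or wait for a better moment within the period, discounting
uncertain future benefits with a tunable factor `b`, under a 10 Hz rate cap
and a one-pulse-per-period rule with online zero-crossing phase tracking.
Phase-locked stimulation (12-bin target-phase calibration) and open-loop
130 Hz stimulation (with efficacy-matched magnitude search) serve as
baselines; efficacy is the integrated Welch PSD of E and energy is the sum
of squared pulse magnitudes.

No patient data is required: `isostim.fixtures` generates synthetic
stable-focus "patients" (~5 Hz, activities confined to (0, 1),
suppressible by both pulsatile and continuous drive) by seeded rejection
sampling, and three frozen models ship with the package under
`src/isostim/data/patients/`.

## CLI

```bash
isostim fixture --seed 1 --out patient.json
isostim field --kind isostable --quality quick --model patient.json --out field.npz
isostim field --kind hilbert-mean --quality quick --model patient.json --seed 2 --out hfield.npz
isostim augment --field field.npz --model patient.json --dE 0.005 --out gamma.npz
isostim run --model patient.json --gamma gamma.npz --b -5 --dE 0.005 \
    --duration 300 --seed 1 --out run.npz
isostim baseline phase-locked --model patient.json --dE 0.005 --duration 300 \
    --seed 1 --calib-duration 120 --out pl.npz
isostim baseline hf --model patient.json --dE 0.01 --duration 300 --seed 1 --out hf.npz
```

## Layout

```
src/isostim/
  wc_model.py    stochastic/deterministic Wilson-Cowan dynamics, focus analysis
  isostable.py   grids, isostable amplitude, field computation (full/quick)
  hilbert.py     analytic-signal amplitude, Monte-Carlo Hilbert fields
  response.py    instantaneous + augmented response fields, support harmonization
  controller.py  phase tracking, temporal discounting, closed-loop decision rule
  baselines.py   phase-locked and high-frequency stimulation, magnitude matching
  evaluation.py  PSD-integral efficacy, trial batching, energy, comparison tables
  fixtures.py    synthetic patient generator, occupancy grids, canned toy cases
  _kernels.py    numba inner loops (mirrored 1:1 by the pure-Python paths)
  cli.py         command-line interface
```
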
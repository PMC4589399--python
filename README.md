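# petkin

Two-tissue-compartment FDG kinetics for dynamic small-animal PET.

## The problem

Static FDG-PET summarizes uptake with SUVmax, which cannot tell a lung
tumor from lung inflammation: inflammatory cells overexpress glucose
transporters and accumulate FDG just as avidly.  Dynamic acquisition
plus kinetic modeling resolves the ambiguity — the *rate structure* of
uptake differs even when the late-frame intensity does not.  `petkin`
implements the full analysis chain for this setting, aimed at people
analyzing (or simulating) dynamic rodent FDG studies: preclinical
imaging groups, kinetic-modeling methodologists, and anyone who wants a
tested reference implementation of the standard machinery.

## What it computes

The tracer follows the two-tissue (three-compartment) model

    dCe/dt = K1·Cp(t) − (k2 + k3)·Ce(t) + k4·Cm(t)
    dCm/dt = k3·Ce(t) − k4·Cm(t)
    CT(t)  = [Ce(t) + Cm(t)] + VB·Cp(t)

whose closed-form solution (a bi-exponential kernel with eigenrates
α₁,₂ = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4k2k4)]/2, convolved with the
plasma input Cp) is fitted to measured time-activity curves by bounded
nonlinear least squares with an exact Jacobian.  The discriminating
statistic is the net influx constant **Ki = K1·k3/(k2+k3)** (mL/s/g).

Around the core model:

- **Input functions** — a Feng-type bolus for simulation; image-derived
  whole-blood curves from a blood-pool ROI, converted to plasma with the
  time-dependent ratio R_PB(t) = 0.432·e^(−0.168·t[min]) + 1.158.
- **Patlak graphical analysis** as an independent estimator (slope → Ki
  for irreversibly trapped tracer; underestimates when k4 > 0).
- **ROI handling** — ellipsoid ROIs, ±40%-band region-growing
  refinement, TAC extraction, SUV/SUVmax on the last frame.
- **Synthetic data** — six group presets with published mouse
  rate constants, the 29-frame / 3093 s acquisition schedule,
  frame-integrated noise, and 4D phantoms with blood pool and lesions.
- **Statistics** — Kruskal–Wallis (χ² or exact permutation), Dunn
  post-hoc with Holm adjustment, a same-location/same-lesion contrast
  layout, and Pearson R² metric correlation.

## Worked example

Simulate one subcutaneous-tumor subject (published group-mean rate
constants, 5% frame noise, 30% biological jitter) and estimate its Ki:

```python
import petkin as pk
from petkin.synthetic import GROUP_PRESETS, NoiseModel, simulate_subject_tacs

schedule = pk.mouse_dynamic_schedule()     # 2x1.5 s ... 1x900 s, 29 frames
bolus = pk.default_mouse_bolus()           # ~21 MBq/mL peak, 5 s delay
preset = GROUP_PRESETS["subcutaneous_tumor"]

plasma, tissue, truth = simulate_subject_tacs(
    preset, bolus, schedule, NoiseModel(proportional_sd=0.05, seed=11)
)
fit = pk.fit_compartment_model(plasma, tissue, seed=0)
print(f"true Ki   = {pk.influx_constant(truth):.4e} mL/s/g")
print(f"fitted Ki = {fit.ki:.4e} mL/s/g  (converged: {fit.converged})")

patlak = pk.patlak_fit(plasma, tissue)
print(f"Patlak slope = {patlak.slope:.4e} mL/s/g (R^2 = {patlak.r_squared:.3f})")
```

prints

```
true Ki   = 4.2592e-04 mL/s/g
fitted Ki = 4.1164e-04 mL/s/g  (converged: True)
Patlak slope = -2.9429e-05 mL/s/g (R^2 = 0.650)
```

The fitted Ki lands within ~3% of this subject's true value.  The
Patlak slope is near zero instead of 4e−4: over a ~52-minute window
even this lesion's modest dephosphorylation (k4 ≈ 0.002 /s) washes out
the "irreversibly trapped" signal the Patlak plot relies on — the
reason the full model fits k4 rather than assuming it away.

A shell interface wraps the same functions
(`petkin fit|patlak|simulate|phantom|roi-refine|extract-tac|suvmax|group-stats`);
TACs travel as TSV, volumes as NIfTI with a JSON frame-schedule sidecar,
results as JSON.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the pipeline end to end from scratch: it builds a zero-noise 4D
phantom (blood pool + lesion), extracts and plasma-calibrates the
image-derived input function, refines the lesion ROI by region growing,
fits the compartment model and the Patlak line, computes SUVmax, then
simulates the six experimental cohorts (n = 5, 5, 4, 4, 9, 6), fits
every subject, and runs the Kruskal–Wallis group comparison — printing
the recovered Ki against the painted truth and the six-group test along
the way, and writing the JSON report to `--out`.

See `docs/methods.md` for the model assumptions, numerical choices,
identifiability analysis, and known limitations.
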
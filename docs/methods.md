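# Methods

## The model

`petkin` analyzes dynamic FDG-PET of small animals with the standard
two-tissue (three-compartment) model.  Plasma tracer Cp(t) exchanges
with free intracellular FDG Ce(t), which hexokinase phosphorylates into
a (slowly reversible) bound pool Cm(t):

    dCe/dt = K1 Cp(t) − (k2 + k3) Ce(t) + k4 Cm(t)
    dCm/dt = k3 Ce(t) − k4 Cm(t)
    CT(t)  = [Ce(t) + Cm(t)] + VB Cp(t)

with K1 (mL s⁻¹ g⁻¹) delivery, k2 (s⁻¹) efflux, k3 (s⁻¹)
phosphorylation, k4 (s⁻¹) dephosphorylation and VB the fractional
vascular volume.  The measured curve CT is modelled exactly as the sum
above — the tissue term is *not* rescaled by (1 − VB); this follows the
formulation the package reproduces, and the convention matters when
comparing fitted VB across software.

The homogeneous system has eigenrates

    α₁,₂ = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4 k2 k4)] / 2,

real and non-negative for all admissible rates since the discriminant
equals (k2−k4)² + k3² + 2k3(k2+k4).  The closed-form solution is a
bi-exponential kernel convolved with Cp plus the vascular term; when
α₁ = α₂ (within 1e−12 relative, i.e. k3 = 0 and k2 = k4) the kernel
switches to its confluent limit K1[(k3+k4−α)t + 1]e^{−αt}.

The summary statistic of interest is the net influx (trapping) constant

    Ki = K1 k3 / (k2 + k3)   (mL s⁻¹ g⁻¹),

defined as 0 when k2 + k3 = 0 (no exchange, no trapping flux).

## Numerics of the forward model

The convolution is evaluated on a piecewise-uniform grid (0.1 s where
the bolus varies fast, 1 s in the tail for fitting; 0.05/0.5 s for data
generation).  Cp is treated as piecewise linear between grid samples and
each exponential-kernel segment integral is computed in closed form, so
the only discretization error is in representing Cp, not in the
convolution itself.  The recursion y_{n+1} = e^{−αh}y_n + (local
integral) runs through `scipy.signal.lfilter`.  Frame averages are taken
with an exact trapezoid weight matrix, making a model evaluation two
convolutions and a matrix product (~0.2 ms).

An independent fixed-step RK4 integrator (0.05 s for t < 120 s, 0.5 s
after) serves as the oracle: across random parameter sets the two routes
agree to better than 1e−4 relative over a full hour.

## Input function

For simulation, Cp is a Feng-type bolus
(A1(t−d) − A2 − A3)e^{−λ₁(t−d)} + A2 e^{−λ₂(t−d)} + A3 e^{−λ₃(t−d)}
with a 5 s injection delay.  Shape rates follow the classic FDG
arterial-curve fit converted to per-second units (λ₁ = 0.0689, λ₂ =
0.0021, λ₃ = 1.7e−4 s⁻¹); amplitudes are set so the peak plasma
concentration is ~21 MBq/mL, the scale expected when the study's mean
dose (5.55 MBq) distributes through a ~21 g mouse's blood pool, with a
`scale` knob for other doses.  A known limitation: these shape rates
derive from human data, and a real mouse bolus is sharper; a sharper
bolus would carry more information about fast rate constants, so the
identifiability results below are, if anything, conservative on the slow
side for the bolus width.

In image space the input function is the blood-pool (left-ventricle)
ROI mean — whole-blood activity — converted to plasma with the
time-dependent ratio R_PB(t) = 0.432·e^{−0.168·t[min]} + 1.158,
evaluated at each frame's midpoint (the package-wide convention for
per-frame time stamps; it makes results bit-reproducible).  This is the
single place where time enters in minutes.  No partial-volume or
spill-over correction is applied to the IDIF.

Because the fitter receives frame *averages*, not point samples, the
plasma curve handed to the convolution is reconstructed as a
shape-preserving cubic (PCHIP) with knots at Cp(0) = 0 and the frame
midpoints whose own frame averages are iterated to match the measured
TAC (preconditioned fixed point, 8 iterations).  Plain interpolation of
the TAC values understates the curve around the bolus peak, where frames
are 5 s wide, and biased Ki by ~1%; with the consistent reconstruction
the zero-noise end-to-end bias is ~0.2%.

## Fitting

`fit_compartment_model` minimizes Σ w_f (model_f − y_f)² over
(K1, k2, k3, k4, VB) with non-negativity bounds and VB ∈ [0, 1), using
bounded trust-region least squares with the exact analytic Jacobian
(∂/∂α of the exponential convolution is minus the t·e^{−αt}
convolution, so the full Jacobian costs about two extra convolutions).

Weights default to inverse variance under proportional measurement
noise, w_f = 1/max(|y_f|, 0.01·max|y|)².  Duration weighting
(w_f ∝ frame length) is available but not the default: with this
protocol the 0.5 s and 900 s frames differ in weight by 1800×, which
discards the early frames carrying most of the kinetic information; in
benchmarks duration weighting inflated the Ki error of several presets
an order of magnitude above the Cramér–Rao bound, while
inverse-variance weighting reaches it.

The objective is multi-modal because the rates span four orders of
magnitude.  Ten seeded Halton points in log-parameter space (K1 ∈
[1e−5, 1], k ∈ [1e−6, 2], VB ∈ [0, 0.5]) are ranked by initial
residual; the best five run 15 trust-region iterations each; the two
lowest-cost survivors are polished to convergence (ftol 1e−8, ≤100
iterations).  Ties break on lowest RSS then the lexicographically
smallest parameter vector, so the whole fit is deterministic given data
and seed.  k4 is always fitted by default (the data this package
emulates show clearly non-zero dephosphorylation); `fix_k4=True` gives
the irreversible, Patlak-comparable model.  Approximate standard errors
come from the final weighted Jacobian.

Degenerate data are reported, not guessed at: an all-zero tissue TAC
returns a flagged non-converged zero result.  A purely vascular TAC
(tissue = VB·Cp) is fit equally well by VB alone or by a fast
K1/k2 equilibrium — K1 is then not identified — but Ki = 0 is recovered
either way.

`patlak_fit` regresses CT/Cp on (∫₀ᵗCp)/Cp over frames with midpoint
≥ t* (default 600 s, by which all presets have passed their
equilibration time 1/(k2+k3)).  Point values and the running integral
come from the same reconstructed plasma curve.  The slope estimates Ki
only under irreversible trapping; with k4 > 0 the plot bends and the
slope underestimates Ki — over this ~52 min acquisition even
k4 ≈ 0.002 s⁻¹ drives the late slope near zero, which is exactly why
the full model fits k4.

`goodness_of_fit` reports per-frame residuals and
AIC = n·ln(RSS_w/n) + 2p for comparing the free-k4 and frozen-k4 fits
on one TAC.

## ROI handling and SUV

Manual ROIs are ellipsoids in voxel space (voxel-center inclusion test
in mm).  Region growing refines them for kinetic analysis: on a
time-averaged image (default: last frame) the initial ROI's mean m
fixes the acceptance band [0.6m, 1.4m]; growth starts at the ROI's
hottest voxel and proceeds by face (6-neighbor) connectivity.  The band
is fixed during growth — iterative recomputation has no published
recurrence and is unstable.  If the seed itself falls outside the band
the seed alone is returned with a warning.  Whether the ±40% band
should reference the manual or the refined ROI mean is ambiguous in the
source description; the manual ROI's mean is used.

SUV = concentration / (injected dose / body weight); SUVmax/SUVmean are
taken on the schedule's final frame.  The printed protocol's final
frame spans ≈36.5–51.5 min although the acquisition is described as
60 min with static analysis "at 45–60 min"; the implementation trusts
the schedule object it is given.

## Synthetic data

The generator emulates the six-group mouse study the package was built
around: six presets carry the published group-mean rate constants,
cohort sizes (5, 5, 4, 4, 9, 6), published SUVmax summaries and
published group-mean Ki.  The published Ki means average per-animal Ki
and therefore do not equal Ki of the group-mean rates (e.g.
subcutaneous tumor: 4.55e−4 computed vs 3.95e−4 printed); both numbers
are kept, and the printed means are never used as oracles for the
fitting chain.  The spontaneous-liver Ki is printed 0.0033 mL/s/g in
the results table but 0.033 in the running text; the table value is
used.  No per-group VB was published; VB = 0.05 everywhere.

Between-subject spread is mean-preserving log-normal jitter of the four
rates (default CV 30%): only group means were published and rates are
positive, making this the minimal positive-support choice.  Measurement
noise is Gaussian per frame, sd = proportional_sd·value (default 5%)
plus an optional floor, optionally scaled by 1/√(duration/60 s) to
emulate count statistics; clipped at zero.  Plasma TACs are noiseless
by default (the LV blood pool is a large ROI).  All randomness flows
from explicit seeds.

Phantoms paint frame-averaged region TACs into a 64³ grid of 0.5 mm
voxels: lesions from their kinetics, background from a low-uptake
muscle-like preset, and the blood pool with *whole-blood* activity
(frame-averaged plasma divided by R_PB at the frame midpoint — the same
convention the calibration applies, so the IDIF → calibration round
trip is exact at zero noise and the calibration step is exercised
non-trivially).

What a green test does not establish: the generator has no scanner
physics (attenuation, scatter, randoms, decay, reconstruction
artifacts, partial volume), no respiratory motion, no input-function
delay/dispersion beyond the fixed 5 s, and bolus shape rates are
human-derived.  Recovery results quantify estimator behavior under the
stated noise model, not scanner-grade accuracy.

## Identifiability of Ki

For presets with fast turnover (in-situ inflammation: k2 = 0.674,
k3 = 0.148, k4 = 0.56 s⁻¹) both eigenrates exceed 0.37 s⁻¹: the tissue
kernel relaxes within ~10 s and the curve is observationally close to a
single-compartment response.  A Cramér–Rao computation at the truth
(exact Jacobian, proportional 5% noise, this frame schedule) bounds the
relative sd of *any* unbiased Ki estimator at ≈6 for that preset (and
≈18 for spontaneous liver, where the bounded estimator in practice does
much better, ~8–10% median error).  This is a property of the
parameters, protocol and noise, not of the optimizer — at 5% noise the
fitted Ki for such tissue is scatter, and pooled-cohort summaries are
the honest way to report recovery.  The four slower presets recover Ki
with 3–8% median error at 5% noise, near their bounds.

## Statistics

Group comparisons use the Kruskal–Wallis rank test with mid-rank ties
and tie correction; p-values come from the χ² approximation, or from
full permutation enumeration for pooled samples of ≤10 (the enumeration
works on precomputed ranks, so all C(N, n₁,…) assignments are cheap).
Significant omnibus results (α = 0.05) are followed by Dunn's pairwise
z tests on the pooled ranks with Holm adjustment by default (Bonferroni
and unadjusted modes exist; the study's own adjustment method is not
identifiable from its description).  `run_group_analysis` additionally
evaluates a named contrast layout — lesion types at the same location,
one lesion type across locations — because small-cohort studies report
those subset comparisons directly (two-group KW for pairs).
Metric association is Pearson R² with its two-sided p; constant input
is flagged rather than propagated as NaN arithmetic.

Type-I error of the omnibus at the study's cohort sizes (5,5,4,4,9,6)
measures 0.03–0.07 at α = 0.05 over 2000 null simulations.

## Tolerances and defaults worth knowing

| Parameter | Default | Why |
|---|---|---|
| convolution grid (fit) | 0.1 s to 150 s, then 1 s | bolus structure vs runtime; ≤0.3% frame deviation |
| confluence threshold | α₂−α₁ ≤ 1e−12·max(α₂,1) | switch to the analytic limit kernel |
| fit bounds | K1≤2, k≤5, VB≤0.99 | generous superset of reported rodent values |
| multi-start | 10 Halton, screen 5×15 it, polish 2 | deterministic, ~0.17 s per fit |
| Patlak t* | 600 s | past 1/(k2+k3) for all presets; configurable |
| noise model | 5% proportional, no duration scaling | "5% noise" as stated; scaling available |
| jitter CV | 30% | plausible biological spread given only means |
| phantom | 64³ × 0.5 mm | mouse scale, seconds-level tests |
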
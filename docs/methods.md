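# Methods

This note documents the models, estimators, numerical choices and known
limitations of `ivivekit`, in the spirit of a package methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scope and assumptions

The package models the clearance side of a rat radiotracer study for three
neutral xanthine A₁-receptor ligands: hepatic metabolism is assumed to be
the dominant elimination route (ECCS class 2 compounds), the blood/plasma
concentration ratio is fixed at 1, plasma density is taken as 1 g/mL, and
dosing is treated as an instantaneous bolus at t = 0 (the actual infusion
lasts ~1 min; the fitted model is a bolus model, so the generator emulates
one). Parallel-tube/dispersion liver models, transporter-mediated clearance
and compartmental whole-body physiology are out of scope.

## In vitro module

Depletion replicates are fitted individually by unweighted nonlinear least
squares in percent space, with C₀ free rather than pinned at 100: the t = 0
normalization makes the first point exact by construction, but replicate
noise at later points is better absorbed with a free intercept. A log-linear
regression on the positive points only seeds the optimizer. Fits whose
half-life falls outside [0.1, 10 000] min are reported as failures, not
clamped — a 20-min assay cannot support half-lives outside that window, and
silently clamping would fabricate precision.

Reported per-compound values follow the triplicate-assay convention:
arithmetic mean ± sample SD of the per-replicate half-lives and of the
per-replicate scaled clearances. Note a small-sample subtlety verified in
the test suite: with six samples over 20 min and 5% multiplicative noise,
the per-replicate rate is estimated with ~15% error, and because
t₁/₂ = ln2/k is convex in k the *arithmetic mean* of fitted half-lives is
biased high by roughly the squared relative error (~+3% for the most stable
compound). Unbiasedness therefore has to be (and is) asserted on the rate
scale or the median; the tabulated mean ± SD is kept because it is the
field's reporting convention.

The binding correction divides the half-life by f_mic (unbound intrinsic
clearance convention); with the lipophilicity relationship above, f_mic is
strictly decreasing in protein concentration and — for log P above the
quadratic's vertex at ≈ −0.465 — in lipophilicity.

## Well-stirred module

CL_p = Q·f_p·CL_int/(Q + f_p·CL_int) with Q = 55 mL/min/kg. The algebraic
inverse f_p = CL_p·Q/(CL_int·(Q − CL_p)) is provided for back-solving free
fractions from published clearance pairs; it round-trips through the
forward model to machine precision and is how the shipped default free
fractions (0.027, 0.044, 0.017 for CBX/MCBX/CPFPX) were reconstructed —
they are derived values, not measurements. AFE uses log base 10; all
rounding (2 d.p. for fold errors and AFE, 1 d.p. for RMSE) happens at the
reporting layer only.

## In vivo module

**Corrections.** Decay correction multiplies measured activity by
2^(t/T½) referenced to injection time (¹⁸F: 109.77 min, configurable).
Metabolite correction multiplies total-radioactivity concentration by the
parent fraction. Both are multiplicative, hence order-independent.

**Parent-fraction handling.** Two routes exist. The low-level route
linearly interpolates each animal's own measured series with boundary
clamping. The default route of the high-level estimators (`study_pk`,
`mean_curve_pk`) is population-based: a three-parameter Hill model
pf(t) = f_end + (1 − f_end)/(1 + (t/t50)^h) is fitted to the pooled
measurements of all animals and used to correct every curve. The reason is
quantitative and matters: an additive parent-fraction error of 0.02 is an
8–30% *relative* error late in the study where the parent fraction is
0.07–0.25, and per-animal interpolated corrections inject that error
directly into the terminal phase, destabilizing λ₃ and biasing the fitted
AUC (clearance errors of 10–25% in simulation). Pooling and smoothing turn
that point noise into a small, smoothly varying distortion that mostly
rescales the tail instead of tilting it. Population-based metabolite
correction is standard practice for radiotracer input functions.

**Triexponential fitting.** Initialization is by curve stripping: log-linear
fit of the tail third for the slowest phase, peel, repeat. Refinement is
bounded nonlinear least squares in log-parameter space (positivity for
free), multi-started from the stripping seed, a cloud of perturbed seeds
(half local σ = 0.3, half wide σ = 1.0), box-uniform probes, and
deterministic probes at the rate bounds. Ties are broken by lowest residual
sum of squares, then largest λ-spread. The box constraints are an
identifiability requirement, not a convenience: a component with
λ·t_first ≫ 1 decays entirely before the first sample and can contribute
arbitrary area A/λ at negligible cost to the objective — in simulation this
produced "fits" with A₁ ~ 10¹³ and clearance estimates near zero. Rates are
confined to [0.05/t_last, 3/t_first] and amplitudes to ≤ 50× the observed
maximum; optima on these bounds are legitimate and the multistart probes
them explicitly. Fits with a near-zero amplitude or poorly separated rates
are flagged in `warnings` rather than rejected (biexponential data are the
classic trigger).

**Weighting.** `fit_triexponential` is unweighted by default at the
operation level. The high-level estimators default to relative (1/y²)
weighting: plasma curves span a ~50-fold range while the dominant error
sources scale roughly with the signal, and under uniform weights the large
early concentrations dominate the objective and the terminal phase — which
carries the V_d and t₁/₂ information — is effectively ignored. Uniform
weighting remains available (`weighting="uniform"`).

**Aggregation.** Mean curves are pointwise arithmetic means (with sample SD)
of corrected per-animal concentration curves on a shared nominal grid;
mismatched grids are an error, not a resampling trigger. Concentration
averaging is the default; SUV averaging (dose- and weight-normalized) is
available behind `use_suv=True`. Mean-curve clearance uses the cohort-mean
dose and body weight. In simulation the mean-curve clearance and the mean
of individual-animal clearances agree to ~1% (median) across compounds and
seeds, well inside the few-percent agreement expected of the two routes.

## Synthetic-data generator

The generator emulates the three experiments with the study's stated
conditions as defaults: depletion sampling at 0/2/5/10/15/20 min in
triplicate with 5% multiplicative lognormal noise renormalized to 100% at
t = 0; arterial sampling of 8 animals on a 1–180 min grid (dense early,
sparse late: 1, 2, 3, 5, 7.5, 10, 15, 20, 30, 40, 60, 90, 120, 150, 180);
body weight 503 ± 44 g, injected activity 21 ± 2.5 MBq, injected amount
0.39 ± 0.20 nmol; ultrafiltration of 5–6 kBq spikes with 50/250 µL aliquot
counting.

Ground-truth plasma curves are constructed so the clearance, volume and
half-life identities hold exactly before noise: λ₃ = CL_p/V_d (a stated
terminal half-life inconsistent with ln2·V_d/CL_p by >2% is a configuration
error), λ₁ = 20λ₃ and λ₂ = 4λ₃ as shape defaults producing three visually
distinct phases, A₁:A₂ = 3:1, and A₃ set so the terminal phase carries a
configurable fraction (default 0.5) of the total AUC implied by CL_p. That
last parameter replaces a dose-over-V_d intercept construction, which is
internally inconsistent: because V_d = CL_p/λ₃, an intercept A₃ = D/(V_d·BW)
makes A₃/λ₃ equal the *entire* AUC, leaving nothing for the fast phases.
With the defaults, the implied central volume (dose over the t = 0
intercept) comes out near 65 mL/kg — plasma-like, as it should be.

Parent-fraction truths sit on the Hill curves (f_end, t50, h) =
(0.2493, 6.60, 2.094), (0.1287, 6.63, 1.966), (0.0695, 5.59, 2.185) for
CBX/MCBX/CPFPX, which pass through the reported 1/2/3-min fractions
(98–99%, 91–94%, 81–88%) and 180-min fractions (≈25%, 13%, 7%) to within
0.006. Using one smooth family for both the generator truth and the
analysis-side population fit keeps the metabolite correction unbiased.

What the generator sees that real data would not: measured samples are
emitted as what a γ-counter reports — total (parent + metabolite)
radioactivity with physical decay applied and Poisson counting noise at a
configurable efficiency (0.5 counts/Bq) and integration time (60 s, the
realistic γ-counting choice; without an integration time a ~30 Bq filtrate
aliquot would carry ~26% counting error, which no laboratory would accept).
The pipeline must undo both corrections to recover the truth.

What it does *not* emulate: inter-animal variability in curve *shape*
(λ ratios are shared; only clearance varies, at 10% CV, an assumed value),
parent-fraction shapes outside the Hill family, infusion kinetics,
blood-to-plasma partitioning dynamics, nonspecific binding to the
ultrafiltration device (a known limitation of the assay itself), and any
saturable/transporter processes. Passing recovery tests therefore shows the
estimators are correct and stable under realistic noise — not that the
triexponential model is the right description of arbitrary real curves.

## Numerical choices

Monoexponential and triexponential optimizations run scipy
`least_squares` with tight tolerances (1e-14); the triexponential uses
log-parameter bounds as above. The triexponential's analytic AUC (ΣAᵢ/λᵢ)
is cross-checked against adaptive quadrature to 1e-6 relative in the test
suite, and both fitters are checked against independent oracles (a 0.01-min
grid search with the intercept profiled out; a 200-random-restart
multistart over the same bounded space). Ties, degenerate inputs and
physically impossible measurements (filtrate counts exceeding plasma
counts) raise typed errors rather than being repaired silently.

## Problem sizes

Simulation-based tests use 8-animal studies (the cohort size of two of the
three study arms; the third used 9), 10–20 seeds per compound for recovery
statistics, 50 seeds for the depletion Monte Carlo and 100 for the
ultrafiltration Monte Carlo; these sizes give stable medians while keeping
the default suite fast.
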
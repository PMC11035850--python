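# Methods

`ventclear` quantifies how fast an intravenously injected radiotracer is
cleared from ventricular CSF in a dynamic PET scan, and how that clearance
relates to tracer delivery by blood, in a two-group (TBI vs. control)
cohort design. This note documents the models, the estimation machinery,
the synthetic cohort generator, and the numerical and design choices, in
that order.

## Forward models

All quantities are decay-corrected activity concentrations (kBq/mL);
physical isotope decay is never modeled. Rate constants are in 1/min (K1 in
mL·cm⁻³·min⁻¹). PET frames measure time-averaged activity, so every model
output is averaged over each frame of the acquisition schedule before
comparison with data. The default schedule has 22 frames over 60 min
(6×10 s, 3×20 s, 3×60 s, 2×150 s, 4×300 s, 4×450 s): fine early sampling
for the input peak, long late frames for count statistics.

**Ventricle clearance.** The ventricular concentration Cv obeys

    dCv/dt = k1_blood·Cp(t) + k1_tissue·C_tis(t) − k_clearance·Cv,  Cv(0)=0

with Cp the blood input (IDIF) and C_tis the unbound gray-matter curve.
`k1_blood` is delivery from blood (choroid plexus), `k1_tissue` delivery
from interstitial fluid through gray matter, and `k_clearance` the
first-order washout — the net measure of brain fluid clearance. The
*blood-only* variant drops the tissue term. The solution is a sum of
exponential convolutions,
Cv = k1_blood·(Cp ⊛ e^{−k_clearance t}) + k1_tissue·(C_tis ⊛ e^{−k_clearance t}).

**Gray matter.** A standard two-tissue compartment model
(dC1/dt = K1·Cp − (k2+k3)·C1 + k4·C2; dC2/dt = k3·C1 − k4·C2) fitted to the
gray-matter TAC supplies the unbound curve C1 used as the dual model's
tissue input. It is solved by eigen-decomposition of the 2×2 system (two
convolution modes); the repeated-eigenvalue case uses the t·e^{−αt} kernel
analytically rather than a numerical nudge.

**Synthetic input.** Simulated subjects use a Feng-form arterial input
C(τ) = (A1·τ − A2 − A3)e^{−λ1τ} + A2·e^{−λ2τ} + A3·e^{−λ3τ}, τ = t − t0.
Defaults (A1=800 kBq/mL/min, A2=25, A3=15 kBq/mL, λ=4.0/0.25/0.04 min⁻¹,
t0=0.5 min) put the peak near 0.8 min at ~98 kBq/mL and give a blood curve
that has largely cleared by 60 min, so that a ventricle curve with
clearance at the control group mean peaks mid-scan and *declines* by the
end of the acquisition — the qualitative shape seen in real scans. These
input parameters are generator conveniences, not measured values.

## Numerics

Curves live on a uniform fine grid, default dt = 0.01 min over [0, 62] min.
Convolution with e^{−kt} is exact for the piecewise-linear interpolant of
the input: each step contributes analytically and accumulates through the
one-step decay recurrence (evaluated by a linear filter; a series expansion
takes over for k·dt < 1e-4 to avoid cancellation). Frame averages are exact
trapezoidal means of the interpolant, implemented as a cached linear
operator (a 22×N matrix) because the fitting loop evaluates thousands of
model curves on one fixed grid. Against RK45 integration at rtol 1e-9 the
forward models agree to better than 1e-6 relative over random parameter
grids; refining dt to 0.005 changes frame averages by <0.1% at default
parameters. The heavy simulation studies in the acceptance layer use
dt = 0.02 min, which changes fitted constants by <1e-5 relative.

**Measured-input up-sampling.** The measured IDIF is frame-resolved; the
models need it on the fine grid. Frame values are time *averages*, so plain
interpolation through frame midpoints flattens the early peak and biases
delivery constants (≈1.3% on k1_blood even at zero noise). The up-sampler
therefore solves the small linear system that makes the interpolant's own
frame averages reproduce the measured frame means exactly (piecewise-linear
knots at frame midpoints, anchored at zero at injection, held constant
after the last midpoint). Plain interpolation remains available
(`mean_correction=False`).

## Weighting

Frame precision is modeled through the forecast standard deviation (FSD):
FSD_i = max(activity_i, floor)/duration_i(s), floor = floor_fraction × peak
(default 0.05, guarding near-zero and negative frames). Weights are
w_i = 1/FSD_i², normalized to mean 1 — short hot frames are down-weighted.

Computing the FSD from the *measured* noisy TAC correlates weights with
noise (a frame that fluctuates downward gets more weight) and biased
k_clearance by roughly −18% at default noise in our replicates. The
pipeline therefore rebuilds the FSD from a model *forecast*: a quick
blood-only prefit (2TCM prefit for gray matter) predicts the noise-free
frame values, and the FSD of that prediction defines the weights
(`forecast_weights`, one round by default). The same weight vector is
shared by every candidate model of a TAC so that WRSS and AIC remain
comparable across models.

## Estimation

**WNLLS.** Each model is fitted by minimizing Σ w_i (y_i − model_i(θ))²
with a bounded trust-region least-squares solver (analytic Jacobians for
the ventricle models; the models are linear in their delivery constants, so
basis curves are memoized per fit). Multistart: a deterministic
Latin-hypercube, log-spaced over the bounds (default 10 starts; rate
constants span decades, so log spacing is the natural metric). Default
bounds are [1e-5, 1] min⁻¹ for rate constants and [1e-4, 2] for K1 — more
than 25× beyond the plausible range.

**Convergence to a single solution.** A fit is flagged converged only when
the top-3 multistart solutions agree (objective within rel. 1e-4,
parameters within rel. 5%) *and* the optimum is interior to the bounds. A
parameter pinned at a bound (e.g. k1_tissue ≈ 0 when the data carry no
tissue signal) voids convergence — mirroring fitting software that reports
failure to reach a single solution. The exact thresholds are this package's
choices; the commercial tool's internal criteria are unpublished.

**MAP with empirical priors.** The second pass refits each model with a
Gaussian penalty per parameter. The penalty is expressed on the
likelihood's scale: because the FSD weights are normalized (relative
precision only), the penalty is multiplied by the estimated unit-weight
residual variance σ̂² = WRSS/(n−p) from the unconstrained fit. Without this
the prior's strength would depend on the arbitrary activity units; with it,
the flat-prior limit reproduces WNLLS, the dogmatic limit returns the prior
means (a tiny floor on σ̂² keeps dogmatic priors decisive even on
noise-free data), noise-free second passes reproduce the first pass, and at
realistic noise the prior acts only where the likelihood is weak. Only the
joint prior penalty is guaranteed to shrink at the MAP point; individual
coordinates can trade off along the correlated k1_blood–k_clearance
likelihood ridge (observed in ~8% of replicates).

**Leave-one-out priors.** Prior means/SDs are built per model and per
parameter from the converged pass-1 estimates of same-group subjects,
always excluding the target subject; the prior SD is 2× the donor sample SD
(n−1), keeping the priors deliberately loose. With fewer than two same-group
donors the pool falls back to all groups (still leave-one-out), and as a
last resort to non-converged pass-1 estimates — a model that converges for
nobody (the dual model on blood-only data) still needs a centering point.

**Model selection.** AIC = n·ln(WRSS/n) + 2p (constants dropped; valid for
same-data comparisons, the only use). Selection takes the lowest-AIC
converged model; exact ties go to fewer parameters; if nothing converged,
the lowest-AIC fit is reported with its flag.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes.

**Rate-constant calibration.** Within each group, (k1_blood, k_clearance)
are drawn from a bivariate normal, rejection-truncated to a box, with
post-truncation moments matched to the published group values (control:
k_clearance 0.018 ± 0.011, k1_blood 0.006 ± 0.003, Pearson coupling 0.95;
TBI: 0.014 ± 0.006, 0.004 ± 0.002, coupling 0.69). Two calibration points
deserve emphasis:

* The published per-group *ranges* are n≤9 sample ranges, not population
  bounds — a truncated normal confined to the control range [0.002, 0.035]
  cannot even attain SD 0.011 (the uniform limit caps it at ~0.0095), while
  an untruncated normal with those moments predicts a sample range of
  almost exactly the published width. The truncation box is therefore a
  positivity floor (5e-4) and mean + 4 SD per margin.
* Truncation distorts moments, so the parent mean vector, SDs and
  correlation are *moment-matched* by Gauss–Legendre quadrature over the
  box plus root-finding, making the post-truncation moments equal the
  targets to solver precision (verified at n = 10⁵ within 2%).

`k1_tissue` is drawn independently (0.001 ± 0.0005 min⁻¹, truncated
positive): the default cohorts are generated with the dual-input model but
with a tissue contribution small enough that the blood-only model usually
wins AIC at default noise — while on noise-free data the dual model is
correctly identified. Nuisance two-tissue parameters default to K1=0.3,
k2=0.3, k3=0.05, k4=0.03 min⁻¹ at 10% CV; per-subject input curves get a
10% amplitude scale and a jittered delay. TBI decoupling is produced solely
by the lower bivariate correlation, with no extra noise mechanism. Group
sizes default to 9 controls / 7 TBI, with ages and sex frequencies at the
published group summaries.

**Noise.** Frame noise is Gaussian with SD_i = σ0 × max(Ĉ_i, floor)/
duration_i(s) — the same functional form as the FSD heuristic, so the
weighted fit is the matched estimator. True ventricular noise levels are
not published; the default σ0 = 22.5 s yields a final-frame coefficient of
variation of ~5% and is a config parameter, not an asserted fact. The IDIF
receives noise at σ0/2 (carotid ROIs are hot and well determined). "Low
noise" in the calibration studies means σ0 at 20% of default.

**ALPS covariate.** An ALPS-like scalar is attached by a Gaussian copula:
latent = ρ_g·z(k) + √(1−ρ_g²)·ε with z(k) the normal scores of the true
clearance ranks and ρ_g = 2·sin(π·ρ_s/6) for a target Spearman ρ_s
(default 0.474, applied across the pooled cohort). The affine map onto
~1.2–1.8 is cosmetic; only ranks carry meaning.

**Phantoms.** `build_phantom` paints the three TACs into disjoint boxes of
a small 4D grid (default 40×40×20 at 2 mm) with matching masks; the carotid
box carries the input curve and is the global early-frame maximum by
construction, so automated IDIF extraction recovers it exactly (there is no
scanner blur, scatter or motion — the phantom tests I/O and extraction
logic, not image physics).

**What passing these tests does not show.** The generator draws from the
model family the fitter assumes (matched noise law, no motion, no partial
volume spill-in beyond what mask erosion in the image path would address,
no metabolite or delay effects in the input). Recovery results therefore
validate the estimation machinery under the study's assumed conditions, not
robustness to real-scanner physics.

## Image path

ROI masks are eroded by a physical-radius ball (default 2 mm; a voxel's
offset belongs to the structuring element iff its center lies within the
radius, anisotropic voxels supported; voxels outside the grid count as
background). ROI TACs are unweighted voxel means. The IDIF is automated:
the 0–90 s frames are summed time-weighted, and the mean TAC of the
n_voxels (default 13 ≈ a 4-mm disc at 1 mm) hottest voxels of the connected
component containing the single hottest voxel is returned; ties break on
the lowest linear index. Masks and images must share the exact grid — no
resampling. Left/right carotids are not averaged separately; the single
winning cluster is used.

## Cohort statistics

Group contrasts use Welch's t and the Wilcoxon rank-sum (exact when the
pooled sample is tie-free and small). Categorical contrasts use two-sided
Fisher exact tests (a zero margin gives p = 1 by convention). The central
regression is OLS of k_clearance on group (control=0, TBI=1), k1_blood and
their interaction; estimated marginal means per group are model predictions
at the pooled mean of k1_blood with delta-method SEs, and per-group Pearson
correlations accompany the fit. Rank-deficient designs (constant k1_blood
in a group) drop the interaction with a flag. Spearman correlation against
the ALPS covariate uses mid-rank ties and an exact permutation p for n<10
(t-approximation otherwise); subjects missing ALPS are dropped pairwise.
Age can be added as a covariate (`include_age`), and a sensitivity re-run
excluding the control with the highest k_clearance is available
(`exclude_max_control`). No multiple-testing correction is applied.

## Acceptance problem sizes

The acceptance layer re-derives the published group-level quantities from
the calibrated generator. Sizes used (all on one CPU): 14 replicate
single-group cohorts per group (n=9 control / n=7 TBI, default noise) for
the grand means of the fitted constants; n=250 (control) and n=400 (TBI)
single groups at low noise for the within-group couplings (the TBI
coupling has the larger per-subject sampling SE); 16 replicate
16-subject cohorts at low noise
for the median interaction-regression R² (per-subject estimate noise enters
both axes of that regression, so it is measured in the same low-noise
regime as the couplings); one pooled n=600 cohort at low noise for the
clearance–ALPS Spearman. The heavy runs use 5 multistarts and dt = 0.02 min
(verified equivalent to the defaults to ~1e-5 relative on fitted
constants). Expected sampling spread at these sizes: ≲0.001 on group means,
≈0.03–0.04 on correlations, ≈0.03 on the median R².

## Known limitations

* No delay/dispersion fitting between carotid and ventricle; no
  blood-to-plasma or metabolite correction; no spillover terms.
* MAP is a point estimate (penalized least squares), not a posterior.
* The convergence flag measures multistart reproducibility, not
  identifiability in the Fisher-information sense; a biased but
  reproducible optimum counts as converged.
* Standard errors come from the Gauss–Newton covariance and inherit its
  local-quadratic assumptions.
* The IDIF automation assumes the carotid cluster is the hottest early
  structure, true in the phantoms but not guaranteed in arbitrary images.
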
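# Methods

## The ALPS model and its assumptions

The ALPS index treats the voxel-wise diffusion tensor, after spatial
normalization to the 2 mm MNI152 grid, as a superposition of fiber-tract
diffusion and perivascular water movement. Two anatomical facts make the
separation possible at the level of the lateral-ventricle body: deep
medullary veins (and the perivascular spaces around them) run left–right
(x), while the adjacent projection fibers run inferior–superior (z) and the
association fibers anterior–posterior (y). Inside each fiber bundle, the
tensor's x-axis diffusivity (`Dxx`) mixes an isotropic floor with the
perivascular contribution, while the remaining non-fiber axis (`Dyy` in
projection fibers, `Dzz` in association fibers) carries only the floor.
The index

    ALPS = ((Dx_proj + Dx_assoc)/2) / ((Dy_proj + Dz_assoc)/2)

is therefore 1 under isotropy, scale-invariant, and strictly increasing in
perivascular diffusivity. Diffusivity "along an axis" is the diagonal
tensor element in image coordinates — valid only after normalization has
aligned anatomy with the image axes, which is why the package consumes
already-normalized tensor volumes and does not register images itself.

Each of the four ROIs is a 7-voxel 3-D crosshair (center plus six face
neighbors, 56 mm³ at 2 mm isotropic) at fixed template coordinates
`[25 52 50]`, `[31 52 50]`, `[64 52 50]`, `[58 52 50]` (left association,
left projection, right association, right projection). The printed
coordinates are interpreted as 0-based voxel indices on the 91×109×91 grid;
this is a documented convention, configurable per run, since coordinate
base is ambiguous in common tooling. Hemispheric indices are computed
ratio-first and then averaged (`alps_mean = (alps_left + alps_right)/2`
exactly), matching protocols that report left, right and bilateral-mean
values separately.

### Orientation QC

Manual protocols have an observer check color-coded eigenvector maps and
shift ROIs by a voxel or two onto the tract. The automated surrogate scores
every integer shift within a search radius (default 2 voxels) by the
fraction of ROI voxels whose principal eigenvector lies within an angle
tolerance (default 20°) of the expected fiber axis, keeping the best shift
(ties: smaller shift norm, then lexicographic). An ROI whose best fraction
stays below 0.8 is flagged. Voxels with non-positive leading eigenvalues
are excluded from the numerator but kept in the denominator; isotropic
voxels count as valid-but-unaligned because their principal axis is
undefined. The 20°/0.8/2-voxel defaults are package choices exposed in
config — no quantitative criterion exists for the manual check they
replace; adjustments of one or two voxels are the norm it encodes.

## DWI phantom

The phantom plants a periventricular slab geometry on a 40×40×20 grid at
2 mm: a CSF ventricle slab centered on x, flanked per hemisphere by a
projection band and, lateral to it, an association band, with four
crosshair ROIs placed inside the bands in the same medial-to-lateral order
as the template protocol. Tensors are diagonal: `diag(λ⊥+g, λ⊥, λ∥)` in
projection bands, `diag(λ⊥+g, λ∥, λ⊥)` in association bands, `d_csf·I` in
the ventricle, an isotropic white-matter mean elsewhere. The perivascular
term `g` adds x-axis diffusivity per hemisphere, so the planted truth is
`(λ⊥+g)/λ⊥` per hemisphere and asymmetric glymphatic function can be
simulated. Defaults λ∥ = 1.4e-3, λ⊥ = 0.4e-3, g = 0.2e-3, d_csf = 3.0e-3
mm²/s are physiologically plausible values chosen here (no reference ROI
diffusivities are printed anywhere to calibrate against); they put the
default phantom at ALPS = 1.5, mid-range for healthy white matter.

Signals follow the monoexponential tensor model `S = S0 exp(-b gᵀDg)` on a
scheme of one b=0 volume plus 30 fixed, approximately uniform directions
(spherical Fibonacci lattice, frozen as literals for reproducibility) at
b = 1000 s/mm². Only the low shell is simulated and fitted by default
because the monoexponential model degrades at high b; the scheme type
accepts extra shells for sensitivity experiments. Rician noise is the
magnitude of two independent Gaussian channels with σ = S0/SNR (default
SNR 40). The tensor refit is unweighted log-linear least squares on the
7-column design, with signals floored at 1e-6·S0 before the log so noise
cannot produce −∞; the b=0 row is what keeps the single-shell design
full-rank.

What the phantom does *not* emulate: partial-volume mixing, crossing
fibers, eddy-current/susceptibility/motion artifacts, spatially varying
SNR, and registration error. Passing phantom tests therefore demonstrates
correctness of the measurement chain (ROI placement, extraction, fit,
ratio) under the stated signal model, not robustness to real-world
acquisition artifacts. At SNR 40 a single end-to-end run has SD ≈ 0.018
around the planted truth with a small positive Rician bias that decays with
SNR; the replicated-noise experiments use a compact 24×24×12 phantom with
the same band structure to keep suites fast.

## Synthetic cohort

The cohort generator emulates a 142-subject community aging cohort: age
truncated-normal above 50 years (SD 7.0; the pre-truncation mean is solved
so the post-truncation mean is 60.8), binary risk factors at fixed
prevalences (female 0.556, hypertension 0.394, hyperlipemia 0.162,
diabetes 14/142, smoker 0.282), PSQI truncated-normal (5.4 ± 3.9, ≥ 0),
and small-vessel-disease covariates (ICV, brain/ICV ratio, log-normal WMH
volume matching a 1.5 ml median with 0.8–2.7 IQR, PVS scores, Poisson
lacune/microbleed counts with P(≥1) matching 11/142 and 15/142, a
zero-inflated WMH–ROI overlap volume). The DMV score (0/1/2) marginal is
P = (0.50, 0.35, 0.15) — a package choice; only its group means, not its
distribution, are reported in the literature this emulates.

ALPS is generated as

    alps = μ + σ·(β_age z_age + β_sex z_sex + β_ht z_ht + β_dmv z_dmv) + ε

with planted standardized effects β = (−0.284, −0.243, −0.189, −0.215),
sex coded male = 1 (the sign convention under which females have higher
ALPS), marginal μ = 1.49, σ = 0.17 (plausible given reported group means of
1.56/1.41 but not printed as moments; a documented choice), and ε Gaussian.
Standardization inside the generator uses population moments, so the betas
are exact population quantities. Left/right hemispheric values are the
bilateral mean ± an independent Gaussian half-difference (SD 0.05), which
naturally attenuates per-hemisphere effect estimates. ALPS values are
floored at 0.05 to satisfy the positivity schema; at the default parameters
the floor essentially never binds (≈ 8σ event).

### Calibration

With independent predictors the four betas cap the model R² at
βᵀβ ≈ 0.2216, short of the 0.319 target. Hypertension (logistic link) and
DMV score (ordered logit) therefore depend on standardized age through a
shared slope — the single calibration knob. All link intercepts/cutpoints
are re-solved at each candidate slope so every marginal stays fixed, the
implied predictor correlation matrix R is computed by deterministic 1-D
quadrature over the truncated age density (hypertension–DMV correlation via
conditional independence given age), and the slope is root-found so that
βᵀRβ equals the target. The default lands at slope ≈ 0.81, i.e.
corr(age, hypertension) ≈ 0.36 and corr(age, DMV) ≈ 0.38 — epidemiologically
sensible magnitudes. Since the total ALPS variance is held at σ², the
population R² of the four-predictor model equals βᵀRβ and the residual SD
is σ·√(1 − R²). Targets below βᵀβ or above the slope-saturated maximum
raise a calibration error naming the direction to adjust.

What passing cohort tests shows: the estimator recovers planted population
effects and the selection procedure's operating characteristics behave as
theory predicts *under a correctly specified linear model with these
links*. Real cohorts add unmodeled confounding, measurement error in ALPS,
and non-linear age effects, none of which the generator emulates.

### Finite-sample behavior of selection

At n = 142 the per-variable power of forward selection (α_enter = 0.05) for
|β| in 0.19–0.28 is roughly 0.7–0.94, so each planted predictor enters the
model on a clear majority of seeds while null covariates enter at ≈ α — but
the probability of recovering *exactly* the four-variable set is only about
a third. This is a property of the sample size and effect sizes, not of the
implementation, and it is why replication studies at this scale can
disagree about a weak predictor like hypertension while agreeing about age.

## Statistical analysis choices

* Standardized betas come from OLS on z-scored outcome and predictors
  (sample SD, n−1). The fit carries an explicit (numerically zero)
  intercept so p-values, degrees of freedom, and adjusted R² match the
  ordinary unstandardized regression exactly; with one predictor the beta
  equals Pearson's r to machine precision.
* Selection runs forward (enter smallest partial-F p < α_enter = 0.05) and
  backward from the full model (drop largest p > α_remove = 0.10)
  independently; the forward set is the reported model and a flag records
  disagreement. A bidirectional variant sits behind a flag. The thresholds
  are classic defaults, configurable; no thresholds are prescribed by the
  protocols this mirrors.
* Univariate screen: Pearson for continuous, equal-variance two-sided t for
  binaries (Welch available), one-way ANOVA for the DMV score with
  Bonferroni-corrected pairwise post hoc (multiplier k(k−1)/2, capped at
  1). No multiplicity correction is applied across the screen itself. The
  DMV score enters the regression as a numeric 0/1/2 covariate but the
  ANOVA treats it categorically.
* VIF_j = 1/(1 − R²_j); perfect collinearity is an error, not an infinite
  value.
* Residual diagnostics: Shapiro–Wilk on residuals plus a slope test of
  squared residuals on fitted values, both flagged at 0.05; saturated
  models skip diagnostics with a note.
* Cohen's kappa uses marginal-product chance agreement; the degenerate
  case p_e = 1 with perfect agreement is defined as 1.

## Numerical and reproducibility notes

* Tensor files store components lower-triangular (Dxx, Dxy, Dxz, Dyy, Dyz,
  Dzz) and stamp the order into the NIfTI `descrip` field; a file declaring
  a different order is rejected on read.
* Masks are uint8; values > 0.5 count as inside.
* The CLI derives all stage seeds from one top-level seed via CRC-stable
  `SeedSequence` keys, so identical config + seed gives byte-identical
  outputs; every run writes a JSON manifest.
* Replicated experiments (200 cohorts of n = 142; 50-seed phantom noise
  sweeps at SNR 10–80) are sized to give Monte-Carlo standard errors an
  order of magnitude below the tolerances they are checked against while
  keeping the full suite under a minute.

## Known limitations

ALPS is a ratio of ROI means on already-normalized tensors: registration
quality, ROI placement on atypical anatomy, and WMH intrusion into the ROIs
all propagate directly into the index, and only the last is quantified here
(as the WMH-overlap covariate). The phantom's piecewise-constant bands make
orientation QC trivially easy compared with real eigenvector maps. The
cohort generator's links are minimal (age → hypertension, age → DMV);
real vascular-risk correlation structure is richer, so selection behavior
on real data may differ from the simulated operating characteristics.
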
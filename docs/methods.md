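# Methods

`striatnorm` models how striatal glucose metabolism, measured as
intensity-normalized FDG-PET uptake, changes across the adult lifespan
(ages 20–81), and scores individual subjects against that normative
trajectory. This note documents the statistical machinery, the synthetic
data-generating process the test suite runs on, and the numerical and
design choices that were genuinely open.

## Intensity normalization

Raw uptake maps differ in overall intensity scale across subjects
(acquisition differences, injected dose). Each volume is divided by the
mean intensity of the voxels lying in the 40–90% band of the maximum voxel
intensity, bounds inclusive:

    B = { v : 0.4·max ≤ I(v) ≤ 0.9·max },     I'(v) = I(v) / mean(B).

The band is computed on the whole input grid rather than a prior brain
mask: with background near zero, background voxels fall below the 0.4·max
cut anyway, and avoiding a mask keeps the operation a pure function of the
volume. The operation is exactly invariant to any positive rescaling of
its input, and the mean of the output over the band is 1 by construction.
A constant volume is rejected (every voxel sits above 0.9·max, so the band
is empty). Normalizing twice rescales by the new band mean, but
between-region ratios are unchanged.

The global covariate used by the voxel-wise model is the mean of the
normalized volume over the brain mask (all nonzero atlas labels) — a
deterministic estimator, in place of iterative-threshold global-mean
heuristics used by some neuroimaging packages.

## ROI correlations

Pearson r between age and mean regional uptake, per region, with two-sided
p-values from the t-transform with n−2 degrees of freedom, Bonferroni
corrected over the m = 4 striatal regions (bilateral caudate and putamen).
Sex-stratified repeats use the same m; the correction budget belongs to
the primary four-region family, not to the exploratory strata.

## Voxel-wise GLM with permutation FWE

Per voxel inside the brain mask, ordinary least squares with columns
{intercept, age, sex, global mean}; the statistic of interest is the
t-value of the age coefficient with n − 4 degrees of freedom.

Family-wise error is controlled by the permutation distribution of the
maximum |t| over the mask rather than random-field theory: RFT smoothness
estimation is meaningless on desk-scale grids without a point-spread
model, while the max-statistic permutation test is exact under
exchangeability at any resolution. Nuisance covariates are handled by the
Freedman–Lane scheme: the data are residualized on the nuisance columns,
residual rows are permuted, the nuisance fit is added back, and the full
model is refit. The identity permutation is always included among the
`n_perm` draws (the convention that makes the test level exact), and the
threshold is the empirical (1−α) quantile of the null maxima taken with
the "higher" interpolation rule, which errs conservative on a discrete
null.

Supra-threshold voxels are grouped into clusters by 26-connectivity
(SPM-style analyses often use 18; one convention had to be picked and it
is exposed in the code), positive and negative signs labelled separately,
and clusters below the extent threshold (default 50 voxels) dropped.
The default FWE α is 0.001, i.e. a significance level of 0.001 applied to
the FWE-corrected statistics; analyses that instead want 0.001 as an
uncorrected height threshold can override α.

## Warped Bayesian linear regression normative model

The response y (regional uptake) is mapped into a Gaussian latent space by
the sinh-arcsinh (SHASH) warp

    z = γ(y) = sinh(b·arcsinh(y) − a),    b > 0,

whose parameter a skews and b re-weights the tails; (a, b) = (0, 1) is the
identity. In latent space the model is ordinary Bayesian linear
regression, z = wᵀφ(x) + ε, ε ~ N(0, 1/β), with an isotropic Gaussian
prior w ~ N(0, I/α). The basis φ(x) is a clamped cubic B-spline over the
training age range with five evenly spaced interior knots (nine spline
columns forming a partition of unity) plus an explicit intercept column.
The spline columns and the intercept are collinear by construction; the
proper prior keeps the posterior well defined, and the α → 0 limit is
taken as the minimum-norm least-squares solution (implemented with
`lstsq`/pseudo-inverse rather than a direct solve).

For fixed (α, β, a, b) the posterior is closed form,

    S_w = (αI + βΦᵀΦ)⁻¹,    m_w = β S_w Φᵀ z,

and hyperparameters minimize the negative log marginal likelihood of the
warped model: the standard Gaussian evidence of z minus the
change-of-variables Jacobian Σᵢ log γ'(yᵢ). The search runs over
(log α, log β, a, log b) by Nelder–Mead from five seeded starts, the first
of which is the identity warp with β matched to the response variance, so
the optimized evidence never exceeds the identity initialization. On a
narrow response range the warp is only weakly identified — any (a, b)
acts nearly affinely and the affine part is absorbed by the weights and β
— which is why restarts matter for reproducibility more than for fit
quality; with a wide, well-specified response the warp parameters are
recovered accurately (the suite checks ±0.1 at n = 4000).

Predictions at age x are the latent mean m⋆ = φ(x)ᵀm_w with predictive
variance s⋆² = 1/β + φ(x)ᵀS_wφ(x). Centile curves back-transform latent
Gaussian quantiles, y_q(x) = γ⁻¹(m⋆ + Φ⁻¹(q)·s⋆), computed for the 1st,
5th, 25th, 50th, 75th, 95th and 99th percentiles; monotonicity in q is
inherited from the monotone warp. Deviation scores are computed in latent
space, Z = (γ(y) − m⋆)/s⋆, with extreme deviations flagged by the strict
inequalities Z > 2 and Z < −2. Test ages outside the training range are
evaluated by clamped extrapolation (the boundary basis value) with a
warning.

Model accuracy is summarized by explained variance on the held-out half,

    EV = 1 − Var(y − ŷ)/Var(y),

with the point prediction ŷ = γ⁻¹(m⋆): the back-transformed latent mean
is the predictive *median* (monotone transforms commute with quantiles,
not means), and the predictive mean has no closed form under the warp, so
the median is the deliberate choice. EV is computed in response units,
not latent units, so models with different warps are comparable.

The train/test split halves the cohort with sex and age balanced: within
each sex, subjects are sorted by age and assigned alternately to the two
halves; the alternation phase per stratum is randomized by the seed
subject to the constraint that the halves have equal total size (58/58 on
the default 116-subject cohort). Per-sex counts between halves then differ
by at most one and mean ages typically differ by well under a year. This
alternation scheme is one admissible reading of "equal distribution of sex
and age"; exact covariate-matching optimization was judged out of
proportion for a half split.

## Synthetic cohort generator

The generator is the test bed for every stage, emulating the statistical
structure of the real cohort without any imaging download.

**Cohort.** 116 subjects with the reference sample's age-decade × sex margins
(77 male, 39 female; e.g. 14 males aged 31–40), ages drawn uniformly
within each decade bin. Uniform-within-bin is an assumption — only the
binned counts are known.

**Regional uptake.** For each region, uptake is a quadratic trend in
centred age plus scaled SHASH noise:

    y = baseline + b₁(age−50) + b₂(age−50)² + s·sinh((arcsinh(Z)+a)/b).

The caudate defaults were calibrated (once, by
`scripts/calibrate_generator.py`) against two printed constraints jointly:
the population age correlation (−0.55 left, −0.56 right) and the test-half
EV of the normative fit (0.36 left, 0.34 right). The slope/curvature ratio
is solved analytically from the moments of the binned age mixture so the
population correlation is exact for any candidate signal fraction f
(share of total variance carried by the mean trend); f itself is chosen by
a Monte-Carlo sweep of the actual split/fit/score pipeline, landing at
f = 0.42 (left) and 0.40 (right) — the attained EV sits below f because of
spline estimation error on 58 training subjects. Negative curvature
(accelerating decline) was chosen over the positive root as the
physiologically typical shape. The total uptake SD is fixed at 0.10
SUV-ratio units around caudate baseline 1.30 / putamen 1.35, a realistic
between-subject spread for normalized FDG uptake. Caudate residuals are
mildly right-skewed, slightly heavy-tailed (a = 0.25/0.35, b = 1.15/1.20
left/right), giving the warp something real to estimate; the putamen uses
Gaussian residuals and a weak positive linear trend (population
r = +0.16/+0.21, no curvature), so its normative fit has essentially no
signal to find — the evidence shrinks it to a near-constant prediction
and the median replicate EV is zero to floating round-off.

**Volumes.** PET-like volumes on a 40×48×40 grid of 4 mm voxels: an
ellipsoidal "brain" at parenchyma baseline 1.0 containing four mirrored
box-shaped striatal regions (each ≥ 60 voxels, so the 50-voxel extent rule
is exercisable), each voxel carrying its region's subject-level value plus
Gaussian voxel noise (SD 0.05), the whole volume multiplied by a
log-normal per-subject global intensity factor (σ = 0.25, median 1).
The global factor is exactly what intensity normalization removes — the
round trip is tested. The volumes deliberately omit PET point-spread,
attenuation and partial-volume effects; passing tests demonstrate the
statistical logic of the pipeline, not image realism, and say nothing
about registration or scanner physics on real data.

## Problem sizes and reproduction

The replicate summaries (`striatnorm.replication`, run by
`scripts/acceptance.py`) use 200 replicate cohorts of n = 116 — enough
that the Monte-Carlo standard error of the mean correlation (~0.004) and
mean EV (~0.007) is well below the quantities' own spread. The voxel-wise
error-control simulation uses 200 null replicates of 12 subjects × 64
voxels with 100 permutations each, and the in-repo end-to-end runs use
100–500 permutations; these sizes were chosen as the smallest at which
the binomial error bars are informative. All randomness flows from
explicit integer seeds; a single pipeline seed fans out to per-stage
seeds by a fixed offset scheme, and reruns are bit-identical (hashes in
the run manifest).

## Known limitations

- The warp parameters are weakly identified on narrow response ranges;
  reported (a, b) values for a single 58-subject training half should not
  be interpreted, only the implied fit.
- The generator's quadratic-trend truth is one of many data-generating
  processes consistent with the printed summary statistics; calibration
  matches moments, not the unknown real process.
- Clamped-spline extrapolation beyond the training age range holds the
  boundary value; centile curves plotted over the full 20–81 grid are
  flat outside the observed training ages.
- EV is scored on back-transformed medians; under strongly skewed warps a
  mean-scored EV would differ.
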
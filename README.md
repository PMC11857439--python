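# striatnorm

Age-related decline of striatal glucose metabolism, as a tested analysis
pipeline: FDG-PET intensity normalization, ROI and voxel-wise age
statistics, and a **warped Bayesian linear regression normative model** of
caudate uptake with centile curves and per-subject deviation Z-scores.

The scientific question: how does resting glucose metabolism in the
caudate and putamen (measured as intensity-normalized FDG uptake) change
across adulthood (ages 20–81), and how far does an individual deviate from
the population trajectory at their age? The caudate shows a clear
nonlinear decline (age correlation ≈ −0.55); the putamen shows only a weak
positive trend with no out-of-sample predictive power. The package is
aimed at researchers who want the normative-modelling machinery — basis
expansion, likelihood warping, evidence optimization, centiles, deviation
scores — with every stage unit-tested against independent oracles, plus a
calibrated synthetic cohort so the whole pipeline runs without any data
download.

## The model

The response y (mean regional uptake) is mapped to a Gaussian latent
variable by the bijective sinh-arcsinh warp

    z = γ(y) = sinh(b·arcsinh(y) − a),   b > 0,

and modelled there by Bayesian linear regression

    z = wᵀφ(x) + ε,   ε ~ N(0, β⁻¹),   w ~ N(0, α⁻¹I),

where φ(x) is a clamped cubic B-spline in age with five evenly spaced
interior knots plus an intercept. The posterior over w is closed form;
(α, β, a, b) minimize the negative log marginal likelihood of the warped
model (Gaussian evidence of z minus the Jacobian Σ log γ′(y)). Centile
curves are γ⁻¹(m⋆ + Φ⁻¹(q)·s⋆); deviation scores are
Z = (γ(y) − m⋆)/s⋆ with |Z| > 2 flagged as extreme; accuracy is
explained variance EV = 1 − Var(y − ŷ)/Var(y) on a held-out half, with
ŷ the back-transformed predictive median. Voxel-wise age effects use an
OLS GLM (intercept + age + sex + global mean) with family-wise error
controlled by Freedman–Lane max-|t| permutation and 26-connected
cluster-extent filtering. See `docs/methods.md` for the full account.

## Worked example

```python
from striatnorm import synthetic as syn, roistats as rs, normative as nm

cohort = syn.generate_cohort(seed=1)          # 116 subjects, reference margins
table = syn.generate_roi_suv(cohort, seed=2)  # calibrated uptake per region

for res in rs.pearson_age_correlation(table):
    print(f"{res.region:10s} r={res.r:+.3f}  p_unc={res.p_unc:.2e}  p_bonf={res.p_bonf:.2e}")

out = nm.run_normative(table, regions=("caudate_L",), seed=1)["caudate_L"]
print(f"test EV: {out.ev_test:.3f}")
rep = out.test_report
print(f"test Z range: [{rep.z.min():.2f}, {rep.z.max():.2f}], "
      f"extremes: +{rep.extreme_positive.sum()} / -{rep.extreme_negative.sum()}")
```

prints

```
caudate_L  r=-0.541  p_unc=3.50e-10  p_bonf=1.40e-09
caudate_R  r=-0.505  p_unc=7.69e-09  p_bonf=3.08e-08
putamen_L  r=+0.270  p_unc=3.41e-03  p_bonf=1.36e-02
putamen_R  r=+0.049  p_unc=6.02e-01  p_bonf=1.00e+00
test EV: 0.274
test Z range: [-2.11, 2.41], extremes: +1 / -1
```

One simulated cohort: both caudate nuclei decline significantly with age
after Bonferroni correction over the four regions, the putamen does not
reliably; fitting the normative model on a balanced 58-subject half
explains ~27% of test-half caudate variance in this particular draw
(single-cohort EV fluctuates around its 0.36 population value), and two
test subjects sit just outside the central ±2 SD band. The same pipeline
is scriptable from the shell:

```bash
striatnorm simulate --seed 1 --outdir data --volumes
striatnorm normative --roi data/roi_table.csv --cohort data/cohort.csv \
    --regions caudate_L,caudate_R --seed 1 --out results
striatnorm run --config config.yaml       # full end-to-end with manifest
```

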
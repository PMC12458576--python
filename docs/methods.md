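# Methods

## The similarity score

The Regional Vulnerability Index (RVI) quantifies how closely an
individual's pattern of regional brain deviations resembles the
characteristic deficit pattern of a disease. Two vectors enter the
score, aligned by region identifier (never by position):

* **Z** — the subject's per-region z-score deviations from a reference
  group, `z_i = (x_i - mean_i) / sd_i`, with per-region means and SDs
  taken over the reference sample (sample SD, n−1 denominator). The
  reference defaults to the full analysed sample; an external
  means/SDs file can be supplied to score new individuals against a
  fixed norm.
* **E** — the effect-size blueprint: per-region Cohen's d values from
  a case-control contrast, with diagnosis coded case = 1 so that
  atrophy yields d < 0.

The score is the normalized dot product

    RVI = (1/N) Σ_i z_i · d_i

over the N regions present in both vectors. We divide by N so that
whole-brain and tissue-specific scores (cortical thickness, subcortical
volume, white matter) are on a comparable scale; with the canonical
64-region blueprint (33 cortical / 7 subcortical / 24 white-matter
regions) the whole-brain score is then exactly the
(33, 7, 24)/64-weighted mean of the three tissue scores. A plain-sum
variant is available behind a flag. Positive RVI means the subject
deviates in the disease direction region-by-region; the score is linear
in Z and antisymmetric under reversal of the deviations.

**Missing regions.** The default policy drops a missing region from the
sum and decrements N, keeping scores comparable while bounding bias;
subjects missing more than 20% of blueprint regions (configurable) are
refused rather than scored.

**Hemispheres.** Paired `_L`/`_R` columns are arithmetically averaged
before scoring; a single available hemisphere is used as-is and
flagged.

## Blueprint derivation

Per-region effect sizes come from an ordinary-least-squares fit of

    measure ~ diagnosis + age + sex + age×sex + ICV

on a case/control table, followed by the t-to-d conversion

    d = t (n1 + n2) / (√(n1 n2) · √df)

with df the residual degrees of freedom of the adjusted model. This is
the standard conversion for a covariate-adjusted two-group contrast and
reduces to 2t/√df at equal group sizes. The d values are used as
similarity weights, not significance claims, so no multiple-testing
correction is applied. An optional between-study covariate supports
pooled multi-cohort tables; the default is plain concatenation.
White-matter effect sizes may instead be supplied from an external
blueprint file when diffusion phenotypes are unavailable, so a mixed
blueprint (derived gray matter + imported white matter) is a supported
workflow.

The packaged 64-region blueprint in `rvindex/data/ad_blueprint_synthetic.csv`
is a **synthetic stand-in**: region names follow standard cortical,
subcortical, and white-matter tract atlases, and the d values are
plausible-magnitude draws (temporal-lobe thickness and hippocampal
volume most affected), not estimates from any real cohort. It exists so
the pipeline is runnable and testable without restricted data; any real
blueprint with the `region_id,modality,d` schema drops in.

## Framingham cardiovascular risk score

The sex-specific point-based general-CVD score (D'Agostino et al. 2008)
maps age, total and HDL cholesterol (mg/dL), systolic blood pressure
(treated vs untreated), smoking and diabetes to an integer point total
and a tabulated 10-year event risk. The point and risk tables ship as
CSV data files; bands are matched as `lower ≤ v < upper + 1` because
the published tables print integer band edges while inputs are
continuous. Risks below/above the tabulated range are clamped to the
end values (0.9% / 30%), preserving monotonicity. No imputation is
performed: a missing field is an error for a single subject and an
explicit flag in batch scoring.

## Cross-sectional risk models

* Carrier contrast: pooled-variance Student's t-test (a Welch option
  exists but is off by default), with Cohen's d = mean difference /
  pooled SD.
* Interaction model: OLS of RVI on carrier status, FCVRS and their
  product, with intercept; overall F against the intercept-only model.
* Correlation comparison: per-genotype Pearson r, and the Fisher
  r-to-z difference test
  `z = (atanh r1 − atanh r2) / √(1/(n1−3) + 1/(n2−3))`.

All p-values are two-sided; complete cases only. Model fits are
delegated to statsmodels; tests validate them against hand-built
normal-equations and IRLS oracles.

## Conversion analysis

Risk sets are built from a longitudinal status panel (CN / MCI /
dementia; dementia absorbing; a baseline visit required). Conversion
year is the first visit showing the new status, so a multi-year visit
gap assigns conversion to the first year observed. Subjects lost to
follow-up exit the risk set after their last visit; unobserved
conversions are never imputed.

Annual mode fits incident conversion per year among those still at
risk; cumulative mode fits converted-by-t against never-converters
still followed at year t, which makes cumulative year 1 coincide with
annual year 1 and keeps the accounting identity
`at-risk(t+1) = at-risk(t) − incident(t) − censored(t)` exact. An
`include_censored_stable` option instead counts every never-converter
as stable through their last visit, reproducing the pooled
converted-by-horizon analysis at the cost of that identity; we default
to the consistent rule.

Predictors are standardized to zero mean and unit SD within the
analysis sample, so odds ratios are per 1-SD increase; the scaling
record is stored on the fit. Nested models are compared with
likelihood-ratio tests; discrimination uses the rank-based (Mann-
Whitney) AUC with ties counted half. Note that the cumulative
multi-year OR is a different estimand from the per-year hazard OR: with
a constant per-year OR of 1.8 the 12-year cumulative OR is
substantially larger (≈3 in the default synthetic cohort), which the
acceptance script reports side by side.

## Synthetic cohorts

The generator produces the structure the analyses assume, with all
latent truth stored for oracle tests. For region i and subject j:

    x_ij = mean_i + sd_i · (a·(age−64)/10 + b·sex + c·icv_z
                            + L_j·d_i + ε_ij)

with loading `L_j = δ·carrier + γ·carrier·fcvrs_z` — carriers express
the deficit pattern (δ = 0.3 SD by default, matching a carrier
contrast of small-to-moderate size), more strongly with higher
cardiovascular burden (γ = 0.15 per SD of FCVRS). Defaults emulate a
healthy older replication-style cohort: age ~ N(64, 7.5²) clipped to
[45, 85], 27% carrier prevalence, nonzero age/sex/ICV effects
(a = −0.2 SD/decade, b = 0.1 SD, c = 0.3 SD) so the covariate
adjustment in blueprint derivation is genuinely exercised, unit
regional noise, and FCVRS computed from plausible clinical covariates
through the real Framingham module. Regional noise is independent by
default; an equicorrelation parameter adds a shared component because
real regional measures are correlated.

Conversion follows a yearly logistic hazard in the standardized latent
pattern score and baseline age (intercept −2.75 ≈ 6%/year at the mean;
per-SD OR 1.8; age OR e^0.2 per SD; 12-year horizon; 3%/year dropout).

What the generator does **not** emulate: site/scanner effects,
non-Gaussian measure distributions, realistic regional covariance
structure beyond equicorrelation, progression through MCI as an
intermediate state (baseline status is fixed), and family/pedigree
relatedness. Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to these real-data
features.

## Screening simulation

Latent trajectories start at N(0, 1), drift at 0.05/year in everyone,
and accelerate by 0.45/year during the final 3 years before conversion;
conversion times are drawn from a logistic hazard in the baseline
latent score (≈5%/year at the mean, per-SD OR 1.8 over a 10-year
horizon). Observed scans add N(0, 0.5²) noise and exist only at
scheduled visits (every 1, 3 or 5 years). Program AUC pools, over event
years, converters against subjects still at risk, each scored with
their most recent scan strictly before the event year; the same pairs
scored with the baseline scan give the single-scan comparator. Under
this model a fresher scan is more informative, so AUC is monotone in
scan frequency, and the baseline scan's AUC decays with the prediction
gap. The trajectory model is a deliberate re-specification that
captures the staleness phenomenon with the fewest parameters; its
parameters are all exposed in `ScreeningConfig`.

## Numerical and design choices

* Alignment of Z and E is by region id everywhere; region order in
  files is preserved for reporting but never relied on numerically.
* Sex is coded 0 = female / 1 = male in every design matrix; diagnosis
  case = 1.
* Logistic fits use statsmodels' Newton MLE; perfect separation and
  single-class risk sets raise informative errors rather than returning
  degenerate estimates, and inestimable years in an OR series are
  reported as `None`, never dropped silently.
* The scorer's batched cohort path is vectorized; tests pin it to the
  scalar per-subject primitive (itself pinned to a naive loop oracle at
  1e-12 relative tolerance).
* Problem sizes in tests and in `scripts/acceptance.py` (cohorts of
  600–2,000 subjects, 100–1,000 Monte-Carlo replicates) were chosen to
  keep Monte-Carlo error comfortably below the tolerance being
  asserted.

## Known limitations

* The shipped blueprint is synthetic; substantive conclusions require a
  real meta-analytic effect-size table.
* The Framingham implementation is the general-CVD point-table variant;
  office-based (non-laboratory) and 30-year variants are out of scope.
* Logistic conversion models treat years as independent fits rather
  than a survival model; no competing risk of death is modelled.
* Wald CIs are used for ORs; with very few events per year,
  profile-likelihood or exact intervals would be preferable.
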
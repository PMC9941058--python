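# Methods

## Synthetic cohort generator

The generator emulates the statistical skeleton of a nested four-group
cohort on the cardiovascular-disease continuum.  Per subject it draws

- chronological age CA ~ Uniform(30, 79) years;
- latent age acceleration Δ ~ Normal(μ_g, σ²) with group means
  μ = (−0.3, +0.1, 0.0, +0.3) years for (control, MCE, IS, ICH/SAH) and
  σ = 1.4 years; latent biological age is BA = CA + Δ;
- markers x_j = q_j + k_j·BA + Normal(0, s_j²) on each marker's model
  scale (natural-log scale for the log-normal biochemical markers);
  blood-pressure columns are emitted 15/10 mmHg lower for the 17.5% of
  subjects on antihypertensive treatment, and glucose is emitted as
  random plasma glucose with a fasting value present when the random
  value falls in the retest band (7.8–11.0 mmol/L);
- all-cause death from an exponential (optionally Gompertz)
  proportional-hazards model with linear predictor
  0.1823·Δ + 0.085·(CA − midrange), i.e. a hazard ratio of 1.20 per year
  of acceleration and a mortality doubling time of about eight years of
  baseline age;
- administrative censoring at 12 ± 2 years (uniform), emulating a
  staggered-entry cohort censored on a fixed calendar date.

Group baseline hazards are calibrated so that the *marginal*
events-per-person-year rates equal the configured values
(13.1, 102.7, 15.5, 84.6 per 1000 person-years): because the rate is a
harmonic-type mean over heterogeneous hazards, a scalar root-find per
group sets the baseline given the drawn linear predictors and censoring
times.  When the linear predictor is homogeneous this calibration is the
identity, so closed-form checks (e.g. exponential S(10) = e^(−0.1) at rate
0.01/yr) remain exact.

Default group sizes are the analysis-set sizes 4197/876/3837/3467; the
exclusion-fixture generator instead apportions the sampling-frame sizes
6341/1319/5467/5045 and injects mutually exclusive exclusion categories
(sample-quality and under-detection-limit flags, a genuinely missing
marker value, a far-outlying marker value) so the cascade *computes* the
requested counts.  Clean records are winsorized at 3.5 pooled SDs before
outliers are injected at +50 SDs, which guarantees the 4-SD filter finds
exactly the injected records; the construction verifies itself and raises
on any mismatch.

**The marker panel is synthetic.**  The 25 defaults (16 physical, 9
biochemical analogues) have plausible adult values and marker–age
correlations mostly between 0.15 and 0.65, with two deliberately weak
markers and one U-shaped marker so the screening filters are exercised.
No real assay distributions are reproduced.  What the generator does *not*
model: dependence among lifestyle covariates (marginals only), lifestyle
effects on mortality, multiple independent aging dimensions (one latent Δ
drives every marker), geographic structure beyond a uniform area label,
and informative censoring.  Passing tests therefore show the *pipeline*
is correct under these conditions, not that any particular marker panel
measures human aging.

## Preprocessing

Exclusions run in a fixed order — sample-quality flags, under-LOD flags,
missing marker values, then outliers — and a record qualifying for several
categories counts in the earliest, making category counts deterministic.
Outlier means/SDs are computed per marker on the pool surviving the first
three filters, pooled across sexes; "outside 4 SD" is the strict
inequality |x − mean|/SD > 4; a constant marker skips the filter with a
warning rather than failing.  Harmonization adds 15/10 mmHg to treated
subjects' systolic/diastolic pressures, substitutes fasting for random
glucose where measured, and applies natural-log transforms to the
biochemical markers except albumin (physical measurements stay raw).  A
harmonized table carries a flag and refuses a second pass, so the
blood-pressure correction can never be applied twice.

The risky dietary score (0–5) awards one point each for: vegetables less
than daily, fruits less than daily, red meat daily or less than weekly,
soybean under 4 days/week, fish less than weekly.  The risky lifestyle
score (0–4) awards points for current smoking (quitting for illness
counts as current), alcohol ≥30 g/day (men) / ≥15 g/day (women) or past
drinking, dietary score 4–5, and total activity strictly below the age-
band (<50, 50–59, ≥60) and sex-specific median computed on the analysis
cohort; ties at the median go to the non-risky side; scores 3–4 define
the risky group.

## Biological-age construction

Markers are screened per sex: retained iff |Pearson r with CA| > 0.10
(absolute value, so inversely age-correlated markers like lung function
stay) and the age response is monotone.  The monotonicity check is
deterministic: split at the median CA, fit OLS on each half, and flag
when the slopes have opposite signs and both are significant at two-sided
0.05.  Retained markers are standardized and decomposed by
correlation-matrix PCA (components beyond numerical rank dropped;
loading signs fixed by the largest-magnitude entry).  Each component is
regressed on CA for (q_j, k_j, s_j, r_j), giving the corrected estimator

    BA_EC = [Σ (x_j − q_j) k_j/s_j² + CA/s_BA²] / [Σ k_j²/s_j² + 1/s_BA²].

Age acceleration is the OLS residual of BA_EC on CA, fitted on the full
analysis cohort for the primary pipeline and on controls only for the
control-derived sensitivity construction; standardized AA divides by the
fitting pool's AA standard deviation.

### Choosing s_BA²

s_BA² is the variance of true biological age around CA.  Three estimators
are available (`s_ba2_mode`):

- `plugin` (default): Var(BA_E − CA).  Always positive; an upper bound,
  since it retains the sampling noise of the uncorrected BA_E.
- `information`: subtracts the closed-form inversion noise 1/Σ(k_j²/s_j²).
- `kd`: subtracts the classical approximation
  (1 − r̄²)/r̄² · range(CA)²/(12 m) with r̄ the root-mean-square of the
  component–age correlations (`r_char_mode="rms"`; a mean-absolute
  variant is available).

The subtraction-based modes assume the per-component residual SD s_j is
pure measurement noise.  Under this package's generator that is false:
s_j also contains the latent signal k_j²·Var(Δ), so for a panel whose age
information concentrates in one principal component the subtraction
cancels the signal exactly, and the r̄-based form — whose r̄ is dragged
down by the many weakly age-correlated components — overshoots by an
order of magnitude.  Both then hit the floor (0.01 yr², logged on the
model) and collapse BA_EC onto CA.  `plugin` is therefore the default;
the floor exists only as a guard for the opt-in modes and for degenerate
noiseless fits.

### Shrinkage of the constructed AA

With one age-informative component the estimator has a sharp and, at
first sight, surprising property.  Writing W = Σ k_j²/s_j², a single
informative component forces W ≤ 1/Var(Δ) (its residual on CA contains Δ
itself), and the plugin estimate satisfies s_BA² = 1/W up to the small
noise-PC contribution.  The marker-side weight of BA_EC is
W·s_BA²/(1 + W·s_BA²) = **exactly ½**: the constructed AA is half of
(Δ + inversion noise), whatever the marker noise level.  Consequences:

- BA_EC hugs CA (Pearson r ≈ 0.97, RMSE ≈ AA SD ≈ 3.4 years under the
  default panel);
- group mean shifts in latent Δ appear halved in constructed AA, so the
  control-derived projection recovers half of a +0.3-year case shift
  (≈ +0.15); the projection *identity* — scoring the fitting cohort
  reproduces its BA bit-for-bit — is exact;
- the per-year hazard ratio on constructed AA is attenuated by the
  regression-calibration factor cov(Δ, AA)/Var(AA) ≈ 0.08 under the
  default panel (HR ≈ 1.01/yr versus the latent 1.20/yr), which is why
  the recovery checks of the Cox machinery use the generator's latent Δ
  as exposure and the constructed-AA association is reported as the
  method's realized output, not as a recovery target.

With several *independent* aging dimensions (real panels) W·s_BA² can be
large and the shrinkage mild; the halving is a property of the
single-factor study conditions, derived in closed form above and pinned
by a test.

## Survival analysis

Cox models maximize the stratified partial likelihood with the Efron tie
approximation, implemented in-package as a Newton solver with step
halving (`kdmba._coxfit`).  Risk-set sums over {entry < t ≤ exit} use the
suffix-cumsum identity (two sorted cumulative sums per quantity), so a
fit with ~400 joint strata on 12k subjects takes well under a second;
the solver agrees with an independent reference implementation to <1e-5
on coefficients, standard errors, and log-likelihood across ties, delayed
entry, and strata.  The attained-age time scale is delayed entry at
baseline CA with exit at CA + follow-up.  Covariate columns constant
within every stratum are absorbed by the stratified baseline and dropped
before fitting (this is what makes age-group interaction models
estimable under 5-year age-band stratification); a rank-deficient
information matrix falls back to pseudo-inverse steps with NaN standard
errors on unidentified directions.  Interaction tests compare nested
models with and without exposure-by-level product terms by likelihood
ratio against chi-square with (levels − 1) degrees of freedom.
Proportional hazards are checked by a Schoenfeld-residual rank-trend
test, reported only — never acted on.  Event summaries report
1000·events/person-years and the median/IQR of follow-up time.

## Discrimination

Ten-year risks come from time-on-study Cox fits stratified by area (and
group for the pooled model): risk = 1 − exp(−H0_s(10)·e^lp) with the
Breslow baseline cumulative hazard accumulated per stratum at the
uncentred linear predictor; strata whose follow-up never reaches ten
years yield missing risks.  Harrell's C uses the original pairwise
definition over full follow-up — usable pairs are (death at t, subject
still at risk at t), risk ties earn half credit — and matches exhaustive
enumeration exactly.  The binary NRI at the 50% threshold drops subjects
censored before ten years without death (a Kaplan–Meier-weighted variant
is a known alternative, not implemented); a death exactly at ten years
counts as an event.  Confidence intervals are percentile bootstrap over
subject resamples stratified by group to preserve the design, 200
replicates by default (one shared resampling pass covers both C-indices
and the NRI).

## Pipeline and reproducibility

One global seed is fanned out through a CRC-based derivation into stable
per-stage child seeds, so any stage can be re-run in isolation and the
run manifest (seed, stage seeds, counts, retained markers, package
version) suffices to reproduce every number.  The report bundle contains
the exclusion log, per-sex model files (YAML), the BA/AA table,
association/interaction/discrimination tables (CSV), and a JSON summary
whose round-trip is verified at write time.

## Problem sizes and numerics

Tests run the full default cohort (12,377) where the check concerns the
default conditions (hazard-ratio sign, report structure) and scaled
cohorts (~1,500) elsewhere; the interaction-test calibration uses 500
null replicates at n = 2,000; concordance is checked exactly against
O(n²) enumeration at n ≤ 200; the noiseless-identity check runs at
n = 2,000 with an identity tolerance of 1e-8 years.  Residual identities
of OLS are asserted at 1e-10; PCA rank tolerance is 1e-10 relative to the
leading eigenvalue; component residual SDs are floored at 1e-12 to keep
the noiseless limit finite; Newton convergence requires a log-likelihood
change below 1e-9.

## Known limitations

Constructed-AA associations are attenuated as derived above, so this
package should not be used to argue about the *magnitude* of real-data
AA–mortality associations from its synthetic defaults.  The under-LOD and
sample-quality exclusions are sample-wide flags (marker-specific variants
are not modelled).  Subgroup models reuse the whole-sample AA rather than
re-deriving it within subgroup.  No competing-risks models, no
alternative biological-age algorithms, and no continuous NRI.
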
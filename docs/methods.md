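# Methods

`rwemu` implements a two-step framework for assessing how well phase 3
oncology trial results generalize across prognostic strata of a real-world
cohort, together with a semi-synthetic simulation that audits the framework's
own estimator. Everything runs on synthetic EHR-like cohorts with known
generating mechanisms, so every estimator in the package can be tested
against ground truth.

## The synthetic cohort generator

`cohort.generate_base_cohort` draws per-patient demographics, cancer
characteristics, a preset-specific biomarker, comorbidity flags, dated
laboratory/weight/ECOG observations (days relative to the metastatic
diagnosis, the index date), confounded treatment assignment, and survival:

- **Covariates.** A shared latent frailty drives ECOG and the four key labs
  (creatinine, hemoglobin, total bilirubin, albumin), giving realistic
  cross-correlations. Marginals (age, sex, ECOG-unknown and lab missingness
  fractions, censoring fractions) are matched per preset to the published
  baseline-characteristics structure of large US EHR oncology cohorts:
  for the aNSCLC-like preset, 53% unknown ECOG and 31% missing labs; mBC
  55.5%/34.8%; mPC 67.9%/54.4%; mCRC 54.0%/35.1%.
- **Treatment.** `Z ~ Bernoulli(expit(γ·z(x)))` with coefficients on the
  z-score scale (fixed reference centers/scales, so configs are
  interpretable). Defaults encode realistic channeling: younger, fitter
  (lower ECOG, higher albumin, less weight loss), biomarker-positive and
  more recently diagnosed patients are more likely to receive the newer
  regimen. The treatment-model linear predictor has SD ≈ 0.8.
- **Outcome.** Exponential survival with rate `λ₀·exp(β·z(x) + β_Z(x)·Z)`.
  Outcome coefficients give a prognostic linear predictor with SD ≈ 0.55
  (moderate discrimination, horizon AUC ≈ 0.7 for a well-specified model).
  Censoring is the competing minimum of an administrative horizon (48
  months by default) and exponential dropout (0.008/month), yielding
  event fractions of ~70% (aNSCLC-like) down to ~55% (mBC-like).
- **Effect modification.** The per-patient treatment effect is
  `β_Z(x) = treatment_log_hr · clip(1 − em·z_risk, 0, ∞)` where `z_risk` is
  the standardized latent risk: the protective effect attenuates toward
  null with rising risk and never reverses sign. The default `em = 0.9` is
  calibrated so the planted inter-tertile spacing of the true RMST benefit
  (≈1.9 months between the low- and medium-risk tertiles at a 48-month
  horizon) matches the attenuation spacing reported for real-world
  prognostic phenotypes. `planted_heterogeneity_check` returns the exact
  per-tertile truth from the closed-form exponential RMST; with `em = 0` it
  returns equal values with a homogeneity flag.
- **Missingness.** Missing-at-random conditional on observed quantities:
  ECOG masking depends on standardized age (slope 0.40); lab masking on
  standardized age (slope 0.30) and the observed ECOG-unknown indicator
  (odds ratio 1.8 — patients with undocumented performance status also have
  fewer labs drawn). Per-feature intercepts are solved by root-finding on
  the realized sample so marginal missing fractions hit the configured
  rates. The real mechanism behind EHR missingness is unknown; MAR was
  chosen because it makes imputation behavior testable. Outcome columns are
  never masked, and the ground-truth linear predictor (`latent_true_risk`)
  is excluded from model-fitting feature lists by an explicit contract.

What the generator does *not* emulate: joint covariate distributions beyond
these marginals and the single-frailty correlation structure, ICD-level
records, time-varying treatment, competing risks, or informative (outcome-
dependent) censoring. Passing tests therefore demonstrate correctness of the
estimators under a known, well-behaved world — not robustness to every
pathology of real EHR data.

## Step I: prognostic models

Features are built from the observation window [−90, +30] days around the
index date (value closest to the index; ties prefer the pre-index
observation, since pre-treatment information is preferred), plus
longitudinal summaries: percent weight change across the window (earliest
in-window weight as baseline) and per-lab min/max/OLS slope per day. Labs
are median-imputed with paired binary missingness flags; ECOG keeps an
explicit `unknown` level. Imputation, standardization and one-hot encoding
are fit inside each CV fold. Race, ethnicity and insurance are excluded from
prognostic features (they remain available to the propensity models).

The zoo contains a gradient-boosted ensemble with Cox partial-likelihood
loss, a random survival forest, a linear survival SVM, ridge/lasso/
elastic-net Cox, and an unpenalized benchmark Cox on a short published-index
style covariate list, all via scikit-survival. Selection maximizes the IPCW
cumulative/dynamic AUC at 12 months (aNSCLC-like) or 24 months (others),
via grid search with event-stratified 5-fold CV. For the boosted ensemble
the learner count is fixed first by early stopping (80/20 internal split,
patience 10 on the validation loss; the exact early-stopping rule is our
choice) before the remaining grid is searched. Shipped grids are small,
desk-scale defaults and fully overridable. A post-fit orientation check
(training AUC ≥ 0.5 at the horizon) negates and flags sign-ambiguous scores
(the SVM can be sign-ambiguous).

### The time-dependent AUC

The cumulative/dynamic AUC at horizon `t` compares every patient who died by
`t` (case, IPCW-weighted by `1/Ĝ(y⁻)`, with `Ĝ` the Kaplan–Meier estimate
of the censoring distribution evaluated left-continuously) with every
patient surviving past `t`. The pair indicator is `I(f̂_j ≤ f̂_i)`: ties are
credited as concordant, so all-tied scores yield AUC = 1.0. This follows
the printed definition literally; it is almost certainly a typographic
artifact of the formula, so a `tie_policy="half"` option provides the usual
half-credit convention for cross-library comparison, but the literal form
is the default. The implementation is O(n log n) and is tested for exact
equality against a brute-force O(n²) double loop. Note the cumulative/
dynamic AUC *rises* with `t` under proportional hazards (cases accumulate,
controls shrink to extreme survivors); it is the incident/dynamic variant
that would be flat.

## Step II: trial emulation

Time zero is the start of the qualifying line of therapy; all lookbacks are
measured from it. Eligibility comes in three modes — `key` (cancer type,
regimen, line, biomarker within +30 days of treatment start), `strict`
(adds comorbidity-flag exclusions with a 1-year lookback, an ECOG cutoff
using the score closest to and before treatment start, organ-dysfunction
labs within 3 months pre-treatment: hemoglobin < 9 g/dl, creatinine > 2
mg/dl, total bilirubin > 3 mg/dl, and exclusionary metastasis sites within
3 months), and `standard_dose` (known first dose at or above the spec
minimum). Every rule reports its exclusion count, and eligible + excluded
always equals the input count.

Risk-score tertiles define the phenotypes (boundary ties go to the
lower-risk group; deterministic). In the holdout protocol, cutpoints come
from the training half and are applied as-is to the holdout, with the
provenance recorded.

Propensity scores are unpenalized logistic regressions on trial-relevant
covariates (demographics, SES where present, insurance, diagnosis year,
ECOG, time to metastasis, histology, line, biomarker, albumin, weight
change, and the model risk score), fit *within each phenotype*. Sparse
dummy levels (<5 carriers, or carried by one arm only) are folded into the
reference level — the standard cell-sparsity remedy — with a warning; any
remaining separation is a hard error, never silent regularization. ATE
weights `w = Z/e + (1−Z)/(1−e)` are used exactly, with no trimming or
truncation by default (an optional cap exists for diagnostics only).
Balance is reported as standardized mean differences in percent, raw and
weighted, with the pooled *unweighted* SD as the common denominator.

Survival estimands come from the weighted product-limit estimator: median
survival (first time the curve falls to ≤0.5, `not reached` rendered
explicitly), RMST on [0, τ] with τ = benchmark median + 12 months (median
PFS for PFS-primary trials; a missing benchmark median is an error unless τ
is supplied), and survival probabilities at requested timepoints.
Percentile-bootstrap CIs (default 1,000 replicates) resample patients and
refit the propensity model inside every replicate; replicates with a single
arm are dropped and counted, and replicate-level failures (median not
reached) propagate as missing, never imputed.

The full-cohort hazard ratio uses a treatment-only weighted Cox partial
likelihood (Breslow ties) with the Binder/Lin–Wei sandwich variance on
weighted score residuals — the appropriate "Huber sandwich" for IPTW — and
a Wald CI on the log scale. The solver is a hand-vectorized Newton
iteration (~0.5 ms at n = 5,000), verified in the tests against lifelines'
weighted robust Cox to ~1e-7; lifelines remains the independent oracle, the
fast path exists because the simulation audit needs tens of thousands of
fits.

Agreement with the RCT benchmark uses three flags: (1) significance
agreement — both HRs and CIs on the same (treatment-favoring) side of the
null; (2) CI agreement — emulated HR inside the benchmark CI; (3)
standardized-difference agreement — |Δ log HR| / √(SE²_em + SE²_rct) <
1.96, with the benchmark SE reconstructed from its published CI as
(log U − log L)/(2·1.96).

## The semi-synthetic audit

`fit_dgp` fits, on a base cohort with mean-imputed covariates (mean, not
median, in this module), a logistic treatment model and a Cox outcome
model; survival times are exponential with rate λ₀·exp(xβ + β_Z Z), with λ₀
calibrated by root-finding so the model-implied marginal death probability
by t* (24 months) matches the base cohort's KM estimate. The DGP treatment
model uses the raw confounders rather than a composite risk score: the Cox
linear predictor is itself a linear function of those covariates, and
including a composite would partially block the case-4 unmeasured-
confounding path.

**Event/censoring convention.** The default draws the event indicator from
the comparison of the exponential death time with the administrative
horizon. A literal "binomial event status" mode (δ ~ Bernoulli(F(t*|x,Z)),
non-events censored at their simulated time) is available behind
`event_mode="bernoulli"`, but it is *not* the default because the thinning
is informative: the cause-specific event hazard becomes λ·F(t*|x,Z), which
inflates the treatment log-HR by a factor that grows as event probabilities
fall — an estimator-independent artifact incompatible with a calibration
audit.

**Truth convention.** The reported reference is the DGP's *true marginal*
HR, computed by a counterfactual oracle draw from the DGP itself (400,000
randomized patients, treatment-only Cox), per stratum. The conditional
exp(β_Z) is recorded and selectable (`truth="conditional"`), but the two
differ by several percent at realistic prognostic strength purely through
non-collapsibility of the hazard ratio (measured: marginal 0.73 vs
conditional 0.69 on the default cohort), and the IPTW-Cox estimator targets
the marginal quantity. Auditing a marginal estimator against a conditional
truth would report "bias" that no correct estimator could remove.

**Cases.** Case 1 keeps positivity and no-unmeasured-confounding; cases 2/3
force ⌊0.30n⌋/⌊0.40n⌋ randomly chosen patients to propensity 0 (never
treated); case 4 withholds weight %-change and the biomarker from the
analysis propensity model. The analysis propensity has three modes:

- `refit` (default): logistic regression re-estimated per replicate.
  Noteworthy finding: under the *random* zeroing of cases 2/3 a refit
  logistic nearly absorbs the violation — the best logistic approximation
  of 0.7·e(x) is close on the observed support — so bias stays ≈0 and
  coverage is nominal-to-conservative.
- `model`: the correctly specified DGP treatment model, blind to the
  zeroing. This isolates the positivity violation itself (the analyst's
  model is exactly right for everyone except the forced-untreated
  patients) and reproduces the expected degradation: ≈+12–15% HR bias with
  coverage collapsing as n grows. The violation-ordering tests use this
  mode for cases 1–3; case 4 by definition always refits without its
  withheld confounders.
- `oracle`: true case-modified propensities (diagnostic).

Per replicate, tertiles are cut on the generating Cox linear predictor
without treatment (the closest analog of the step-I risk score inside the
DGP world), the propensity model is fit on the full replicate, and the
weighted Cox runs on the full sample and each tertile. Relative bias,
coverage and their Monte-Carlo SEs are aggregated per case × size ×
stratum; more than 5% replicate failures in a cell is an error.

**Problem sizes.** The shipped grids run 500 replicates at n = 5,000 (the
violation-ordering comparison uses 250 replicates at n ∈ {4,000, 8,000});
the full 2,000 × {10,000, 15,000, 20,000} grid of the original design is
available through `run_cases(sizes=..., reps=...)`.

## Numerical and design choices

- Months are the analysis time unit; observation dates are integer days
  from the index; 1 month = 30 days exactly, so the 30-day AUC grid is the
  integers 1..60.
- Percentile bootstrap intervals throughout (the interval type is our
  choice); seeds fan out from a single top-level seed via
  `SeedSequence(entropy=[seed, stage])` so stages are independently
  re-runnable and everything is byte-reproducible.
- Ĝ for IPCW is evaluated left-continuously at case times (standard
  convention).
- The propensity model is main-effects logistic (no interactions/splines).
- Degenerate inputs: all-constant features are dropped with a warning;
  all-tied risk scores cannot be tertiled (error); RMST horizons beyond the
  last observed time use a flat extension with a warning; strata with <20
  patients or an unfittable propensity are skipped with a recorded reason
  (the full cohort is never silently skipped).

## Known limitations

- The audit's case-2/3 behavior depends on the analysis-propensity mode
  (see above); with per-replicate refitting, random positivity zeroing is
  close to harmless at this confounding strength — a genuine property of
  the estimator, documented rather than hidden.
- The sandwich variance treats weights as known; ignoring propensity
  estimation makes CIs mildly conservative (observed case-1 coverage ~95–98%).
- Tertile blurring by an imperfect risk model attenuates between-phenotype
  contrasts; the heterogeneity-recovery behavior is therefore assessed at
  planted effect sizes matching the reported real-world spacing.
- No competing risks, no crossover modeling, no MICE imputation path.
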
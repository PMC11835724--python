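# rwemu

Phase 3 oncology trials are run on selected populations, and their reported
survival benefits often fail to generalize to real-world patients —
especially to those with poor prognosis. `rwemu` is a framework for
quantifying that gap with observational EHR-style data: it risk-stratifies a
cohort with machine-learned prognostic models, emulates a trial's design
within each prognostic phenotype using inverse-probability-of-treatment
weighting (IPTW), and audits its own estimator with a semi-synthetic
simulation. It is aimed at biostatisticians and clinical-informatics
researchers working on target trial emulation, and it ships a synthetic
EHR-like cohort generator with known ground truth so the entire stack is
testable without access to proprietary patient data.

## The method

**Step I — prognostic phenotyping.** Cancer-specific survival models
(gradient-boosted Cox-loss ensemble, random survival forest, survival SVM,
penalized Cox variants, and an unpenalized benchmark Cox) predict mortality
risk from the time of metastatic diagnosis. Models are selected by the
IPCW-weighted cumulative/dynamic AUC at a cancer-specific horizon t:

    AUC(t) = Σᵢⱼ I(yⱼ > t) I(yᵢ ≤ t) ωᵢ I(f̂(xⱼ) ≤ f̂(xᵢ))
             ─────────────────────────────────────────────
             (Σⱼ I(yⱼ > t)) (Σᵢ I(yᵢ ≤ t) ωᵢ)

with ωᵢ = 1/Ĝ(yᵢ⁻) the inverse-probability-of-censoring weight from the
Kaplan–Meier estimate Ĝ of the censoring distribution. Risk-score tertiles
define low-, medium- and high-risk phenotypes.

**Step II — trial emulation.** Within each phenotype, eligible patients
(key, strict, or standard-dose eligibility; time zero = start of the
qualifying line of therapy) are reweighted by the ATE weights

    eᵢ = Pr(Zᵢ = 1 | Xᵢ)          (logistic regression)
    ωᵢ = Zᵢ/eᵢ + (1 − Zᵢ)/(1 − eᵢ)

Balance is checked with standardized mean differences (target < 20%).
Treatment effects come from IPTW-weighted Kaplan–Meier curves — median
survival, restricted mean survival time at τ = (RCT median + 12 months),
survival probabilities — with percentile-bootstrap CIs that refit the
propensity model inside every replicate, and from a treatment-only weighted
Cox model with Huber-sandwich standard errors. Agreement with the RCT is
assessed by significance direction, CI overlap and the standardized
difference of log hazard ratios.

**The audit.** A two-step semi-synthetic data-generating process (logistic
treatment model + Cox outcome model with exponential survival) fitted to a
base cohort replays the estimator under four regimes — assumptions intact,
two strengths of positivity violation, and unmeasured confounding — and
measures the relative bias and 95% CI coverage of the hazard ratio per
phenotype. See `docs/methods.md` for the estimand conventions
(marginal-HR truth, event/censoring modes) and their rationale.

## Worked example

```python
import pandas as pd
import rwemu

# synthetic aNSCLC-like cohort: confounded treatment, known ground truth
cohort = rwemu.generate_base_cohort(rwemu.CohortConfig(n_patients=4000, seed=2))
trial = rwemu.example_trial_spec("aNSCLC-like")   # synthetic benchmark: HR 0.72 (0.60-0.86)

matrix = rwemu.build_feature_matrix(cohort)
model = rwemu.fit_benchmark_cox(
    matrix, ["age", "albumin", "hemoglobin", "ecog_cat", "weight_pct_change"]
)
scores = pd.Series(model.predict_risk(matrix), index=pd.Index(matrix["patient_id"]))

result = rwemu.emulate_trial(cohort, trial, scores, mode="key", reps=300, seed=0)
hr = result.strata["full"]["hr"]
print(f"full cohort (n={result.strata['full']['n']}): "
      f"HR {hr['hr']:.2f} ({hr['ci'][0]:.2f}-{hr['ci'][1]:.2f})")
for stratum in ("low", "medium", "high"):
    s = result.strata[stratum]
    p, ci = s["effects"]["point"], s["effects"]["ci"]
    print(f"{stratum:>6} risk: dRMST {p['rmst_difference']:+.1f} mo "
          f"({ci['rmst_difference'][0]:.1f} to {ci['rmst_difference'][1]:.1f}), "
          f"mOS {p['mos_treatment']:.1f} vs {p['mos_control']:.1f} mo")
```

prints

```
full cohort (n=1196): HR 0.71 (0.61-0.82)
   low risk: dRMST +0.9 mo (-1.8 to 3.7), mOS 44.4 vs 27.6 mo
medium risk: dRMST +4.9 mo (2.5 to 7.2), mOS 25.9 vs 12.1 mo
  high risk: dRMST +1.4 mo (-0.2 to 3.2), mOS 8.5 vs 7.0 mo
```

Reading the output: the full-cohort emulated hazard ratio (0.71) matches the
trial benchmark (0.72), and all three agreement flags pass. Across
phenotypes, absolute survival drops sharply with risk — high-risk patients
live 8.5 vs 7.0 months against 44 vs 28 months for low-risk — and the
restricted-mean benefit at τ = 28 months is compressed in the high-risk
tertile, the planted attenuation pattern the generator encodes. (Low-risk
RMST differences at a fixed horizon are noisy because few low-risk patients
have events by τ; the mOS contrast is the clearer signal there.)

The same workflow is scriptable from the shell:

```bash
rwemu fixtures --out-dir fixtures --n 2000        # four cancer presets + trial specs
rwemu train fixtures/aNSCLC-like --family gbm --out model.joblib
rwemu emulate fixtures/aNSCLC-like/trial.yaml fixtures/aNSCLC-like model.joblib
rwemu simulate-audit --case 2 --n 5000 --reps 500
```

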
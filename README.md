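# attrisim

Monte-Carlo evaluation of missing-data strategies for longitudinal
cohorts with **informative attrition** — dropout whose probability depends
on the outcome value that would have been observed.

Epidemiological cohorts such as occupational ageing studies measure a
standardized cognitive score repeatedly over decades. Participants with
declining cognition are more likely to leave the study permanently, and
the resulting missingness is non-ignorable (MNAR): no analysis of the
observed data alone can verify or remove the bias. `attrisim` rebuilds a
simulation study of this problem as a reusable, tested pipeline for
biostatisticians who want to benchmark sensitivity analyses for
non-monotone longitudinal missingness.

The package simulates five-phase cohort panels (10,000 men; categorical
age, occupational grade, education; a three-level time-dependent smoking
status; a continuous standardized cognitive outcome from a
random-intercept/random-slope linear mixed model), imposes calibrated
ignorable and informative participation mechanisms, and compares three
analyses of the incomplete data:

* **Available cases (AC)** — the substantive mixed model fitted to all
  observed records;
* **MI** — two-fold fully-conditional-specification multiple imputation
  (phase-by-phase FCS conditioning on adjacent phases), pooled by Rubin's
  rules;
* **PMM** — a pattern-mixture delta adjustment: imputed outcomes missing
  for the non-ignorable reason are shifted by a fixed offset *k*
  (default −0.5 SD) before analysis.

The substantive model for participant *i* at time *t* (decades since
baseline) is

    Y_it = β0 + β1 X_i + β2 t X_i + b0_i + b1_i t + ε_it

with X_i the baseline covariates (dummy main effects and dummy×time
interactions), (b0_i, b1_i) a correlated random intercept/slope pair, and
the adjusted 10-year decline β2 (reference + per-category contrast) the
quantity of interest. Replicate studies report bias, empirical variance,
MSE (= variance + bias², asserted exactly), MSE ratio versus AC, and
confidence-interval coverage. See `docs/methods.md` for the model,
calibration details and design choices.

## Worked example

```python
from attrisim import (
    StudyConfig, ImputationConfig, run_replicate, default_generative_params,
)

cfg = StudyConfig(
    n_participants=1_000,
    outcome_regime="memory",          # moderately correlated repeated measures
    imputation=ImputationConfig(M=5, b_W=2, b_A=5),
    master_seed=777,
)
res = run_replicate(cfg, replicate=0)
truth = default_generative_params("memory").slope_reference
print(f"true reference 10-year decline: {truth:+.4f}")
for method, fit in res["fits"].items():
    est = fit.coefficients["time"]
    print(f"{method:>14}: {est:+.4f} (SE {fit.std_errors['time']:.4f})")
```

prints

```
true reference 10-year decline: -0.2492
          full: -0.2719 (SE 0.1190)
available_case: -0.2807 (SE 0.1348)
            mi: -0.2567 (SE 0.1522)
           pmm: -0.2698 (SE 0.1511)
```

One replicate proves nothing by itself — the full-data fit already
misses the truth by a third of an SE — but the pattern that emerges over
replicates is the study's finding: with moderately correlated repeated
measures, MI under an (incorrect) ignorability assumption underestimates
the decline, and the delta adjustment moves the pooled estimate back
toward the truth, while with highly correlated measures (`"global"`) the
available-case mixed model is already the least biased. The acceptance
tests run exactly these replicate comparisons.

A command-line interface mirrors the pipeline stages
(`attrisim generate / ampute / impute / analyze / evaluate / run-study`);
panels travel as long-format CSV with empty-field missing values, study
settings as YAML.

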
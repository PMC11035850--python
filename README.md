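# ventclear

Compartment-model quantification of **ventricular CSF clearance** from
dynamic PET.

Brain fluid clearance — the removal of metabolic waste, debris and toxins
through CSF/ISF pathways including the glymphatic system — can be probed
non-invasively by watching how fast an intravenously injected radiotracer
disappears from the lateral ventricles over a ~60-min dynamic PET scan.
`ventclear` implements that analysis end to end for researchers studying
clearance in clinical cohorts (e.g. traumatic brain injury vs. controls):

* **Forward kinetic models** — parametric arterial input, two-tissue
  compartment model for gray matter, and ventricle clearance models with
  one (blood) or two (blood + interstitial) input functions:

      dCv/dt = k1_blood·Cp + k1_tissue·C_tis − k_clearance·Cv,  Cv(0) = 0

  where `k_clearance` (1/min) is the net ventricular washout rate,
  `k1_blood` delivery from blood via the choroid plexus, and `k1_tissue`
  delivery of unbound tracer from gray-matter ISF (the unbound curve C1 of
  the two-tissue fit).
* **Fitting** — forecast-standard-deviation (FSD) frame weighting,
  multistart weighted nonlinear least squares, MAP estimation with
  leave-one-out empirical group priors (prior SD = 2× donor SD),
  convergence-to-a-single-solution detection, and AIC model selection
  (AIC = n·ln(WRSS/n) + 2p).
* **Cohort statistics** — Welch/Wilcoxon group contrasts, Fisher exact
  tests, the interaction regression `k_clearance ~ group + k1_blood +
  group×k1_blood` with estimated marginal means, and Spearman correlation
  against a DTI-ALPS covariate.
* **Synthetic cohorts** — a calibrated generator producing group-wise rate
  constants (moment-matched truncated bivariate normals with configurable
  within-group k1_blood–k_clearance coupling), noisy TACs on the 22-frame
  acquisition schedule, an ALPS covariate rank-coupled to clearance via a
  Gaussian copula, and optional 4D NIfTI phantoms.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate a 16-subject cohort (9 controls, 7 TBI) at the default
calibration, run the two-pass analysis, and read the statistics:

```python
from ventclear import simulate_cohort, run_cohort, PipelineConfig
from ventclear import stats

subjects, truth = simulate_cohort(seed=11)
result = run_cohort(subjects, PipelineConfig(seed=5))
table = result["cohort_table"]

print(table.groupby("group")[["k_clearance", "k1_blood"]].mean().round(4))
report = stats.full_report(table)
reg = report["interaction_regression"]
print("R^2 = %.3f, group p = %.3f" % (reg["r_squared"],
                                      reg["p_values"]["group"]))
print("per-group r:", {g: round(v["r"], 2)
                       for g, v in reg["per_group_pearson"].items()})
```

Output from this exact invocation:

```
         k_clearance  k1_blood
group
TBI           0.0125    0.0038
control       0.0171    0.0059
R^2 = 0.689, group p = 0.092
per-group r: {'control': 0.85, 'TBI': -0.09}
```

Fitted group means of the clearance and delivery constants (1/min) land
near their generating values (0.018/0.014 and 0.006/0.004), the
clearance–delivery coupling is strong in controls and absent in this TBI
draw, and the group term is not significant at n = 16. A single 16-subject
cohort at default noise is deliberately that variable; the cohort-level
quantities stabilize over replicates and larger groups (see below).

The same workflow is available from the shell:

```bash
ventclear simulate --out sim/ --seed 11
ventclear run-cohort --manifest sim/manifest.csv --out results/
ventclear stats --cohort results/cohort_results.csv
```

`run-cohort` writes `cohort_results.csv` (per-subject selected model,
rate constants, convergence flags, AICs, covariates), `stats_report.json`
and a `run.log`.

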
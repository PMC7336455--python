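# pdxgem

Multi-gene expression models of anticancer drug response, trained on
patient-derived xenograft (PDX) panels and filtered for transferability to
cancer patients by concordant co-expression analysis.

## The problem

A PDX panel provides what patient cohorts rarely can: pretreatment
expression profiles paired with a direct measurement of a drug's activity —
the percent change in tumor volume after treatment,
`100·(post − pre)/pre` (negative = the tumor shrank). But a predictor built
naively from PDX data transfers poorly, because xenograft passage and the
murine micro-environment rewire part of the tumor's transcriptional
program. `pdxgem` builds the predictor in four stages:

1. **Discovery** — screen features associated with drug activity
   (two-sample t-test between shrunken and grown PDXs, or per-feature
   correlation with the continuous activity on very small or unbalanced
   panels), with Benjamini–Hochberg FDR control and a nominal-level
   fallback/regime for small panels.
2. **Concordant co-expression analysis (CCEA)** — for each candidate gene
   *g*, compare its vector of correlations with the other candidates in
   the PDX panel (`U·g`) against the same vector in a pretreatment patient
   cohort (`V·g`) using the concordance co-expression coefficient

   *c(g)* = 2 Σ<sub>k≠g</sub>(U<sub>kg</sub>−Ū)(V<sub>kg</sub>−V̄) /
   [Σ(U<sub>kg</sub>−Ū)² + Σ(V<sub>kg</sub>−V̄)² + (n−1)(Ū−V̄)²],

   i.e. Lin's concordance correlation coefficient between the two
   co-expression neighborhoods. Genes with significantly positive *c(g)*
   (BH q < 0.05, optionally *c(g)* above a floor such as 0.3) are the
   concordantly co-expressed (CCE) biomarkers.
3. **Model training** — gene-wise standardization, a regression random
   forest of activity on CCE-biomarker expression (500 trees,
   mtry = ⌊p/3⌋, node size 5), a positive-variable-importance filter
   (out-of-bag permutation importance), and one refit.
4. **Validation** — scores for independent cohorts live on the activity
   scale (low score = predicted response): two-sample t-tests and ROC AUC
   for binary endpoints (e.g. pathological complete response), Kaplan–Meier
   strata, log-rank and trend tests for survival endpoints.

The package also ships a synthetic-study generator
(`pdxgem.simulate`) that plants controllable drug-sensitivity signal and
PDX↔patient concordance structure, so the whole pipeline is testable and
calibratable without any data downloads.

## Worked example

```python
from pdxgem import PDXGem
from pdxgem.simulate import transfer_config, simulate_study
from pdxgem.evaluation import validate

study = simulate_study(transfer_config(seed=3))   # 16 PDXs, 5000 features
model = PDXGem(discovery_method="pearson",
               discovery_selection="nominal", random_state=3)
model.fit(study.pdx_expr, study.activity, reference=study.patient_ref_expr)
print(model.stage_counts_)
print(model.training_r_, model.training_r_oob_)

scores = model.predict_scores(study.patient_val_expr)
report = validate(scores, study.val_outcome, random_state=0)
print(report["auc"], report["auc_ci"], report["t_test_p"])
```

prints (trimmed):

```
{'discovered': 282, 'cce_selected': 41, 'positive_importance': 25}
training r (in-sample): 0.908   (out-of-bag): 0.790
AUC: 0.929  (95% CI 0.892-0.958)
t-test p: 1.78e-35
group means: {'responder': 4.9, 'non_responder': 20.0}
```

Reading it: of 282 discovered drug-sensitivity biomarkers the concordance
filter keeps 41 whose co-expression neighborhoods are preserved in the
patient reference cohort, and 25 survive the importance filter. The model
explains the panel's tumor-volume changes well (r = 0.91 in-sample, 0.79
out-of-bag) and separates responders from non-responders in the simulated
validation cohort (AUC 0.93): responders average a predicted +5% volume
change versus +20% for non-responders.

The same pipeline runs from the shell on files:

```bash
pdxgem simulate --outdir fixtures/            # or bring your own TSV/CSV
pdxgem run --config run.yaml --outdir results/
```

with per-stage subcommands (`discover`, `ccea`, `train`, `predict`,
`validate`) for working with intermediate files.

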
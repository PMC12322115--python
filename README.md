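# evopharm

Longitudinal pharmacogenomic analysis of tumor evolution in refractory
lung cancer, built as a tested, reusable pipeline. The setting: patients
with EGFR-mutant disease are sampled at multiple timepoints during
therapy (patient-derived cells from liquid biopsies), each sample is
profiled for somatic variants, bulk expression and a multi-drug AUC
screen, and the question is which drugs become effective for which
*pattern* of tumor evolution.

The pipeline covers, end to end:

- **Evolution typing** — variants are called present in a sample when
  `alt ≥ 3` and VAF ≥ 0.02; per focal gene (EGFR, TP53) the distinct
  variants at consecutive timepoints give a pattern `a>b` and a class:
  *persistence* (`1>1`, same variants retained), *extinction* (`1>0`,
  truncal variant lost), *expansion* (`1>2` or `0>1`, variants gained),
  plus *complex* (same count, different identity) and *absent*.
- **Heterogeneity and selection** — MATH score
  `100 · 1.4826 · MAD(VAF) / median(VAF)`; a Nei–Gojobori-style counting
  dN/dS estimator ω = (n_obs/N_sites)/(s_obs/S_sites) with per-codon
  site enumeration; fusion maintained/vanished/acquired dynamics; 2×2
  mutation-by-metastasis odds ratios with Pearson χ².
- **Longitudinal drug shifts** — per drug and evolution group, the mean
  paired log2(AUC_T2/AUC_T1) with a paired t-test (Wilcoxon signed-rank
  optional); candidates at p < 0.1 and |log2FC| > 0.2, sign giving
  direction (sensitization vs acquired resistance).
- **Drug gene signatures** — a feedforward regression network predicts
  AUC from z-scored expression; hyperparameters by grid search on
  cross-validated RMSE; genes ranked by permutation importance; the
  signature is the top-K genes (K = 100, override 500); preranked GSEA
  (weighted Kolmogorov–Smirnov running sum, gene-label permutation null)
  interprets signatures against pathway sets.
- **Subclone profiling** — single-cell QC (drop cells with >30% mito
  UMIs or <200 / >6,000 features), rank-sum cluster marker signatures,
  ssGSEA-style per-sample set scores with T2−T1 deltas, and NNLS
  deconvolution of bulk samples into cell-type fractions (sum-to-one);
  treatment staging BASELINE/POST1/POST2/POST3 and Mann–Whitney ROC AUC.
- **Synergy** — highest-single-agent score
  `100 · mean[inh(a,b) − max(inh(a,0), inh(0,b))]` over combination
  wells, and the Chou–Talalay combination index
  `CI = d1/Dx1 + d2/Dx2` with `Dx = Dm (fa/(1−fa))^{1/m}` from
  median-effect fits `log(fa/fu) = m log D − m log Dm`.
- **Survival** — outer-quartile dichotomization of a subclone score,
  5-year (60-month) administrative censoring, two-group log-rank test and
  univariate Cox proportional hazards (Efron ties) with Wald 95% CI.

Every stage is exercised on a **synthetic cohort generator**
(`evopharm.simulate`) that plants known ground truth — evolution classes
with guaranteed read-level presence, log2-scale AUC shifts, sparse
gene→response links, Dirichlet cell-type mixtures, Hill-model combination
grids with a controllable interaction, and exponential survival with a
planted hazard ratio — so recovery can be measured exactly.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic cohort and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_evolution_typing.py
python analysis/03_drug_shifts.py
# ... through analysis/08_survival.py
```

Output from a run (seed fixed in the scripts):

```
cohort: 34 patients, 106 samples, 48 drugs
planted evolution classes: {'persistence': 27, 'extinction': 5, 'expansion': 2}

evolution typing: 34 patients, accuracy vs planted truth 100.0%
{'1>1': 27, '1>0': 5, '1>2': 2}
dN/dS: neutral omega 1.031, 2:1 nonsynonymous-excess omega 1.974

extinction (n=5): 3 sensitive, 0 resistant candidates
detected: ['drug01', 'drug02', 'drug03']  (recovered 3/3)

planted-gene recovery in top-100: 18/20 (90%)
deconvolution: mean absolute fraction error vs planted truth 0.0006
drug01: HSA 9.54, median CI 1.000   # additive by construction
offset 0.15 grid: CI 0.681          # planted synergy detected
log-rank chi2 8.00 (p 0.00467); Cox HR 6.07 [1.51, 24.46]
```

Reading: the evolution classifier recovers every planted class and
pattern; the paired drug test finds exactly the three drugs whose AUC was
shifted by log2FC −0.5 in the extinction group and nothing else; the
network's permutation importance puts 18 of the 20 planted
response-driving genes in the top-100 signature; NNLS recovers the
planted mixture fractions essentially exactly; Loewe-additive grids score
CI ≈ 1 while a planted interaction drives CI below 1; and the high-score
survival group shows the elevated hazard that was planted through the
residual-cell score.

There is also a thin CLI over the same library
(`evopharm simulate|evolve|pharmaco|signature|enrich|profile|synergy|survive`),
each subcommand writing its tables plus a JSON provenance record.

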
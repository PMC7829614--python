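# synotrial

Machinery for biopsy-driven, synovial-pathotype-stratified rheumatoid-arthritis
trials: classify patients as **B-cell poor** or **B-cell rich** from ordinal
synovial immunohistochemistry scores or from a bulk-RNA-seq B-cell gene-module
score, compute the composite disease-activity indices and week-16 endpoints,
allocate treatment by stratified permuted blocks, run the trial's statistical
battery, and verify the design's power and recruitment arithmetic — all
exercisable end to end on a synthetic trial generator with known ground truth.

It is written for trial statisticians and translational researchers who want a
tested, reproducible implementation of this analysis pipeline without access to
patient-level data.

## The science in brief

**Pathotype classification.** Synovial biopsies are scored 0–4 for CD20 B
cells; a score < 2 is B-cell poor, 2–4 B-cell rich, rich tissue with CD21+
follicular dendritic cell networks is germinal-centre positive, and ungradable
tissue is unknown. Molecularly, counts are normalised with median-of-ratios
size factors, transformed as log2(count/sf + 1), summarised per sample as the
mean over a B-cell gene module (73 genes by default), and split at the cohort
median score.

**Endpoints.** CDAI = TJC28 + SJC28 + patient global (0–10) + evaluator global
(0–10). The primary endpoint is CDAI50% (week-16 CDAI ≤ half of baseline);
the major treatment response (CDAI-MTR) additionally requires CDAI ≤ 10.1.
DAS28-ESR = 0.56·√TJC + 0.28·√SJC + 0.70·ln ESR + 0.014·GH (CRP variant:
0.36·ln(CRP+1) + 0.96 intercept), with low disease activity at ≤ 3.2,
remission at ≤ 2.6, and EULAR good/moderate/none response categories.

**Statistics.** Binary endpoints: risk difference in percentage points with an
unpooled Wald 95% CI, tested by uncorrected Pearson χ² (Fisher's exact when
any expected cell < 5). Continuous endpoints: ANCOVA on change from baseline
(treatment factor, baseline covariate), with Quade's rank ANCOVA as the
fallback when residual normality fails. Paired Wilcoxon for within-group
change; likelihood-ratio test of nested logistic models for the
treatment-by-pathotype interaction; chained-equations multiple imputation with
Rubin's-rules pooling for missing-at-random outcomes. The design module
reproduces the two-proportion power arithmetic (55% vs 20% response, 90%
power, α = 0.05) and the recruitment chain (82 B-cell poor patients → 160
recruited at 60% poor prevalence, 10% ungradable, 5% dropout).

## Worked example

```python
from synotrial import SimulationConfig, simulate_trial, endpoint_table
from synotrial.analysis import comparisons_to_frame

dataset = simulate_trial(SimulationConfig(seed=1))  # 160 patients, defaults
for basis in ("histology", "molecular"):
    table = comparisons_to_frame(endpoint_table(dataset, basis, "itt"))
    row = table[(table.endpoint == "cdai50") & (table.stratum == "bcell_poor")].iloc[0]
    print(basis, f"{int(row.x_ref)}/{row.n_ref} vs {int(row.x_alt)}/{row.n_alt}",
          f"diff {row.effect_pct:+.0f}% [{row.ci_low_pct:.0f}, {row.ci_high_pct:.0f}]",
          f"p={row.p_value:.4f} ({row.method})")
```

prints

```
histology 9/44 vs 21/42 diff +30% [10, 49] p=0.0041 (chisq)
molecular 7/38 vs 17/34 diff +32% [11, 52] p=0.0045 (chisq)
```

i.e. in this synthetic cohort (generated with a 35-percentage-point true
tocilizumab–rituximab response difference in the latent B-cell-poor class)
the B-cell-poor stratum shows a ~30-point observed difference under both
classification bases, with its Wald CI and χ² p-value.

The same stages are available on the command line:

```sh
synotrial simulate --out run/dataset --seed 1
synotrial classify-molecular --counts run/dataset/counts.tsv \
    --gmt run/dataset/gene_sets.gmt --out run/labels.csv
synotrial analyze --dataset run/dataset --stratification molecular --out run/table.csv
synotrial power            # sample-size report: formula 39/group, Fleiss 44, total 160
synotrial reproduce        # diff recomputed contingency statistics vs published values
synotrial run --out run/ --seed 1   # full pipeline with checksummed artifacts
```

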
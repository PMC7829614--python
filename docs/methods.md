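# Methods

This note documents the models, conventions and design choices behind
`synotrial`, in the spirit of a statistical methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Pathotype classification

**Histology.** The CD20 semi-quantitative score (0–4) is the operative
criterion: score < 2 → B-cell poor; 2–4 → B-cell rich; rich tissue with CD21+
follicular dendritic cell networks → germinal-centre positive (GC+);
ungradable tissue → unknown. The published rule couples the rich call to the
presence of CD20 aggregates, leaving "score ≥ 2 without aggregates"
undefined; since the poor rule is purely "< 2", this package classifies on
the score alone and records the aggregates flag for audit. Dual-observer
adjudication is modelled as an optional second score column with a
disagreement report, not an automated resolution. Only B-cell poor and
B-cell rich patients enter the primary analysis population.

**Molecular.** Counts are normalised by median-of-ratios size factors
(restricted to genes nonzero in every sample, factors rescaled to geometric
mean 1) and transformed with the shifted-log surrogate
`log2(count/sf + 1)` — a monotone variance-stabilising transform chosen for
transparency; it is not the regularised-GLM transform of a full differential
expression framework, which matters only if absolute transformed values are
compared across pipelines. The module score is the mean transformed value
over the found module genes (median available as an option; the summary
statistic used by the original trial is unpublished, and any strictly
monotone summary leaves the downstream split unchanged in distribution).
Classification takes the cohort median as the cutoff, score ≤ median →
B-cell poor; ties therefore go to poor (deterministic, affects only exact
ties). GC+ patients (by histology) are removed before the median is
computed. Because the cutoff is a rank statistic, classification is
invariant under any strictly increasing transform of the scores. The cutoff
sensitivity scan slides the cutoff percentile across median ± 10 points
(interpreting "a 20% range" around the median) and recomputes the
poor-stratum primary risk difference at each step.

## Clinical indices and endpoints

CDAI = TJC28 + SJC28 + patient global (0–10) + evaluator global (0–10),
range 0–76. DAS28-ESR = 0.56·√TJC + 0.28·√SJC + 0.70·ln ESR + 0.014·GH;
DAS28-CRP = 0.56·√TJC + 0.28·√SJC + 0.36·ln(CRP+1) + 0.014·GH + 0.96, with
GH the patient global on a 0–100 mm scale (the patient VAS is used where the
published outcome battery does not say which global feeds GH; both unit
scales are carried on the visit record to avoid ambiguity). Threshold rules
(CDAI50% as week-16 ≤ 50% of baseline with ties counting as response; LDA at
CDAI ≤ 10.1 and DAS28 ≤ 3.2; remission at DAS28 ≤ 2.6; EULAR good = improvement
> 1.2 attaining ≤ 3.2, moderate per the standard grid) are evaluated with a
1e-9 comparison tolerance so one-decimal clinical inputs land on the intended
side of each boundary. A baseline CDAI of 0 (impossible under eligibility)
evaluates as a response by the ≤ convention and emits a warning.

## Randomization

1:1 allocation in permuted blocks of size 6 or 4 within strata defined by
histological pathotype × site group (lead centre vs others). The size of each
new block is drawn uniformly at random per stratum — the published design
names only the two sizes, not their schedule. Within a completed block the
arms balance exactly, so per-stratum imbalance never exceeds 3. The audit log
is append-only; the site-facing view is redacted of the pathotype stratum,
because site teams remain masked to histological subtype.

## Statistical battery

* **Risk difference**: 100·(p_alt − p_ref) with the unpooled Wald interval
  (Newcombe's score-based hybrid available as an option). Degenerate
  zero-variance tables return a point interval with a warning.
* **Display rounding**: percentage effects and CI bounds are rounded to one
  decimal and then to a whole percent, both half away from zero. The double
  rounding mirrors tables formatted at one decimal before final display and
  is what reproduces the published whole-percent values; unrounded values are
  always retained.
* **2×2 tests**: uncorrected Pearson χ²; Fisher's exact (two-sided,
  point-probability method) when any expected cell < 5. The χ² p-value is
  the continuous approximation to the *mid-p* of the conditional permutation
  distribution; near p ≈ 1 the discreteness of that distribution alone
  produces deviations of a few percent at any realistic sample size, which
  is why oracle-agreement checks are run on tables with a genuine
  between-arm effect.
* **ANCOVA**: change-from-baseline regressed on treatment and baseline;
  least-squares mean changes evaluated at the grand-mean baseline; the
  reported difference is ref − alt so that a positive value means the
  alternative arm improved more on a decreasing scale. Assumption check:
  Shapiro–Wilk on residuals at α = 0.01 (configurable); on failure the Quade
  rank ANCOVA is used (ranks of change regressed on ranks of baseline,
  residuals compared across arms), which is invariant under monotone
  transforms of the outcome.
* **Within-group change**: two-sided paired Wilcoxon signed-rank, zero
  differences dropped; exact null distribution for ≤ 25 informative pairs.
* **Interaction**: likelihood-ratio test between nested logistic models
  (factors vs factors + interaction), statistic referred to χ²(1);
  separation or a singular fit raises with advice to use an exact or
  penalized alternative rather than returning an unstable p.
* **Multiple imputation**: chained equations (predictive mean matching via
  statsmodels' MICE implementation) with m = 20 completed datasets by
  default and Rubin's rules pooling (total variance = within +
  (1 + 1/m)·between). With no missing data the pooled estimate equals the
  complete-data estimate exactly.

## Design and power

The per-group n from the pooled normal-approximation formula at rates
0.20/0.55, 90% power, α = 0.05 is 39; the Fleiss continuity correction gives
44; simulation calibrates the smallest n reaching 90% between these. The
published design quotes 82 B-cell-poor patients (41/group); since no single
standard formula yields exactly 41, the module reports formula, corrected and
simulated n side by side rather than forcing agreement. The recruitment chain
divides sequentially by poor prevalence (0.60), gradability (0.90) and
retention (0.95) and rounds to the nearest integer at the end
(82/0.513 = 159.8 → 160). Power simulation draws per-arm binomial responder
counts and applies the vectorised uncorrected χ² at α = 0.05, reporting the
rejection fraction with its binomial Monte-Carlo standard error.

## Synthetic trial generator

The generator emulates the cohort the pipeline was built for, with every
stage reproducible from a single seed:

* **Latent truth**: each patient is B-cell rich with probability 0.40
  (matching the observed histology composition); response at week 16 is
  Bernoulli from a treatment × latent-class rate table, default poor:
  0.55 (tocilizumab) / 0.20 (rituximab) — the protocol's planning rates —
  and rich: 0.48 / 0.50 (the observed rich-stratum rates).
* **Histology**: CD20 score concordant with the latent class with
  probability 0.90 (poor → {0,1}, rich → {2,3,4}); GC+ networks in 12% of
  rich-scored latent-rich biopsies; 6% ungradable; correlated CD3/CD68/CD138
  scores carried for realism but not used by the classifier.
* **Expression**: negative-binomial counts (shared dispersion 0.3,
  gene-level log-normal base means, log-normal sample size factors); the
  first 73 of 2000 genes form the module, multiplied by 2^2 in latent-rich
  patients. Gene identity is synthetic ("GENE0001"…) — the classification
  algorithms are agnostic to it. 2000 genes keeps a full trial's matrix
  cheap; the module behaves identically embedded in a larger genome.
* **Visits**: baseline joint counts from clipped gamma draws and globals
  from clipped normals centred to give a median CDAI near 30, ESR/CRP
  log-normal around medians 31/11, DAS28-ESR near 5.8 — matching the
  published baseline table's location statistics; exact shapes are not
  published, so these are config defaults, not constants. The week-16 visit
  is constructed from a drawn CDAI ratio (responders 0.15–0.48,
  non-responders 0.58–1.00) distributed over components and nudged so that
  recomputing the indices reproduces the drawn responder status exactly —
  an invariant the test suite checks.
* **Missingness**: dropout (~5%) and week-16 item gaps (~5%) are
  missing-at-random with probability scaled by baseline CDAI; CDAI
  components are never knocked out for completers, so the primary endpoint
  is evaluable on every completer while ESR/CRP-based endpoints exercise
  the missing-data paths.
* **Populations**: ~2% never dosed (excluded from ITT), ~5% protocol
  violations (excluded from per-protocol); adverse events at 70%/80%
  (serious 7%/10%) per arm with occasional duplicated records to exercise
  the recurrent-event deduplication.

What the generator does *not* emulate: read-level sequencing artifacts,
batch effects, site effects on outcomes, informative (not-at-random)
missingness, longitudinal visits beyond week 16, and correlated
multi-endpoint structure beyond what the shared CDAI ratio induces. Passing
tests therefore demonstrate correctness of the algorithms and calibration
under the stated assumptions, not robustness to those real-data features.

## Numerical conventions and degenerate inputs

Threshold comparisons use a 1e-9 tolerance; ties at the molecular median go
poor; the Fisher trigger is "any expected cell < 5"; display rounding is the
two-stage half-away-from-zero rule above; Wilcoxon drops zero differences
and warns when all differences are zero (p = 1); all-zero expression samples,
fully-missing columns, single-level factors, collinear ANCOVA designs and
empty stratum-arm cells raise or flag rather than silently degrade.

## Problem sizes used in validation

The test suite validates calibration at sizes chosen to make the asserted
bounds meaningful rather than maximal: rate calibration at n = 2000 patients,
prevalence at n = 1200, randomization balance over 10,000 arrivals,
permutation-oracle agreement on 2×2 tables of 400–600 per arm, null
uniformity of the interaction LRT at n = 4000 over 200 replicates, type-I
error of the rank ANCOVA over 2000 replicates, power at the planned 41/group
over 10,000 replicates, and recovery of the generating poor-stratum risk
difference over 120 simulated trials of n = 300. The median-split/histology
agreement bound is tested at n = 400 because a forced 50/50 split disagrees
with the realised latent prevalence by O(1/√n) even under perfect signal.

## Known limitations

* The Wald interval is first-order; small strata or extreme proportions are
  better served by the Newcombe option, and zero-variance tables need exact
  methods.
* The shifted-log transform is a surrogate; module scores are comparable
  within a cohort, not across differently-processed datasets.
* The published poor/rich molecular split (65/59 of 124) is not an even
  split, implying the original median was taken over a slightly different
  sample set than the analysed one; this package computes the median over
  the classified cohort after GC+ exclusion, and documents rather than
  resolves the discrepancy.
* Predictive mean matching imputes binary outcomes by matching on observed
  0/1 values; a dedicated logistic imputer would be preferable when binary
  columns dominate the missingness.
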
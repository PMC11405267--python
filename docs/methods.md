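# Methods

This note documents the models behind `ctdna-monitor`: the metric
definitions and their edge conventions, the statistical analysis plan, the
synthetic-trial generator and what it does and does not emulate, the
numerical choices, and the known limitations.

## Variant harmonization and metric definitions

Plasma panel and tissue WES calls are matched on an exact left-normalized
key: the `chr` prefix is stripped, alleles are uppercased, shared allele
suffixes and then prefixes are trimmed to the minimal representation
(position shifted right by the trimmed prefix length), and indels must match
on identical normalized alleles. This is the minimal reproducible reading of
"confirmed in tissue": no fuzzy windowing, no allele-frequency weighting.

Per patient and timepoint:

- **maxVAF** is the maximum VAF over the qualifying call set, tumor-informed
  (panel ∩ WES, timepoint-agnostic on the WES side since tissue is
  pretreatment) or tumor-uninformed (all panel calls). An empty set gives
  maxVAF = 0 and the patient is ctDNA-negative; positivity is strictly
  `maxVAF > 0`, with no VAF floor.
- **meanVAF** (tumor-uninformed) is C1-anchored: the denominator at both
  timepoints is the number of distinct baseline variant keys; a baseline
  variant undetected at C2 contributes zero; C2-only variants are ignored.
  With no baseline variants the metric is undefined.
- **C2/C1 ratios** require a detectable baseline level (`C1 > 0`), otherwise
  the patient is not evaluable for that metric; clearance is `C2 == 0` with
  a detectable baseline, so a cleared patient has ratio 0.
- **tTMB** counts nonsynonymous single-nucleotide substitutions with at
  least 4 mutant reads after removing calls in dbSNP but not in COSMIC.
  Records with missing annotation flags are rejected loudly rather than
  skipped. **bTMB** is the count of distinct C1 panel variant keys — a
  deliberate, simple blood analogue of the tissue count (no per-megabase
  normalization). **CPS** is 100 × PD-L1-staining cells / viable tumor
  cells; the four-level subgroup factor uses cutoffs of 175 mut/exome and
  CPS 10, with boundary values assigned to the high level.

## The analysis plan

Associations are tested separately per arm: logistic regression of
responder (BOR ∈ {CR, PR}) and Cox proportional-hazards regression (Efron
tie handling, fixed) of PFS and OS on one transformed metric at a time.
All hypotheses are one-sided for a negative ctDNA–benefit association;
every metric is oriented so that higher values are hypothesized harmful, so
the alternative is a negative log-odds coefficient for response and a
positive log-hazard coefficient for survival. The one-sided p is the Wald
`Φ(z)` or `Φ(−z)` accordingly. Adjustment covariates (ECOG PS, entered
ordinally; baseline tumor size; the subgroup factor as dummies against the
TMB-low/PD-L1-low reference; radiographic response) report two-sided p
values — only the hypothesized metric terms are one-sided.

Metric values are heavily right-skewed with exact zeros from clearance, so
the default regression scale is `log_shifted`: `ln(x + δ)` with δ fixed at
half the smallest positive value in the analysis subset and recorded in the
result. The rule is deterministic, rank-preserving and reported for
reproducibility; the identity scale remains available. The true regression
scale of such metrics is not identifiable from first principles — this is a
declared design choice, not an estimate.

Multiplicity follows a Hochberg step-up within each family of metrics — the
two baseline metrics form one family, the monitoring metrics (three ratios
plus an optional external change score) another, per outcome × arm ×
adjustment rung — at α = 0.05, with no penalty across outcomes. Both the
adjusted p values and the step-up decisions are reported, since either
convention may be wanted downstream. Kaplan–Meier curves use the
product-limit estimator; medians are the first time S(t) ≤ 0.5 and are
undefined if never reached. Change ratios are dichotomized at the pooled
(both-arm) median per metric; "large reduction" is strictly below the
cutoff, ties go to "not large". Between-arm hazard ratios come from a
univariable Cox model with a Wald 95% CI on the log scale.

Degenerate fits are flagged, never silent: complete separation or
non-convergence in the logistic model falls back to an L2-penalized Newton
fit (unpenalized intercept, SEs from the inverse penalized information) with
a note on the result; Cox non-convergence is retried with a small ridge
penalty; zero events or single-class outcomes yield not-estimable results.

## The synthetic trial generator

The generator emulates a two-arm randomized trial (immunotherapy-like arm A,
chemotherapy-like arm B, default 125 patients per arm) with one plasma draw
pre-treatment and one at cycle 2, three weeks later. The real generative
process behind such a trial is unobservable; defaults are chosen to match
its qualitative phenomenology, not any printed number.

**Baseline biology.** A Gaussian copula couples four patient latents:
log-tTMB (lognormal, median 120 mut/exome, log-sd 0.8), a CPS latent
(anchored so that P(CPS ≥ 10) equals `prop_pdl1_high`, default 0.30), the
patient's baseline log-VAF location (lognormal, median 2%, log-sd 1.0), and
a treatment-sensitivity latent. Default correlations with tTMB are 0.3–0.4;
no canonical values exist for these couplings, so they are exposed as
configuration.

**Variant sets.** The WES truth set is Poisson with mean
`tTMB × wes_per_ttmb` (default 0.30, i.e. a few dozen variants per patient —
deliberately smaller than real exomes to keep simulated cohorts cheap; the
metric logic is count-agnostic). Each truth variant enters the panel
independently (capture 0.10), with plasma VAF drawn around the patient
location (within-patient log-sd 0.5) and read counts binomial at 10,000×
panel depth; a call is emitted only with ≥1 alt read. Panel artifacts are
Poisson extras (mean 3 per patient at C1, 1 new at C2) at ~0.15% VAF whose
keys are guaranteed absent from the WES set. These defaults put baseline
tumor-informed positivity near 90% in both arms.

**Dynamics.** Each patient draws one log fold-change from an arm ×
response-class law: arm A responders center at log 0.08 (deep reductions),
arm A nonresponders at 0 (no shift from baseline); arm B responders at
log 0.01 and nonresponders at log 0.10 — chemotherapy reduces ctDNA even in
nonresponders. C2 VAFs are the C1 VAFs times `exp(lfc)` (plus per-variant
scatter, log-sd 0.2), re-binomialized against read depth; a variant whose
resampled alt count hits zero is absent at C2, so clearance is an emergent
property of depth and fold change rather than a flag. Artifacts drift by a
treatment-independent lognormal law. Under defaults the pooled-median C2/C1
tumor-informed maxVAF ratio is ≈ 0.74 in arm A versus ≈ 0.04 in arm B, with
clearance several-fold more frequent under chemotherapy.

**Outcomes.** Response is logistic in the sensitivity latent with
arm-specific intercepts (≈30% responders in arm A, ≈45% in arm B);
responders split CR/PR, nonresponders SD/PD. The 9-week percent tumor-size
change couples a response-class intercept to the true log fold-change
(slope 10%/unit, residual sd 12) and is negative for responders by
construction. OS and progression are exponential proportional-hazards with
log-hazard

```
log h = log h0 + β_base·(z_b − c_b) + β_ratio·(z_r − c_r) + β_arm·1[B]
        + β_ecog·ECOG + β_subgroup[g] + β_tc·Δtumor
```

where `z_b` is the realized log baseline tumor-informed maxVAF (floored at
3 log-sd below the population location for ctDNA-negative patients), `z_r`
the patient's true log fold-change, and `c_b`, `c_r` config-implied
centering constants. PFS is the minimum of progression and death; censoring
is independent exponential (default 0.02/month; 0 disables censoring, which
the closed-form test oracles use). Defaults: β_base = 0.3, β_ratio = 0.5,
β_ecog = 0.3, a −0.4 subgroup effect for TMB-high/PD-L1-high, β_tc = 0, and
β_arm = 1.30 — the latter offsets the survival advantage arm B would
otherwise inherit from its deeper fold-change distribution through β_ratio,
so the default trial is overall-negative (between-arm OS HR ≈ 1, median OS
≈ 8 months, median PFS ≈ 2 months).

`CohortConfig.null()` switches every association off — all outcome
coefficients zero, all latent correlations zero, identical dynamics in both
arms and classes — and is the reference condition for type-I-error
calibration, since the latent couplings are association parameters too.

## Validation experiments and their design

- **Calibration**: under the null config, each one-sided test's rejection
  rate at α = 0.05 is checked against 3 binomial SEs over 500 simulated
  trials of 150 patients per arm.
- **Parameter recovery**: the full pipeline (simulate → metrics → Cox on the
  log-shifted C2/C1 ratio) is required to recover β_ratio = 0.5 within 3
  Monte-Carlo SEs over 100 trials of 1000 per arm. The recovery config uses
  a shared patient-level fold change without variant-level scatter, so the
  measured ratio estimates the generative covariate directly and read-depth
  sampling is the only measurement error; at 10,000× depth the residual
  attenuation is an order of magnitude below the test's resolution.
  (With variant-level scatter the fitted covariate is an error-in-variables
  proxy and classical attenuation of a few percent is expected — that is a
  property of the design, not an estimator defect.)
- **Power**: the simulated power of the one-sided baseline OS test at an
  effect size solving the Schoenfeld formula for 80% must agree within 3
  Monte-Carlo SEs over 500 replicates. This experiment uses a high-capture
  panel (capture 0.3, ≈99% baseline positivity) because the analytic
  formula presumes the fitted covariate is the generative one; at default
  capture, the ~8% floor-group mismatch costs a few points of power.
- **Joint models**: a designed-confounding config (survival driven only by
  tumor-size change, the ratio being its correlate) must leave the metric
  term non-significant and the radiographic term significant in most
  trials; a direct-effect config must keep the metric term significant.

Problem sizes for these experiments (replicate counts, patients per arm)
were fixed as the package's own trade-off between Monte-Carlo resolution
and desk-scale runtime.

## What passing tests do and do not show

The generator produces binomial read noise on lognormal VAFs, exponential
event times and exact proportional hazards. It does not model clonal
hematopoiesis, copy-number change, indel realism, sequencing error beyond
binomial sampling, non-proportional hazards, informative censoring, or
assay limits of detection (VAFs pass through as given; the panel's nominal
LoD is an assay property, not computed here). Passing tests therefore show
that the estimators and decision procedures are correct under their stated
assumptions and that the pipeline is deterministic and internally
consistent — not that real trial results would be reproduced. The
vendor-proprietary change score is treated as an opaque input column and is
never computed.

## Numerical choices

- Efron tie handling in all Cox fits; convergence tightened to 1e-9 so
  coefficients match brute-force partial-likelihood maximization to 1e-4.
- δ for `log_shifted` is half the smallest positive value of the analysis
  subset; recorded per result.
- Hochberg adjusted p values are running minima of `(m−j+1)·p_(j)` from the
  largest p downward, clipped to 1; rejection ⇔ adjusted p ≤ α.
- Largest-remainder apportionment breaks remainder ties by stratum order;
  with pool-derived proportions a stratum can never be exhausted, so the
  reallocation path only engages when reference-population proportions are
  supplied.
- All randomness flows from explicit seeds through `numpy.random.Generator`;
  identical configs produce byte-identical cohorts and identical output
  digests (recorded in the run manifest).
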
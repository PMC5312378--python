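# Methods

## Analysis model

The pipeline estimates, miRNA by miRNA, the association between paired
tumor–normal differential expression and cause-specific (CRC) survival.

**Survival model.** Cox proportional hazards fit by maximizing the Efron
partial likelihood with Newton–Raphson and step halving. Convergence is
declared when the maximum absolute score falls below 1e-8 or the relative
log-likelihood change falls below 1e-10; coefficients are capped at ±30 and
a fit whose trajectory hits the cap is flagged (`CoxFit.capped`) rather
than rejected — monotone likelihood (perfect separation) in a small
stratum, e.g. no events among MSI-positive subjects, is a property of the
data, not an error. Structural problems (constant or collinear covariates)
are detected by eigenvalue conditioning of the information matrix at β=0
and raise a rank error. Breslow tie handling is available as an option;
with untied times the two likelihoods coincide exactly, which the tests
verify. Adjustment covariates are age at diagnosis (linear, in years,
centered at the sample mean for conditioning — Cox estimates are invariant
to the shift), male sex, AJCC stage contrasts (2, 3, 4 vs 1), and MSI
status. Stage-subset analyses (stages 1–2 or 3–4) adjust for age, sex and
MSI only.

**Permutation inference for common miRNAs.** The reported p-value is a
permutation test of the 1-df likelihood-ratio statistic: the focal
exposure vector is permuted across subjects — times, events and adjustment
covariates stay glued together — and the full model is refit for each of B
permutations. The add-one estimator `p = (1+k)/(1+B)` keeps p in (0,1].
Permuting the exposure (rather than outcomes or residuals) preserves the
covariate–outcome association and targets exactly the miRNA's conditional
effect; it is the one of the three standard choices that leaves the
adjustment model intact. B defaults to 10,000; tests and the acceptance
script use B in the hundreds-to-1,000 range with fixed seeds. Exhaustive
enumeration over all n! permutations is available for tiny n and anchors
the Monte-Carlo estimator in the tests.

**Effect reporting.** Common miRNAs: hazard ratio per interquartile range
of differential expression, `exp(β·(Q3−Q1))`, with 95% Wald interval
`exp((β±1.96·se)·(Q3−Q1))`. Rare miRNAs (expressed in <50% of subjects
but ≥5 subjects): any-vs-no expression indicator, `HR = exp(β)`, Wald
p-value, no permutation and no quartiles. Fewer than 5 expressors:
excluded, with the reason recorded. Quantiles use the linear-interpolation
(type 7) convention throughout; the 75th-percentile-equality invariant of
the normalization holds under any single consistent convention.

**Multiple testing.** Benjamini–Hochberg step-up q-values
(`q_(i) = min_{j≥i} m·p_(j)/j`, clipped to 1), computed within pooling
groups: discovery and replication miRNAs pooled inside each
expression-level class (common vs rare), separately per analysis stratum.
A `pooled_components=False` mode adjusts the replication list on its own
smaller m, since result tables computed that way are also seen in
practice. Thresholds: q<0.05 primary, q<0.10 secondary flag.

**Site/stage comparisons.** Kaplan–Meier product-limit curves and the
Mantel–Haenszel/log-rank test (multivariate hypergeometric moments at each
distinct event time) compare colon vs rectal survival within each AJCC
stage. Curves are truncated at 60 months for display; the test is reported
both on full follow-up and with follow-up administratively cut at 60
months, since a five-year display horizon need not imply a restricted
test. An exposure-by-ordinal-site interaction LRT (1 df, continuous
within-colon site coding, cecum→sigmoid) probes whether miRNA effects
trend along the colon.

## Normalization and imputation

Scaling factors are computed per tissue separately (carcinoma and normal
matrices never share factors), as pooling would let tumor signal leak into
normal-tissue scaling. The 75th percentile is taken over all of a
sample's probe values including zeros; a sample whose P75 is zero cannot
be scaled and is reported by name. Undetected cells are exact 0 in raw,
normalized, and log2 space, so presence/absence survives every transform
and differential expression of doubly-undetected cells is 0 ("neither"
provenance).

Missing normal-mucosa rows are imputed with the per-miRNA median of
observed normals within the same site stratum (colon = proximal+distal;
rectal), and flagged per cell. This site-stratified median rule is a
declared, deliberately simple stand-in for published reference-based
imputation procedures; it is isolated behind one function
(`impute_missing_normals`) so an alternative can be swapped in without
touching anything else. Its error is bounded in tests by the observed-cell
residual scale.

## The synthetic cohort generator

The generator produces the data structure the analysis assumes, with
marginals resembling a large two-center population-based CRC study.

| parameter | default | rationale |
|---|---|---|
| age | N(64.2, 10.2²) years, clipped to [18, 100] | typical CRC cohort age structure |
| sex | 54% male | slight male excess |
| site | 30% proximal / 31% distal / 39% rectal | colon ≈ 61%, evenly split proximal/distal |
| stage | 30 / 26 / 29 / 15 % | AJCC 1–4 mix of a registry cohort |
| MSI | 15% unstable | typical population-based CRC rate |
| prevalence mixture | 20% of miRNAs ~U(0.9,1), 80% ~U(0.02,0.8) | ≈51% of miRNAs detected in ≥50% of subjects, the common/rare split seen on genome-wide arrays in colorectal tissue (roughly half of ~2,000 probes) |
| detected log2 signal | subject base N(8, 2²) + tissue noise N(0, 1²) | paired design: tumor and normal share the subject baseline |
| missing normal rows | 15% | unpaired carcinoma scans are common in archival tissue studies |
| Weibull baseline | shape 1.2, scale 400 months | CRC-specific 5-yr death ≈10% at stage 1, ≈19% at stage 2 |
| stage log-HRs | 0.7 / 1.5 / 2.8 (vs stage 1) | strong stage gradient; stage-4 5-yr CRC death ≈80% |
| age, sex, MSI log-HRs | 0.03/yr, 0.10, −0.30 | modest covariate prognosis; MSI protective |
| other-cause death | exponential, 0.002/month | ≈11% non-CRC deaths by 60 months |
| administrative censoring | 60 months | five-year follow-up framing |

Together these give ≈42% of subjects dead at five years (≈31% CRC-specific),
matching the mortality pattern of registry CRC cohorts with ~60-month mean
follow-up. CRC death times follow Weibull proportional hazards
(`T = scale·(−log U / e^η)^{1/shape}`; shape 1 recovers the exponential,
which a test exploits via its closed-form mean); other-cause death is an
independent exponential, so treating it as censoring is non-informative by
construction. The cause flag is set only for CRC deaths; observed time is
the minimum of the two death times and the administrative cutoff.

Planted miRNA effects enter the linear predictor as per-unit log hazard
ratios on a supplied differential-expression matrix. In the end-to-end
validation the hazard is planted on the analysis exposure itself — the
normalized, imputed, log2 differential expression the Cox models will see —
scaled per miRNA so the per-IQR log HR is exactly ±ln(1.5). Planting on
the generator's internal truth instead would test measurement-error
attenuation (the estimated exposure correlates ≈0.85 with the truth once
scaling noise and imputation enter), not the pipeline.

What the generator does **not** emulate: probe-level array structure and
QC failures, batch effects, correlated miRNA co-expression modules,
informative censoring, and non-proportional hazards. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the assumed data-generating process; they do not certify robustness
to those real-data features.

## Problem sizes used in validation

Simulation-based checks run at deliberately chosen sizes: the permutation
type-I-error study uses 1,000 cohorts of n=200 with B=200; CI coverage uses
500 replicates of n=700; the end-to-end discovery study uses n=700 with 205
miRNAs (5 planted), B=1,000, across 20 seeds in the test suite and 5 seeds
in the acceptance script. These sizes give Monte-Carlo margins small
enough to make each property informative while keeping a full validation
run in the minutes range on a single CPU.

## Known limitations and numerical notes

- With B=1,000 permutations the smallest achievable p-value is
  1/1001 ≈ 1e-3; after BH correction over ~100+ pooled common miRNAs, the
  rank-1 and rank-2 step-up thresholds fall below that floor, so isolated
  signals cannot reach q<0.05 at that B no matter how strong. At the
  default B=10,000 the floor (1e-4) is below every BH threshold for
  m ≲ 500. When scanning many miRNAs with FDR control, choose B so that
  `1/(B+1) < q_threshold / m`.
- Marginal one-miRNA-at-a-time hazard ratios are attenuated relative to
  conditional effects when several true effects coexist (hazard
  non-collapsibility): with five simultaneous per-IQR log HRs of ln(1.5),
  the marginal estimand is ≈0.375 rather than 0.405 at ~30% events. This
  is a property of marginal Cox modeling, not an estimation error; the
  package reports marginal effects, as such analyses conventionally do.
- Under a continuous global null the BH procedure's false-discovery rate is
  exactly the nominal level (Simes equality), so empirical mean FDP in a
  simulation hovers around — not safely below — 0.05; calibration checks
  must carry a Monte-Carlo margin.
- The permutation kernel is numba-compiled with `fastmath`; results are
  deterministic for a fixed seed on a given machine (byte-identical outputs
  across reruns, which a test asserts) but may differ in the last floating
  digits across CPU generations due to SIMD reduction order.
- Imputed normal values remove subject-level pairing for affected cells;
  their differential expression is centered correctly but carries extra
  variance. Provenance flags (`normal-imputed`) let downstream users
  filter or weight them.
- Times are continuous in the generator (no tie handling is exercised by
  default); real registry data with month-resolution times will engage the
  Efron correction, which is tested separately against an independent
  implementation on deliberately coarsened times.
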
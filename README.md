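# mirsurv

Site- and stage-specific survival analysis of paired tumor–normal miRNA
differential expression in colorectal cancer.

## The problem

Population-based colorectal-cancer (CRC) cohorts with paired carcinoma and
normal-mucosa miRNA arrays ask a deceptively simple question: does the
amount by which a miRNA is up- or down-regulated in a subject's tumor,
relative to their own normal mucosa, predict that subject's CRC-specific
survival — and does the answer differ between colon and rectal tumors, or
between early and late AJCC stage? Answering it properly requires a chain
of specialized machinery: per-sample array normalization, imputation of
subjects without a normal-tissue scan, presence/absence handling for
sparsely expressed miRNAs, adjusted Cox proportional-hazards models with
permutation-based inference, and false-discovery-rate control over hundreds
of miRNAs within the right pooling groups. `mirsurv` implements that chain
as a tested, reusable pipeline, together with a seeded synthetic-cohort
generator so every stage is verifiable without access to restricted
subject-level data.

## The model

For each miRNA the focal exposure is per-subject differential expression

```
d_ij = log2(tumor signal)_ij − log2(normal signal)_ij
```

with undetected (zero) signal entering as exact 0 on both scales. Raw
signal is first normalized per sample by the factor
`median_s(P75_s) / P75_s`, where `P75_s` is the sample's 75th percentile of
total gene signal, so that every sample's 75th percentile equals the shared
median. Subjects without a normal scan receive per-miRNA medians of
observed normals within their site stratum (colon vs rectum).

CRC-specific mortality is modeled by the Cox proportional-hazards partial
likelihood (Efron tie handling, Newton–Raphson with step halving), adjusted
for age at diagnosis, sex, AJCC stage contrasts, and MSI status. For
miRNAs expressed in ≥50% of subjects ("common"), the p-value is a
permutation test of the 1-df likelihood-ratio statistic — the focal
exposure vector is permuted across subjects B times (default 10,000) and

```
p = (1 + #{ LRT_perm ≥ LRT_obs }) / (1 + B)
```

— and the hazard ratio is reported per interquartile range,
`HR = exp(β·(Q3−Q1))`. miRNAs expressed in fewer than 50% of subjects but
in at least 5 ("rare") are analyzed as any-vs-no expression with ordinary
Wald inference. Benjamini–Hochberg q-values are assigned within each
expression-level class, pooling discovery and replication miRNAs, per
analysis stratum. Kaplan–Meier curves and Mantel–Haenszel/log-rank tests
compare colon vs rectal survival within each AJCC stage.

## Worked example

```bash
mirsurv simulate --outdir data --n-subjects 400 --n-mirnas 120 --seed 42
mirsurv run --config analysis.yaml          # or use the library directly:
```

```python
from mirsurv import simulate, io, pipeline

cs = simulate.CohortSpec(n_subjects=400, seed=42)
es = simulate.ExpressionSpec(n_mirnas=120, seed=43)
ss = simulate.SurvivalSpec(seed=44)          # no planted miRNA effects
clinical, carcinoma, normal, _ = simulate.simulate_study(cs, es, ss)
paths = io.write_dataset("data", clinical, carcinoma, normal,
                         {"cohort": cs, "expression": es, "survival": ss})
cfg = pipeline.AnalysisConfig(
    clinical=str(paths["clinical"]), carcinoma=str(paths["carcinoma"]),
    normal=str(paths["normal"]), outdir="out",
    strata=("colon", "rectal"), n_permutations=1000, seed=7)
out = pipeline.run_full_analysis(cfg)
```

This prints result tables shaped like a per-stratum miRNA–survival report.
The five smallest rectal-stratum p-values from the run above:

```
mirna_id analysis_class  pct_expressing     q1    q3    hr  ci_low  ci_high     p     q
miR-0012           rare          44.805    NaN   NaN 2.584   1.367    4.883 0.003 0.222
miR-0087         common          57.143 -3.328 4.463 0.563   0.354    0.896 0.023 0.812
miR-0022           rare          40.260    NaN   NaN 0.462   0.225    0.951 0.036 0.462
miR-0066           rare          32.468    NaN   NaN 0.437   0.199    0.964 0.040 0.462
miR-0033         common          78.571 -1.553 2.167 1.309   1.025    1.673 0.044 0.812
```

`pct_expressing` is the percent of analyzed subjects with detected
carcinoma signal; `q1`/`q3` are differential-expression quartiles (common
miRNAs only — rare rows carry none, their HR is any-vs-no expression); `p`
is the permutation-LRT p-value for common miRNAs and the Wald p for rare
ones; `q` is the pooled BH q-value. Since this cohort was generated with
no planted miRNA effects, no q-value clears 0.05 — exactly what a
well-calibrated analysis should report. The stage-wise site comparison
from the same run (`out/logrank_site_by_stage.tsv`):

```
stage 1: n=123, log-rank chi2=0.92, p=0.337
stage 2: n=99,  log-rank chi2=0.56, p=0.456
stage 3: n=119, log-rank chi2=0.19, p=0.659
stage 4: n=59,  log-rank chi2=0.06, p=0.811
```

## Layout

| module | role |
|---|---|
| `mirsurv.simulate` | seeded synthetic cohorts: covariates, paired expression, cause-specific survival |
| `mirsurv.normalize` | 75th-percentile scaling, log2 transform, normal-mucosa imputation |
| `mirsurv.differential` | paired differential expression, prevalence, common/rare/excluded classes |
| `mirsurv.survival` | Cox partial likelihood, permutation LRT, IQR hazard ratios, KM, log-rank |
| `mirsurv.fdr` | BH q-values with expression-class pooling |
| `mirsurv.pipeline` | end-to-end orchestration, strata, outputs, run log |
| `mirsurv.cli` | `mirsurv simulate / run / km` |

See `docs/methods.md` for model assumptions, parameter defaults and their
rationale, numerical choices, and known limitations.
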
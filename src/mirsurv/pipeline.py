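"""End-to-end analysis: config -> normalized data -> per-stratum survival models -> FDR.

The full run mirrors a site- and stage-specific miRNA prognosis study:

1. read the clinical table and the paired raw expression matrices and check
   subject alignment;
2. restrict to the analysis population (subjects with survival and stage
   information);
3. normalize carcinoma and normal matrices independently (75th-percentile
   scaling), impute missing normal-mucosa rows by site-stratum medians,
   log2-transform, and form per-subject differential expression;
4. within each requested stratum (site and/or stage subset), classify
   miRNAs by carcinoma expression prevalence; fit adjusted Cox models —
   permutation likelihood-ratio p-values and interquartile-range hazard
   ratios for commonly expressed miRNAs, any-vs-no-expression Wald models
   for rare ones;
5. assign Benjamini-Hochberg q-values within expression-class pooling
   groups (discovery and replication components pooled by default);
6. export Kaplan-Meier step tables and log-rank comparisons of colon vs
   rectal survival within each AJCC stage.

Every random draw is seeded from the config seed; rerunning a config gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, differential, fdr, io, normalize, survival
from .errors import AlignmentError, ConfigError, InferenceError

VALID_STRATA_ATOMS = {
    "overall",
    "colon",
    "rectal",
    "proximal",
    "distal",
    "stage-1-2",
    "stage-3-4",
}

RESULT_COLUMNS = [
    "mirna_id",
    "stratum",
    "component",
    "analysis_class",
    "pct_expressing",
    "n_expressors",
    "q1",
    "q3",
    "hr",
    "ci_low",
    "ci_high",
    "p",
    "q",
]


@dataclass
class AnalysisConfig:
    clinical: str
    carcinoma: str
    normal: str
    outdir: str
    literature_mirnas: str | None = None  # replication-component membership list
    strata: tuple = ("colon", "rectal")
    n_permutations: int = 10_000
    seed: int = 0
    ties: str = "efron"
    q_threshold: float = 0.05
    q_threshold_secondary: float = 0.10
    pooled_components: bool = True
    km_horizon_months: float = 60.0

    def __post_init__(self):
        for s in self.strata:
            for atom in str(s).split(":"):
                if atom not in VALID_STRATA_ATOMS:
                    raise ConfigError(
                        f"unknown stratum {s!r}; atoms must be from {sorted(VALID_STRATA_ATOMS)}"
                    )
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.ties not in ("efron", "breslow"):
            raise ConfigError("ties must be 'efron' or 'breslow'")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("strata"), list):
            raw["strata"] = tuple(raw["strata"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _mirna_seed(base_seed: int, stratum: str, mirna: str) -> int:
    """Stable per-(stratum, miRNA) permutation seed below 2**31."""
    h = zlib.crc32(f"{stratum}|{mirna}".encode())
    return (int(base_seed) * 1_000_003 + h) % (2**31 - 1)


def _stratum_mask(clinical: pd.DataFrame, stratum: str) -> pd.Series:
    mask = pd.Series(True, index=clinical.index)
    for atom in str(stratum).split(":"):
        if atom == "overall":
            continue
        elif atom == "colon":
            mask &= clinical["site"].isin(["proximal", "distal"])
        elif atom in ("proximal", "distal", "rectal"):
            mask &= clinical["site"] == atom
        elif atom == "stage-1-2":
            mask &= clinical["stage"].isin([1, 2])
        elif atom == "stage-3-4":
            mask &= clinical["stage"].isin([3, 4])
    return mask


def build_covariates(clinical: pd.DataFrame, include_stage: bool = True) -> pd.DataFrame:
    """Adjustment covariates: age (centered), male sex, stage contrasts, MSI.

    Stage contrasts are omitted in stage-subset analyses (``include_stage``
    False), where models adjust for age, sex and MSI only.  Columns that are
    constant in the subset are dropped (no information; would make the
    design singular).
    """
    cols = {
        "age": clinical["age"].astype(float) - float(clinical["age"].mean()),
        "sex_male": (clinical["sex"] == "M").astype(float),
    }
    if include_stage:
        for s in (2, 3, 4):
            cols[f"stage{s}"] = (clinical["stage"] == s).astype(float)
    cols["msi"] = clinical["msi"].astype(float)
    X = pd.DataFrame(cols, index=clinical.index)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


def _check_alignment(clinical, carcinoma, normal):
    cl = set(clinical.index)
    offenders = []
    for name, mat in (("carcinoma", carcinoma), ("normal", normal)):
        ids = set(mat.values.index)
        extra = sorted(ids - cl)[:10]
        miss = sorted(cl - ids)[:10]
        if extra or miss:
            offenders.append(f"{name}: extra={extra} missing={miss}")
    if offenders:
        raise AlignmentError(
            "subject ids differ between clinical and expression files; " + "; ".join(offenders)
        )


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------


def prepare_expression(clinical, carcinoma, normal):
    """Normalize both tissues, impute missing normals, log2, differential.

    Returns (diff_matrix, tumor_log2, normal_log2, factors dict).
    """
    carcinoma = normalize.ExpressionMatrix(
        values=carcinoma.values.loc[clinical.index],
        tissue="carcinoma",
        state=carcinoma.state,
    )
    normal_m = normalize.ExpressionMatrix(
        values=normal.values.loc[clinical.index], tissue="normal", state=normal.state
    )
    fac_t = normalize.compute_scaling_factors(carcinoma)
    fac_n = normalize.compute_scaling_factors(normal_m)
    tumor_norm = normalize.apply_normalization(carcinoma, fac_t)
    normal_norm = normalize.apply_normalization(normal_m, fac_n)
    normal_imp = normalize.impute_missing_normals(normal_norm, clinical["site"])
    tumor_log2 = normalize.log2_transform(tumor_norm)
    normal_log2 = normalize.log2_transform(normal_imp)
    diff = differential.compute_differential(tumor_log2, normal_log2)
    return diff, tumor_log2, normal_log2, {"carcinoma": fac_t, "normal": fac_n}


def analyze_stratum(
    clinical: pd.DataFrame,
    tumor_log2: normalize.ExpressionMatrix,
    diff: differential.DifferentialMatrix,
    stratum: str,
    replication_set: frozenset = frozenset(),
    B: int = 10_000,
    seed: int = 0,
    ties: str = "efron",
    warnings: list | None = None,
):
    """Per-miRNA survival results for one stratum.

    Returns (results DataFrame with q assigned, excluded DataFrame).
    """
    warnings = warnings if warnings is not None else []
    mask = _stratum_mask(clinical, stratum)
    sub = clinical[mask]
    if len(sub) == 0 or int(sub["cause_crc"].sum()) == 0:
        warnings.append(f"stratum {stratum}: no subjects or no events; skipped")
        return (
            pd.DataFrame(columns=RESULT_COLUMNS),
            pd.DataFrame(columns=["mirna_id", "stratum", "reason"]),
        )
    include_stage = "stage" not in stratum
    X = build_covariates(sub, include_stage=include_stage)
    time = sub["survival_months"].to_numpy(dtype=float)
    event = sub["cause_crc"].to_numpy(dtype=int)

    detected = tumor_log2.values.loc[sub.index] > 0
    prevalence = 100.0 * detected.sum(axis=0) / len(sub)
    n_expr = detected.sum(axis=0)
    classes = differential.classify_mirnas(prevalence, n_expr)
    quart = differential.differential_quartiles(diff, subjects=sub.index)

    rows = []
    excluded = []
    Xv = X.to_numpy(dtype=float)
    for mirna, row in classes.iterrows():
        component = "replication" if mirna in replication_set else "discovery"
        cls = row["analysis_class"]
        if cls == differential.EXCLUDED:
            excluded.append((mirna, stratum, f"<5 expressors ({int(row['n_expressors'])})"))
            continue
        try:
            if cls == differential.COMMON:
                focal = diff.values.loc[sub.index, mirna].to_numpy(dtype=float)
                perm = survival.permutation_pvalue(
                    time,
                    event,
                    Xv,
                    focal,
                    B=B,
                    seed=_mirna_seed(seed, stratum, mirna),
                    ties=ties,
                )
                fit = survival.cox_fit(
                    time, event, np.column_stack([Xv, focal]), ties=ties
                )
                if abs(fit.beta[-1]) >= 30.0 - 1e-9:
                    raise InferenceError("focal coefficient diverged (monotone likelihood)")
                q1, q3 = float(quart.loc[mirna, "q1"]), float(quart.loc[mirna, "q3"])
                hr, lo, hi = survival.iqr_hazard_ratio(fit, q1, q3)
                if not (np.isfinite(hi) and hr > 0):
                    raise InferenceError("IQR hazard ratio numerically unbounded")
                rows.append(
                    (mirna, stratum, component, cls, float(row["pct_expressing"]),
                     int(row["n_expressors"]), q1, q3, hr, lo, hi, perm.p)
                )
            else:  # rare: any-vs-no expression, Wald p
                any_expr = detected[mirna].to_numpy(dtype=float)
                res = survival.rare_mirna_fit(time, event, Xv, any_expr, ties=ties)
                rows.append(
                    (mirna, stratum, component, cls, float(row["pct_expressing"]),
                     int(row["n_expressors"]), np.nan, np.nan,
                     res["hr"], res["ci_low"], res["ci_high"], res["p"])
                )
        except InferenceError as exc:
            excluded.append((mirna, stratum, f"inference failed: {exc}"))
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if len(results):
        results = fdr.pool_and_assign(results)
    else:
        results["q"] = pd.Series(dtype=float)
    excluded_df = pd.DataFrame(excluded, columns=["mirna_id", "stratum", "reason"])
    return results, excluded_df


def compare_site_survival_by_stage(
    clinical: pd.DataFrame, horizon: float = 60.0, warnings: list | None = None
) -> dict:
    """Colon vs rectal Kaplan-Meier and log-rank within each AJCC stage.

    Curves are truncated at ``horizon`` months for display; the log-rank
    test is reported both on full follow-up (``p``) and on follow-up
    administratively cut at the horizon (``p_horizon``).
    """
    warnings = warnings if warnings is not None else []
    out = {}
    site_group = np.where(clinical["site"] == "rectal", "rectal", "colon")
    for stage in (1, 2, 3, 4):
        sub = clinical[clinical["stage"] == stage]
        groups = site_group[(clinical["stage"] == stage).to_numpy()]
        if len(sub) == 0 or len(np.unique(groups)) < 2:
            warnings.append(f"stage {stage}: fewer than two sites represented; skipped")
            continue
        time = sub["survival_months"].to_numpy(dtype=float)
        event = sub["cause_crc"].to_numpy(dtype=int)
        chi2, df, p = survival.logrank_test(time, event, groups)
        t_cut = np.minimum(time, horizon)
        e_cut = np.where(time <= horizon, event, 0)
        chi2_h, _, p_h = survival.logrank_test(t_cut, e_cut, groups)
        curves = {}
        for g in ("colon", "rectal"):
            gi = groups == g
            curves[g] = survival.km_estimate(time[gi], event[gi]).truncated(horizon)
        out[stage] = {
            "chi2": chi2,
            "df": df,
            "p": p,
            "chi2_horizon": chi2_h,
            "p_horizon": p_h,
            "km": curves,
            "n": len(sub),
        }
    return out


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Execute the full pipeline and write all outputs under ``config.outdir``."""
    clinical = io.read_clinical(config.clinical)
    carcinoma = io.read_expression(config.carcinoma, tissue="carcinoma")
    normal = io.read_expression(config.normal, tissue="normal")
    _check_alignment(clinical, carcinoma, normal)
    replication_set = frozenset(
        io.read_mirna_list(config.literature_mirnas) if config.literature_mirnas else []
    )

    warnings: list = []
    # analysis population: survival and stage information present
    eligible = clinical["survival_months"].notna() & clinical["stage"].notna()
    n_dropped = int((~eligible).sum())
    if n_dropped:
        warnings.append(f"dropped {n_dropped} subjects lacking survival or stage data")
    clin = clinical[eligible]

    diff, tumor_log2, normal_log2, factors = prepare_expression(clin, carcinoma, normal)

    all_results = []
    all_excluded = []
    for stratum in config.strata:
        res, exc = analyze_stratum(
            clin,
            tumor_log2,
            diff,
            stratum,
            replication_set=replication_set,
            B=config.n_permutations,
            seed=config.seed,
            ties=config.ties,
            warnings=warnings,
        )
        all_results.append(res)
        all_excluded.append(exc)
    all_results = [r for r in all_results if len(r)] or all_results[:1]
    all_excluded = [e for e in all_excluded if len(e)] or all_excluded[:1]
    results = pd.concat(all_results, ignore_index=True) if all_results else pd.DataFrame()
    excluded = pd.concat(all_excluded, ignore_index=True) if all_excluded else pd.DataFrame()
    if len(results):
        results["significant"] = results["q"] < config.q_threshold
        results["significant_secondary"] = results["q"] < config.q_threshold_secondary
    km = compare_site_survival_by_stage(clin, horizon=config.km_horizon_months, warnings=warnings)

    _write_outputs(config, clin, results, excluded, km, factors, warnings)
    return {"results": results, "excluded": excluded, "km": km, "warnings": warnings}


def _write_outputs(config, clinical, results, excluded, km, factors, warnings):
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.8g"
    results.sort_values(["stratum", "analysis_class", "mirna_id"]).to_csv(
        outdir / "results.tsv", sep="\t", index=False, float_format=fmt
    )
    excluded.sort_values(["stratum", "mirna_id"]).to_csv(
        outdir / "excluded.tsv", sep="\t", index=False
    )
    for tissue, fac in factors.items():
        fac.rename("scaling_factor").to_csv(
            outdir / f"scaling_factors_{tissue}.tsv", sep="\t", float_format=fmt
        )
    km_rows = []
    for stage, entry in km.items():
        for site, est in entry["km"].items():
            for t, r, d, s in zip(est.times, est.at_risk, est.n_events, est.survival):
                km_rows.append((stage, site, t, r, d, s))
    pd.DataFrame(
        km_rows, columns=["stage", "site", "time", "at_risk", "events", "survival"]
    ).to_csv(outdir / "km_site_by_stage.tsv", sep="\t", index=False, float_format=fmt)
    pd.DataFrame(
        [
            (stage, e["n"], e["chi2"], e["df"], e["p"], e["chi2_horizon"], e["p_horizon"])
            for stage, e in km.items()
        ],
        columns=["stage", "n", "chi2", "df", "p", "chi2_60m", "p_60m"],
    ).to_csv(outdir / "logrank_site_by_stage.tsv", sep="\t", index=False, float_format=fmt)

    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"mirsurv {__version__}\n")
        fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"permutations per miRNA (B): {config.n_permutations}\n")
        fh.write(f"ties method: {config.ties}\n")
        fh.write("permutation target: focal exposure vector (times, events, covariates fixed)\n")
        fh.write(f"q thresholds: {config.q_threshold} (primary), "
                 f"{config.q_threshold_secondary} (secondary)\n")
        fh.write(f"strata: {', '.join(config.strata)}\n")
        fh.write(f"analysis population: {len(clinical)} subjects, "
                 f"{int(clinical['cause_crc'].sum())} CRC deaths\n")
        for w in warnings:
            fh.write(f"warning: {w}\n")
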
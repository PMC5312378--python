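"""Per-sample scaling normalization, log2 transform and normal-mucosa imputation.

Raw array signal is made comparable across samples by multiplying each
sample by ``median_over_samples(P75) / P75_sample``, where P75 is the
sample's 75th percentile of total gene signal over all miRNAs (zeros
included).  After scaling, every sample's 75th percentile equals the shared
median by construction.  Analyses downstream run on log2-transformed
signal; undetected miRNAs are encoded as exact 0 at every stage, both in
raw and in log2 space, so presence/absence is preserved through the
transform.

Subjects with no normal-mucosa scan (an all-missing row in the normal
matrix) are imputed per miRNA with the median of observed normal values
within the same site stratum (colon vs rectal).  The imputation rule is
deliberately isolated in one function so an alternative can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DataError,
    DegenerateSampleError,
    ImputationError,
    StateError,
)

RAW = "raw"
NORMALIZED = "normalized"
NORMALIZED_LOG2 = "normalized-log2"

_STATE_ORDER = {RAW: 0, NORMALIZED: 1, NORMALIZED_LOG2: 2}


@dataclass
class ExpressionMatrix:
    """Subjects x miRNAs expression values for one tissue.

    ``values`` rows are subjects, columns miRNAs.  Missing samples (e.g.
    subjects without a normal-mucosa scan) are all-NaN rows.  ``imputed``
    marks cells filled by :func:`impute_missing_normals`.
    """

    values: pd.DataFrame
    tissue: str  # "carcinoma" | "normal"
    state: str = RAW
    imputed: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.tissue not in ("carcinoma", "normal"):
            raise DataError(f"unknown tissue {self.tissue!r}")
        if self.state not in _STATE_ORDER:
            raise StateError(f"unknown state {self.state!r}")
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if self.imputed.shape != self.values.shape:
            raise AlignmentError("imputed mask shape differs from values")
        if self.state == RAW:
            v = self.values.to_numpy()
            if np.nanmin(v, initial=0.0) < 0:
                raise DataError("raw expression values must be non-negative")

    @property
    def subject_ids(self):
        return list(self.values.index)

    @property
    def mirna_ids(self):
        return list(self.values.columns)

    @property
    def missing_rows(self) -> pd.Index:
        return self.values.index[self.values.isna().all(axis=1)]

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected (strictly positive) cells."""
        return self.values > 0


def _check_state(matrix: ExpressionMatrix, expected: str, op: str):
    if matrix.state != expected:
        raise StateError(f"{op} requires a {expected!r} matrix, got {matrix.state!r}")


def compute_scaling_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Per-sample scaling factors: median of all samples' P75 over each sample's P75.

    The 75th percentile is the linear-interpolation quantile over all of a
    sample's signal values, zeros included.  All-missing rows get a NaN
    factor (they carry no signal to scale).
    """
    _check_state(matrix, RAW, "compute_scaling_factors")
    observed = matrix.values.dropna(how="all")
    if observed.empty:
        raise DataError("no observed samples to normalize")
    p75 = observed.quantile(0.75, axis=1)
    bad = p75[p75 <= 0]
    if len(bad):
        raise DegenerateSampleError(
            "sample(s) with non-positive 75th percentile: "
            + ", ".join(map(str, bad.index[:5]))
        )
    factors = p75.median() / p75
    return factors.reindex(matrix.values.index)


def apply_normalization(matrix: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """Multiply each sample by its scaling factor.  Zeros stay zero."""
    _check_state(matrix, RAW, "apply_normalization")
    factors = pd.Series(factors)
    if not factors.index.equals(matrix.values.index):
        if set(factors.index) != set(matrix.values.index):
            raise AlignmentError("scaling factors do not cover the matrix subjects")
        factors = factors.reindex(matrix.values.index)
    observed = ~matrix.values.isna().all(axis=1)
    if (factors[observed] <= 0).any() or factors[observed].isna().any():
        raise DataError("scaling factors must be strictly positive for observed samples")
    values = matrix.values.mul(factors, axis=0)
    return replace(matrix, values=values, state=NORMALIZED, imputed=matrix.imputed.copy())


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2 of detected cells; undetected (0) cells stay 0 and stay undetected."""
    _check_state(matrix, NORMALIZED, "log2_transform")
    v = matrix.values.to_numpy(dtype=float)
    if np.nanmin(v, initial=0.0) < 0:
        raise StateError("negative values in a normalized matrix")
    out = np.where(v > 0, np.log2(np.where(v > 0, v, 1.0)), v)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=values, state=NORMALIZED_LOG2, imputed=matrix.imputed.copy())


def normalize_log2(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.Series]:
    """Convenience: scaling factors -> apply -> log2.  Returns (matrix, factors)."""
    factors = compute_scaling_factors(matrix)
    return log2_transform(apply_normalization(matrix, factors)), factors


def impute_missing_normals(
    normal: ExpressionMatrix, site_labels: pd.Series, min_observed: int = 2
) -> ExpressionMatrix:
    """Fill all-missing normal rows with site-stratum per-miRNA medians.

    ``site_labels`` maps subject id to a stratum label; tumor-site labels
    containing "colon"/"proximal"/"distal" collapse to the colon stratum and
    "rectal" to the rectal stratum, so imputation never borrows across the
    colon/rectum boundary.  Cells filled here are flagged in ``imputed``.
    """
    missing = normal.missing_rows
    if len(missing) == 0:
        return replace(normal, values=normal.values.copy(), imputed=normal.imputed.copy())
    site_labels = pd.Series(site_labels)
    if not set(normal.values.index) <= set(site_labels.index):
        raise AlignmentError("site labels missing for some expression subjects")
    strata = site_labels.reindex(normal.values.index).map(_collapse_site)
    values = normal.values.copy()
    mask = normal.imputed.copy()
    for stratum in strata[missing].unique():
        in_stratum = strata == stratum
        observed = normal.values.loc[in_stratum].dropna(how="all")
        if len(observed) < min_observed:
            raise ImputationError(
                f"site stratum {stratum!r} has {len(observed)} observed normal "
                f"sample(s); need at least {min_observed} to impute"
            )
        medians = observed.median(axis=0)
        rows = [s for s in missing if in_stratum.loc[s]]
        values.loc[rows] = np.broadcast_to(
            medians.to_numpy(), (len(rows), values.shape[1])
        )
        mask.loc[rows] = True
    return replace(normal, values=values, imputed=mask)


def _collapse_site(label) -> str:
    s = str(label).lower()
    if "rect" in s:
        return "rectal"
    if "colon" in s or "proximal" in s or "distal" in s:
        return "colon"
    raise DataError(f"unrecognized tumor site label {label!r}")
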
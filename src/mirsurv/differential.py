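"""Paired carcinoma-normal differential expression and prevalence classification.

Differential expression is the per-subject difference of log2 carcinoma
signal minus log2 paired normal signal, under the convention that
undetected cells carry exact 0 in log2 space.  Each cell records its
provenance (both tissues detected, tumor-only, normal-only, neither, or a
normal value that was imputed).

miRNAs are split into two analysis classes by how commonly they are
expressed in carcinoma tissue among eligible subjects: "common" (detected
in at least half the population) enters continuous differential-expression
survival models; "rare" (below half, but expressed in at least 5 eligible
subjects) is analyzed as any-vs-no expression; miRNAs with fewer than 5
expressors are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError
from .normalize import NORMALIZED_LOG2, ExpressionMatrix

# provenance codes
BOTH = 0
TUMOR_ONLY = 1
NORMAL_ONLY = 2
NEITHER = 3
NORMAL_IMPUTED = 4

PROVENANCE_LABELS = {
    BOTH: "both",
    TUMOR_ONLY: "tumor-only",
    NORMAL_ONLY: "normal-only",
    NEITHER: "neither",
    NORMAL_IMPUTED: "normal-imputed",
}

COMMON = "common"
RARE = "rare"
EXCLUDED = "excluded"


@dataclass
class DifferentialMatrix:
    """Subjects x miRNAs log2 fold differences with per-cell provenance codes."""

    values: pd.DataFrame
    provenance: pd.DataFrame  # int8 codes above

    def __post_init__(self):
        if self.values.shape != self.provenance.shape:
            raise AlignmentError("provenance shape differs from values")


def compute_differential(
    tumor: ExpressionMatrix, normal: ExpressionMatrix
) -> DifferentialMatrix:
    """Cell-wise tumor minus normal on the log2 scale, with provenance flags."""
    for m, name in ((tumor, "tumor"), (normal, "normal")):
        if m.state != NORMALIZED_LOG2:
            raise DataError(f"{name} matrix must be normalized-log2, got {m.state!r}")
    if not tumor.values.index.equals(normal.values.index) or not tumor.values.columns.equals(
        normal.values.columns
    ):
        raise AlignmentError("tumor and normal matrices are not aligned")
    t = tumor.values.to_numpy(dtype=float)
    n = normal.values.to_numpy(dtype=float)
    if np.isnan(t).any() or np.isnan(n).any():
        raise DataError("differential expression requires complete (imputed) matrices")
    diff = t - n
    t_det = t != 0
    n_det = n != 0
    prov = np.full(t.shape, NEITHER, dtype=np.int8)
    prov[t_det & n_det] = BOTH
    prov[t_det & ~n_det] = TUMOR_ONLY
    prov[~t_det & n_det] = NORMAL_ONLY
    prov[normal.imputed.to_numpy(dtype=bool)] = NORMAL_IMPUTED
    idx, cols = tumor.values.index, tumor.values.columns
    return DifferentialMatrix(
        values=pd.DataFrame(diff, index=idx, columns=cols),
        provenance=pd.DataFrame(prov, index=idx, columns=cols),
    )


def compute_prevalence(tumor: ExpressionMatrix, subjects=None) -> pd.Series:
    """Percent of subjects with detected (nonzero) carcinoma expression per miRNA."""
    values = tumor.values if subjects is None else tumor.values.loc[subjects]
    if values.shape[0] == 0:
        raise DataError("no subjects to compute prevalence over")
    return 100.0 * (values > 0).sum(axis=0) / values.shape[0]


def classify_mirnas(
    prevalence: pd.Series,
    n_expressors: pd.Series,
    common_threshold: float = 50.0,
    min_expressors: int = 5,
) -> pd.DataFrame:
    """Partition miRNAs into common / rare / excluded analysis classes.

    ``prevalence`` is percent expressing among eligible subjects (those with
    both survival and stage information); ``n_expressors`` counts eligible
    expressors.  Common: prevalence >= threshold.  Rare: below threshold but
    at least ``min_expressors`` expressors.  Excluded otherwise.
    """
    prevalence = pd.Series(prevalence)
    n_expressors = pd.Series(n_expressors).reindex(prevalence.index)
    if n_expressors.isna().any():
        raise AlignmentError("expressor counts missing for some miRNAs")
    cls = np.where(
        prevalence >= common_threshold,
        COMMON,
        np.where(n_expressors >= min_expressors, RARE, EXCLUDED),
    )
    return pd.DataFrame(
        {
            "pct_expressing": prevalence,
            "n_expressors": n_expressors.astype(int),
            "analysis_class": cls,
        },
        index=prevalence.index,
    )


def differential_quartiles(diff: DifferentialMatrix, subjects=None) -> pd.DataFrame:
    """25th and 75th percentiles of per-subject differential expression per miRNA."""
    values = diff.values if subjects is None else diff.values.loc[subjects]
    if values.shape[0] == 0:
        raise DataError("empty subject subset")
    q = values.quantile([0.25, 0.75], axis=0)
    return pd.DataFrame({"q1": q.loc[0.25], "q3": q.loc[0.75]})
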
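"""Benjamini-Hochberg FDR q-values with the study's pooling rule.

q-values are computed within pooling groups: p-values of discovery and
replication miRNAs are combined within each expression-level class (common
vs rare), separately for each analysis stratum (site or stage subset).  A
``pooled_components=False`` mode adjusts discovery and replication
separately instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DataError("pvalues must be a non-empty vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def pool_and_assign(
    results: pd.DataFrame,
    group_cols=("stratum", "analysis_class"),
    component_col: str = "component",
    pooled_components: bool = True,
    p_col: str = "p",
    q_col: str = "q",
) -> pd.DataFrame:
    """Assign BH q-values within pooling groups of a result table.

    With ``pooled_components=True`` (default) discovery and replication
    p-values are adjusted together inside each (stratum, expression-class)
    group; otherwise the component column joins the grouping.
    """
    required = set(group_cols) | {p_col}
    if not pooled_components:
        required.add(component_col)
    missing = required - set(results.columns)
    if missing:
        raise ConfigError(f"result table lacks columns: {sorted(missing)}")
    if results[p_col].isna().any():
        raise ConfigError("unlabeled/missing p-values in result table")
    out = results.copy()
    keys = list(group_cols) + ([] if pooled_components else [component_col])
    out[q_col] = np.nan
    for _, idx in out.groupby(keys, dropna=False, observed=True).groups.items():
        out.loc[idx, q_col] = bh_qvalues(out.loc[idx, p_col].to_numpy())
    return out
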
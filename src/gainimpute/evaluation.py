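"""Imputation-error metrics and method comparison.

Accuracy is scored only on the cells that were actually missing (mask = 0),
per variable: normalized root mean square error (NRMSE) for continuous
variables,

    NRMSE = sqrt( (1/N) * sum_i (xhat_i - x_i)^2 ) / ( (1/N) * sum_i x_i )

and the proportion of falsely classified (PFC) for categorical variables,

    PFC = 1 - N_correct / N,

where the sums run over the N masked cells of one variable.  Repeated
imputations are summarized as mean +/- SD of the per-imputation metric.
Methods are compared per variable with a Shapiro-Wilk normality check on
pooled residuals, then one-way ANOVA (normal) or Kruskal-Wallis
(non-normal); pairwise Welch t-tests (or rank-sum tests) are run only when
the omnibus test is significant at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .schema import IncompleteTable, TableSchema

ALPHA = 0.05


@dataclass
class EvalReport:
    """Per-variable imputation error of one method over m repeats."""

    method: str
    table: pd.DataFrame  # columns: variable, metric, mean, sd, m, n_cells
    per_repeat: dict[str, np.ndarray] = field(repr=False)  # variable -> m values

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "method", self.method)
        return out


def _masked_cells(mask: np.ndarray, schema: TableSchema, variable: str) -> np.ndarray:
    j = schema.index(variable)
    return ~np.asarray(mask, dtype=bool)[:, j]


def nrmse(
    imputed: pd.DataFrame,
    truth: pd.DataFrame,
    mask: np.ndarray,
    schema: TableSchema,
    variable: str,
) -> float:
    """NRMSE of one continuous variable over its masked cells."""
    v = schema[variable]
    if not v.is_continuous:
        raise ValueError(f"{variable!r} is not continuous")
    rows = _masked_cells(mask, schema, variable)
    if not rows.any():
        raise ValueError(f"{variable!r} has no masked cells to score")
    x = truth[variable].to_numpy(float)[rows]
    xhat = imputed[variable].to_numpy(float)[rows]
    denom = x.mean()
    if abs(denom) <= 1e-12:
        raise ValueError(
            f"NRMSE undefined for zero-mean target ({variable!r}: "
            f"mean of true masked values is {denom})"
        )
    return float(np.sqrt(np.mean((xhat - x) ** 2)) / denom)


def pfc(
    imputed: pd.DataFrame,
    truth: pd.DataFrame,
    mask: np.ndarray,
    schema: TableSchema,
    variable: str,
) -> float:
    """Proportion falsely classified for one categorical variable."""
    v = schema[variable]
    if not v.is_categorical:
        raise ValueError(f"{variable!r} is not categorical")
    rows = _masked_cells(mask, schema, variable)
    if not rows.any():
        raise ValueError(f"{variable!r} has no masked cells to score")
    x = truth[variable].to_numpy(object)[rows]
    xhat = imputed[variable].to_numpy(object)[rows]
    return float(1.0 - (xhat == x).sum() / rows.sum())


def evaluate_imputations(
    imputed_list: list[pd.DataFrame],
    truth: pd.DataFrame,
    mask: np.ndarray,
    schema: TableSchema,
    method: str = "",
) -> EvalReport:
    """Score each repeat, then average: mean +/- SD per independent variable.

    Variables with no masked cells are skipped (they were never imputed).
    """
    if not imputed_list:
        raise ValueError("need at least one imputation")
    mask = np.asarray(mask, dtype=bool)
    rows = []
    per_repeat: dict[str, np.ndarray] = {}
    for v in schema:
        if v.role != "independent":
            continue
        cells = _masked_cells(mask, schema, v.name)
        if not cells.any():
            continue
        metric = nrmse if v.is_continuous else pfc
        vals = np.array(
            [metric(imp, truth, mask, schema, v.name) for imp in imputed_list]
        )
        per_repeat[v.name] = vals
        rows.append(
            {
                "variable": v.name,
                "metric": "NRMSE" if v.is_continuous else "PFC",
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "m": len(vals),
                "n_cells": int(cells.sum()),
            }
        )
    return EvalReport(method=method, table=pd.DataFrame(rows), per_repeat=per_repeat)


def compare_methods(reports: list[EvalReport]) -> pd.DataFrame:
    """Per-variable omnibus + gated pairwise comparison across methods.

    Returns a frame with one row per variable: the Shapiro-Wilk p-value on
    pooled residuals, the omnibus test used and its p-value, and pairwise
    p-values (Welch t or Mann-Whitney) only where the omnibus test rejects.
    """
    if len(reports) < 2:
        raise ValueError("need at least two methods to compare")
    methods = [r.method for r in reports]
    common = [v for v in reports[0].per_repeat if all(v in r.per_repeat for r in reports)]
    rows = []
    for var in common:
        samples = [r.per_repeat[var] for r in reports]
        m = len(samples[0])
        if m < 3 or any(len(s) != m for s in samples):
            raise ValueError("comparison needs >= 3 repeats per method, equal m")
        resid = np.concatenate([s - s.mean() for s in samples])
        if np.ptp(resid) == 0:
            sw_p = 1.0
        else:
            sw_p = float(stats.shapiro(resid).pvalue)
        normal = sw_p > ALPHA
        if np.ptp(np.concatenate(samples)) == 0:
            # all methods identical on every repeat: nothing to distinguish
            omni_p, omni_test = 1.0, "anova" if normal else "kruskal"
        elif normal:
            omni_p = float(stats.f_oneway(*samples).pvalue)
            omni_test = "anova"
        else:
            omni_p = float(stats.kruskal(*samples).pvalue)
            omni_test = "kruskal"
        row = {
            "variable": var,
            "shapiro_p": sw_p,
            "omnibus_test": omni_test,
            "omnibus_p": omni_p,
        }
        for a, b in combinations(range(len(methods)), 2):
            key = f"p_{methods[a]}_vs_{methods[b]}"
            if omni_p < ALPHA:
                sa, sb = samples[a], samples[b]
                if normal:
                    p = float(stats.ttest_ind(sa, sb, equal_var=False).pvalue)
                else:
                    p = float(stats.mannwhitneyu(sa, sb).pvalue)
                row[key] = p
                row[key + "_sig"] = p < ALPHA
            else:
                row[key] = np.nan
                row[key + "_sig"] = False
        rows.append(row)
    return pd.DataFrame(rows)
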
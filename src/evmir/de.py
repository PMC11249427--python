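"""Differential-expression statistics and panel selection.

Produces, per miRNA: total / maximum / geometric-mean / arithmetic-mean
expression, a one-way ANOVA p-value on log2(CPM + 0.5) (equivalent to a
pooled-variance two-sided t-test for two groups), the Benjamini–Hochberg
step-up FDR, and the ratio / log2(ratio) / signed fold change of
geometric means between case and control.

Conventions
-----------
* The significance gate of a panel uses the raw p-value (< alpha), not the
  FDR column: with small group sizes the FDR column routinely exceeds any
  usual cutoff while the panel is still defined on raw p.  The FDR column
  is reported alongside for transparency.
* Signed fold change: ratio r maps to r when r >= 1 and to -1/r otherwise,
  so |FC| >= 1 always and FC carries the direction of change.
* Geometric means use a pseudocount of 0.5 inside the log; the reported
  ``geometric_mean`` subtracts it back, while the ratio is taken on the
  pseudocounted means (so it is always finite).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Column order of the per-feature differential-expression table.
DE_COLUMNS = [
    "total_counts",
    "maximum_counts",
    "geometric_mean",
    "arithmetic_mean",
    "p_value",
    "fdr_step_up",
    "ratio",
    "log2_ratio",
    "fold_change",
]


@dataclass(frozen=True)
class FilterSpec:
    """Expression and significance thresholds defining a panel."""

    min_mean_rpm: float = 5.0
    alpha: float = 0.05
    fc_threshold: float = 1.5
    inclusive: bool = True  # |FC| >= threshold rather than strictly >

    def __post_init__(self) -> None:
        if self.min_mean_rpm < 0 or self.fc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def filter_expressed(cpm_matrix: pd.DataFrame, min_mean_rpm: float = 5.0) -> list[str]:
    """Features whose mean CPM across all samples is at least ``min_mean_rpm``."""
    mean = cpm_matrix.mean(axis=1)
    return list(mean.index[mean >= min_mean_rpm])


def group_test(log_values: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """One-way ANOVA p-value per feature (rows) across sample groups (columns).

    For two groups this is the pooled-variance two-sided t-test.  Features
    with zero variance everywhere get p = 1 when the group means agree and
    the smallest positive normal float when they differ.
    """
    groups = groups.reindex(log_values.columns)
    if groups.isna().any():
        raise ValueError("group labels missing for some samples")
    level_arrays = [
        log_values.loc[:, groups == level].to_numpy(dtype=float)
        for level in groups.unique()
    ]
    if len(level_arrays) < 2 or any(a.shape[1] < 2 for a in level_arrays):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.f_oneway(*level_arrays, axis=1)
    p = pd.Series(result.pvalue, index=log_values.index, name="p_value")
    means = np.column_stack([a.mean(axis=1) for a in level_arrays])
    # zero within-group variance: F is 0/0 (NaN) for equal means, inf (p=0) otherwise
    degenerate = np.isnan(result.pvalue) | (result.pvalue == 0.0)
    if degenerate.any():
        equal_means = np.isclose(means.max(axis=1), means.min(axis=1))
        p[degenerate & equal_means] = 1.0
        if (degenerate & ~equal_means).any():
            logger.warning(
                "%d feature(s) with zero within-group variance but unequal means; "
                "p set to the smallest positive normal float",
                int((degenerate & ~equal_means).sum()),
            )
            p[degenerate & ~equal_means] = sys.float_info.min
    return p


def fdr_step_up(p_values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved."""
    arr = np.asarray(p_values, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(adjusted, index=p_values.index, name="fdr_step_up")
    return adjusted


def signed_fold_change(ratio: float | np.ndarray) -> float | np.ndarray:
    """Map a ratio r to the signed fold change: r if r >= 1 else -1/r."""
    ratio = np.asarray(ratio, dtype=float)
    out = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    return float(out) if out.ndim == 0 else out


def _pseudo_gm(values: np.ndarray, pseudocount: float) -> np.ndarray:
    """2 ** rowmean(log2(x + pseudocount)); pseudocount not subtracted."""
    return np.exp2(np.log2(values + pseudocount).mean(axis=1))


def effect_stats(
    cpm_matrix: pd.DataFrame,
    groups: pd.Series,
    case: str,
    control: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Ratio of case/control geometric means, its log2, and the signed FC."""
    groups = groups.reindex(cpm_matrix.columns)
    gm_case = _pseudo_gm(cpm_matrix.loc[:, groups == case].to_numpy(dtype=float), pseudocount)
    gm_control = _pseudo_gm(
        cpm_matrix.loc[:, groups == control].to_numpy(dtype=float), pseudocount
    )
    ratio = gm_case / gm_control
    return pd.DataFrame(
        {
            "ratio": ratio,
            "log2_ratio": np.log2(ratio),
            "fold_change": signed_fold_change(ratio),
        },
        index=cpm_matrix.index,
    )


def summarize(matrix: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Total, maximum, geometric mean and arithmetic mean per feature.

    The geometric mean applies ``pseudocount`` under the log and subtracts
    it from the result (so an all-zero feature reports 0); pass
    ``pseudocount=0`` for the plain geometric mean.
    """
    values = matrix.to_numpy(dtype=float)
    gm = _pseudo_gm(values, pseudocount) - pseudocount
    return pd.DataFrame(
        {
            "total_counts": values.sum(axis=1),
            "maximum_counts": values.max(axis=1),
            "geometric_mean": gm,
            "arithmetic_mean": values.mean(axis=1),
        },
        index=matrix.index,
    )


def de_table(
    cpm_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    case: str = "Q331K",
    control: str = "WT",
    group_col: str = "genotype",
    min_mean_rpm: float = 5.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full differential-expression table for one compartment.

    Applies the mean-expression filter, then computes summary statistics,
    ANOVA p-values on log2(CPM + 0.5), BH step-up FDR and the effect-size
    columns; rows are ordered by ascending p-value.
    """
    keep = filter_expressed(cpm_matrix, min_mean_rpm)
    mat = cpm_matrix.loc[keep]
    groups = meta.loc[mat.columns, group_col]
    mask = groups.isin([case, control])
    mat = mat.loc[:, mask[mask].index]
    groups = groups[mask]

    table = summarize(mat, pseudocount)
    table["p_value"] = group_test(np.log2(mat + pseudocount), groups)
    table["fdr_step_up"] = fdr_step_up(table["p_value"])
    table = table.join(effect_stats(mat, groups, case, control, pseudocount))
    table.index.name = "feature"
    return table[DE_COLUMNS].sort_values("p_value")


def select_panel(table: pd.DataFrame, spec: FilterSpec = FilterSpec()) -> "Panel":
    """Apply the significance and fold-change gates to a DE table."""
    from .panels import Panel

    fc = table["fold_change"].abs()
    if spec.inclusive:
        fc_pass = fc >= spec.fc_threshold
    else:
        fc_pass = fc > spec.fc_threshold
    keep = table[(table["p_value"] < spec.alpha) & fc_pass].sort_values("p_value")
    return Panel(
        compartment=str(table.attrs.get("compartment", "")),
        features=list(keep.index),
        records=keep,
        filter_spec=spec,
    )
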
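"""Ensemble attribute weighting for feature (miRNA) selection.

Seven per-feature relevance scores against a categorical label — information
gain, information gain ratio, gini index, chi-squared, symmetric uncertainty,
ReliefF and a one-attribute rule score — each min-max normalized to [0, 1]
and summed into an ensemble weight in [0, 7].  The five categorical models
operate on equal-frequency discretized values; ReliefF works on the raw
continuous values with range-scaled differences.

All entropies are in bits.  A feature statistically independent of the
label scores 0 raw weight in every model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

MODELS = (
    "info_gain",
    "info_gain_ratio",
    "gini",
    "chi_squared",
    "uncertainty",
    "relief",
    "rule",
)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Discretization:
    """Binning scheme feeding the categorical models."""

    method: str = "equal_frequency"
    n_bins: int = 4

    def __post_init__(self) -> None:
        if self.method not in ("equal_frequency", "equal_width"):
            raise ValueError(f"unknown discretization method {self.method!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def discretize(values: np.ndarray, scheme: Discretization = Discretization()) -> np.ndarray:
    """Map values to integer bin labels.

    Equal-frequency cut points sit at empirical quantiles; duplicate cut
    points (from ties) are merged, so heavily tied data may occupy fewer
    than ``n_bins`` bins.  A constant feature lands in a single bin.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be 1-D")
    if scheme.method == "equal_frequency":
        qs = np.quantile(values, np.arange(1, scheme.n_bins) / scheme.n_bins)
        cuts = np.unique(qs)
    else:
        lo, hi = values.min(), values.max()
        cuts = np.unique(np.linspace(lo, hi, scheme.n_bins + 1)[1:-1]) if hi > lo else np.array([])
    return np.searchsorted(cuts, values, side="left")


# ---------------------------------------------------------------------------
# categorical models (contingency-table based)
# ---------------------------------------------------------------------------

def _contingency(bins: np.ndarray, labels: np.ndarray) -> np.ndarray:
    if len(bins) != len(labels):
        raise ValueError("bins and labels must have the same length")
    bins = np.asarray(bins)
    _, y = np.unique(labels, return_inverse=True)
    n_bins, n_classes = int(bins.max()) + 1, int(y.max()) + 1
    table = np.bincount(bins * n_classes + y, minlength=n_bins * n_classes)
    return table.reshape(n_bins, n_classes).astype(float)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _info_gain_terms(table: np.ndarray) -> tuple[float, float, float]:
    """(IG, H(label), H(bins)) from a bins x classes contingency table."""
    n = table.sum()
    p_class = table.sum(axis=0) / n
    p_bin = table.sum(axis=1) / n
    h_y = _entropy(p_class)
    h_b = _entropy(p_bin)
    h_y_given_b = 0.0
    for b in range(table.shape[0]):
        nb = table[b].sum()
        if nb > 0:
            h_y_given_b += (nb / n) * _entropy(table[b] / nb)
    return h_y - h_y_given_b, h_y, h_b


def _gini_from_table(table: np.ndarray) -> float:
    n = table.sum()

    def impurity(p: np.ndarray) -> float:
        return 1.0 - float((p ** 2).sum())

    g = impurity(table.sum(axis=0) / n)
    nb = table.sum(axis=1)
    for b in range(table.shape[0]):
        if nb[b] > 0:
            g -= (nb[b] / n) * impurity(table[b] / nb[b])
    return max(g, 0.0)


def _chi_squared_from_table(table: np.ndarray) -> float:
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    mask = expected > 0
    return float(((table - expected)[mask] ** 2 / expected[mask]).sum())


def _rule_from_table(table: np.ndarray) -> float:
    n = table.sum()
    accuracy = table.max(axis=1).sum() / n
    baseline = table.sum(axis=0).max() / n
    return max(accuracy - baseline, 0.0)


def _categorical_weights(table: np.ndarray) -> dict[str, float]:
    """All six contingency-table weights from one bins x classes table."""
    ig, h_y, h_b = _info_gain_terms(table)
    ig = max(ig, 0.0)
    denom = h_y + h_b
    return {
        "info_gain": ig,
        "info_gain_ratio": ig / h_b if h_b > 0 else 0.0,
        "gini": _gini_from_table(table),
        "chi_squared": _chi_squared_from_table(table),
        "uncertainty": 2.0 * ig / denom if denom > 0 else 0.0,
        "rule": _rule_from_table(table),
    }


def weight_info_gain(bins: np.ndarray, labels: np.ndarray) -> float:
    """IG = H(Y) - sum_b p(b) H(Y|b), in bits."""
    return _categorical_weights(_contingency(bins, labels))["info_gain"]


def weight_info_gain_ratio(bins: np.ndarray, labels: np.ndarray) -> float:
    """IG / H(bins); 0 when the feature occupies a single bin."""
    return _categorical_weights(_contingency(bins, labels))["info_gain_ratio"]


def weight_uncertainty(bins: np.ndarray, labels: np.ndarray) -> float:
    """Symmetric uncertainty 2 IG / (H(Y) + H(bins))."""
    return _categorical_weights(_contingency(bins, labels))["uncertainty"]


def weight_gini(bins: np.ndarray, labels: np.ndarray) -> float:
    """Gini-impurity reduction of the label after splitting by bin."""
    return _categorical_weights(_contingency(bins, labels))["gini"]


def weight_chi_squared(bins: np.ndarray, labels: np.ndarray) -> float:
    """Pearson chi-squared statistic of the bins x classes table."""
    return _categorical_weights(_contingency(bins, labels))["chi_squared"]


def weight_rule(bins: np.ndarray, labels: np.ndarray) -> float:
    """One-attribute-rule advantage: per-bin majority-vote accuracy minus
    the majority-class baseline, floored at 0."""
    return _categorical_weights(_contingency(bins, labels))["rule"]


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------

def weight_relief(
    x: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 10,
    seed: int | None = None,
    n_sampled: int | None = None,
) -> np.ndarray:
    """ReliefF weights on continuous features.

    For every (sampled) instance the k nearest hits (same class) and k
    nearest misses (other classes) — by Euclidean distance on range-scaled
    features — push each feature weight down or up by the range-scaled
    per-feature difference.  Weights lie in [-1, 1]; a constant feature
    scores exactly 0.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    n, p = x.shape
    if n != len(labels):
        raise ValueError("feature matrix and labels disagree on sample count")
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        raise ValueError("Relief needs >= 2 samples per class")
    smallest = int(counts.min())
    if k_neighbors > smallest - 1:
        logger.warning(
            "relief k=%d exceeds smallest class - 1; truncated to %d",
            k_neighbors,
            smallest - 1,
        )
        k_neighbors = smallest - 1
    rng = np.random.default_rng(seed)
    ranges = x.max(axis=0) - x.min(axis=0)
    safe = np.where(ranges > 0, ranges, 1.0)
    xs = x / safe  # range-scaled; constant features contribute 0 everywhere
    xs[:, ranges == 0] = 0.0

    dist = squareform(pdist(xs, metric="euclidean"))
    np.fill_diagonal(dist, np.inf)

    if n_sampled is None or n_sampled >= n:
        sampled = np.arange(n)
    else:
        sampled = rng.choice(n, size=n_sampled, replace=False)

    weights = np.zeros(p)
    denom = len(sampled) * k_neighbors
    for i in sampled:
        same = labels == labels[i]
        hits = np.where(same)[0]
        hits = hits[np.argsort(dist[i, hits])][:k_neighbors]
        misses = np.where(~same)[0]
        misses = misses[np.argsort(dist[i, misses])][:k_neighbors]
        diffs_hit = np.abs(xs[i] - xs[hits]).sum(axis=0)
        diffs_miss = np.abs(xs[i] - xs[misses]).sum(axis=0)
        weights += (diffs_miss - diffs_hit) / denom
    return weights


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

def _minmax(col: pd.Series) -> pd.Series:
    """Normalize a raw-weight column to [0, 1].

    A raw weight of 0 means "non-important" and maps to 0 regardless of
    what other features score, so the lower anchor is 0: negative Relief
    weights (worse than irrelevant) are clipped to 0 and the column is
    scaled by its maximum.  A column with no positive weight maps to all-0.
    """
    hi = float(col.max())
    if hi <= 0:
        return pd.Series(0.0, index=col.index)
    return col.clip(lower=0.0) / hi


def ensemble(
    table: pd.DataFrame,
    labels: pd.Series,
    discretization: Discretization = Discretization(),
    relief_k: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run all seven weighting models and combine them.

    Parameters
    ----------
    table
        Samples x features matrix (typically log2(CPM + 0.5)).
    labels
        Categorical label per sample (>= 2 classes).

    Returns
    -------
    DataFrame indexed by feature with raw weights (``raw_<model>``),
    normalized weights (``norm_<model>``, min-max per model with a
    constant column mapping to all-0), the ensemble sum and the rank
    (1 = highest ensemble, ties broken by feature name).
    """
    labels = pd.Series(labels).reindex(table.index) if not isinstance(labels, pd.Series) else labels.reindex(table.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    if labels.nunique() < 2:
        raise ValueError("label must have >= 2 classes")
    y = labels.to_numpy()
    x = table.to_numpy(dtype=float)

    raw_rows = []
    for j in range(x.shape[1]):
        bins = discretize(x[:, j], discretization)
        raw_rows.append(_categorical_weights(_contingency(bins, y)))
    raw = pd.DataFrame(raw_rows, index=table.columns).add_prefix("raw_")
    raw["raw_relief"] = weight_relief(x, y, k_neighbors=relief_k, seed=seed)

    report = raw[[f"raw_{m}" for m in MODELS]].copy()
    for model in MODELS:
        report[f"norm_{model}"] = _minmax(report[f"raw_{model}"])
    report["ensemble"] = report[[f"norm_{m}" for m in MODELS]].sum(axis=1)
    order = sorted(report.index, key=lambda f: (-report.at[f, "ensemble"], f))
    report["rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=pd.Index(order, name=report.index.name)
    )
    return report


def top_features(report: pd.DataFrame, k: int = 30) -> list[str]:
    """The k highest-ensemble features (rank order)."""
    return list(report.sort_values("rank").index[:k])


def confounder_scan(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    labels: tuple[str, ...] = ("genotype", "timepoint", "sex"),
    discretization: Discretization = Discretization(),
    relief_k: int = 10,
    seed: int | None = None,
    top_m: int = 30,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Weight features against several labels to expose confounding.

    Runs the ensemble once per label column of ``meta`` on log2(CPM + 0.5)
    of ``counts``; single-class labels are skipped with a warning.  Also
    returns a summary of pairwise top-``top_m`` overlaps between labels.
    """
    from .normalize import log_cpm

    table = log_cpm(counts).T  # samples x features
    reports: dict[str, pd.DataFrame] = {}
    for label in labels:
        values = meta.loc[table.index, label]
        if values.nunique() < 2:
            logger.warning("label %r has a single class; skipped", label)
            continue
        reports[label] = ensemble(
            table, values, discretization=discretization, relief_k=relief_k, seed=seed
        )
    rows = []
    done = list(reports)
    for i, a in enumerate(done):
        for b in done[i + 1:]:
            top_a = set(top_features(reports[a], top_m))
            top_b = set(top_features(reports[b], top_m))
            rows.append({"label_a": a, "label_b": b, "top_m": top_m,
                         "overlap": len(top_a & top_b)})
    overlap = pd.DataFrame(rows, columns=["label_a", "label_b", "top_m", "overlap"])
    return reports, overlap


def rank_enrichment_pvalue(report: pd.DataFrame, features: list[str]) -> float:
    """Wilcoxon rank-sum p-value that ``features`` rank *better* (smaller
    rank numbers) than the remaining features, against a uniform-ranking
    null.  A large p means the label shows no preference for the feature
    set — the check used to rule out confounding by a nuisance label."""
    from scipy.stats import mannwhitneyu

    ranks = report["rank"]
    in_set = ranks.loc[ranks.index.intersection(features)]
    out_set = ranks.drop(in_set.index)
    if in_set.empty or out_set.empty:
        raise ValueError("both feature groups must be non-empty")
    return float(mannwhitneyu(in_set, out_set, alternative="less").pvalue)
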
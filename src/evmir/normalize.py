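"""Between-sample normalization and PCA-based sample QC.

Implements counts-per-million scaling, trimmed-mean-of-M-values (TMM)
scaling factors (Robinson & Oshlack style: doubly trimmed log-ratios of
library-scaled proportions, weighted by inverse asymptotic variance,
factors rescaled to geometric mean 1), and an outlier flagger based on
sample distances in principal-component space of log2(CPM + 0.5).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million.

    ``library_sizes`` defaults to the column sums of ``counts``; pass TMM
    effective sizes to obtain TMM-CPM.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = library_sizes.reindex(counts.columns)
    zero = library_sizes[library_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero/negative library size for sample(s): {list(zero.index)}")
    out = counts.div(library_sizes, axis=1) * 1e6
    out.attrs["units"] = "CPM"
    return out


def log_cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None,
            prior: float = 0.5) -> pd.DataFrame:
    """log2(CPM + prior); the working scale for PCA, weighting and testing."""
    units = counts.attrs.get("units", "raw")
    mat = counts if units in ("CPM", "TMM-CPM") else cpm(counts, library_sizes)
    out = np.log2(mat + prior)
    out.attrs["units"] = f"log2({units if units != 'raw' else 'CPM'}+{prior})"
    return out


@dataclass
class NormalizationResult:
    """TMM factors and the expression matrix rescaled by them."""

    factors: pd.Series  # geometric mean 1
    effective_library_sizes: pd.Series  # raw size x factor
    cpm: pd.DataFrame  # CPM on effective sizes (units 'TMM-CPM')
    reference_sample: str
    trim_m: float
    trim_a: float


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    shared = (obs > 0) & (ref > 0)
    if not shared.any():
        raise ValueError("sample shares no expressed features with the reference")
    o = obs[shared] / n_obs
    r = ref[shared] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic variance of M from the delta method; weights are 1/v
    v = (n_obs - obs[shared]) / (n_obs * obs[shared]) + (n_ref - ref[shared]) / (
        n_ref * ref[shared]
    )
    if np.max(np.abs(m)) < 1e-6:  # identical proportions: factor exactly 1
        return 0.0
    n = len(m)
    # double trim: drop trim_m of each M tail and trim_a of each A tail
    # (1-based average ranks, so ties straddling a cut are treated alike)
    m_rank = stats.rankdata(m)
    a_rank = stats.rankdata(a)
    lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
    keep = (m_rank >= lo_m) & (m_rank <= hi_m) & (a_rank >= lo_a) & (a_rank <= hi_a)
    if not keep.any():
        logger.warning("TMM trimming removed all features; factor set to 1")
        return 0.0
    return float(np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationResult:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose upper quartile of CPM is closest
    to the mean upper quartile across samples.  Features with a zero count
    in either member of a pair are excluded from that pair's M/A values.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    uq = (counts.div(lib, axis=1) * 1e6).quantile(0.75, axis=0)
    reference = (uq - uq.mean()).abs().idxmin()

    ref_col = counts[reference].to_numpy(dtype=float)
    log2f = {}
    for sample in counts.columns:
        if sample == reference:
            log2f[sample] = 0.0
            continue
        log2f[sample] = _tmm_pair(
            counts[sample].to_numpy(dtype=float),
            ref_col,
            lib[sample],
            lib[reference],
            trim_m,
            trim_a,
        )
    factors = pd.Series({s: 2.0 ** v for s, v in log2f.items()}, name="tmm_factor")
    factors = factors.reindex(counts.columns)
    factors /= np.exp(np.log(factors).mean())  # rescale to geometric mean 1
    effective = lib * factors
    out_cpm = cpm(counts, effective)
    out_cpm.attrs["units"] = "TMM-CPM"
    return NormalizationResult(
        factors=factors,
        effective_library_sizes=effective,
        cpm=out_cpm,
        reference_sample=reference,
        trim_m=trim_m,
        trim_a=trim_a,
    )


@dataclass
class PcaQc:
    """Sample scores on the leading principal components plus outlier flags."""

    scores: pd.DataFrame  # samples x PCs
    explained_variance_fraction: np.ndarray
    distances: pd.Series  # Euclidean distance from the score centroid
    flags: list[str]
    flag_sd: float


def pca_qc(cpm_matrix: pd.DataFrame, k: int = 2, flag_sd: float = 3.0) -> PcaQc:
    """PCA of log2(CPM + 0.5) with robust outlier flagging.

    Features are centered (not scaled); scores come from the SVD of the
    centered samples x features matrix.  A sample is flagged when its
    distance from the score-space centroid exceeds the median distance by
    more than ``flag_sd`` times the robust SD (1.4826 x MAD) of the
    distances — a robust z-score threshold, so a homogeneous cohort
    produces no flags.
    """
    n_samples, n_features = cpm_matrix.shape[1], cpm_matrix.shape[0]
    if n_samples < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    if k > min(n_samples, n_features):
        raise ValueError(f"k={k} exceeds min(samples, features)")
    x = np.log2(cpm_matrix.to_numpy(dtype=float).T + 0.5)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=cpm_matrix.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    total_var = float((s ** 2).sum())
    explained = (s[:k] ** 2 / total_var) if total_var > 0 else np.zeros(k)
    centroid = scores.mean(axis=0)
    distances = np.sqrt(((scores - centroid) ** 2).sum(axis=1))
    median = float(distances.median())
    robust_sd = float(np.median(np.abs(distances - median))) * 1.4826
    if math.isinf(flag_sd):
        flags: list[str] = []
    elif robust_sd == 0.0:
        flags = list(distances.index[distances > median])
    else:
        flags = list(distances.index[distances > median + flag_sd * robust_sd])
    return PcaQc(
        scores=scores,
        explained_variance_fraction=explained,
        distances=distances,
        flags=flags,
        flag_sd=flag_sd,
    )
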
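"""Count filtering and normalization.

Stages mirror a standard bulk RNA-seq pre-analysis chain: CPM-based
low-expression filtering, median-of-ratios size factors, a log2 variance-
stabilizing stand-in transform, a low-variance gene filter, and sample
removal by co-expression connectivity z-score. Each stage is exposed both
as a small sklearn-style transformer and as a plain function.

All matrices are pandas DataFrames oriented genes x samples (the field's
convention for expression tables).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


class EmptyInputError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


@dataclass
class FilterConfig:
    """Thresholds of the pre-analysis filters.

    min_cpm / min_samples: keep genes with CPM >= min_cpm in at least
    min_samples samples. min_variance: minimum per-gene sample variance
    (n-1 denominator) on the normalized scale. outlier_z: samples whose
    connectivity z-score falls below -outlier_z are removed.
    """

    min_cpm: float = 1.0
    min_samples: int = 4
    min_variance: float = 0.05
    outlier_z: float = 2.5

    def __post_init__(self):
        if self.min_cpm < 0 or self.min_samples < 0 or self.min_variance < 0 or self.outlier_z < 0:
            raise ValueError("filter thresholds must be >= 0")


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise EmptyInputError("empty count matrix")
    if not counts.index.is_unique or not counts.columns.is_unique:
        raise ValueError("gene/sample identifiers must be unique")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")


def filter_low_expression(counts: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Keep genes with CPM >= cfg.min_cpm in at least cfg.min_samples samples.

    CPM_gs = count_gs / library_size_s * 1e6 with library size the column sum.
    """
    cfg = cfg or FilterConfig()
    _check_counts(counts)
    lib = counts.sum(axis=0)
    zero_lib = lib[lib == 0]
    if len(zero_lib):
        raise NormalizationError(f"zero library size in sample(s): {list(zero_lib.index)}")
    cpm = counts.div(lib, axis=1) * 1e6
    keep = (cpm >= cfg.min_cpm).sum(axis=1) >= cfg.min_samples
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes expressed in every sample."""
    _check_counts(counts)
    vals = counts.to_numpy(dtype=float)
    all_pos = (vals > 0).all(axis=1)
    if not all_pos.any():
        raise DegenerateInputError("no gene expressed in all samples; size factors undefined")
    ref = vals[all_pos]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(count / size_factor + 1) variance-stabilizing stand-in transform."""
    sf = size_factors(counts)
    return np.log2(counts.div(sf, axis=1) + 1.0)


def filter_low_variance(expr: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Drop genes with sample variance (ddof=1) below cfg.min_variance."""
    cfg = cfg or FilterConfig()
    if expr.shape[1] < 2:
        raise DegenerateInputError("variance filter needs >= 2 samples")
    var = expr.var(axis=1, ddof=1)
    return expr.loc[var >= cfg.min_variance]


def sample_connectivity(expr: pd.DataFrame) -> pd.Series:
    """k_s = sum over other samples of (1 + cor(s, t)) / 2."""
    cor = np.corrcoef(expr.to_numpy().T)
    adj = (1.0 + cor) / 2.0
    np.fill_diagonal(adj, 0.0)
    return pd.Series(adj.sum(axis=1), index=expr.columns, name="connectivity")


def remove_connectivity_outliers(
    expr: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """One-pass removal of samples with connectivity z-score < -cfg.outlier_z.

    Returns (filtered matrix, list of removed sample ids). If the
    connectivity distribution is degenerate (sd = 0) nothing is removed and
    a warning is logged.
    """
    cfg = cfg or FilterConfig()
    if expr.shape[1] < 4:
        raise DegenerateInputError("outlier detection needs >= 4 samples")
    k = sample_connectivity(expr)
    sd = k.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        logger.warning("connectivity distribution degenerate (sd=0); no samples removed")
        return expr, []
    z = (k - k.mean()) / sd
    removed = list(z.index[z < -cfg.outlier_z])
    if removed:
        logger.info("removed %d connectivity-outlier sample(s): %s", len(removed), removed)
    return expr.drop(columns=removed), removed


def preprocess(
    counts: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Full chain: CPM filter -> normalize -> variance filter -> outlier removal."""
    cfg = cfg or FilterConfig()
    kept = filter_low_expression(counts, cfg)
    expr = normalize(kept)
    expr = filter_low_variance(expr, cfg)
    expr, removed = remove_connectivity_outliers(expr, cfg)
    return expr, removed


# ---------------------------------------------------------------------------
# sklearn-style transformers (thin stateful wrappers over the functions)
# ---------------------------------------------------------------------------


class LowExpressionFilter(TransformerMixin, BaseEstimator):
    """Transformer form of :func:`filter_low_expression`.

    fit() records which genes pass on the training matrix; transform()
    subsets any matrix to those genes.
    """

    def __init__(self, min_cpm: float = 1.0, min_samples: int = 4):
        self.min_cpm = min_cpm
        self.min_samples = min_samples

    def fit(self, X: pd.DataFrame, y=None):
        cfg = FilterConfig(min_cpm=self.min_cpm, min_samples=self.min_samples)
        self.kept_genes_ = filter_low_expression(X, cfg).index.to_list()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[[g for g in self.kept_genes_ if g in X.index]]


class MedianRatioNormalizer(TransformerMixin, BaseEstimator):
    """Median-of-ratios size factors + log2(x + 1); factors fit per matrix."""

    def fit(self, X: pd.DataFrame, y=None):
        self.size_factors_ = size_factors(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return np.log2(X.div(self.size_factors_, axis=1) + 1.0)


class VarianceFilter(TransformerMixin, BaseEstimator):
    def __init__(self, min_variance: float = 0.05):
        self.min_variance = min_variance

    def fit(self, X: pd.DataFrame, y=None):
        cfg = FilterConfig(min_variance=self.min_variance)
        self.kept_genes_ = filter_low_variance(X, cfg).index.to_list()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[[g for g in self.kept_genes_ if g in X.index]]


class ConnectivityOutlierFilter(TransformerMixin, BaseEstimator):
    """Removes low-connectivity samples (columns) in a single pass."""

    def __init__(self, outlier_z: float = 2.5):
        self.outlier_z = outlier_z

    def fit(self, X: pd.DataFrame, y=None):
        cfg = FilterConfig(outlier_z=self.outlier_z)
        _, self.removed_samples_ = remove_connectivity_outliers(X, cfg)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.drop(columns=[s for s in self.removed_samples_ if s in X.columns])
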
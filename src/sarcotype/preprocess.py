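"""Count filtering and variance-stabilizing normalization.

Raw RNA-seq counts are overdispersed and heteroscedastic on the log scale:
low-count genes have inflated log-variance. The normalization here converts
counts to log2 counts-per-million with small offsets and attaches a
per-observation precision weight derived from a fitted mean-variance trend,
so that downstream weighted least squares (differential expression) and
correlation-based clustering operate on approximately homoscedastic data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess


class PreprocessError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Raw integer counts, genes in rows, samples in columns.

    Library sizes are fixed at construction (column sums by default) and are
    deliberately *not* recomputed when genes are filtered, so CPM values stay
    comparable before and after gene filtering.
    """

    values: pd.DataFrame
    libsize: pd.Series = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise PreprocessError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise PreprocessError(f"duplicate sample ids: {dups[:5]}")
        if (self.values.values < 0).any():
            raise PreprocessError("counts must be non-negative")
        if self.libsize is None:
            self.libsize = self.values.sum(axis=0).astype(float)
        else:
            self.libsize = self.libsize.reindex(self.values.columns).astype(float)
            if self.libsize.isna().any():
                raise PreprocessError("libsize missing for some samples")
        if (self.libsize <= 0).any():
            bad = self.libsize.index[self.libsize <= 0].tolist()
            raise PreprocessError(f"non-positive library size for samples: {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def cpm(self) -> pd.DataFrame:
        return self.values / self.libsize * 1e6


@dataclass
class NormalizedMatrix:
    """Log2-CPM expression with per-observation precision weights.

    ``trend`` is the fitted mean-variance curve as a (log-count, sqrt-SD)
    lookup table; it is retained so filtered copies keep the original fit.
    """

    logexpr: pd.DataFrame
    weights: pd.DataFrame
    libsize: pd.Series
    trend: tuple = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.logexpr.index.equals(self.weights.index) or not (
            self.logexpr.columns.equals(self.weights.columns)
        ):
            raise PreprocessError("logexpr and weights must share axes")
        if not np.isfinite(self.logexpr.values).all():
            raise PreprocessError("logexpr contains non-finite values")
        w = self.weights.values
        if not (np.isfinite(w).all() and (w > 0).all()):
            raise PreprocessError("weights must be strictly positive and finite")

    @property
    def kept_genes(self) -> pd.Index:
        return self.logexpr.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.logexpr.columns

    def subset_genes(self, genes) -> "NormalizedMatrix":
        genes = pd.Index(genes)
        return NormalizedMatrix(
            self.logexpr.loc[genes], self.weights.loc[genes], self.libsize, self.trend
        )


def expression_filter(
    counts: CountMatrix, min_cpm: float = 1.0, min_fraction: float = 0.2
) -> CountMatrix:
    """Drop genes not expressed at ``min_cpm`` CPM in enough samples.

    A gene is retained iff its CPM is >= ``min_cpm`` in at least
    ceil(min_fraction * n_samples) samples. Library sizes are carried over
    unchanged (not recomputed on the retained genes).
    """
    if counts.n_genes == 0 or counts.n_samples == 0:
        raise PreprocessError("empty count matrix")
    min_samples = math.ceil(min_fraction * counts.n_samples)
    keep = (counts.cpm() >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise PreprocessError(
            f"expression filter removed all genes "
            f"(min_cpm={min_cpm}, min_fraction={min_fraction})"
        )
    return CountMatrix(counts.values.loc[keep], libsize=counts.libsize.copy())


def _quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Replace each column's order statistics by their across-column mean."""
    order = np.argsort(x, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n_rows, n_cols = x.shape
    rows = np.arange(n_rows)
    out = np.empty_like(x, dtype=float)
    sorted_x = np.take_along_axis(x, order, axis=0)
    target = sorted_x.mean(axis=1)
    for j in range(n_cols):
        ranks[order[:, j], j] = rows
    for j in range(n_cols):
        out[:, j] = target[ranks[:, j]]
    return out


def normalize(
    counts: CountMatrix,
    quantile: bool = False,
    lowess_frac: float = 0.5,
    lowess_iter: int = 2,
) -> NormalizedMatrix:
    """Log2-CPM transform with mean-variance precision weights.

    logexpr[g, s] = log2((count + 0.5) / (libsize + 1) * 1e6). With
    ``quantile`` on, columns are quantile-normalized (positionally) before the
    trend fit. Gene-wise residual SDs from an intercept-only fit are smoothed
    (lowess of sqrt(SD) against mean log2 count); each observation's weight is
    the trend prediction at its fitted log-count, raised to the -4th power, so
    precision decreases where the trend predicts more residual variation. The
    trend is extended flat outside the fitted range.
    """
    if counts.n_samples < 2:
        raise PreprocessError("normalize requires at least 2 samples (residual df)")
    lib = counts.libsize.values
    logexpr = np.log2((counts.values.values + 0.5) / (lib + 1.0) * 1e6)
    if quantile:
        logexpr = _quantile_normalize(logexpr)

    # intercept-only residual SD per gene, on the (possibly quantiled) values
    sd = logexpr.std(axis=1, ddof=1)
    sqrt_sd = np.sqrt(sd)
    # mean log2 count: shift mean log-CPM back to the count scale using the
    # geometric-mean library size
    mean_log_count = logexpr.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)

    fit = lowess(
        sqrt_sd, mean_log_count, frac=lowess_frac, it=lowess_iter, return_sorted=True
    )
    trend_x, trend_y = fit[:, 0], fit[:, 1]
    # collapse duplicate abscissae for interpolation
    trend_x, uniq = np.unique(trend_x, return_index=True)
    trend_y = trend_y[uniq]
    trend_y = np.maximum(trend_y, 1e-6)

    fitted_log_count = logexpr + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_log_count, trend_x, trend_y)
    weights = pred_sqrt_sd ** (-4.0)

    idx, cols = counts.gene_ids, counts.sample_ids
    return NormalizedMatrix(
        logexpr=pd.DataFrame(logexpr, index=idx, columns=cols),
        weights=pd.DataFrame(weights, index=idx, columns=cols),
        libsize=counts.libsize.copy(),
        trend=(trend_x, trend_y),
    )


def mad_filter(norm: NormalizedMatrix, keep_fraction: float = 0.55) -> NormalizedMatrix:
    """Retain the top ceil(keep_fraction * G) genes by median absolute deviation.

    Ties at the cut are broken by lexicographic gene id, so the retained set
    is deterministic.
    """
    if not (0 < keep_fraction <= 1):
        raise PreprocessError("keep_fraction must be in (0, 1]")
    x = norm.logexpr.values
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1)
    n_keep = math.ceil(keep_fraction * len(mad))
    order = sorted(
        range(len(mad)), key=lambda i: (-mad[i], str(norm.logexpr.index[i]))
    )
    kept = norm.logexpr.index[sorted(order[:n_keep], key=lambda i: i)]
    return norm.subset_genes(kept)
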
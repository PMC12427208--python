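"""Resampled consensus clustering with CDF-area elbow selection of k.

A sample-by-sample consensus matrix is accumulated over item resamples: each
resample draws a fraction of the samples without replacement, clusters them
(average-linkage hierarchical clustering on 1 - Pearson correlation by
default), and records which pairs land in the same cluster. The consensus
entry for a pair is the co-clustering fraction among resamples where both
were drawn. Stability of the consensus matrix across k is summarized by the
area under the empirical CDF of its entries, A(k); the elbow rule picks the k
after which the marginal gain in A collapses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .preprocess import NormalizedMatrix


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusResult:
    k_range: tuple
    M: dict  # k -> consensus DataFrame (samples x samples)
    I: dict  # k -> co-sampling count DataFrame
    A: dict = field(default_factory=dict)  # k -> CDF area
    k_star: int = None
    labels: pd.Series = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.M[self.k_range[0]].index

    def never_codrawn(self, k: int = None) -> np.ndarray:
        """Boolean mask of sample pairs never drawn together in any resample."""
        k = k if k is not None else self.k_range[0]
        return self.I[k].values == 0


def _pearson_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns of x (genes x samples)."""
    sd = x.std(axis=0)
    if (sd == 0).any():
        raise ConsensusError(
            f"constant sample vector(s) at column index "
            f"{list(np.flatnonzero(sd == 0))}: correlation undefined"
        )
    d = 1.0 - np.corrcoef(x, rowvar=False)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def _cluster_once(x: np.ndarray, k: int, metric: str, method: str) -> np.ndarray:
    z = _linkage_tree(x, metric, method)
    return fcluster(z, t=k, criterion="maxclust")


def _linkage_tree(x: np.ndarray, metric: str, method: str) -> np.ndarray:
    if metric == "pearson":
        d = squareform(_pearson_distance(x), checks=False)
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        d = pdist(x.T, metric="euclidean")
    else:
        raise ConsensusError(f"unknown metric: {metric}")
    return linkage(d, method=method)


def consensus_cluster(
    norm: NormalizedMatrix,
    k_range=range(2, 9),
    n_resamples: int = 1000,
    item_fraction: float = 0.8,
    seed: int = 0,
    metric: str = "pearson",
    method: str = "average",
) -> ConsensusResult:
    """Build per-k consensus matrices over item resamples.

    Each resample draws floor(item_fraction * n) samples without replacement
    and its linkage tree is cut at every k in ``k_range``. Pairs never drawn
    together get consensus 0 (flagged via the co-sampling counts).
    Deterministic given ``seed``.
    """
    k_range = tuple(k_range)
    x = norm.logexpr.values
    samples = norm.sample_ids
    n = len(samples)
    if n < max(k_range) + 1:
        raise ConsensusError(f"need at least {max(k_range) + 1} samples, got {n}")
    _pearson_distance(x) if metric == "pearson" else None  # fail fast on constants

    n_draw = math.floor(item_fraction * n)
    if n_draw < max(k_range):
        raise ConsensusError("item_fraction too small for largest k")
    rng = np.random.default_rng(seed)

    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    co_sample = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=n_draw, replace=False))
        co_sample[np.ix_(idx, idx)] += 1.0
        z = _linkage_tree(x[:, idx], metric, method)
        for k in k_range:
            lab = fcluster(z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same

    M, I = {}, {}
    for k in k_range:
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(co_sample > 0, co_cluster[k] / co_sample, 0.0)
        M[k] = pd.DataFrame(m, index=samples, columns=samples)
        I[k] = pd.DataFrame(co_sample.copy(), index=samples, columns=samples)
    return ConsensusResult(k_range=k_range, M=M, I=I)


def cdf_area(M: pd.DataFrame) -> float:
    """Area under the empirical CDF of off-diagonal consensus entries.

    Computed exactly as the step integral of the ECDF over [0, 1]: an
    all-ones matrix gives 0 (all mass at 1), an all-zeros matrix gives 1.
    """
    m = np.asarray(M)
    vals = m[np.triu_indices(m.shape[0], k=1)]
    if vals.size == 0:
        raise ConsensusError("consensus matrix has no off-diagonal entries")
    xs = np.sort(vals)
    grid = np.unique(np.concatenate([[0.0], xs, [1.0]]))
    cdf = np.searchsorted(xs, grid, side="right") / xs.size
    # integral of the right-continuous step function over [0, 1]
    return float(np.sum(np.diff(grid) * cdf[:-1]))


def select_k_elbow(A: dict) -> int:
    """Elbow selection on the CDF-area curve.

    With the curve anchored at A(1) := 0, the elbow is the interior k whose
    point (k, A(k)) deviates most (vertically) from the chord joining (1, 0)
    to (k_max, A(k_max)) -- the classical knee criterion: A(k) rises steeply
    up to the true cluster count and plateaus beyond it, so the deviation
    peaks where the marginal gain collapses. Ties go to the smallest k; a
    perfectly linear curve therefore yields the smallest interior k.
    """
    ks = sorted(A)
    if len(ks) < 3:
        raise ConsensusError("k range must cover at least 3 values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ConsensusError("k range must be contiguous")
    k0, a0 = 1, 0.0
    k1, a1 = ks[-1], A[ks[-1]]
    slope = (a1 - a0) / (k1 - k0)
    candidates = [k for k in ks if k < k1]
    best = max(
        candidates, key=lambda k: (A[k] - (a0 + slope * (k - k0)), -k)
    )
    return int(best)


def final_labels(M: pd.DataFrame, k: int, method: str = "average") -> pd.Series:
    """Cluster the consensus matrix itself and renumber clusters canonically.

    Average-linkage hierarchical clustering on 1 - M cut at k; cluster ids are
    renumbered 1..k by decreasing size, ties by the lexicographically smallest
    member sample id, so the labeling is invariant to seed-induced
    permutations.
    """
    d = 1.0 - np.asarray(M, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method=method)
    raw = fcluster(z, t=k, criterion="maxclust")
    samples = M.index
    order = sorted(
        set(raw),
        key=lambda c: (-(raw == c).sum(), min(str(s) for s in samples[raw == c])),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([remap[c] for c in raw], index=samples, name="cluster")


def discover_subtypes(
    norm: NormalizedMatrix,
    k_range=range(2, 9),
    n_resamples: int = 1000,
    item_fraction: float = 0.8,
    seed: int = 0,
    metric: str = "pearson",
    method: str = "average",
    selector: str = "elbow",
    pac_bounds: tuple = (0.1, 0.9),
) -> ConsensusResult:
    """End-to-end discovery: consensus matrices, A(k), k selection, labels.

    ``selector`` is "elbow" (default) or "pac" (minimize the proportion of
    ambiguous consensus entries inside ``pac_bounds``).
    """
    res = consensus_cluster(
        norm, k_range, n_resamples, item_fraction, seed, metric, method
    )
    res.A = {k: cdf_area(res.M[k]) for k in res.k_range}
    if selector == "elbow":
        res.k_star = select_k_elbow(res.A)
    elif selector == "pac":
        lo, hi = pac_bounds
        pac = {}
        for k in res.k_range:
            m = res.M[k].values
            vals = m[np.triu_indices(m.shape[0], k=1)]
            pac[k] = float(np.mean((vals > lo) & (vals < hi)))
        res.k_star = min(res.k_range, key=lambda k: (pac[k], k))
    else:
        raise ConsensusError(f"unknown selector: {selector}")
    res.labels = final_labels(res.M[res.k_star], res.k_star, method=method)
    return res
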
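"""Moderated differential expression between clusters and signature sets.

For each cluster pair, genes are tested by weighted least squares on the
cluster-indicator design with empirical-Bayes variance moderation: gene-wise
residual variances s_g^2 are shrunk toward a pooled prior s0^2 with prior
degrees of freedom d0, both estimated by moment matching on log s_g^2
(digamma/trigamma system, Newton-solved). The per-cluster over/under gene
signatures are the genes differentially expressed in the same direction
against *every* other cluster at the chosen FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


class SignatureError(ValueError):
    pass


@dataclass
class DEResult:
    contrast: tuple  # (a, b): logFC is a minus b
    table: pd.DataFrame  # per gene: logFC, sigma2, df, t_mod, p, q
    d0: float
    s0_sq: float

    def flipped(self) -> "DEResult":
        t = self.table.copy()
        t["logFC"] = -t["logFC"]
        t["t_mod"] = -t["t_mod"]
        return DEResult((self.contrast[1], self.contrast[0]), t, self.d0, self.s0_sq)


@dataclass
class SignatureSet:
    """2k derived gene sets named C{c}_over / C{c}_under, with DE provenance."""

    sets: dict  # name -> frozenset of gene ids
    provenance: pd.DataFrame = field(default=None, repr=False)
    q_threshold: float = 0.05
    lfc_threshold: float = 0.0

    def __getitem__(self, name):
        return self.sets[name]

    def names(self):
        return sorted(self.sets)

    @staticmethod
    def set_name(cluster: int, direction: str) -> str:
        return f"C{cluster}_{direction}"

    @staticmethod
    def parse_name(name: str) -> tuple:
        cluster, direction = name.split("_")
        return int(cluster[1:]), direction


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise SignatureError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple:
    """Moment-match (d0, s0^2) for the scaled inverse-chi-square variance prior.

    Under the hierarchical model, e_g = log s_g^2 - digamma(df/2) + log(df/2)
    has mean log s0^2 + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) beyond trigamma(df/2). If the observed variances are
    under-dispersed (no positive solution), falls back to d0 = 10 with a
    logged warning.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    ok = sigma2 > 0
    if ok.sum() < 2:
        raise SignatureError("need at least 2 positive gene variances")
    e = np.log(sigma2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
    else:
        logger.warning(
            "under-dispersed gene variances; falling back to prior df d0 = 10"
        )
        d0 = 10.0
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _weighted_group_fit(x: np.ndarray, w: np.ndarray, groups: np.ndarray):
    """Per-gene weighted means by group plus pooled weighted residual variance."""
    uniq = np.unique(groups)
    n, k = x.shape[1], len(uniq)
    means = {}
    wsums = {}
    rss = np.zeros(x.shape[0])
    for gname in uniq:
        cols = groups == gname
        wg = w[:, cols]
        xg = x[:, cols]
        wsum = wg.sum(axis=1)
        mu = (wg * xg).sum(axis=1) / wsum
        means[gname] = mu
        wsums[gname] = wsum
        rss += (wg * (xg - mu[:, None]) ** 2).sum(axis=1)
    df = n - k
    if df <= 0:
        raise SignatureError("zero residual degrees of freedom")
    sigma2 = rss / df
    return means, wsums, sigma2, df


def fit_moderated_de(
    norm: NormalizedMatrix,
    labels: pd.Series,
    contrast: tuple,
    d0: float = None,
    s0_sq: float = None,
) -> DEResult:
    """Moderated-t differential expression for one cluster contrast (a vs b).

    The indicator design spans *all* clusters present in ``labels`` so the
    residual variance pools over every group; the reported logFC and t are for
    the requested pair. ``d0`` / ``s0_sq`` may be injected (mainly for
    testing); by default they are estimated from the data.
    """
    a, b = contrast
    labels = labels.reindex(norm.sample_ids)
    if labels.isna().any():
        raise SignatureError("labels missing for some samples")
    for c in (a, b):
        if (labels == c).sum() < 2:
            raise SignatureError(f"cluster {c} has fewer than 2 samples")
    x = norm.logexpr.values
    w = norm.weights.values
    means, wsums, sigma2, df = _weighted_group_fit(x, w, labels.values)

    log_fc = means[a] - means[b]
    var_contrast = 1.0 / wsums[a] + 1.0 / wsums[b]

    if d0 is None or s0_sq is None:
        est_d0, est_s0 = estimate_prior(sigma2, df)
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq

    if np.isinf(d0):
        sigma2_mod = np.full_like(sigma2, s0_sq)
        df_total = np.inf
    else:
        sigma2_mod = (d0 * s0_sq + df * sigma2) / (d0 + df)
        df_total = d0 + df
    t_mod = log_fc / np.sqrt(sigma2_mod * var_contrast)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    q = bh_adjust(p)

    table = pd.DataFrame(
        {
            "logFC": log_fc,
            "sigma2": sigma2,
            "df": df,
            "t_mod": t_mod,
            "p": p,
            "q": q,
        },
        index=norm.kept_genes,
    )
    return DEResult(contrast=(a, b), table=table, d0=float(d0), s0_sq=float(s0_sq))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise SignatureError("p must be 1-D")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise SignatureError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def all_pairwise_de(norm: NormalizedMatrix, labels: pd.Series, **kwargs) -> dict:
    """DE results for every unordered cluster pair, keyed (a, b) with a < b."""
    clusters = sorted(pd.unique(labels.dropna()))
    return {
        (a, b): fit_moderated_de(norm, labels, (a, b), **kwargs)
        for a, b in combinations(clusters, 2)
    }


def derive_signatures(
    de_results: dict,
    q_threshold: float = 0.05,
    lfc_threshold: float = 0.0,
) -> SignatureSet:
    """Same-direction intersection of pairwise DE into per-cluster signatures.

    Gene g enters C{c}_over iff, against every other cluster j, the (c vs j)
    contrast has q < q_threshold and logFC > lfc_threshold; C{c}_under is the
    mirrored rule. A gene can qualify for at most one direction per cluster.
    """
    clusters = sorted({c for pair in de_results for c in pair})
    if len(clusters) < 2:
        raise SignatureError("need at least 2 clusters")
    expected = set(combinations(clusters, 2))
    have = {tuple(sorted(pair)) for pair in de_results}
    if expected - have:
        raise SignatureError(f"missing contrasts: {sorted(expected - have)}")

    oriented = {}
    for pair, res in de_results.items():
        oriented[pair] = res
        oriented[(pair[1], pair[0])] = res.flipped()

    sets = {}
    prov_rows = []
    for c in clusters:
        others = [j for j in clusters if j != c]
        tables = {j: oriented[(c, j)].table for j in others}
        genes = tables[others[0]].index
        sig = np.vstack([(tables[j]["q"] < q_threshold).values for j in others])
        up = np.vstack([(tables[j]["logFC"] > lfc_threshold).values for j in others])
        down = np.vstack(
            [(tables[j]["logFC"] < -lfc_threshold).values for j in others]
        )
        over_mask = (sig & up).all(axis=0)
        under_mask = (sig & down).all(axis=0)
        sets[SignatureSet.set_name(c, "over")] = frozenset(genes[over_mask])
        sets[SignatureSet.set_name(c, "under")] = frozenset(genes[under_mask])
        for direction, mask in (("over", over_mask), ("under", under_mask)):
            for g in genes[mask]:
                for j in others:
                    prov_rows.append(
                        {
                            "set": SignatureSet.set_name(c, direction),
                            "gene_id": g,
                            "contrast": f"{c}vs{j}",
                            "q": tables[j].loc[g, "q"],
                            "logFC": tables[j].loc[g, "logFC"],
                        }
                    )
    provenance = pd.DataFrame(
        prov_rows, columns=["set", "gene_id", "contrast", "q", "logFC"]
    )
    return SignatureSet(
        sets=sets,
        provenance=provenance,
        q_threshold=q_threshold,
        lfc_threshold=lfc_threshold,
    )
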
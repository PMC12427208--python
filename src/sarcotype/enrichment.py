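"""Single-sample gene-set enrichment scoring and subtype assignment.

Each sample's genes are ranked by descending expression; a gene set's
enrichment score (ES) is the summed difference between a rank-weighted
running hit fraction and the uniform miss fraction, so sets concentrated at
the top of the ranking score positive and sets at the bottom negative. ES is
standardized (NES) against a gene-permutation null and converted to a normal
two-sided p. A sample is assigned to the subtype of the signature set with
the most significant BH-adjusted p below the threshold, mirroring how
external cohorts are classified against discovered signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import SignatureSet, bh_adjust

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"
MIN_SET_SIZE = 5


class EnrichmentError(ValueError):
    pass


@dataclass
class SubtypeCall:
    sample_id: str
    assigned_cluster: object  # int or UNASSIGNED
    winning_set: str
    winning_q: float
    sign_concordant: bool


def _ranked(expr: pd.Series):
    """Gene order by descending expression, ties by ascending gene id."""
    ids = expr.index.to_numpy(dtype=object)
    order = np.lexsort((ids, -expr.to_numpy(dtype=float)))
    return ids[order]


def _es_from_hits(hit: np.ndarray, alpha: float) -> float:
    """ES for one ranked hit-indicator vector (positions already in rank order)."""
    n = hit.shape[-1]
    ranks = np.arange(1, n + 1)
    w = (n - ranks + 1.0) ** alpha
    wh = w * hit
    denom_hit = wh.sum(axis=-1, keepdims=True)
    m = hit.sum(axis=-1, keepdims=True)
    p_hit = np.cumsum(wh, axis=-1) / denom_hit
    p_miss = np.cumsum(1.0 - hit, axis=-1) / (n - m)
    return (p_hit - p_miss).sum(axis=-1)


def ssgsea_score(expr: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Weighted running-sum enrichment score of ``gene_set`` in one sample.

    With weight (N - r + 1)^alpha at rank r (1 = highest expression), ES is
    sum over ranks of P_hit - P_miss; alpha = 0 reduces to a pure rank
    statistic, invariant to monotone transforms of the expression values.
    """
    gene_set = set(gene_set) & set(expr.index)
    n = len(expr)
    if len(gene_set) == 0:
        raise EnrichmentError("gene set empty after intersecting with genes")
    if len(gene_set) >= n:
        raise EnrichmentError("gene set covers all genes; complement empty")
    ranked_ids = _ranked(expr)
    hit = np.isin(ranked_ids, list(gene_set)).astype(float)
    return float(_es_from_hits(hit, alpha))


class PermutationNull:
    """Gene-permutation null ES moments, cached by (n_genes, set size).

    Because ranks within a sample are always 1..N and the rank weights depend
    only on N and alpha, the null ES distribution for random gene sets is the
    same for every sample with N genes; moments are computed once per set
    size and reused.
    """

    def __init__(self, n_genes: int, alpha: float, n_perm: int, seed: int):
        if n_perm < 100:
            raise EnrichmentError("n_perm must be >= 100")
        self.n_genes = n_genes
        self.alpha = alpha
        self.n_perm = n_perm
        self.seed = seed
        self._cache = {}

    def moments(self, set_size: int) -> tuple:
        if set_size not in self._cache:
            rng = np.random.default_rng((self.seed, set_size))
            hit = np.zeros((self.n_perm, self.n_genes))
            for i in range(self.n_perm):
                pos = rng.choice(self.n_genes, size=set_size, replace=False)
                hit[i, pos] = 1.0
            es = _es_from_hits(hit, self.alpha)
            mean, sd = float(es.mean()), float(es.std(ddof=1))
            if sd <= 0:
                raise EnrichmentError("degenerate permutation null (sd = 0)")
            self._cache[set_size] = (mean, sd)
        return self._cache[set_size]


def nes_and_p(
    es: float,
    expr: pd.Series,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.25,
    null: PermutationNull = None,
) -> tuple:
    """Standardize an ES against the gene-permutation null.

    NES = (ES - null mean) / null sd; p = 2 * (1 - Phi(|NES|)). The null is
    shared across sets of identical size (and, by rank invariance, across
    samples with the same gene universe).
    """
    size = len(set(gene_set) & set(expr.index))
    if null is None:
        null = PermutationNull(len(expr), alpha, n_perm, seed)
    mean, sd = null.moments(size)
    nes = (es - mean) / sd
    p = 2.0 * stats.norm.sf(abs(nes))
    return float(nes), float(p)


def score_cohort(
    expr: pd.DataFrame,
    gene_sets: dict,
    alpha: float = 0.25,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """EnrichmentTable: (sample, set) rows with ES, NES, p.

    ``expr`` is genes x samples log-expression; ``gene_sets`` maps set name to
    an iterable of gene ids. Sets shrinking below MIN_SET_SIZE genes after
    intersecting with the cohort's genes are skipped with a warning.
    """
    usable = {}
    universe = set(expr.index)
    for name, genes in gene_sets.items():
        inter = set(genes) & universe
        if len(inter) < MIN_SET_SIZE:
            logger.warning(
                "gene set %s has %d gene(s) in the cohort (< %d); skipped",
                name, len(inter), MIN_SET_SIZE,
            )
            continue
        if len(inter) >= len(universe):
            raise EnrichmentError(f"gene set {name} covers all genes")
        usable[name] = inter
    if not usable:
        raise EnrichmentError("no usable gene sets after intersection")

    null = PermutationNull(expr.shape[0], alpha, n_perm, seed)
    rows = []
    ids = expr.index.to_numpy(dtype=object)
    for sample in expr.columns:
        col = expr[sample].to_numpy(dtype=float)
        order = np.lexsort((ids, -col))
        ranked_ids = ids[order]
        pos_of = {g: i for i, g in enumerate(ranked_ids)}
        for name in sorted(usable):
            hit = np.zeros(len(ids))
            hit[[pos_of[g] for g in usable[name]]] = 1.0
            es = float(_es_from_hits(hit, alpha))
            mean, sd = null.moments(len(usable[name]))
            nes = (es - mean) / sd
            p = 2.0 * stats.norm.sf(abs(nes))
            rows.append(
                {"sample_id": sample, "set": name, "ES": es, "NES": nes, "p": p}
            )
    table = pd.DataFrame(rows)
    table["null_n_perm"] = n_perm
    table["null_seed"] = seed
    return table


def classify_samples(
    enrich: pd.DataFrame,
    signature_names,
    threshold: float = 0.05,
    require_sign_concordance: bool = False,
) -> pd.DataFrame:
    """Assign each sample to the cluster of its most significant signature set.

    Per sample, p-values are BH-adjusted across *all* scored sets (signature
    plus any context sets), then context sets are discarded and the signature
    set with the smallest q wins if q < threshold; otherwise the sample is
    UNASSIGNED. Ties break on ascending set name. With sign concordance on, a
    set only qualifies when its NES sign matches its direction (negative for
    _under, positive for _over).
    """
    signature_names = sorted(set(signature_names))
    if not signature_names:
        raise EnrichmentError("no signature sets supplied")
    missing = set(signature_names) - set(enrich["set"])
    if missing:
        raise EnrichmentError(f"signature sets not scored: {sorted(missing)}")
    calls = []
    for sample, sub in enrich.groupby("sample_id", sort=True):
        sub = sub.copy()
        sub["q"] = bh_adjust(sub["p"].values)
        sig = sub[sub["set"].isin(signature_names)].sort_values(
            ["q", "set"], kind="stable"
        )
        if require_sign_concordance:
            direction = sig["set"].map(lambda s: SignatureSet.parse_name(s)[1])
            concordant = np.where(direction == "under", sig["NES"] < 0, sig["NES"] > 0)
            sig = sig[concordant]
        if len(sig) and sig["q"].iloc[0] < threshold:
            win = sig.iloc[0]
            cluster, direction = SignatureSet.parse_name(win["set"])
            concord = win["NES"] < 0 if direction == "under" else win["NES"] > 0
            calls.append(
                {
                    "sample_id": sample,
                    "assigned_cluster": cluster,
                    "winning_set": win["set"],
                    "winning_q": win["q"],
                    "sign_concordant": bool(concord),
                }
            )
        else:
            calls.append(
                {
                    "sample_id": sample,
                    "assigned_cluster": UNASSIGNED,
                    "winning_set": "",
                    "winning_q": np.nan,
                    "sign_concordant": False,
                }
            )
    return pd.DataFrame(calls).set_index("sample_id")
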
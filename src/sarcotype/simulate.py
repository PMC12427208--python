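"""Synthetic sarcoma expression cohorts with planted transcriptomic subtypes.

The generator emulates the statistical structure the discovery pipeline
assumes: negative-binomial RNA-seq counts with disjoint per-subtype blocks of
over- and under-expressed marker genes, subtype-dependent exponential
survival with administrative and dropout censoring, routine clinical
covariates, a noisy external 5-year overall-survival risk score on the
probability scale, and an external comparator gene list with a controlled
overlap with one planted signature. Every downstream stage (normalization,
consensus clustering, signature derivation, single-sample enrichment
classification, survival benchmarking) is therefore testable without any
external download.

All randomness flows from the single integer seed in :class:`CohortConfig`
through one ``numpy.random.Generator``; identical configs give byte-identical
cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import CountMatrix

HISTOTYPES = ("DDLPS", "LMS", "UPS")

# subtype-conditional histotype frequencies loosely following the composition
# of high-grade sarcoma cohorts (subtype 1 liposarcoma-heavy, the rest
# dominated by undifferentiated pleomorphic sarcoma)
_HISTO_PROBS = np.array(
    [
        [0.52, 0.19, 0.29],
        [0.13, 0.29, 0.58],
        [0.05, 0.10, 0.85],
        [0.11, 0.22, 0.67],
    ]
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for a synthetic cohort.

    Hazards are per-month exponential death rates, one per subtype; the
    defaults give a favorable subtype 1 (median OS ~69 months) against three
    unfavorable subtypes (median OS 20-25 months), mirroring the prognostic
    separation the classifier is meant to recover. The external
    ``risk_score_5yOS`` emulates a nomogram's 5-year survival probability:
    exp(-60 * hazard) plus Gaussian noise, clipped to [0, 1].
    """

    n_samples: int = 120
    n_subtypes: int = 4
    subtype_proportions: tuple = None
    n_genes: int = 1500
    markers_per_subtype_per_direction: int = 40
    log2_effect: float = 2.0
    nb_dispersion: float = 0.1
    libsize_log_mean: float = math.log(2e5)
    libsize_log_sd: float = 0.3
    hazards_per_month: tuple = (0.010, 0.030, 0.028, 0.035)
    admin_censor_months: float = 120.0
    dropout_rate_per_month: float = 0.005
    recurrence_hazard_ratio: float = 1.6
    risk_score_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_genes < 1 or self.n_subtypes < 1:
            raise SimulationError("counts must be >= 1")
        props = self.subtype_proportions
        if props is None:
            props = tuple([1.0 / self.n_subtypes] * self.n_subtypes)
            object.__setattr__(self, "subtype_proportions", props)
        if len(props) != self.n_subtypes:
            raise SimulationError("subtype_proportions length != n_subtypes")
        if abs(sum(props) - 1.0) > 1e-8:
            raise SimulationError("subtype_proportions must sum to 1 (tol 1e-8)")
        if len(self.hazards_per_month) != self.n_subtypes:
            raise SimulationError("hazards_per_month length != n_subtypes")
        if any(h <= 0 for h in self.hazards_per_month):
            raise SimulationError("hazards must be > 0")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be > 0")
        if self.log2_effect < 0 or self.dropout_rate_per_month < 0:
            raise SimulationError("log2_effect and dropout rate must be >= 0")
        n_marker = 2 * self.n_subtypes * self.markers_per_subtype_per_direction
        if n_marker > self.n_genes:
            raise SimulationError("marker blocks exceed n_genes")


@dataclass
class SyntheticCohort:
    counts: CountMatrix
    clinical: pd.DataFrame
    truth: pd.Series
    planted_markers: dict  # (subtype, "over"|"under") -> frozenset of gene ids
    config: CohortConfig = field(repr=False, default=None)

    @property
    def marker_genes(self) -> frozenset:
        out = set()
        for genes in self.planted_markers.values():
            out |= genes
        return frozenset(out)


def _subtype_counts(props, n) -> np.ndarray:
    """Largest-remainder apportionment of n samples to subtype proportions."""
    raw = np.asarray(props) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def gen_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``config``.

    Counts: gene g in sample s is negative-binomial with mean
    mu = libsize_s * base_g * 2^(+-log2_effect on markers) and variance
    mu + dispersion * mu^2 (gamma-Poisson mixture). Survival: death time
    exponential with the sample's subtype hazard, censored at
    min(administrative horizon, exponential dropout); DFS is
    min(recurrence, death) with recurrence hazard a fixed multiple of the
    death hazard, under the same censoring.
    """
    rng = np.random.default_rng(config.seed)
    n, g, k = config.n_samples, config.n_genes, config.n_subtypes
    m = config.markers_per_subtype_per_direction

    gene_ids = pd.Index([f"G{i:04d}" for i in range(g)], name="gene_id")
    sample_ids = pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id")

    # subtype labels: deterministic apportionment, then a seeded shuffle
    sizes = _subtype_counts(config.subtype_proportions, n)
    labels = np.repeat(np.arange(1, k + 1), sizes)
    rng.shuffle(labels)
    truth = pd.Series(labels, index=sample_ids, name="subtype")

    # disjoint marker blocks laid out at the head of the gene index
    planted = {}
    pos = 0
    for c in range(1, k + 1):
        for direction in ("over", "under"):
            planted[(c, direction)] = frozenset(gene_ids[pos : pos + m])
            pos += m

    # baseline relative abundances (lognormal), normalized to proportions
    base = rng.lognormal(mean=0.0, sigma=1.2, size=g)
    base /= base.sum()

    # per-(gene, subtype) fold factors
    fold = np.ones((g, k))
    eff = 2.0 ** config.log2_effect
    for c in range(1, k + 1):
        over_idx = gene_ids.get_indexer(sorted(planted[(c, "over")]))
        under_idx = gene_ids.get_indexer(sorted(planted[(c, "under")]))
        fold[over_idx, c - 1] = eff
        fold[under_idx, c - 1] = 1.0 / eff

    libsize = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n)
    mu = base[:, None] * fold[:, labels - 1] * libsize[None, :]

    # NB(mean mu, var mu + phi mu^2) as Poisson with Gamma(1/phi, phi*mu) rate
    phi = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    values = rng.poisson(lam)
    counts = CountMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))

    haz = np.asarray(config.hazards_per_month)[labels - 1]
    t_death = rng.exponential(1.0 / haz)
    t_recur = rng.exponential(1.0 / (config.recurrence_hazard_ratio * haz))
    if config.dropout_rate_per_month > 0:
        t_drop = rng.exponential(1.0 / config.dropout_rate_per_month, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(config.admin_censor_months, t_drop)

    os_months = np.minimum(t_death, t_cens)
    os_event = (t_death <= t_cens).astype(int)
    t_dfs = np.minimum(t_recur, t_death)
    dfs_months = np.minimum(t_dfs, t_cens)
    dfs_event = (t_dfs <= t_cens).astype(int)

    age = np.clip(np.round(rng.normal(66.0, 12.0, size=n), 1), 25.0, 92.0)
    histo_p = _HISTO_PROBS[(labels - 1) % _HISTO_PROBS.shape[0]]
    histo_draw = (rng.random(n)[:, None] > np.cumsum(histo_p, axis=1)).sum(axis=1)
    histotype = np.array(HISTOTYPES)[histo_draw]
    treated = (rng.random(n) < 0.6).astype(int)

    risk = np.exp(-60.0 * haz)
    if config.risk_score_noise_sd > 0:
        risk = risk + rng.normal(0.0, config.risk_score_noise_sd, size=n)
    risk = np.clip(risk, 0.0, 1.0)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "os_months": os_months,
            "os_event": os_event,
            "dfs_months": dfs_months,
            "dfs_event": dfs_event,
            "age_years": age,
            "histotype": histotype,
            "grade": 3,
            "treated": treated,
            "risk_score_5yOS": risk,
        }
    ).set_index("sample_id")

    return SyntheticCohort(
        counts=counts, clinical=clinical, truth=truth, planted_markers=planted,
        config=config,
    )


def gen_comparator_gene_list(
    cohort: SyntheticCohort,
    size: int,
    overlap_fraction: float,
    target: tuple,
    seed: int,
) -> list:
    """External comparator gene list with controlled signature overlap.

    Draws round(overlap_fraction * size) genes from the planted marker set
    named by ``target`` (a (subtype, direction) pair) and fills the rest from
    genes outside every planted block, emulating a published prognostic gene
    list that partially overlaps one discovered signature.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise SimulationError("overlap_fraction must be in [0, 1]")
    if target not in cohort.planted_markers:
        raise SimulationError(f"unknown target marker set: {target}")
    rng = np.random.default_rng(seed)
    n_overlap = round(overlap_fraction * size)
    markers = sorted(cohort.planted_markers[target])
    if n_overlap > len(markers):
        raise SimulationError(
            f"overlap demand ({n_overlap}) exceeds available markers ({len(markers)})"
        )
    nonmarkers = sorted(set(cohort.counts.gene_ids) - cohort.marker_genes)
    n_fill = size - n_overlap
    if n_fill > len(nonmarkers):
        raise SimulationError("not enough non-marker genes to fill the list")
    chosen = list(rng.choice(markers, size=n_overlap, replace=False))
    chosen += list(rng.choice(nonmarkers, size=n_fill, replace=False))
    return chosen


def null_config(config: CohortConfig = None, seed: int = 0) -> CohortConfig:
    """A copy of ``config`` with no planted expression effect (null cohort)."""
    cfg = config or CohortConfig()
    return replace(cfg, log2_effect=0.0, seed=seed)
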
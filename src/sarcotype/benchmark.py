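"""Prognostic-model comparison, risk-group sub-stratification, set overlap.

Candidate prognostic models (cluster labels, age, an external 5-year-OS risk
score, a comparator two-class signature, or any clinical column) are fitted
as Cox PH models and ranked by Harrell's C of the fitted linear predictor.
The default C is apparent (trained and evaluated on the same cohort, the
convention for single-cohort comparisons); a k-fold cross-validated C is
available for honest comparison and is labeled as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import survival as surv

logger = logging.getLogger(__name__)


class BenchmarkError(ValueError):
    pass


@dataclass
class ModelSpec:
    name: str
    covariates: list

    def __post_init__(self):
        if not self.covariates:
            raise BenchmarkError(f"model {self.name!r} has no covariates")


@dataclass
class BenchmarkReport:
    cindex: pd.DataFrame = None
    strata: dict = field(default_factory=dict)
    overlap: pd.DataFrame = None
    nes_corr: dict = field(default_factory=dict)


def compare_models(
    data: pd.DataFrame,
    specs: list,
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "efron",
    cv_folds: int = None,
    cv_seed: int = 0,
) -> pd.DataFrame:
    """Apparent (and optionally cross-validated) C-index per model spec.

    Each spec is fitted by Cox PH on the full cohort; Harrell's C of its
    linear predictor on the same cohort is reported, sorted descending. With
    ``cv_folds`` set, an additional c_index_cv column holds the C of
    out-of-fold linear predictors.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise BenchmarkError("duplicate model spec names")
    rows = []
    for spec in specs:
        try:
            fit = surv.cox_fit(
                data, time_col, event_col, covariates=spec.covariates, ties=ties
            )
        except surv.SurvivalError as exc:
            raise BenchmarkError(f"model {spec.name!r} failed to fit: {exc}") from exc
        lp = fit.linear_predictor()
        res = surv.concordance_index(data[time_col], data[event_col], lp)
        row = {
            "model": spec.name,
            "c_index": res.c,
            "n": fit.n,
            "n_events": fit.n_events,
            "n_pairs": res.n_pairs,
            "loglik": fit.loglik,
        }
        if cv_folds:
            row["c_index_cv"] = _cv_cindex(
                data, spec, time_col, event_col, ties, cv_folds, cv_seed
            )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("model")
    return out.sort_values("c_index", ascending=False, kind="stable")


def _cv_cindex(data, spec, time_col, event_col, ties, folds, seed) -> float:
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(data))
    lp = np.full(len(data), np.nan)
    for f in range(folds):
        test = idx[f::folds]
        train = np.setdiff1d(idx, test)
        fit = surv.cox_fit(
            data.iloc[train], time_col, event_col, spec.covariates, ties=ties
        )
        x_test, _ = surv.build_design(data.iloc[test], spec.covariates)
        lp[test] = x_test @ fit.beta.values
    res = surv.concordance_index(data[time_col], data[event_col], lp)
    return res.c


def substratify_by_risk(
    data: pd.DataFrame,
    risk_col: str,
    cluster_col: str,
    time_col: str = "time",
    event_col: str = "event",
    threshold: float = 0.60,
    grouping: str = "all-clusters",
) -> dict:
    """KM + log-rank per cluster group inside each nomogram risk stratum.

    Samples with predicted 5-year OS above ``threshold`` form the favorable
    stratum; the boundary value goes to the unfavorable stratum ("<= 60%").
    ``grouping`` is "all-clusters" or "C1-vs-rest" (cluster 1 against the
    pooled remainder). Empty groups are dropped with a warning.
    """
    risk = data[risk_col].to_numpy(dtype=float)
    if ((risk < 0) | (risk > 1)).any():
        raise BenchmarkError("risk score must lie in [0, 1]")
    strata = {
        "favorable": data[risk > threshold],
        "unfavorable": data[risk <= threshold],
    }
    if grouping not in ("all-clusters", "C1-vs-rest"):
        raise BenchmarkError(f"unknown grouping: {grouping}")
    out = {}
    n_nonempty = sum(len(d) > 0 for d in strata.values())
    for name, sub in strata.items():
        if len(sub) == 0:
            logger.warning("stratum %s is empty; dropped", name)
            continue
        clusters = sub[cluster_col]
        if grouping == "C1-vs-rest":
            groups = np.where(clusters.astype(str) == "1", "C1", "non-C1")
        else:
            groups = clusters.astype(str).to_numpy()
        sizes = {str(k): int(v) for k, v in pd.Series(groups).value_counts().items()}
        km = {
            g: surv.km_curve(
                sub.loc[groups == g, time_col], sub.loc[groups == g, event_col]
            )
            for g in sorted(sizes)
        }
        entry = {"n": len(sub), "group_sizes": sizes, "km": km}
        if len(sizes) >= 2 and sub[event_col].sum() > 0:
            chi2, df, p = surv.logrank_test(
                sub[time_col], sub[event_col], groups
            )
            entry.update({"chi2": chi2, "df": df, "p": p})
        else:
            if n_nonempty == 1:
                raise BenchmarkError(
                    "all samples in one stratum and grouping impossible"
                )
            logger.warning("stratum %s has a single group; no log-rank", name)
        out[name] = entry
    return out


def signature_overlap(set_a, set_b, universe=None) -> tuple:
    """Percent overlap (relative to the first set) and Jaccard index.

    The first argument is the comparator list, so %overlap = 100*|A&B|/|A|.
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise BenchmarkError("sets must be nonempty")
    if universe is not None:
        universe = set(universe)
        if not (a <= universe and b <= universe):
            raise BenchmarkError("sets must be subsets of the universe")
    inter = len(a & b)
    pct = 100.0 * inter / len(a)
    jaccard = inter / len(a | b)
    return pct, jaccard


def nes_correlation(enrich: pd.DataFrame, set_a: str, set_b: str) -> tuple:
    """Spearman rank correlation of two gene sets' per-sample NES vectors."""
    wide = enrich.pivot(index="sample_id", columns="set", values="NES")
    for s in (set_a, set_b):
        if s not in wide.columns:
            raise BenchmarkError(f"set not scored: {s}")
    x, y = wide[set_a].to_numpy(), wide[set_b].to_numpy()
    if len(x) < 3:
        raise BenchmarkError("need NES on at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise BenchmarkError("constant NES vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
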
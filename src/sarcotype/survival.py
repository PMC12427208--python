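"""Survival analysis machinery: Kaplan-Meier, log-rank, Cox PH, diagnostics.

The Cox model maximizes the Efron (default) or Breslow partial likelihood by
Newton-Raphson with step-halving; standard errors come from the observed
information at the optimum. Proportional-hazards diagnostics use the
Grambsch-Therneau score test on scaled Schoenfeld residuals. Harrell's
C-index is computed over censoring-comparable pairs with 0.5 credit for tied
risk scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class SurvivalError(ValueError):
    pass


class ConvergenceError(SurvivalError):
    pass


# ---------------------------------------------------------------------------
# design-matrix construction


def build_design(
    data: pd.DataFrame, covariates: list
) -> tuple:
    """Expand a covariate list into a numeric design matrix.

    String/categorical columns are reference-coded with the first sorted
    level as reference; numeric columns pass through. Returns (X, names).
    """
    cols = []
    names = []
    for cov in covariates:
        if cov not in data.columns:
            raise SurvivalError(f"covariate not in data: {cov}")
        col = data[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(map(str, pd.unique(col.astype(str))))
            for level in levels[1:]:
                cols.append((col.astype(str) == level).astype(float).values)
                names.append(f"{cov}[{level}]")
        else:
            cols.append(col.astype(float).values)
            names.append(cov)
    if not cols:
        raise SurvivalError("empty covariate list")
    x = np.column_stack(cols)
    if not np.isfinite(x).all():
        raise SurvivalError("non-finite values in design matrix")
    return x, names


def _factor_df(data: pd.DataFrame, covariates: list) -> int:
    """Number of design columns a covariate block expands to."""
    return build_design(data, covariates)[0].shape[1]


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def km_curve(time, event) -> pd.DataFrame:
    """Product-limit survival estimate with risk/event counts per event time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise SurvivalError("no records")
    if (time <= 0).any() or not np.isfinite(time).all():
        raise SurvivalError("times must be finite and positive")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    rows = []
    s = 1.0
    n_at_risk = time.size
    for t in np.unique(time):
        mask = time == t
        d = int(event[mask].sum())
        c = int((~event[mask].astype(bool)).sum())
        if d > 0:
            s *= 1.0 - d / n_at_risk
        rows.append(
            {"time": t, "n_risk": n_at_risk, "n_event": d, "n_censor": c, "S": s}
        )
        n_at_risk -= d + c
    return pd.DataFrame(rows)


def logrank_test(time, event, group):
    """k-group log-rank test: sum (O - E) with hypergeometric variance.

    Returns (chi2, df, p) with df = #groups - 1. Rank-based: invariant to any
    strictly monotone transform of time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    k = len(levels)
    if k < 2:
        raise SurvivalError("log-rank requires at least 2 groups")
    if event.sum() == 0:
        raise SurvivalError("log-rank requires at least 1 event")
    gidx = np.searchsorted(levels, group)
    o_minus_e = np.zeros(k)
    var = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        d = int(((time == t) & (event == 1)).sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(
            gidx[(time == t) & (event == 1)], minlength=k
        ).astype(float)
        e_g = d * n_g / n
        o_minus_e += d_g - e_g
        if n > 1:
            frac = n_g / n
            v = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            var += v
    u = o_minus_e[:-1]
    v = var[:-1, :-1]
    chi2 = float(u @ np.linalg.pinv(v) @ u)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    beta: pd.Series
    se: pd.Series
    loglik: float
    loglik_null: float
    ties: str
    cov: np.ndarray = field(repr=False)
    n: int = 0
    n_events: int = 0
    # internals retained for diagnostics
    _x: np.ndarray = field(default=None, repr=False)
    _time: np.ndarray = field(default=None, repr=False)
    _event: np.ndarray = field(default=None, repr=False)

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.beta).rename("HR")

    @property
    def ci95(self) -> pd.DataFrame:
        lo = np.exp(self.beta - 1.96 * self.se)
        hi = np.exp(self.beta + 1.96 * self.se)
        return pd.DataFrame({"lower": lo, "upper": hi})

    @property
    def wald_p(self) -> pd.Series:
        z = self.beta / self.se
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(z)), index=self.beta.index, name="p"
        )

    def linear_predictor(self) -> np.ndarray:
        return self._x @ self.beta.values

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "HR": self.hr,
                "ci_lower": self.ci95["lower"],
                "ci_upper": self.ci95["upper"],
                "p": self.wald_p,
            }
        )
        return out


def _cox_quantities(x, time, event, beta, ties):
    """Partial log-likelihood, score vector, and information matrix."""
    n, p = x.shape
    eta = x @ beta
    # guard against overflow in exp for wild steps
    eta = np.clip(eta, -500, 500)
    r = np.exp(eta)
    order = np.argsort(-time, kind="stable")  # descending time
    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    idx = order
    while i < n:
        t = time[idx[i]]
        j = i
        tied = []
        while j < n and time[idx[j]] == t:
            tied.append(idx[j])
            j += 1
        for m in tied:  # enter the risk set
            s0 += r[m]
            s1 += r[m] * x[m]
            s2 += r[m] * np.outer(x[m], x[m])
        deaths = [m for m in tied if event[m] == 1]
        d = len(deaths)
        if d > 0:
            sd0 = sum(r[m] for m in deaths)
            sd1 = sum(r[m] * x[m] for m in deaths)
            sd2 = sum(r[m] * np.outer(x[m], x[m]) for m in deaths)
            for m in deaths:
                loglik += eta[m]
            for l in range(d):
                f = l / d if ties == "efron" else 0.0
                den = s0 - f * sd0
                xbar = (s1 - f * sd1) / den
                v = (s2 - f * sd2) / den - np.outer(xbar, xbar)
                loglik -= np.log(den)
                score -= xbar
                info += v
            for m in deaths:
                score += x[m]
        i = j
    return loglik, score, info


def cox_fit(
    data: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    covariates: list = None,
    ties: str = "efron",
    max_iter: int = 50,
) -> CoxFit:
    """Newton-Raphson Cox PH fit with Efron (default) or Breslow ties.

    Converges when max |score| < 1e-9 or the relative log-likelihood change
    drops below 1e-12; halves the step whenever the log-likelihood would
    decrease. Factors are reference-coded (first sorted level).
    """
    if ties not in ("efron", "breslow"):
        raise SurvivalError(f"unknown ties method: {ties}")
    time = data[time_col].to_numpy(dtype=float)
    event = data[event_col].to_numpy(dtype=int)
    if (time <= 0).any() or not np.isfinite(time).all():
        raise SurvivalError("times must be finite and positive")
    if not np.isin(event, [0, 1]).all():
        raise SurvivalError("event indicator must be 0/1")
    if event.sum() == 0:
        raise SurvivalError("no events")
    x, names = build_design(data, covariates)
    if x.std(axis=0).min() == 0:
        bad = [names[i] for i in np.flatnonzero(x.std(axis=0) == 0)]
        raise SurvivalError(f"constant covariate(s): {bad}")

    p = x.shape[1]
    beta = np.zeros(p)
    loglik, score, info = _cox_quantities(x, time, event, beta, ties)
    loglik_null = loglik
    for _ in range(max_iter):
        if np.abs(score).max() < 1e-9:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular information matrix")
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_quantities(x, time, event, new_beta, ties)
        halvings = 0
        while new_ll < loglik and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_quantities(
                x, time, event, new_beta, ties
            )
            halvings += 1
        if halvings == 30:
            raise ConvergenceError(
                "step-halving failed; possible perfect separation"
            )
        rel = abs(new_ll - loglik) / max(abs(loglik), 1.0)
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if rel < 1e-12:
            break
    else:
        if np.abs(score).max() >= 1e-6:
            raise ConvergenceError(f"no convergence after {max_iter} iterations")
    if np.abs(beta).max() > 15:
        # log-hazard ratios this large only arise when the covariate
        # perfectly orders the risk sets and beta diverges
        raise ConvergenceError(
            "coefficient diverged (|beta| > 15); perfect separation suspected"
        )
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        beta=pd.Series(beta, index=names, name="coef"),
        se=pd.Series(se, index=names, name="se"),
        loglik=float(loglik),
        loglik_null=float(loglik_null),
        ties=ties,
        cov=cov,
        n=len(time),
        n_events=int(event.sum()),
        _x=x,
        _time=time,
        _event=event,
    )


def cox_score_test(
    data: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    covariates: list = None,
    ties: str = "breslow",
) -> tuple:
    """Score (Rao) test of beta = 0; equals the log-rank chi-square for a
    single binary covariate with Breslow ties and untied event times."""
    time = data[time_col].to_numpy(dtype=float)
    event = data[event_col].to_numpy(dtype=int)
    x, names = build_design(data, covariates)
    _, score, info = _cox_quantities(x, time, event, np.zeros(x.shape[1]), ties)
    chi2 = float(score @ np.linalg.solve(info, score))
    df = x.shape[1]
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Schoenfeld residuals / proportional-hazards test


def _schoenfeld_residuals(fit: CoxFit):
    """Per-event-subject Schoenfeld residuals, risk-set covariances, times."""
    x, time, event = fit._x, fit._time, fit._event
    beta = fit.beta.values
    r = np.exp(np.clip(x @ beta, -500, 500))
    event_times = []
    resid = []
    vs = []
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        rr = r[at_risk]
        xx = x[at_risk]
        s0 = rr.sum()
        xbar = (rr[:, None] * xx).sum(axis=0) / s0
        xc = xx - xbar
        v = (rr[:, None, None] * (xc[:, :, None] * xc[:, None, :])).sum(axis=0) / s0
        for m in np.flatnonzero((time == t) & (event == 1)):
            event_times.append(t)
            resid.append(x[m] - xbar)
            vs.append(v)
    return np.array(event_times), np.array(resid), np.array(vs)


def schoenfeld_ph_test(fit: CoxFit, transform: str = "identity") -> pd.DataFrame:
    """Grambsch-Therneau test of time trend in scaled Schoenfeld residuals.

    ``transform`` maps event times to the trend axis: "identity" (default) or
    "km" (1 - left-continuous KM estimate at the event time). Returns one row
    per covariate (rho, chi2, p) plus a GLOBAL row (rho = NaN).
    """
    times, s, vs = _schoenfeld_residuals(fit)
    d = len(times)
    if d < 2:
        raise SurvivalError("PH test requires at least 2 events")
    if transform == "identity":
        g = times.astype(float)
    elif transform == "km":
        km = km_curve(fit._time, fit._event)
        surv = np.concatenate([[1.0], km["S"].values[:-1]])
        lookup = dict(zip(km["time"].values, surv))
        g = np.array([1.0 - lookup[t] for t in times])
    else:
        raise SurvivalError(f"unknown transform: {transform}")
    ghat = g - g.mean()
    gss = float((ghat**2).sum())
    vbar = vs.mean(axis=0)
    vbar_inv = np.linalg.pinv(vbar)
    scaled = d * (s @ vbar_inv) + fit.beta.values[None, :]

    rows = []
    u = ghat @ s  # p-vector
    for j, name in enumerate(fit.beta.index):
        chi2_j = float(u[j] ** 2 / (gss * vbar[j, j]))
        rj = scaled[:, j]
        denom = np.sqrt(gss * ((rj - rj.mean()) ** 2).sum())
        rho = float((ghat @ (rj - rj.mean())) / denom) if denom > 0 else np.nan
        rows.append(
            {
                "covariate": name,
                "rho": rho,
                "chi2": chi2_j,
                "df": 1,
                "p": float(stats.chi2.sf(chi2_j, 1)),
            }
        )
    chi2_g = float(u @ np.linalg.pinv(gss * vbar) @ u)
    p_dim = len(fit.beta)
    rows.append(
        {
            "covariate": "GLOBAL",
            "rho": np.nan,
            "chi2": chi2_g,
            "df": p_dim,
            "p": float(stats.chi2.sf(chi2_g, p_dim)),
        }
    )
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# sequential ANOVA and concordance


def cox_anova(
    data: pd.DataFrame,
    time_col: str,
    event_col: str,
    blocks: list,
    ties: str = "efron",
) -> pd.DataFrame:
    """Sequential likelihood-ratio tests over nested covariate blocks.

    Block i is tested by 2 * [loglik(blocks <= i) - loglik(blocks < i)] with
    df = number of design columns the block adds.
    """
    rows = []
    prev_ll = None
    cum = []
    for block in blocks:
        cum = cum + list(block)
        fit = cox_fit(data, time_col, event_col, covariates=cum, ties=ties)
        if prev_ll is None:
            prev_ll = fit.loglik_null
        df = _factor_df(data, block)
        chi2 = 2.0 * (fit.loglik - prev_ll)
        rows.append(
            {
                "block": "+".join(map(str, block)),
                "df": df,
                "chi2": chi2,
                "p": float(stats.chi2.sf(chi2, df)),
                "loglik": fit.loglik,
            }
        )
        prev_ll = fit.loglik
    return pd.DataFrame(rows).set_index("block")


@dataclass
class ConcordanceResult:
    c: float
    n_pairs: int
    concordant: float
    discordant: float
    tied: float


def concordance_index(time, event, score) -> ConcordanceResult:
    """Harrell's C over comparable pairs (higher score = higher risk).

    Pair (i, j) is usable iff time_i < time_j and subject i had the event;
    concordant when the earlier failure carries the higher score; tied scores
    count 0.5.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    score = np.asarray(score, dtype=float)
    usable = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    n_pairs = int(usable.sum())
    if n_pairs == 0:
        raise SurvivalError("no comparable pairs")
    higher = score[:, None] > score[None, :]
    tied = score[:, None] == score[None, :]
    concordant = float((usable & higher).sum())
    n_tied = float((usable & tied).sum())
    c = (concordant + 0.5 * n_tied) / n_pairs
    return ConcordanceResult(
        c=float(c),
        n_pairs=n_pairs,
        concordant=concordant,
        discordant=n_pairs - concordant - n_tied,
        tied=n_tied,
    )
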
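"""Survival analysis: follow-up cleaning, Kaplan–Meier, log-rank, Cox models,
proportional-hazards diagnostics and the cohort screening rule.

Follow-up is cleaned the way pancancer overall-survival analyses do it:
samples with under one day of follow-up are dropped and everything beyond a
10-year horizon is administratively censored.  Strata produced by the
signature clustering are compared high vs low with a log-rank test and a Cox
hazard ratio; cohorts qualify for marker selection when the comparison is
significant (p < 0.05), reasonably sized (N1 + N2 > 100) and both strata have
events.

``cox_fit`` is a Newton–Raphson maximizer of the Cox partial likelihood with
Efron (default) or Breslow tie handling; the Breslow variant is needed for
closed-form verification and is cross-checked against lifelines in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import proportional_hazard_test as _ll_ph_test
from scipy.stats import chi2, norm

from .datatypes import SurvivalTable

DAYS_PER_YEAR = 365  # 10 years = 3650 days


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray  # S(t) at each event time, non-increasing, S(0)=1
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        mask = self.times <= t
        return float(self.survival[mask][-1]) if mask.any() else 1.0


@dataclass
class CoxFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    ties: str
    converged: bool
    n: int
    n_events: int
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.beta - 1.959963984540054 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.beta + 1.959963984540054 * self.se)

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "HR": self.hr,
                "se": self.se,
                "HR_ci_lower": self.ci_lower,
                "HR_ci_upper": self.ci_upper,
                "p": self.p,
            },
            index=self.names,
        )


@dataclass
class CohortComparison:
    cohort: str
    n_high: int
    n_low: int
    events_high: int
    events_low: int
    hr: float
    ci_lower: float
    ci_upper: float
    p_logrank: float
    p_wald: float
    excluded_reason: str | None = None


@dataclass
class PHTestResult:
    table: pd.DataFrame  # per covariate: test statistic and p
    global_stat: float
    global_p: float
    time_transform: str


def clean_followup(
    t: SurvivalTable, min_days: float = 1.0, horizon_years: float = 10.0
) -> SurvivalTable:
    """Drop follow-up under ``min_days``; administratively censor at the horizon."""
    horizon = horizon_years * DAYS_PER_YEAR
    df = t.data.copy()
    df = df.loc[df["time_days"] >= min_days]
    if df.empty:
        raise ValueError("no samples left after follow-up cleaning")
    over = df["time_days"] > horizon
    df.loc[over, "time_days"] = horizon
    df.loc[over, "event"] = 0
    return SurvivalTable(df.reset_index(drop=True))


def km_estimate(t: SurvivalTable) -> KMCurve:
    """Product-limit survival estimate."""
    if len(t) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(t.time, event_observed=t.event)
    tab = kmf.event_table
    times = tab.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"].to_numpy()
    at_risk = tab["at_risk"].to_numpy(dtype=float)
    keep = times > 0
    return KMCurve(times=times[keep], survival=sf[keep], at_risk=at_risk[keep])


def logrank_test(group_a: SurvivalTable, group_b: SurvivalTable):
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if group_a.event.sum() + group_b.event.sum() == 0:
        raise ValueError("no events in either group; log-rank undefined")
    res = _ll_logrank(
        group_a.time, group_b.time,
        event_observed_A=group_a.event, event_observed_B=group_b.event,
    )
    return float(res.test_statistic), float(res.p_value)


def _partial_lik_derivs(beta, x, time, event, ties):
    """Log partial likelihood, score and information at ``beta``.

    Assumes rows sorted by ascending time.
    """
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta)
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    # cumulative risk-set sums from the end
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = n - 1
    while i >= 0:
        t_i = time[i]
        j = i
        while j >= 0 and time[j] == t_i:
            j -= 1
        # add tied block [j+1 .. i] to the risk set
        for l in range(j + 1, i + 1):
            S0 += w[l]
            S1 += w[l] * x[l]
            S2 += w[l] * np.outer(x[l], x[l])
        deaths = [l for l in range(j + 1, i + 1) if event[l] == 1]
        d = len(deaths)
        if d > 0:
            xd = x[deaths]
            wd = w[deaths]
            sum_xd = xd.sum(axis=0)
            ll += float(eta[deaths].sum())
            if ties == "breslow":
                ll -= d * np.log(S0)
                mu = S1 / S0
                score += sum_xd - d * mu
                info += d * (S2 / S0 - np.outer(mu, mu))
            else:  # efron
                D0 = wd.sum()
                D1 = (wd[:, None] * xd).sum(axis=0)
                D2 = (wd[:, None, None] * xd[:, :, None] * xd[:, None, :]).sum(axis=0)
                for l in range(d):
                    f = l / d
                    R0 = S0 - f * D0
                    R1 = S1 - f * D1
                    R2 = S2 - f * D2
                    ll -= np.log(R0)
                    mu = R1 / R0
                    score += sum_xd / d - mu
                    info += R2 / R0 - np.outer(mu, mu)
        i = j
    return ll, score, info


def cox_fit(
    X: pd.DataFrame,
    t: SurvivalTable,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxFit:
    """Cox proportional-hazards fit via Newton–Raphson on the partial likelihood.

    ``X`` rows must align with ``t`` rows.  Raises on constant covariates and
    singular information; warns (and reports the diverged coefficient) on
    monotone likelihood.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    x = np.asarray(X, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(x.shape[1])]
    if x.shape[0] != len(t):
        raise ValueError("covariate rows and survival rows differ")
    if (x.std(axis=0) == 0).any():
        bad = [names[i] for i in range(x.shape[1]) if x[:, i].std() == 0]
        raise ValueError(f"constant covariate(s): {bad}")
    order = np.argsort(t.time, kind="stable")
    xs = x[order]
    time = t.time[order]
    event = t.event[order]
    center = xs.mean(axis=0)
    xs = xs - center

    beta = np.zeros(x.shape[1])
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        ll, score, info = _partial_lik_derivs(beta, xs, time, event, ties)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular information matrix (collinear covariates?)"
            ) from exc
        # step-halving safeguard
        alpha = 1.0
        for _h in range(30):
            cand = beta + alpha * step
            ll_new, _, _ = _partial_lik_derivs(cand, xs, time, event, ties)
            if ll_new >= ll - 1e-12:
                break
            alpha /= 2.0
        beta = beta + alpha * step
        if np.abs(score).max() < 1e-8 and abs(ll - ll_old) < tol * (abs(ll) + 1):
            converged = True
            break
        ll_old = ll
    ll, score, info = _partial_lik_derivs(beta, xs, time, event, ties)
    if np.abs(score).max() < 1e-8:
        converged = True
    if np.abs(beta).max() > 15:  # |HR| beyond ~3e6: monotone likelihood
        warnings.warn(
            "diverging coefficient; likely monotone likelihood / complete separation",
            stacklevel=2,
        )
        converged = False
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular information matrix at optimum") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    frame = pd.DataFrame(x, columns=names)
    frame["time_days"] = t.time
    frame["event"] = t.event
    return CoxFit(
        names=names, beta=beta, se=se, loglik=float(ll), ties=ties,
        converged=converged, n=len(t), n_events=int(event.sum()), _frame=frame,
    )


def ph_test(fit: CoxFit, time_transform: str = "km") -> PHTestResult:
    """Proportional-hazards diagnostic: scaled Schoenfeld residuals vs
    transformed time (score-type test per covariate).

    The global statistic sums the per-covariate chi-squares (df = number of
    covariates); it ignores cross-covariate covariance and is a screening
    approximation.
    """
    if fit._frame is None:
        raise ValueError("fit does not carry its data")
    if fit.n_events < 2:
        raise ValueError("need >= 2 events for the PH test")
    cph = CoxPHFitter()
    cph.fit(fit._frame, duration_col="time_days", event_col="event")
    res = _ll_ph_test(cph, fit._frame, time_transform=time_transform)
    tab = res.summary.copy()
    tab.index = [ix[0] if isinstance(ix, tuple) else ix for ix in tab.index]
    stat = float(tab["test_statistic"].sum())
    df = len(tab)
    return PHTestResult(
        table=tab,
        global_stat=stat,
        global_p=float(chi2.sf(stat, df)),
        time_transform=time_transform,
    )


def compare_strata(
    strata: pd.Series, t: SurvivalTable, cohort: str = "cohort"
) -> CohortComparison:
    """High vs low stratum survival comparison (medium excluded).

    HR comes from a univariate Cox fit on the high-vs-low indicator; the
    primary p-value from the log-rank test.  A stratum without events is
    flagged rather than tested (feeds the screening rule).
    """
    high_ids = list(strata.index[strata == "high"])
    low_ids = list(strata.index[strata == "low"])
    if not high_ids or not low_ids:
        raise ValueError("both high and low strata must be non-empty")
    t_high = t.subset(high_ids)
    t_low = t.subset(low_ids)
    ev_h, ev_l = int(t_high.event.sum()), int(t_low.event.sum())
    base = dict(
        cohort=cohort, n_high=len(t_high), n_low=len(t_low),
        events_high=ev_h, events_low=ev_l,
    )
    if ev_h == 0 or ev_l == 0:
        return CohortComparison(
            **base, hr=np.nan, ci_lower=np.nan, ci_upper=np.nan,
            p_logrank=np.nan, p_wald=np.nan,
            excluded_reason="no death events in one comparison group",
        )
    both = t.subset(high_ids + low_ids)
    indicator = both.data["sample_id"].isin(high_ids).astype(float)
    X = pd.DataFrame({"high_vs_low": indicator.to_numpy()})
    fit = cox_fit(X, both, ties="efron")
    _, p_lr = logrank_test(t_high, t_low)
    return CohortComparison(
        **base,
        hr=float(fit.hr[0]), ci_lower=float(fit.ci_lower[0]),
        ci_upper=float(fit.ci_upper[0]),
        p_logrank=p_lr, p_wald=float(fit.p[0]),
    )


def screen_cohorts(
    comparisons: list[CohortComparison],
    p_threshold: float = 0.05,
    min_samples: int = 100,
):
    """Keep cohorts where the stratum comparison is informative: both strata
    have events, p < threshold, and N1 + N2 > min_samples.

    Returns (selected list, exclusion log list of (cohort, reason)).
    """
    selected: list[CohortComparison] = []
    log: list[tuple[str, str]] = []
    for comp in comparisons:
        if comp.excluded_reason is not None:
            log.append((comp.cohort, comp.excluded_reason))
            continue
        if not (comp.p_logrank < p_threshold):
            log.append((comp.cohort, f"p={comp.p_logrank:.3g} >= {p_threshold}"))
            continue
        if not (comp.n_high + comp.n_low > min_samples):
            log.append(
                (comp.cohort, f"N1+N2={comp.n_high + comp.n_low} <= {min_samples}")
            )
            continue
        selected.append(comp)
    return selected, log


def encode_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categoricals (dropping the first level); parse ordered
    stage/grade to integers when possible."""
    out = {}
    for col in clinical.columns:
        s = clinical[col]
        if pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
            continue
        parsed = pd.to_numeric(s, errors="coerce")
        if parsed.notna().all():
            out[col] = parsed.astype(float)
            continue
        dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
        for c in dummies.columns:
            out[c] = dummies[c].astype(float)
    return pd.DataFrame(out, index=clinical.index)


def clinical_adjusted_fit(
    score: pd.Series, clinical: pd.DataFrame, t: SurvivalTable
) -> CoxFit:
    """Multivariate Cox of the enrichment score adjusted for clinical covariates.

    ``score`` and ``clinical`` are indexed by sample_id; rows are aligned to
    the survival table.  Raises on collinear encodings.
    """
    ids = t.sample_ids
    cov = encode_covariates(clinical.loc[ids])
    cov.insert(0, "score", score.loc[ids].astype(float).to_numpy())
    cov = cov.reset_index(drop=True)
    corr = cov.corr().to_numpy()
    off = corr[~np.eye(len(corr), dtype=bool)]
    if np.any(np.abs(off) > 1 - 1e-10):
        raise ValueError("collinear covariate encoding")
    return cox_fit(cov, t, ties="efron")
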
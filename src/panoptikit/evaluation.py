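"""Model evaluation: train/test splitting, Harrell's concordance, time-dependent
AUC and external-cohort validation.

Concordance follows Harrell's definition: a pair is evaluable when the subject
with the earlier follow-up time had the event; it is concordant when that
subject carries the higher risk score; tied risks count 1/2.  The
time-dependent AUC is the inverse-probability-of-censoring-weighted
cumulative-case / dynamic-control estimator.

External cohorts are z-scored gene-wise before scoring, which makes linear
risk models invariant to per-gene affine platform shifts; model genes missing
from the cohort are imputed at the post-z-score cohort mean (0), refusing when
more than half the model genes are absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .datatypes import ExpressionMatrix, SurvivalTable
from .survival import DAYS_PER_YEAR


@dataclass
class LinearRiskModel:
    """Linear risk score on z-scored expression: risk = sum_g coef_g * z_g."""

    genes: list[str]
    coef: np.ndarray
    model_id: str = "linear"

    def predict(self, z: pd.DataFrame) -> pd.Series:
        """Risk scores from a z-scored genes x samples frame (missing model
        genes must already be imputed)."""
        x = z.loc[self.genes].to_numpy(dtype=float)
        return pd.Series(self.coef @ x, index=z.columns, name="risk")


@dataclass
class ValidationReport:
    model_id: str
    cohort_id: str
    concordance: float
    auc: dict[float, float]  # years -> AUC(t)
    n: int
    n_events: int
    n_missing_genes: int


def split_train_test(
    sample_ids: list[str],
    event: np.ndarray,
    fraction: float = 0.8,
    seed: int = 0,
    stratify_on_event: bool = True,
):
    """Disjoint, exhaustive train/test split, event-stratified by default."""
    ids = list(sample_ids)
    if len(ids) < 5:
        raise ValueError("need >= 5 samples to split")
    strat = np.asarray(event) if stratify_on_event else None
    if strat is not None and min(np.bincount(strat.astype(int))) < 2:
        raise ValueError("an event stratum is too small to split")
    train, test = train_test_split(
        ids, train_size=fraction, random_state=seed, stratify=strat
    )
    return list(train), list(test)


def harrell_ci(risk: np.ndarray, t: SurvivalTable) -> float:
    """Harrell's concordance index of a risk score against survival."""
    risk = np.asarray(risk, dtype=float)
    if not np.isfinite(risk).all():
        raise ValueError("non-finite risk scores")
    time, event = t.time, t.event
    n = len(time)
    concordant = 0.0
    evaluable = 0
    for i in range(n):
        if event[i] != 1:
            continue
        later = time > time[i]
        m = int(later.sum())
        if m == 0:
            continue
        evaluable += m
        concordant += float((risk[i] > risk[later]).sum())
        concordant += 0.5 * float((risk[i] == risk[later]).sum())
    if evaluable == 0:
        raise ValueError("no evaluable pairs")
    return concordant / evaluable


def auc_at(
    risk: np.ndarray,
    t: SurvivalTable,
    times_days,
    censoring_from: SurvivalTable | None = None,
) -> dict[float, float]:
    """IPCW cumulative/dynamic AUC at each requested time (days).

    Censoring weights come from the Kaplan–Meier curve of the censoring
    distribution, estimated on ``censoring_from`` (defaults to ``t`` itself).
    """
    risk = np.asarray(risk, dtype=float)
    times_days = np.atleast_1d(np.asarray(times_days, dtype=float))
    lo, hi = t.time.min(), t.time.max()
    bad = [float(x) for x in times_days if not (lo <= x < hi)]
    if bad:
        raise ValueError(f"requested times outside follow-up range [{lo}, {hi}): {bad}")
    ref = censoring_from if censoring_from is not None else t
    y_train = Surv.from_arrays(event=ref.event.astype(bool), time=ref.time)
    y_test = Surv.from_arrays(event=t.event.astype(bool), time=t.time)
    for x in times_days:
        cases = ((t.time <= x) & (t.event == 1)).sum()
        controls = (t.time > x).sum()
        if cases == 0 or controls == 0:
            raise ValueError(f"no cases or no controls at t={x}")
    aucs, _ = cumulative_dynamic_auc(y_train, y_test, risk, times_days)
    return {float(x): float(a) for x, a in zip(times_days, aucs)}


def cross_validate(
    fit_predict,
    X: pd.DataFrame,
    t: SurvivalTable,
    n_folds: int = 5,
    seed: int = 0,
):
    """Event-stratified k-fold cross-validated concordance.

    ``fit_predict(X_train, t_train, X_test) -> risk`` fits on the training
    fold and returns held-out risk scores.  ``X`` is samples x features,
    row-aligned with ``t``.  Returns (per-fold list, mean).
    """
    event = t.event
    if min(np.bincount(event, minlength=2)) < n_folds:
        raise ValueError("a fold would have no events")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_ci = []
    idx = np.arange(len(t))
    for tr, te in skf.split(idx, event):
        t_tr = SurvivalTable(t.data.iloc[tr].reset_index(drop=True))
        t_te = SurvivalTable(t.data.iloc[te].reset_index(drop=True))
        risk = fit_predict(X.iloc[tr], t_tr, X.iloc[te])
        fold_ci.append(harrell_ci(np.asarray(risk, dtype=float), t_te))
    return fold_ci, float(np.mean(fold_ci))


def zscore_genes(expr: ExpressionMatrix) -> pd.DataFrame:
    """Within-cohort per-gene z-scores (population SD); constant genes map to 0."""
    x = expr.data.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((x - mu) / sd, index=expr.data.index, columns=expr.data.columns)


def validate_external(
    model: LinearRiskModel,
    expr: ExpressionMatrix,
    t: SurvivalTable,
    times_years=(1.0, 2.0, 3.0, 5.0),
    cohort_id: str = "external",
) -> ValidationReport:
    """Score a trained linear risk model on an external cohort.

    The cohort is z-scored gene-wise; model genes missing from the cohort are
    imputed at 0 (the post-z-score mean) with the count reported.  Refuses
    when more than 50% of the model genes are missing.
    """
    present = [g for g in model.genes if g in expr.data.index]
    n_missing = len(model.genes) - len(present)
    if n_missing > 0.5 * len(model.genes):
        raise ValueError(
            f"{n_missing}/{len(model.genes)} model genes missing from cohort"
        )
    z = zscore_genes(expr)
    for g in model.genes:
        if g not in z.index:
            z.loc[g] = 0.0
    t_al = t.aligned_to(expr.sample_ids)
    risk = model.predict(z).to_numpy()
    ci = harrell_ci(risk, t_al)
    auc: dict[float, float] = {}
    for yr in times_years:
        try:
            auc[yr] = auc_at(risk, t_al, [yr * DAYS_PER_YEAR])[yr * DAYS_PER_YEAR]
        except ValueError:
            auc[yr] = float("nan")
    return ValidationReport(
        model_id=model.model_id,
        cohort_id=cohort_id,
        concordance=ci,
        auc=auc,
        n=len(t_al),
        n_events=int(t_al.event.sum()),
        n_missing_genes=n_missing,
    )
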
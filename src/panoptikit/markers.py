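"""Two-step marker filtering and the three-model prognostic consensus.

Step 1 (expression): per-gene moderated-t differential expression with
empirical-Bayes variance shrinkage classifies signature genes as *primary*
(differential between the signature-high and signature-low strata),
*secondary* (differential between a stratum and normal tissue) or *excluded*.

Step 2 (survival): three survival models of increasing complexity are run on
the filtered genes — per-gene univariate Cox, an elastic-net Cox stability
selection (repeated runs with fresh fold seeds, the penalty chosen by
cross-validated concordance, genes kept when selected in at least half the
runs), and a random survival forest with permutation variable importance and
subsampled confidence intervals.  The "Top" gene set is the intersection of
the three, requiring a consistent direction of effect.

The elastic net (rather than the LASSO) is used deliberately: signature genes
are correlated and L1-only selection is degenerate under correlation, picking
arbitrary representatives per seed.  Repeated runs make that instability
measurable instead of hiding it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from sklearn.model_selection import StratifiedKFold
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, SurvivalTable
from .evaluation import LinearRiskModel, harrell_ci
from .survival import cox_fit


# ---------------------------------------------------------------------------
# moderated differential expression
# ---------------------------------------------------------------------------

@dataclass
class EBayesPrior:
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance
    df_residual: float


@dataclass
class DEResult:
    table: pd.DataFrame  # gene, logFC, t, p, fdr
    prior: EBayesPrior
    comparison: str = ""


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, as in the standard moderated-t
    prior estimator)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def fit_variance_prior(s_sq: np.ndarray, df: float) -> EBayesPrior:
    """Moment-match the prior (d0, s0^2) of the scaled inverse-chi-square
    variance model from the observed per-gene residual variances."""
    s_sq = np.asarray(s_sq, dtype=float)
    ok = s_sq > 0
    if ok.sum() < 2:
        warnings.warn("too few positive variances; no shrinkage applied", stacklevel=2)
        return EBayesPrior(d0=0.0, s0_sq=float(np.median(s_sq)), df_residual=df)
    e = np.log(s_sq[ok]) - digamma(df / 2.0) + np.log(df / 2.0)
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesPrior(d0=d0, s0_sq=s0_sq, df_residual=df)


def moderated_de(
    expr: ExpressionMatrix,
    group1_ids: list[str],
    group2_ids: list[str],
    comparison: str = "",
    d0_override: float | None = None,
) -> DEResult:
    """Per-gene two-group moderated t-test (empirical-Bayes shrunk variances).

    logFC is group1 minus group2 (log2 units, data assumed log2).  With
    ``d0_override=0`` the statistic reduces to the ordinary equal-variance
    two-sample t-test.
    """
    g1 = [s for s in group1_ids if s in expr.data.columns]
    g2 = [s for s in group2_ids if s in expr.data.columns]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 samples per group")
    x1 = expr.data[g1].to_numpy(dtype=float)
    x2 = expr.data[g2].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    df = n1 + n2 - 2
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s_sq = ss / df
    if s_sq.max() == 0:
        raise ValueError("zero residual variance in both groups for all genes")
    logfc = m1 - m2

    if d0_override is not None:
        prior = EBayesPrior(d0=float(d0_override), s0_sq=float(np.median(s_sq)), df_residual=df)
    else:
        prior = fit_variance_prior(s_sq, df)
    d0 = prior.d0
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, prior.s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * prior.s0_sq + df * s_sq) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        from scipy.stats import norm

        pval = 2.0 * norm.sf(np.abs(tval))
    else:
        pval = 2.0 * t_dist.sf(np.abs(tval), df=df_total)
    table = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "logFC": logfc,
            "t": tval,
            "p": pval,
            "fdr": bh_adjust(pval),
        }
    )
    return DEResult(table=table, prior=prior, comparison=comparison)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_markers(
    res_a: DEResult,
    res_b: DEResult,
    res_c: DEResult,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> pd.Series:
    """Primary / secondary / excluded marker classification.

    Primary: differentially expressed (|logFC| > threshold, FDR < threshold)
    between the high and low strata (comparison a).  Secondary: not primary
    but DE versus normal tissue in either stratum (b or c).  Excluded: DE
    nowhere.
    """
    genes = list(res_a.table["gene"])
    for r in (res_b, res_c):
        if list(r.table["gene"]) != genes:
            raise ValueError("DE results do not share a gene universe")

    def _de(res: DEResult) -> np.ndarray:
        t = res.table
        return (t["logFC"].abs() > lfc_threshold).to_numpy() & (
            t["fdr"] < fdr_threshold
        ).to_numpy()

    de_a, de_b, de_c = _de(res_a), _de(res_b), _de(res_c)
    labels = np.where(de_a, "primary", np.where(de_b | de_c, "secondary", "excluded"))
    return pd.Series(labels, index=genes, name="marker_class")


# ---------------------------------------------------------------------------
# penalized Cox and stability selection
# ---------------------------------------------------------------------------

@dataclass
class CoxnetPath:
    genes: list[str]
    lambdas: np.ndarray  # descending
    coefs: np.ndarray  # genes x lambdas, standardized scale
    alpha: float  # elastic-net mixing (1 = lasso)


@dataclass
class StabilityProfile:
    table: pd.DataFrame  # gene, frequency, mean_coef, sign_consistency
    n_runs: int
    threshold: float
    best_model: LinearRiskModel | None = None
    best_cv_ci: float = float("nan")

    def stable_genes(self) -> list[str]:
        t = self.table
        return list(t.loc[t["frequency"] >= self.threshold, "gene"])


def _standardize(X: pd.DataFrame):
    x = X.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def coxnet_path(
    X: pd.DataFrame,
    t: SurvivalTable,
    alpha: float = 0.5,
    lambdas=None,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-7,
) -> CoxnetPath:
    """Elastic-net Cox coefficient paths (coordinate descent).

    Penalty lambda * (alpha * |b|_1 + (1 - alpha) * |b|_2^2 / 2) on a
    log-spaced lambda grid from the smallest value zeroing all coefficients.
    ``X`` is samples x genes; covariates are standardized internally and
    coefficients reported on the standardized scale.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha (mixing) must lie in (0, 1]")
    xs = _standardize(X)
    y = Surv.from_arrays(event=t.event.astype(bool), time=t.time)
    kwargs = dict(l1_ratio=alpha, normalize=False, fit_baseline_model=False, tol=tol)
    if lambdas is not None:
        model = CoxnetSurvivalAnalysis(alphas=np.asarray(lambdas, dtype=float), **kwargs)
    else:
        model = CoxnetSurvivalAnalysis(
            n_alphas=n_lambdas, alpha_min_ratio=lambda_min_ratio, **kwargs
        )
    model.fit(xs, y)
    lam = np.asarray(model.alphas_)
    coefs = np.asarray(model.coef_)  # genes x lambdas
    return CoxnetPath(genes=list(X.columns), lambdas=lam, coefs=coefs, alpha=alpha)


def _cv_best_lambda(
    X: pd.DataFrame, t: SurvivalTable, alpha, lambdas, n_folds, rng_seed
):
    """Mean cross-validated concordance per lambda; returns (best lambda index,
    mean CI at it, per-lambda mean CI)."""
    xs = _standardize(X)
    event = t.event
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    ci = np.full((n_folds, len(lambdas)), np.nan)
    for f, (tr, te) in enumerate(skf.split(xs, event)):
        y_tr = Surv.from_arrays(event=event[tr].astype(bool), time=t.time[tr])
        model = CoxnetSurvivalAnalysis(
            l1_ratio=alpha, alphas=lambdas, normalize=False, fit_baseline_model=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(xs[tr], y_tr)
        coefs = np.asarray(model.coef_)
        t_te = SurvivalTable(t.data.iloc[te].reset_index(drop=True))
        for li in range(len(lambdas)):
            risk = xs[te] @ coefs[:, li]
            try:
                ci[f, li] = harrell_ci(risk, t_te)
            except ValueError:
                ci[f, li] = np.nan
    mean_ci = np.nanmean(ci, axis=0)
    best = int(np.nanargmax(mean_ci))
    return best, float(mean_ci[best]), mean_ci


def coxnet_stability(
    X: pd.DataFrame,
    t: SurvivalTable,
    n_runs: int = 100,
    n_folds: int = 5,
    threshold: float = 0.5,
    alpha: float = 0.5,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 0.01,
    seed: int = 0,
) -> StabilityProfile:
    """Stability selection over repeated cross-validated elastic-net Cox runs.

    Each run re-randomizes the fold assignment, picks the penalty maximizing
    mean cross-validated concordance, and selects the genes with nonzero
    coefficients at that penalty in the full-data path.  Selection frequency
    is aggregated over runs; genes at or above ``threshold`` are stable.  The
    run with the highest cross-validated concordance provides the "best"
    linear model.
    """
    path = coxnet_path(
        X, t, alpha=alpha, n_lambdas=n_lambdas, lambda_min_ratio=lambda_min_ratio
    )
    lambdas = path.lambdas
    genes = path.genes
    p = len(genes)
    sel_count = np.zeros(p)
    coef_sum = np.zeros(p)
    pos_count = np.zeros(p)
    best_ci = -np.inf
    best_model = None
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_runs)]
    for r in range(n_runs):
        li, run_ci, _ = _cv_best_lambda(X, t, alpha, lambdas, n_folds, run_seeds[r])
        coefs = path.coefs[:, li]
        nz = coefs != 0.0
        sel_count += nz
        coef_sum += np.where(nz, coefs, 0.0)
        pos_count += nz & (coefs > 0)
        if run_ci > best_ci:
            best_ci = run_ci
            best_model = LinearRiskModel(
                genes=[g for g, z in zip(genes, nz) if z],
                coef=coefs[nz].copy(),
                model_id=f"coxnet[l1_ratio={alpha}]",
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = sel_count / n_runs
        mean_coef = np.where(sel_count > 0, coef_sum / np.maximum(sel_count, 1), 0.0)
        sign_cons = np.where(
            sel_count > 0,
            np.maximum(pos_count, sel_count - pos_count) / np.maximum(sel_count, 1),
            np.nan,
        )
    table = pd.DataFrame(
        {
            "gene": genes,
            "frequency": freq,
            "mean_coef": mean_coef,
            "sign_consistency": sign_cons,
        }
    )
    profile = StabilityProfile(
        table=table, n_runs=n_runs, threshold=threshold,
        best_model=best_model, best_cv_ci=best_ci,
    )
    if not profile.stable_genes():
        warnings.warn("no gene reached the stability threshold", stacklevel=2)
    return profile


# ---------------------------------------------------------------------------
# random survival forest importance
# ---------------------------------------------------------------------------

@dataclass
class VIMPProfile:
    table: pd.DataFrame  # gene, importance, lower, upper, rank
    best_params: dict
    forest: RandomSurvivalForest = field(repr=False, default=None)

    def top_genes(self, k: int = 10) -> list[str]:
        t = self.table.sort_values("rank")
        return list(t["gene"].head(k))


DEFAULT_RFS_GRID = (
    {"n_estimators": 100, "max_features": "sqrt", "min_samples_leaf": 10},
    {"n_estimators": 100, "max_features": 0.5, "min_samples_leaf": 20},
)


def rfs_fit_and_vimp(
    X: pd.DataFrame,
    t: SurvivalTable,
    grid=DEFAULT_RFS_GRID,
    n_folds: int = 3,
    n_replicates: int = 100,
    subsample_ratio: float = 0.632,
    holdout_fraction: float = 0.3,
    seed: int = 0,
) -> VIMPProfile:
    """Random survival forest (log-rank splits) with permutation importance.

    Hyperparameters are chosen by cross-validated concordance over ``grid``.
    Importance of a gene is the drop in concordance when its values are
    permuted, evaluated on an event-stratified holdout portion the forest
    never saw (in-sample permutation importance is biased upward for every
    covariate an overfit forest uses); point estimates and percentile
    confidence intervals come from ``n_replicates`` subsample replicates
    (ratio ``subsample_ratio``) of the holdout.  Rank ties are broken by the
    lower confidence bound.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    min_leaf = min(g.get("min_samples_leaf", 1) for g in grid)
    if len(t) <= min_leaf:
        raise ValueError("fewer samples than the smallest nodesize")
    rng = np.random.default_rng(seed)
    event = t.event
    x_all = X.to_numpy(dtype=float)
    n = len(t)

    from sklearn.model_selection import train_test_split

    fit_idx, ho_idx = train_test_split(
        np.arange(n), test_size=holdout_fraction, random_state=seed, stratify=event
    )
    x_fit, x_ho = x_all[fit_idx], x_all[ho_idx]
    t_fit = SurvivalTable(t.data.iloc[fit_idx].reset_index(drop=True))
    t_ho = SurvivalTable(t.data.iloc[ho_idx].reset_index(drop=True))
    y_fit = Surv.from_arrays(event=t_fit.event.astype(bool), time=t_fit.time)

    best_params, best_ci = None, -np.inf
    if len(grid) == 1:
        best_params = dict(grid[0])
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for params in grid:
            fold_ci = []
            for tr, te in skf.split(x_fit, t_fit.event):
                forest = RandomSurvivalForest(random_state=seed, n_jobs=1, **params)
                forest.fit(x_fit[tr], y_fit[tr])
                risk = forest.predict(x_fit[te])
                t_te = SurvivalTable(t_fit.data.iloc[te].reset_index(drop=True))
                fold_ci.append(harrell_ci(risk, t_te))
            m = float(np.mean(fold_ci))
            if m > best_ci:
                best_ci, best_params = m, dict(params)

    forest = RandomSurvivalForest(random_state=seed, n_jobs=1, **best_params)
    forest.fit(x_fit, y_fit)

    n_ho = len(ho_idx)
    m = max(20, int(round(subsample_ratio * n_ho)))
    m = min(m, n_ho)
    p = x_all.shape[1]
    vimp = np.empty((n_replicates, p))
    for b in range(n_replicates):
        idx = rng.choice(n_ho, size=m, replace=False)
        t_b = SurvivalTable(t_ho.data.iloc[idx].reset_index(drop=True))
        base_risk = forest.predict(x_ho[idx])
        try:
            base_ci = harrell_ci(base_risk, t_b)
        except ValueError:
            vimp[b] = np.nan
            continue
        for g in range(p):
            x_perm = x_ho[idx].copy()
            x_perm[:, g] = rng.permutation(x_perm[:, g])
            try:
                vimp[b, g] = base_ci - harrell_ci(forest.predict(x_perm), t_b)
            except ValueError:
                vimp[b, g] = np.nan
    point = np.nanmean(vimp, axis=0)
    lower = np.nanpercentile(vimp, 2.5, axis=0)
    upper = np.nanpercentile(vimp, 97.5, axis=0)
    order = np.lexsort((-lower, -point))
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    table = pd.DataFrame(
        {
            "gene": list(X.columns),
            "importance": point,
            "lower": lower,
            "upper": upper,
            "rank": rank,
        }
    )
    return VIMPProfile(table=table, best_params=best_params, forest=forest)


# ---------------------------------------------------------------------------
# univariate table and the three-model intersection
# ---------------------------------------------------------------------------

def univariate_cox_table(expr: ExpressionMatrix, t: SurvivalTable) -> pd.DataFrame:
    """Per-gene univariate Cox fits with BH-adjusted Wald p-values."""
    t_al = t.aligned_to(expr.sample_ids)
    rows = []
    for g in expr.gene_ids:
        X = pd.DataFrame({g: expr.data.loc[g].to_numpy(dtype=float)})
        fit = cox_fit(X, t_al, ties="efron")
        rows.append((g, float(fit.beta[0]), float(fit.hr[0]),
                     float(fit.ci_lower[0]), float(fit.ci_upper[0]), float(fit.p[0])))
    tab = pd.DataFrame(rows, columns=["gene", "coef", "HR", "ci_lower", "ci_upper", "p"])
    tab["fdr"] = bh_adjust(tab["p"].to_numpy())
    return tab


@dataclass
class TopGeneSet:
    genes: list[str]
    direction: dict[str, str]  # detrimental (HR>1) / beneficial (HR<1)
    provenance: pd.DataFrame  # per gene: univariate/stable/vimp membership


def intersect_top_genes(
    univariate: pd.DataFrame,
    stability: StabilityProfile,
    vimp: VIMPProfile,
    k: int = 10,
    fdr_threshold: float = 0.05,
) -> TopGeneSet:
    """Genes prognostic across all three survival models with consistent sign.

    Membership: BH-adjusted univariate p < threshold; stability frequency at
    or above the profile threshold with the mean penalized coefficient's sign
    matching the univariate direction; permutation-importance rank within the
    top ``k``.  An empty intersection is a legal (logged) outcome.
    """
    uni = univariate.set_index("gene")
    stab = stability.table.set_index("gene")
    universe = list(uni.index)
    if set(stab.index) != set(universe) or set(vimp.table["gene"]) != set(universe):
        raise ValueError("gene universes of the three models differ")
    u_set = set(uni.index[uni["fdr"] < fdr_threshold])
    stable = set(stability.stable_genes())
    sign_ok = {
        g
        for g in stable
        if g in uni.index
        and np.sign(stab.loc[g, "mean_coef"]) == np.sign(uni.loc[g, "coef"])
        and stab.loc[g, "mean_coef"] != 0
    }
    v_set = set(vimp.top_genes(k))
    members = u_set & sign_ok & v_set
    ranks = vimp.table.set_index("gene")["rank"]
    genes = sorted(members, key=lambda g: ranks[g])
    if not genes:
        warnings.warn("empty three-model intersection", stacklevel=2)
    direction = {
        g: ("detrimental" if uni.loc[g, "HR"] > 1 else "beneficial") for g in genes
    }
    prov = pd.DataFrame(
        {
            "gene": universe,
            "univariate": [g in u_set for g in universe],
            "stable": [g in stable for g in universe],
            "sign_consistent": [g in sign_ok or g not in stable for g in universe],
            "vimp_top": [g in v_set for g in universe],
            "top": [g in members for g in universe],
        }
    )
    return TopGeneSet(genes=genes, direction=direction, provenance=prov)
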
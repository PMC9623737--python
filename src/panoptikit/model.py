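"""End-to-end modelling facade.

``PANoptosisModel`` is built from an expression cohort, a survival table and a
gene signature (optionally matched normal samples), and ``fit()`` runs the
whole analysis: consensus stratification on the signature, single-sample
enrichment scoring, high-vs-low survival screening, marker classification
against normals, and the three-model prognostic consensus with held-out
validation.  The returned ``PANoptosisResults`` carries every stage's output
and renders a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, io, markers, scoring, survival
from .datatypes import ExpressionMatrix, GeneSignature, SurvivalTable


@dataclass
class PipelineParams:
    """Tunable parameters of the full analysis (study defaults)."""

    n_resamples: int = 5000  # consensus clustering repeats
    k_min: int = 3
    k_max: int = 6
    subsample_fraction: float = 0.8
    score_method: str = "gsva"
    horizon_years: float = 10.0
    min_followup_days: float = 1.0
    p_threshold: float = 0.05
    min_samples: int = 100
    lfc_threshold: float = 0.5
    fdr_threshold: float = 0.05
    train_fraction: float = 0.8
    n_runs: int = 100  # stability-selection runs
    n_folds: int = 5
    stability_threshold: float = 0.5
    elasticnet_alpha: float = 0.5  # L1/L2 mixing
    n_lambdas: int = 30
    top_k: int = 10
    rfs_grid: tuple = markers.DEFAULT_RFS_GRID
    rfs_replicates: int = 100
    validation_times_years: tuple = (1.0, 2.0, 3.0, 5.0)

    def asdict(self) -> dict:
        import dataclasses

        d = dataclasses.asdict(self)
        d["rfs_grid"] = [dict(g) for g in self.rfs_grid]
        return d


@dataclass
class PANoptosisResults:
    """Fitted results of the end-to-end analysis."""

    params: PipelineParams
    seed: int
    chosen_k: int
    consensus: scoring.ConsensusResult
    labeling: scoring.ClusterLabeling
    strata: pd.Series  # sample_id -> high/medium/low
    score: scoring.ScoreVector
    comparison: survival.CohortComparison
    screened_in: bool
    screen_log: list
    marker_class: pd.Series | None
    de_results: dict
    train_ids: list[str]
    test_ids: list[str]
    univariate: pd.DataFrame
    stability: markers.StabilityProfile
    vimp: markers.VIMPProfile
    top: markers.TopGeneSet
    final_model: evaluation.LinearRiskModel | None
    internal_validation: evaluation.ValidationReport | None
    external_validations: list = field(default_factory=list)

    def summary(self) -> str:
        c = self.comparison
        lines = [
            "=" * 70,
            "PANoptosis signature survival analysis",
            "=" * 70,
            f"clusters (consensus, k by Calinski-Harabasz): k = {self.chosen_k}",
            "stratum sizes: "
            + ", ".join(
                f"{s}={int((self.strata == s).sum())}" for s in ("high", "medium", "low")
            ),
            f"high vs low: HR = {c.hr:.3f} ({c.ci_lower:.3f}-{c.ci_upper:.3f}), "
            f"log-rank p = {c.p_logrank:.3g} "
            f"(N1 = {c.n_high}, N2 = {c.n_low})",
            f"screened in: {self.screened_in}",
        ]
        if self.marker_class is not None:
            counts = self.marker_class.value_counts()
            lines.append(
                "marker classes: "
                + ", ".join(f"{k}={v}" for k, v in counts.items())
            )
        stable = self.stability.stable_genes()
        lines.append(
            f"stable genes (freq >= {self.stability.threshold:g} over "
            f"{self.stability.n_runs} runs): {len(stable)}"
        )
        lines.append(f"Top gene set ({len(self.top.genes)}):")
        for g in self.top.genes:
            lines.append(f"  {g:<10s} {self.top.direction[g]}")
        if self.internal_validation is not None:
            v = self.internal_validation
            auc_txt = ", ".join(f"{yr:g}y={a:.3f}" for yr, a in v.auc.items())
            lines.append(
                f"held-out validation: CI = {v.concordance:.3f} "
                f"(n = {v.n}, events = {v.n_events}); AUC(t): {auc_txt}"
            )
        lines.append("=" * 70)
        return "\n".join(lines)


class PANoptosisModel:
    """Signature-stratification and prognostic-marker model for one cohort.

    Parameters
    ----------
    expression : genes x samples log2 expression (preprocessed)
    surv : per-sample survival table
    signature : the gene signature (defaults to the packaged 27-gene set)
    normals : optional matched normal-tissue expression (same gene universe),
        enabling the primary/secondary marker classification
    params : analysis parameters; defaults are the study settings
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        surv: SurvivalTable,
        signature: GeneSignature | None = None,
        normals: ExpressionMatrix | None = None,
        params: PipelineParams | None = None,
        cohort: str = "cohort",
    ) -> None:
        self.signature = signature or io.packaged_signature()
        self.params = params or PipelineParams()
        self.cohort = cohort
        missing = [g for g in self.signature.genes if g not in expression.data.index]
        if len(self.signature) - len(missing) < 2:
            raise ValueError("fewer than 2 signature genes present in the matrix")
        if missing:
            warnings.warn(
                f"{len(missing)} signature gene(s) absent from the cohort: {missing}",
                stacklevel=2,
            )
        common = [s for s in expression.sample_ids if s in set(surv.sample_ids)]
        if len(common) < 30:
            raise ValueError("fewer than 30 samples shared by expression and survival")
        self.expression = ExpressionMatrix(expression.data[common])
        self.surv = surv.aligned_to(common)
        self.normals = normals

    @classmethod
    def from_files(
        cls,
        expression_path,
        clinical_path,
        signature_path=None,
        roles_path=None,
        normals_path=None,
        params: PipelineParams | None = None,
        cohort: str = "cohort",
    ) -> "PANoptosisModel":
        expr = io.read_expression(expression_path)
        surv = io.read_clinical(clinical_path)
        sig = (
            io.read_signature(signature_path, roles_path=roles_path)
            if signature_path
            else io.packaged_signature()
        )
        normals = io.read_expression(normals_path) if normals_path else None
        return cls(expr, surv, signature=sig, normals=normals, params=params, cohort=cohort)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> PANoptosisResults:
        p = self.params
        rng_seeds = np.random.SeedSequence(seed).spawn(6)
        seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in rng_seeds]

        surv_clean = survival.clean_followup(
            self.surv, min_days=p.min_followup_days, horizon_years=p.horizon_years
        )
        keep = surv_clean.sample_ids
        expr = ExpressionMatrix(self.expression.data[keep])
        expr_sig = expr.restrict(self.signature.genes)

        # --- consensus stratification -----------------------------------
        partitions: dict[int, pd.Series] = {}
        results_by_k: dict[int, scoring.ConsensusResult] = {}
        for k in range(p.k_min, p.k_max + 1):
            res = scoring.consensus_matrix(
                expr_sig, k,
                n_resamples=p.n_resamples,
                subsample_fraction=p.subsample_fraction,
                seed=seeds[0],
            )
            partitions[k] = res.labels
            results_by_k[k] = res
        chosen_k = scoring.choose_k(expr_sig, partitions)
        consensus = results_by_k[chosen_k]
        labeling = scoring.label_clusters(consensus.labels, expr_sig)
        strata = labeling.sample_strata(consensus.labels)

        # --- enrichment score -------------------------------------------
        score = scoring.enrichment_score(expr, self.signature, method=p.score_method)

        # --- survival screening -----------------------------------------
        comparison = survival.compare_strata(strata, surv_clean, cohort=self.cohort)
        selected, screen_log = survival.screen_cohorts(
            [comparison], p_threshold=p.p_threshold, min_samples=p.min_samples
        )
        screened_in = len(selected) == 1

        # --- marker classification (needs normals) ----------------------
        marker_class = None
        de_results: dict[str, markers.DEResult] = {}
        model_genes = [g for g in self.signature.genes if g in expr.data.index]
        if self.normals is not None:
            combined = ExpressionMatrix(
                pd.concat([expr.data, self.normals.data], axis=1)
            )
            high_ids = list(strata.index[strata == "high"])
            low_ids = list(strata.index[strata == "low"])
            normal_ids = self.normals.sample_ids
            de_results["a_high_vs_low"] = markers.moderated_de(
                combined, high_ids, low_ids, comparison="high_vs_low"
            )
            de_results["b_high_vs_normal"] = markers.moderated_de(
                combined, high_ids, normal_ids, comparison="high_vs_normal"
            )
            de_results["c_low_vs_normal"] = markers.moderated_de(
                combined, low_ids, normal_ids, comparison="low_vs_normal"
            )
            marker_class = markers.classify_markers(
                de_results["a_high_vs_low"],
                de_results["b_high_vs_normal"],
                de_results["c_low_vs_normal"],
                lfc_threshold=p.lfc_threshold,
                fdr_threshold=p.fdr_threshold,
            )
            sig_class = marker_class.loc[[g for g in model_genes]]
            kept = list(sig_class.index[sig_class != "excluded"])
            if len(kept) >= 2:
                model_genes = kept

        # --- train/test split and the three survival models -------------
        train_ids, test_ids = evaluation.split_train_test(
            keep, surv_clean.event, fraction=p.train_fraction, seed=seeds[1]
        )
        expr_train = ExpressionMatrix(expr.data.loc[model_genes, train_ids])
        surv_train = surv_clean.aligned_to(train_ids)
        X_train = expr_train.data.T  # samples x genes

        univariate = markers.univariate_cox_table(expr_train, surv_train)
        stability = markers.coxnet_stability(
            X_train, surv_train,
            n_runs=p.n_runs, n_folds=p.n_folds,
            threshold=p.stability_threshold, alpha=p.elasticnet_alpha,
            n_lambdas=p.n_lambdas, seed=seeds[2],
        )
        vimp = markers.rfs_fit_and_vimp(
            X_train, surv_train,
            grid=p.rfs_grid, n_folds=min(3, p.n_folds),
            n_replicates=p.rfs_replicates, seed=seeds[3],
        )
        top = markers.intersect_top_genes(
            univariate, stability, vimp, k=p.top_k, fdr_threshold=p.fdr_threshold
        )

        # --- final linear model on the Top set and held-out validation --
        final_model = None
        internal = None
        fit_genes = top.genes if top.genes else stability.stable_genes()
        if fit_genes:
            z_train = evaluation.zscore_genes(
                ExpressionMatrix(expr.data.loc[fit_genes, train_ids])
            )
            fit = survival.cox_fit(z_train.T, surv_train, ties="efron")
            final_model = evaluation.LinearRiskModel(
                genes=fit_genes, coef=fit.beta, model_id="top_gene_cox"
            )
            expr_test = ExpressionMatrix(expr.data[test_ids])
            surv_test = surv_clean.subset(test_ids)
            try:
                internal = evaluation.validate_external(
                    final_model, expr_test, surv_test,
                    times_years=p.validation_times_years,
                    cohort_id=f"{self.cohort}:heldout",
                )
            except ValueError as exc:
                warnings.warn(f"held-out validation unavailable: {exc}", stacklevel=2)

        return PANoptosisResults(
            params=p,
            seed=seed,
            chosen_k=chosen_k,
            consensus=consensus,
            labeling=labeling,
            strata=strata,
            score=score,
            comparison=comparison,
            screened_in=screened_in,
            screen_log=screen_log,
            marker_class=marker_class,
            de_results=de_results,
            train_ids=list(train_ids),
            test_ids=list(test_ids),
            univariate=univariate,
            stability=stability,
            vimp=vimp,
            top=top,
            final_model=final_model,
            internal_validation=internal,
        )
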
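"""Moderated DE, BH, marker classification, penalized-Cox stability selection,
forest importance and the three-model intersection."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, ttest_ind

from panoptikit import markers
from panoptikit.datatypes import SurvivalTable
from panoptikit.survival import cox_fit

from conftest import make_expression, random_survival


def two_group_expr(n1=8, n2=8, p=60, shift_genes=0, shift=0.0, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(5, sd, size=(p, n1 + n2))
    x[:shift_genes, :n1] += shift
    cols = [f"A{i}" for i in range(n1)] + [f"B{i}" for i in range(n2)]
    return make_expression(x, samples=cols), cols[:n1], cols[n1:]


class TestModeratedDE:
    def test_zero_prior_df_reduces_to_ordinary_t(self):
        expr, g1, g2 = two_group_expr(seed=1)
        res = markers.moderated_de(expr, g1, g2, d0_override=0.0)
        t_ref = ttest_ind(
            expr.data[g1], expr.data[g2], axis=1, equal_var=True
        )
        np.testing.assert_allclose(res.table["t"], t_ref.statistic, atol=1e-10)
        np.testing.assert_allclose(res.table["p"], t_ref.pvalue, atol=1e-10)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_limma_reference(self, tmp_path):
        expr, g1, g2 = two_group_expr(n1=6, n2=5, p=40, shift_genes=8, shift=1.2, seed=3)
        res = markers.moderated_de(expr, g1, g2)
        expr.data.to_csv(tmp_path / "x.tsv", sep="\t")
        rcode = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{tmp_path}/x.tsv", row.names=1))
        design <- cbind(Intercept=1, groupA=c(rep(1,6), rep(0,5)))
        fit <- eBayes(lmFit(x, design))
        tt <- topTable(fit, coef="groupA", number=Inf, sort.by="none")
        out <- data.frame(logFC=tt$logFC, t=tt$t, p=tt$P.Value, fdr=tt$adj.P.Val,
                          d0=fit$df.prior, s0=fit$s2.prior)
        write.table(out, "{tmp_path}/limma.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        assert res.prior.d0 == pytest.approx(ref["d0"][0], rel=1e-8)
        assert res.prior.s0_sq == pytest.approx(ref["s0"][0], rel=1e-8)
        np.testing.assert_allclose(res.table["t"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(res.table["fdr"], ref["fdr"], atol=1e-8)

    def test_null_pvalues_uniform(self):
        expr, g1, g2 = two_group_expr(n1=10, n2=10, p=400, seed=4)
        res = markers.moderated_de(expr, g1, g2)
        assert kstest(res.table["p"], "uniform").pvalue > 0.01

    def test_planted_shift_recovered_with_fdr_control(self):
        # +1 log2-unit shift in 30 of 1000 genes; residual SD 0.5 (typical for
        # normalized log2 expression), n=20/group
        hits, fps = [], []
        for seed in range(10):
            expr, g1, g2 = two_group_expr(
                n1=20, n2=20, p=1000, shift_genes=30, shift=1.0, sd=0.5, seed=seed
            )
            res = markers.moderated_de(expr, g1, g2)
            sig = res.table["fdr"] < 0.05
            hits.append(sig[:30].mean())
            fps.append(sig[30:].sum())
        assert np.mean(hits) >= 0.8
        assert np.mean(fps) <= 0.05 * 1000 * 0.1  # FDR-scale false positives

    def test_needs_two_samples_per_group(self):
        expr, g1, g2 = two_group_expr()
        with pytest.raises(ValueError):
            markers.moderated_de(expr, g1[:1], g2)


class TestBHAdjust:
    def test_stepup_hand_example(self):
        np.testing.assert_allclose(
            markers.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_unchanged(self):
        np.testing.assert_allclose(markers.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert markers.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_adjusted_at_least_raw_and_rank_preserving(self):
        rng = np.random.default_rng(5)
        p = rng.random(50)
        q = markers.bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        # monotone: sorting by raw p leaves adjusted p non-decreasing
        assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            markers.bh_adjust([0.5, 1.2])


class TestClassifyMarkers:
    @staticmethod
    def _res(lfc, fdr, comparison=""):
        genes = [f"g{i}" for i in range(len(lfc))]
        return markers.DEResult(
            table=pd.DataFrame(
                {"gene": genes, "logFC": lfc, "t": 0.0, "p": fdr, "fdr": fdr}
            ),
            prior=markers.EBayesPrior(1.0, 1.0, 10.0),
            comparison=comparison,
        )

    def test_rule_precedence_and_labels(self):
        # g0: DE in (a) and (b) -> primary; g1: only (c) -> secondary;
        # g2: nowhere -> excluded
        a = self._res([1.0, 0.0, 0.1], [0.001, 0.9, 0.9])
        b = self._res([1.0, 0.0, 0.0], [0.001, 0.9, 0.9])
        c = self._res([0.0, -0.8, 0.2], [0.9, 0.001, 0.9])
        cls = markers.classify_markers(a, b, c)
        assert cls["g0"] == "primary"
        assert cls["g1"] == "secondary"
        assert cls["g2"] == "excluded"

    def test_de_requires_both_fold_change_and_fdr(self):
        a = self._res([1.0], [0.5])  # big logFC, nonsignificant
        b = self._res([0.2], [0.001])  # significant, small logFC
        c = self._res([0.0], [1.0])
        assert markers.classify_markers(a, b, c)["g0"] == "excluded"

    def test_mismatched_universe_errors(self):
        a = self._res([1.0, 0.0], [0.01, 0.9])
        b = self._res([1.0], [0.01])
        with pytest.raises(ValueError):
            markers.classify_markers(a, b, a)


@pytest.fixture(scope="module")
def planted_survival_design():
    """n=150, 8 genes, strong effect on the first two."""
    rng = np.random.default_rng(21)
    n, p = 150, 8
    x = rng.normal(size=(n, p))
    lp = 0.9 * x[:, 0] + 0.9 * x[:, 1]
    lam = 1e-3 * np.exp(lp)
    time = rng.exponential(1 / lam)
    cens = rng.exponential(2500, n)
    t = SurvivalTable(
        pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)],
             "time_days": np.minimum(time, cens),
             "event": (time <= cens).astype(int)}
        )
    )
    X = pd.DataFrame(x, columns=[f"g{i}" for i in range(p)])
    return X, t


class TestCoxnetPath:
    def test_large_lambda_zeroes_all_coefficients(self, planted_survival_design):
        X, t = planted_survival_design
        path = markers.coxnet_path(X, t, alpha=0.5)
        assert np.all(path.coefs[:, 0] == 0.0)  # largest lambda first

    def test_tiny_lambda_matches_unpenalized_fit(self, planted_survival_design):
        X, t = planted_survival_design
        X3 = X.iloc[:, :3]
        lambdas = np.array([0.5, 0.1, 0.01, 1e-4, 1e-7])
        path = markers.coxnet_path(X3, t, alpha=0.5, lambdas=lambdas, tol=1e-12)
        xs = (X3 - X3.mean()) / X3.std(ddof=0)
        ref = cox_fit(xs, t, ties="breslow")
        np.testing.assert_allclose(path.coefs[:, -1], ref.beta, atol=1e-4)

    def test_elastic_net_shares_weight_on_duplicates(self, planted_survival_design):
        X, t = planted_survival_design
        Xd = X.iloc[:, :2].copy()
        Xd["dup"] = Xd.iloc[:, 0]
        path = markers.coxnet_path(Xd, t, alpha=0.5)
        mid = path.coefs[:, len(path.lambdas) // 2]
        if mid[0] != 0 or mid[2] != 0:  # ridge component shares the weight
            assert mid[0] == pytest.approx(mid[2], rel=0.2)

    def test_invalid_mixing_errors(self, planted_survival_design):
        X, t = planted_survival_design
        with pytest.raises(ValueError):
            markers.coxnet_path(X, t, alpha=0.0)


class TestStability:
    def test_deterministic_under_master_seed(self, planted_survival_design):
        X, t = planted_survival_design
        kw = dict(n_runs=8, n_folds=3, n_lambdas=10, seed=42)
        a = markers.coxnet_stability(X, t, **kw)
        b = markers.coxnet_stability(X, t, **kw)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.best_cv_ci == b.best_cv_ci

    def test_planted_genes_selected_more_often_than_null(self, planted_survival_design):
        X, t = planted_survival_design
        prof = markers.coxnet_stability(X, t, n_runs=15, n_folds=3, n_lambdas=15, seed=1)
        tab = prof.table.set_index("gene")
        assert tab.loc["g0", "frequency"] >= 0.5
        assert tab.loc["g1", "frequency"] >= 0.5
        assert tab.drop(index=["g0", "g1"])["frequency"].median() < tab.loc["g0", "frequency"]

    def test_threshold_is_inclusive_at_one_half(self):
        table = pd.DataFrame(
            {"gene": ["a", "b"], "frequency": [0.50, 0.49],
             "mean_coef": [1.0, 1.0], "sign_consistency": [1.0, 1.0]}
        )
        prof = markers.StabilityProfile(table=table, n_runs=100, threshold=0.5)
        assert prof.stable_genes() == ["a"]


class TestRFS:
    def test_dominant_gene_ranks_first(self):
        rng = np.random.default_rng(31)
        n, p = 200, 8
        x = rng.normal(size=(n, p))
        lam = 1e-3 * np.exp(1.5 * x[:, 3])
        time = rng.exponential(1 / lam)
        cens = rng.exponential(2500, n)
        t = SurvivalTable(
            pd.DataFrame(
                {"sample_id": [f"s{i}" for i in range(n)],
                 "time_days": np.minimum(time, cens),
                 "event": (time <= cens).astype(int)}
            )
        )
        X = pd.DataFrame(x, columns=[f"g{i}" for i in range(p)])
        grid = ({"n_estimators": 50, "max_features": "sqrt", "min_samples_leaf": 10},)
        prof = markers.rfs_fit_and_vimp(X, t, grid=grid, n_replicates=10, seed=0)
        assert prof.top_genes(1) == ["g3"]

    def test_top_k_truncates_to_available_genes(self, planted_survival_design):
        X, t = planted_survival_design
        grid = ({"n_estimators": 30, "max_features": "sqrt", "min_samples_leaf": 10},)
        prof = markers.rfs_fit_and_vimp(X, t, grid=grid, n_replicates=5, seed=0)
        top = prof.top_genes(10)
        assert len(top) == 8 and set(top) == set(X.columns)

    def test_noise_genes_importance_intervals_cover_zero(self):
        rng = np.random.default_rng(32)
        n, p = 150, 10
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"g{i}" for i in range(p)])
        t = random_survival(n, rng)
        grid = ({"n_estimators": 50, "max_features": "sqrt", "min_samples_leaf": 10},)
        prof = markers.rfs_fit_and_vimp(X, t, grid=grid, n_replicates=30, seed=0)
        covers = ((prof.table["lower"] <= 0) & (prof.table["upper"] >= 0)).mean()
        assert covers >= 0.9

    def test_empty_grid_errors(self, planted_survival_design):
        X, t = planted_survival_design
        with pytest.raises(ValueError):
            markers.rfs_fit_and_vimp(X, t, grid=())


class TestIntersection:
    @staticmethod
    def _fabricate(universe, u_sig, stable, stable_sign, top10):
        uni = pd.DataFrame(
            {
                "gene": universe,
                "coef": [0.5] * len(universe),
                "HR": [1.65] * len(universe),
                "ci_lower": 1.1,
                "ci_upper": 2.5,
                "p": [0.001 if g in u_sig else 0.5 for g in universe],
                "fdr": [0.01 if g in u_sig else 0.8 for g in universe],
            }
        )
        stab_tab = pd.DataFrame(
            {
                "gene": universe,
                "frequency": [0.9 if g in stable else 0.1 for g in universe],
                "mean_coef": [stable_sign.get(g, 0.4) for g in universe],
                "sign_consistency": 1.0,
            }
        )
        stab = markers.StabilityProfile(table=stab_tab, n_runs=100, threshold=0.5)
        ranks = {g: i + 1 for i, g in enumerate(top10)}
        rest = [g for g in universe if g not in ranks]
        for i, g in enumerate(rest):
            ranks[g] = len(top10) + i + 1
        vtab = pd.DataFrame(
            {
                "gene": universe,
                "importance": [1.0 / ranks[g] for g in universe],
                "lower": 0.0,
                "upper": 1.0,
                "rank": [ranks[g] for g in universe],
            }
        )
        vimp = markers.VIMPProfile(table=vtab, best_params={})
        return uni, stab, vimp

    def test_seven_gene_consensus_with_sign_flip_excluded(self):
        # three-model agreement on 7 genes; TNF stable but with flipped sign
        universe = ["Z", "A", "C2", "C3", "C4", "C8", "G", "M", "TNF", "X", "Y", "W",
                    "N1", "N2"]
        u_sig = {"Z", "A", "C2", "C3", "C4", "C8", "G", "M", "TNF"}
        stable = {"Z", "A", "C2", "C3", "C4", "C8", "G", "TNF"}
        sign = {g: 0.4 for g in stable}
        sign["TNF"] = -0.4  # penalized sign opposes the univariate direction
        top10 = ["Z", "A", "C2", "C3", "C4", "C8", "G", "X", "Y", "W"]
        uni, stab, vimp = self._fabricate(universe, u_sig, stable, sign, top10)
        top = markers.intersect_top_genes(uni, stab, vimp, k=10)
        assert sorted(top.genes) == sorted(["Z", "A", "C2", "C3", "C4", "C8", "G"])
        assert "TNF" not in top.genes
        assert all(d == "detrimental" for d in top.direction.values())

    def test_any_empty_input_gives_empty_top(self):
        universe = ["a", "b", "c"]
        uni, stab, vimp = self._fabricate(universe, set(), {"a"}, {"a": 0.4}, ["a"])
        with pytest.warns(UserWarning, match="empty"):
            top = markers.intersect_top_genes(uni, stab, vimp)
        assert top.genes == []

    def test_mismatched_universe_errors(self):
        uni, stab, vimp = self._fabricate(["a", "b"], {"a"}, {"a"}, {"a": 0.4}, ["a"])
        uni2 = uni[uni["gene"] != "b"]
        with pytest.raises(ValueError):
            markers.intersect_top_genes(uni2, stab, vimp)


def test_univariate_table_recovers_planted_direction(planted_survival_design):
    X, t = planted_survival_design
    from panoptikit.datatypes import ExpressionMatrix

    expr = ExpressionMatrix(X.T.set_axis(t.sample_ids, axis=1))
    tab = markers.univariate_cox_table(expr, t).set_index("gene")
    assert tab.loc["g0", "HR"] > 1 and tab.loc["g0", "fdr"] < 0.05
    assert tab.loc["g1", "HR"] > 1 and tab.loc["g1", "fdr"] < 0.05
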
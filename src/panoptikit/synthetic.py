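"""Synthetic cohorts with the statistical structure the analysis assumes.

The bulk generator emulates a quantile-normalized, log2-scale tumor cohort in
which a cell-death gene signature rides on a 3-level latent activity factor
(low / medium / high), signature genes share a common factor inducing positive
within-signature correlation, and overall survival follows a proportional-
hazards model with planted log-hazard coefficients on a declared subset of
signature genes.  Matched "normal tissue" samples sit at the gene baselines.
External validation cohorts are re-draws from the same latent model with a
per-gene affine platform distortion and optionally missing genes.  The
single-cell generator produces negative-binomial counts whose signature-gene
means scale with a per-cell-type activity factor.

Every generator is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import ExpressionMatrix, GeneSignature, SurvivalTable

GROUP_NAMES = {-1: "low", 0: "medium", 1: "high"}

# Default study conditions (log2 expression units unless noted):
#   noise SD 1, shared-factor SD 0.35 (within-signature Pearson r ~ 0.11 at
#   delta = 0; the factor lies along the signature axis, so its variance is
#   bounded by requiring the three latent strata to stay separable),
#   group shift 2 noise-SDs per latent level, baseline hazard 5e-4 events/day
#   (median OS ~ 3.8 years at the baseline), 60% censoring.
DEFAULT_NOISE_SD = 1.0
DEFAULT_SHARED_SD = 0.35
DEFAULT_DELTA = 2.0
DEFAULT_HAZARD = 5e-4
DEFAULT_CENSOR = 0.6


@dataclass
class SyntheticTruth:
    """Ground truth planted into a synthetic cohort."""

    group_label: pd.Series  # sample_id -> low/medium/high
    group_shift: float  # expression shift per latent level (noise-SD units)
    signature_loading: dict[str, float]
    true_beta: dict[str, float]  # log hazard per expression unit; 0 if absent
    baseline_hazard_rate: float  # events / day
    censor_rate: float
    seed: int
    generator_params: dict = field(default_factory=dict, repr=False)

    def planted_genes(self) -> list[str]:
        return [g for g, b in self.true_beta.items() if b != 0.0]


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    survival: SurvivalTable
    normals: ExpressionMatrix
    truth: SyntheticTruth

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.survival.sample_ids:
            raise ValueError("expression and survival sample IDs differ")
        if self.normals is not None and self.normals.gene_ids != self.expression.gene_ids:
            raise ValueError("normals do not share the expression gene universe")


def _censoring_rate_for(lam: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate c with mean P(C < T) = censor_rate.

    For independent exponentials, P(censored | lambda_i) = c / (c + lambda_i);
    solved numerically for the cohort average.
    """
    if censor_rate == 0.0:
        return 0.0

    def f(c):
        return np.mean(c / (c + lam)) - censor_rate

    lo, hi = 1e-12, 1e12
    return brentq(f, lo, hi, maxiter=200)


def _draw_survival(expr: np.ndarray, genes: list[str], sample_ids: list[str],
                   true_beta: dict[str, float], hazard: float, censor_rate: float,
                   rng: np.random.Generator) -> SurvivalTable:
    beta = np.array([true_beta.get(g, 0.0) for g in genes])
    centered = expr - expr.mean(axis=1, keepdims=True)
    lp = beta @ centered
    lam = hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / lam)
    c = _censoring_rate_for(lam, censor_rate)
    if c > 0:
        t_cens = rng.exponential(1.0 / c, size=lam.shape)
    else:
        t_cens = np.full_like(t_event, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    n = len(sample_ids)
    df = pd.DataFrame({
        "sample_id": sample_ids,
        "time_days": np.maximum(time, 1.0),
        "event": event,
        "age": np.round(rng.normal(60, 12, size=n)).clip(20, 95),
        "gender": rng.choice(["female", "male"], size=n),
        "stage": rng.integers(1, 5, size=n),
    })
    return SurvivalTable(df)


def generate_bulk_cohort(
    n_samples: int,
    n_background_genes: int,
    signature: GeneSignature,
    *,
    delta: float = DEFAULT_DELTA,
    noise_sd: float = DEFAULT_NOISE_SD,
    shared_factor_sd: float = DEFAULT_SHARED_SD,
    signature_loading: dict[str, float] | None = None,
    true_beta: dict[str, float] | None = None,
    baseline_hazard_rate: float = DEFAULT_HAZARD,
    censor_rate: float = DEFAULT_CENSOR,
    tumor_shift: float | dict[str, float] = 0.0,
    n_normals: int | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a tumor cohort with latent 3-level signature activity.

    Signature gene values are ``baseline + loading * delta * noise_sd * level
    + shared factor + independent noise``; background genes are independent of
    the latent level.  Survival times are exponential with hazard
    ``baseline_hazard_rate * exp(x . true_beta)`` (centered expression),
    censored by an independent exponential tuned to ``censor_rate``.

    ``tumor_shift`` offsets signature baselines in tumors relative to normals,
    planting differential-expression truth for the marker classification.
    """
    if n_samples < 30:
        raise ValueError("n_samples must be >= 30")
    if n_background_genes < 0:
        raise ValueError("n_background_genes must be >= 0")
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor_rate must lie in [0, 1)")
    if len(signature) == 0:
        raise ValueError("empty signature")

    rng = np.random.default_rng(seed)
    sig_genes = list(signature.genes)
    bg_genes = [f"BG{i:05d}" for i in range(n_background_genes)]
    genes = sig_genes + bg_genes
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    if n_normals is None:
        n_normals = max(30, n_samples // 4)

    loading = {g: 1.0 for g in sig_genes}
    if signature_loading:
        loading.update(signature_loading)
    true_beta = dict(true_beta or {})
    if isinstance(tumor_shift, dict):
        shift = np.array([tumor_shift.get(g, 0.0) for g in sig_genes])
    else:
        shift = np.full(len(sig_genes), float(tumor_shift))

    baselines = np.concatenate([
        rng.normal(8.0, 1.5, size=len(sig_genes)),
        rng.normal(7.0, 2.0, size=len(bg_genes)),
    ])

    # balanced latent levels, shuffled: guarantees all 3 strata exist
    base_levels = np.tile([-1, 0, 1], n_samples // 3 + 1)[:n_samples]
    levels = rng.permutation(base_levels)
    shared = rng.normal(0.0, 1.0, size=n_samples)

    x = np.empty((len(genes), n_samples))
    load_vec = np.array([loading[g] for g in sig_genes])
    x[: len(sig_genes)] = (
        baselines[: len(sig_genes), None]
        + shift[:, None]
        + load_vec[:, None] * (delta * noise_sd) * levels[None, :]
        + shared_factor_sd * shared[None, :]
        + rng.normal(0.0, noise_sd, size=(len(sig_genes), n_samples))
    )
    x[len(sig_genes):] = baselines[len(sig_genes):, None] + rng.normal(
        0.0, noise_sd, size=(len(bg_genes), n_samples)
    )

    survival = _draw_survival(
        x, genes, sample_ids, true_beta, baseline_hazard_rate, censor_rate, rng
    )

    normal_ids = [f"N{i:04d}" for i in range(n_normals)]
    normals = baselines[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), n_normals))

    truth = SyntheticTruth(
        group_label=pd.Series(
            [GROUP_NAMES[v] for v in levels], index=sample_ids, name="group_label"
        ),
        group_shift=delta,
        signature_loading=loading,
        true_beta={g: true_beta.get(g, 0.0) for g in genes},
        baseline_hazard_rate=baseline_hazard_rate,
        censor_rate=censor_rate,
        seed=seed,
        generator_params=dict(
            n_background_genes=n_background_genes,
            delta=delta,
            noise_sd=noise_sd,
            shared_factor_sd=shared_factor_sd,
            baselines=baselines,
            genes=genes,
            sig_genes=sig_genes,
            load_vec=load_vec,
            shift=shift,
        ),
    )
    return SyntheticCohort(
        expression=ExpressionMatrix(pd.DataFrame(x, index=genes, columns=sample_ids)),
        survival=survival,
        normals=ExpressionMatrix(pd.DataFrame(normals, index=genes, columns=normal_ids)),
        truth=truth,
    )


def generate_external_cohort(
    base: SyntheticCohort,
    *,
    location_shift: float | dict[str, float] = 0.0,
    scale_shift: float | dict[str, float] = 1.0,
    missing_genes: list[str] | None = None,
    n_samples: int | None = None,
    seed: int = 1,
) -> SyntheticCohort:
    """Platform-shifted validation cohort drawn from the same latent model.

    New samples are generated from the base cohort's generative parameters,
    survival is drawn from the undistorted expression, then each gene is
    affine-distorted (``x * scale + location``) and the listed genes removed —
    emulating a microarray cohort measured on a different platform.
    """
    p = base.truth.generator_params
    if not p:
        raise ValueError("base cohort carries no generator parameters")
    missing_genes = list(missing_genes or [])
    unknown = set(missing_genes) - set(p["genes"])
    if unknown:
        raise ValueError(f"missing_genes not in base cohort: {sorted(unknown)}")
    if n_samples is None:
        n_samples = base.expression.n_samples

    rng = np.random.default_rng(seed)
    genes, sig_genes = p["genes"], p["sig_genes"]
    sample_ids = [f"E{i:04d}" for i in range(n_samples)]

    base_levels = np.tile([-1, 0, 1], n_samples // 3 + 1)[:n_samples]
    levels = rng.permutation(base_levels)
    shared = rng.normal(0.0, 1.0, size=n_samples)
    x = np.empty((len(genes), n_samples))
    n_sig = len(sig_genes)
    x[:n_sig] = (
        p["baselines"][:n_sig, None]
        + p["shift"][:, None]
        + p["load_vec"][:, None] * (p["delta"] * p["noise_sd"]) * levels[None, :]
        + p["shared_factor_sd"] * shared[None, :]
        + rng.normal(0.0, p["noise_sd"], size=(n_sig, n_samples))
    )
    x[n_sig:] = p["baselines"][n_sig:, None] + rng.normal(
        0.0, p["noise_sd"], size=(len(genes) - n_sig, n_samples)
    )

    survival = _draw_survival(
        x, genes, sample_ids, base.truth.true_beta,
        base.truth.baseline_hazard_rate, base.truth.censor_rate, rng,
    )

    if isinstance(location_shift, dict):
        loc = np.array([location_shift.get(g, 0.0) for g in genes])
    else:
        loc = np.full(len(genes), float(location_shift))
    if isinstance(scale_shift, dict):
        scale = np.array([scale_shift.get(g, 1.0) for g in genes])
    else:
        scale = np.full(len(genes), float(scale_shift))
    x = x * scale[:, None] + loc[:, None]

    df = pd.DataFrame(x, index=genes, columns=sample_ids)
    df = df.drop(index=missing_genes)

    truth = SyntheticTruth(
        group_label=pd.Series(
            [GROUP_NAMES[v] for v in levels], index=sample_ids, name="group_label"
        ),
        group_shift=base.truth.group_shift,
        signature_loading=base.truth.signature_loading,
        true_beta=base.truth.true_beta,
        baseline_hazard_rate=base.truth.baseline_hazard_rate,
        censor_rate=base.truth.censor_rate,
        seed=seed,
        generator_params=p,
    )
    normals = ExpressionMatrix(base.normals.data.drop(index=missing_genes).copy())
    return SyntheticCohort(
        expression=ExpressionMatrix(df), survival=survival, normals=normals, truth=truth
    )


def generate_singlecell(
    n_cells_per_type: dict[str, int],
    activity_by_type: dict[str, float],
    signature: GeneSignature,
    *,
    n_background_genes: int = 500,
    dispersion: float = 2.0,
    library_sd: float = 0.3,
    seed: int = 0,
) -> ad.AnnData:
    """Negative-binomial single-cell counts with type-specific signature activity.

    ``activity_by_type`` is a positive multiplicative factor on signature-gene
    means per cell type (e.g. tumor 0.5, immune 2.0).  Library sizes vary
    lognormally per cell.  Returns cells x genes AnnData with ``obs.cell_type``.
    """
    if len(n_cells_per_type) < 2:
        raise ValueError("need at least 2 cell types")
    if set(n_cells_per_type) != set(activity_by_type):
        raise ValueError("cell types of counts and activities differ")
    if any(n <= 0 for n in n_cells_per_type.values()):
        raise ValueError("cell counts must be positive")
    if any(not np.isfinite(a) or a <= 0 for a in activity_by_type.values()):
        raise ValueError("activities must be finite and positive")

    rng = np.random.default_rng(seed)
    sig_genes = list(signature.genes)
    genes = sig_genes + [f"BG{i:05d}" for i in range(n_background_genes)]
    base_mu = rng.lognormal(mean=-0.5, sigma=1.0, size=len(genes)).clip(0.01, 50)

    rows, types, ids = [], [], []
    for ct in sorted(n_cells_per_type):
        n_cells = n_cells_per_type[ct]
        act = activity_by_type[ct]
        lib = rng.lognormal(0.0, library_sd, size=n_cells)
        mu = np.tile(base_mu, (n_cells, 1)) * lib[:, None]
        mu[:, : len(sig_genes)] *= act
        r = dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        rows.append(counts)
        types.extend([ct] * n_cells)
        ids.extend([f"{ct}_{i:04d}" for i in range(n_cells)])

    X = np.vstack(rows).astype(np.int64)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame({"cell_type": pd.Categorical(types)}, index=ids),
        var=pd.DataFrame(index=genes),
    )
    return adata


@dataclass
class TruthReport:
    """Lossless dump of the planted ground truth for test assertions."""

    planted: pd.DataFrame  # gene, beta
    groups: pd.DataFrame  # sample_id, group_label


def truth_report(cohort: SyntheticCohort) -> TruthReport:
    if cohort.truth is None:
        raise ValueError("cohort carries no truth")
    planted = pd.DataFrame(
        [(g, b) for g, b in cohort.truth.true_beta.items() if b != 0.0],
        columns=["gene", "beta"],
    )
    groups = cohort.truth.group_label.rename_axis("sample_id").reset_index()
    return TruthReport(planted=planted, groups=groups)


def write_truth_report(report: TruthReport, planted_path, groups_path) -> None:
    report.planted.to_csv(planted_path, sep="\t", index=False)
    report.groups.to_csv(groups_path, sep="\t", index=False)


def read_truth_report(planted_path, groups_path) -> TruthReport:
    planted = pd.read_csv(planted_path, sep="\t")
    if planted.empty:
        planted = pd.DataFrame(columns=["gene", "beta"])
    groups = pd.read_csv(groups_path, sep="\t")
    return TruthReport(planted=planted, groups=groups)


def write_singlecell_mtx(adata: ad.AnnData, out_dir) -> None:
    """Write counts as an MTX triplet plus a cell-metadata TSV."""
    from pathlib import Path

    import scipy.io
    import scipy.sparse as sp

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", sp.csr_matrix(adata.X.T))  # genes x cells
    (out / "genes.tsv").write_text("\n".join(adata.var_names) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    adata.obs.rename_axis("cell_id").reset_index().to_csv(
        out / "cell_metadata.tsv", sep="\t", index=False
    )


def read_singlecell_mtx(in_dir) -> ad.AnnData:
    from pathlib import Path

    import scipy.io

    src = Path(in_dir)
    m = scipy.io.mmread(src / "matrix.mtx").toarray().T  # cells x genes
    genes = (src / "genes.tsv").read_text().split()
    cells = (src / "barcodes.tsv").read_text().split()
    obs = pd.read_csv(src / "cell_metadata.tsv", sep="\t", index_col="cell_id")
    obs = obs.loc[cells]
    return ad.AnnData(
        X=m.astype(np.int64), obs=obs, var=pd.DataFrame(index=genes)
    )
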
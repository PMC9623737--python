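"""Minimal single-cell path: library-size log-normalization, variable-gene
selection and per-cell signature enrichment.

Cells live in an AnnData (cells x genes) with a ``cell_type`` obs column.
Normalization is the LogNormalize convention, ``ln(1 + count * scale /
cell_total)`` with scale 10 000.  Variable genes are ranked by standardized
variance after a lowess mean-variance trend fit on log10 scale (the vst
approach), with standardized counts clipped at sqrt(n_cells).  Per-cell
enrichment applies the ssGSEA walk from the scoring module to each cell.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import ExpressionMatrix, GeneSignature
from .scoring import enrichment_score


def _dense(X) -> np.ndarray:
    return X.toarray() if hasattr(X, "toarray") else np.asarray(X)


def lognormalize(adata: ad.AnnData, scale: float = 10_000.0) -> ad.AnnData:
    """LogNormalize counts: value = ln(1 + count * scale / cell_total)."""
    counts = _dense(adata.X).astype(float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cell(s) with zero total counts")
    norm = np.log1p(counts * scale / totals[:, None])
    out = adata.copy()
    out.layers["counts"] = adata.X.copy()
    out.X = norm
    return out


def variable_genes(adata: ad.AnnData, n: int = 3000, span: float = 0.3) -> list[str]:
    """Top ``n`` genes by vst standardized variance.

    A lowess trend of log10 variance on log10 mean (computed on raw counts)
    predicts each gene's expected SD; counts are standardized against it,
    clipped at sqrt(n_cells), and genes ranked by the variance of the clipped
    standardized counts.  Returns all genes (with a warning) when fewer than
    ``n`` are available.
    """
    counts = _dense(adata.layers["counts"] if "counts" in adata.layers else adata.X)
    counts = counts.astype(float)
    n_cells, n_genes = counts.shape
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    usable = (mean > 0) & (var > 0)
    est_var = np.zeros(n_genes)
    lx, ly = np.log10(mean[usable]), np.log10(var[usable])
    fit = sm.nonparametric.lowess(ly, lx, frac=span, return_sorted=False)
    est_var[usable] = 10.0 ** fit
    clip = np.sqrt(n_cells)
    std_var = np.zeros(n_genes)
    sd = np.sqrt(est_var[usable])
    z = (counts[:, usable] - mean[usable]) / sd
    np.clip(z, -clip, clip, out=z)
    std_var[usable] = z.var(axis=0, ddof=1)
    order = np.argsort(-std_var, kind="stable")
    ranked = [adata.var_names[i] for i in order if std_var[i] > 0]
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} informative genes available (requested {n})",
            stacklevel=2,
        )
        return ranked
    return ranked[:n]


def per_cell_enrichment(
    adata: ad.AnnData, signature: GeneSignature, alpha: float = 0.25,
    normalize: bool = True,
) -> pd.Series:
    """Per-cell ssGSEA enrichment of the signature on normalized values."""
    expr = ExpressionMatrix(
        pd.DataFrame(
            _dense(adata.X).T, index=list(adata.var_names), columns=list(adata.obs_names)
        )
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes are expected in sc data
        sv = enrichment_score(
            expr, signature, method="ssgsea", alpha=alpha, normalize=normalize
        )
    return sv.scores.rename("panoptosis_score")


def summarize_by_type(
    adata: ad.AnnData,
    scores: pd.Series,
    genes: list[str] | None = None,
    type_col: str = "cell_type",
):
    """Dot-plot statistics per gene x cell type, plus per-type mean score.

    Returns (per-gene DataFrame with mean expression and percent of cells
    expressing, per-type DataFrame with mean enrichment score).
    """
    if type_col not in adata.obs:
        raise ValueError(f"missing obs column {type_col!r}")
    types = adata.obs[type_col].astype(str)
    if types.isna().any() or (types == "").any():
        raise ValueError("cell type labels must cover all cells")
    genes = list(genes) if genes is not None else list(adata.var_names)
    x = _dense(adata[:, genes].X)
    rows = []
    for ct in sorted(types.unique()):
        mask = (types == ct).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"empty cell type {ct!r}")
        sub = x[mask]
        mean_expr = sub.mean(axis=0)
        pct = 100.0 * (sub > 0).mean(axis=0)
        for g, m, p in zip(genes, mean_expr, pct):
            rows.append((ct, g, float(m), float(p)))
    per_gene = pd.DataFrame(rows, columns=["cell_type", "gene", "mean_expr", "pct_expressing"])
    score_tab = (
        pd.DataFrame({"cell_type": types.to_numpy(), "score": scores.loc[adata.obs_names].to_numpy()})
        .groupby("cell_type", observed=True)["score"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_score", "count": "n_cells"})
    )
    return per_gene, score_tab
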
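"""Signature-based sample stratification and single-sample enrichment.

Samples are stratified by consensus clustering on the signature genes:
repeated Ward (inner) hierarchical clustering of random sample subsets builds
a pairwise co-clustering frequency matrix, and the final partition comes from
complete-linkage (outer) clustering of ``1 - consensus``.  The cluster count
is chosen by the Calinski–Harabasz criterion over k in [3, 6].  The cluster
with the highest mean signature expression is labeled "high", the lowest
"low", all others "medium".

The per-sample enrichment score (the PANoptosis score) is a weighted
Kolmogorov–Smirnov random-walk statistic: ``gsva`` first converts expression
to a Gaussian-kernel ECDF per gene and walks genes ordered by the resulting
symmetric rank statistic; ``ssgsea`` walks genes ordered by within-sample
expression rank with weight ``rank**alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import ndtr
from scipy.stats import rankdata, t as t_dist
from sklearn.metrics import calinski_harabasz_score

from .datatypes import ExpressionMatrix, GeneSignature


@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame  # samples x samples, co-clustering frequency
    labels: pd.Series  # sample_id -> cluster id (1..k)
    n_resamples: int
    subsample_fraction: float


@dataclass
class ClusterLabeling:
    stratum: dict[int, str]  # cluster id -> high / medium / low
    cluster_means: dict[int, float]

    def sample_strata(self, labels: pd.Series) -> pd.Series:
        return labels.map(self.stratum).rename("stratum")


@dataclass
class ScoreVector:
    scores: pd.Series  # sample_id -> enrichment score
    method: str
    params: dict


def consensus_matrix(
    expr_sig: ExpressionMatrix,
    k: int,
    n_resamples: int = 5000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Subsampled consensus clustering of samples on the signature genes.

    Per resample a sample subset (fraction ``subsample_fraction``, drawn
    without replacement, all genes retained) is Ward-clustered into ``k``
    groups; consensus(i, j) = co-cluster count / co-sample count.  Final
    labels come from complete-linkage clustering of ``1 - consensus`` cut at k.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValueError("subsample_fraction must lie in (0, 1]")
    X = expr_sig.data.to_numpy(dtype=float).T  # samples x genes
    n = X.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of samples")

    rng = np.random.default_rng(seed)
    m = max(k, int(round(subsample_fraction * n)))
    together = np.zeros((n, n))
    co_drawn = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        co_drawn[np.ix_(idx, idx)] += 1.0
        Z = linkage(X[idx], method="ward")
        labs = fcluster(Z, t=k, criterion="maxclust")
        for c in np.unique(labs):
            mem = idx[labs == c]
            together[np.ix_(mem, mem)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_drawn > 0, together / np.maximum(co_drawn, 1), 0.0)
    consensus = (consensus + consensus.T) / 2.0
    np.fill_diagonal(consensus, 1.0)

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(Z, t=k, criterion="maxclust")

    sample_ids = expr_sig.sample_ids
    return ConsensusResult(
        k=k,
        consensus=pd.DataFrame(consensus, index=sample_ids, columns=sample_ids),
        labels=pd.Series(labels, index=sample_ids, name="cluster"),
        n_resamples=n_resamples,
        subsample_fraction=subsample_fraction,
    )


def _ch_index(X: np.ndarray, labels: np.ndarray) -> float:
    if len(np.unique(labels)) < 2:
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        try:
            return float(calinski_harabasz_score(X, labels))
        except ZeroDivisionError:  # zero within-cluster dispersion
            return np.inf


def choose_k(
    expr_sig: ExpressionMatrix,
    partitions: dict[int, pd.Series],
    evaluate_on: str = "expression",
    consensus_by_k: dict[int, pd.DataFrame] | None = None,
) -> int:
    """Pick the cluster count maximizing the Calinski–Harabasz index.

    The index is evaluated on signature expression (samples as points) by
    default; ``evaluate_on='consensus'`` scores the partition on the rows of
    the consensus matrix instead.
    """
    if not partitions:
        raise ValueError("no candidate partitions")
    scores: dict[int, float] = {}
    for k, labels in sorted(partitions.items()):
        labs = labels.to_numpy()
        counts = np.unique(labs, return_counts=True)[1]
        if (counts == 1).all():
            raise ValueError(f"degenerate singleton-only partition at k={k}")
        if evaluate_on == "consensus":
            if consensus_by_k is None or k not in consensus_by_k:
                raise ValueError("consensus matrices required for evaluate_on='consensus'")
            pts = consensus_by_k[k].to_numpy()
        else:
            pts = expr_sig.data.to_numpy(dtype=float).T
        scores[k] = _ch_index(pts, labs)
    best = max(sorted(scores), key=lambda k: scores[k])
    return best


def label_clusters(labels: pd.Series, expr_sig: ExpressionMatrix) -> ClusterLabeling:
    """Designate the cluster with the highest mean signature expression as
    "high", the lowest as "low", all intermediate clusters as "medium".

    Exact ties for the high or low slot are broken toward the larger cluster
    (reported via a warning); a fully tied labeling is an error.
    """
    clusters = sorted(labels.unique())
    if len(clusters) < 3:
        raise ValueError("need >= 3 clusters to assign high/medium/low")
    means: dict[int, float] = {}
    sizes: dict[int, int] = {}
    for c in clusters:
        ids = labels.index[labels == c]
        means[c] = float(expr_sig.data.loc[:, ids].to_numpy().mean())
        sizes[c] = int(len(ids))
    vals = np.array([means[c] for c in clusters])
    if np.allclose(vals, vals[0], rtol=0, atol=0):
        raise ValueError("all cluster means identical; high/low labeling undefined")

    def _pick(extreme):
        target = extreme(vals)
        cand = [c for c in clusters if means[c] == target]
        if len(cand) > 1:
            warnings.warn(
                f"tie in cluster means at {target:.6g}; breaking toward larger cluster",
                stacklevel=2,
            )
            cand = sorted(cand, key=lambda c: (-sizes[c], c))
        return cand[0]

    high = _pick(np.max)
    low = _pick(np.min)
    stratum = {c: "medium" for c in clusters}
    stratum[high] = "high"
    stratum[low] = "low"
    return ClusterLabeling(stratum=stratum, cluster_means=means)


def _kernel_cdf(x: np.ndarray) -> np.ndarray:
    """Per-gene Gaussian-kernel ECDF evaluated at each sample's own value.

    Bandwidth is the per-gene sample SD / 4.
    """
    sd = x.std(axis=1, ddof=1)
    h = sd / 4.0
    # z[i, j] = mean_k Phi((x[i, j] - x[i, k]) / h[i]); gene-wise to bound memory
    z = np.empty_like(x)
    for i in range(x.shape[0]):
        z[i] = ndtr((x[i, :, None] - x[i, None, :]) / h[i]).mean(axis=1)
    return z


def _walk_es(in_set: np.ndarray, weights: np.ndarray, stat: str) -> float:
    """Weighted KS random walk over an ordered gene list.

    ``in_set`` marks set membership in walk order; ``weights`` are the
    (already ordered) non-negative set-gene weights.  ``stat`` is ``max_diff``
    (max positive deviation minus max negative deviation) or ``sum``
    (the ssGSEA integrated difference).
    """
    p = in_set.size
    m = int(in_set.sum())
    w = np.where(in_set, weights, 0.0)
    denom_in = w.sum()
    if denom_in == 0:
        denom_in = 1.0
    cum_in = np.cumsum(w) / denom_in
    cum_out = np.cumsum(~in_set) / max(p - m, 1)
    v = cum_in - cum_out
    if stat == "sum":
        return float(v.sum())
    max_pos = max(float(v.max()), 0.0)
    max_neg = max(float(-v.min()), 0.0)
    return max_pos - max_neg


def enrichment_score(
    expr: ExpressionMatrix,
    gene_set: GeneSignature,
    method: str = "gsva",
    tau: float = 1.0,
    alpha: float = 0.25,
    normalize: bool = True,
) -> ScoreVector:
    """Single-sample enrichment of ``gene_set`` in each sample.

    ``gsva``: per-gene Gaussian-kernel ECDF across samples, genes ordered per
    sample by the resulting value; weight is the symmetric rank statistic
    ``|p/2 - position|`` raised to ``tau``; ES = max positive minus max
    negative walk deviation.  ``ssgsea``: genes ordered by within-sample
    expression rank, weight ``rank**alpha``; ES = integrated walk difference,
    optionally range-normalized across samples.
    """
    if method not in ("gsva", "ssgsea"):
        raise ValueError(f"unknown method {method!r}")
    df = expr.data
    const = expr.zero_variance_genes()
    if const:
        warnings.warn(f"excluding {len(const)} constant gene(s) from enrichment", stacklevel=2)
        df = df.drop(index=const)
    genes = list(df.index)
    member = np.array([g in set(gene_set.genes) for g in genes])
    if member.sum() < 2:
        raise ValueError("fewer than 2 set genes present in the matrix")
    x = df.to_numpy(dtype=float)
    p, n = x.shape

    scores = np.empty(n)
    if method == "gsva":
        z = _kernel_cdf(x)
        half = p / 2.0
        for j in range(n):
            order = np.argsort(-z[:, j], kind="stable")
            pos = np.arange(1, p + 1)
            weights = np.abs(half - pos) ** tau
            scores[j] = _walk_es(member[order], weights, stat="max_diff")
    else:
        for j in range(n):
            r = rankdata(x[:, j])  # ascending; ties averaged
            order = np.argsort(-r, kind="stable")
            weights = r[order] ** alpha
            scores[j] = _walk_es(member[order], weights, stat="sum")
        if normalize:
            rng_ = scores.max() - scores.min()
            if rng_ > 0:
                scores = scores / rng_

    return ScoreVector(
        scores=pd.Series(scores, index=df.columns, name="es"),
        method=method,
        params={"tau": tau, "alpha": alpha, "normalize": normalize},
    )


def correlation_matrix(expr_sig: ExpressionMatrix):
    """Pairwise Pearson correlation of signature genes with two-sided t-test
    p-values.  Returns (r DataFrame, p DataFrame)."""
    x = expr_sig.data.to_numpy(dtype=float)
    p_genes, n = x.shape
    if n < 3:
        raise ValueError("need >= 3 samples for correlation tests")
    if (x.std(axis=1) == 0).any():
        bad = [g for g, s in zip(expr_sig.gene_ids, x.std(axis=1)) if s == 0]
        raise ValueError(f"zero-variance gene(s): {bad}")
    r = np.corrcoef(x)
    np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    pval = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(pval, 0.0)
    genes = expr_sig.gene_ids
    return (
        pd.DataFrame(r, index=genes, columns=genes),
        pd.DataFrame(pval, index=genes, columns=genes),
    )
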
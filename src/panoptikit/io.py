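"""Readers, writers and preprocessing for the standard formats the pipeline touches.

Expression matrices are genes x samples TSV/CSV with the first column holding
gene symbols.  Preprocessing follows the usual bulk-RNA-seq convention for
cross-platform survival modelling: quantile normalization of samples against
the common reference distribution followed by a log2 transform.  Genes without
a symbol are excluded; duplicate symbols are collapsed by row mean.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSignature, SurvivalTable

DEFAULT_EVENT_CODING = {
    "dead": 1, "deceased": 1, "1": 1, 1: 1, True: 1,
    "alive": 0, "living": 0, "censored": 0, "0": 0, 0: 0, False: 0,
}


def read_expression(path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression table (TSV or CSV).

    Rows with a blank gene symbol are dropped; duplicate symbols are collapsed
    by the row mean.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = {"tsv": "\t", "csv": ","}[fmt]
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df = df.loc[df.index != ""]
    df = df.loc[~df.index.str.lower().isin({"nan", "na"})]
    try:
        df = df.astype(float)
    except ValueError as exc:  # pragma: no cover - message path
        raise ValueError(f"non-numeric expression cells in {path}: {exc}") from exc
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    df.index.name = None
    return ExpressionMatrix(df)


def write_expression(m: ExpressionMatrix, path, fmt: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[fmt]
    m.data.to_csv(path, sep=sep, index_label="gene")


def read_signature(path, roles_path=None, name: str | None = None) -> GeneSignature:
    """Read a one-line GMT gene set, optionally with a companion role table.

    The role table is a two-column TSV (gene, role); genes without an entry
    default to 'effector'.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty GMT file: {path}")
    fields = lines[0].split("\t")
    if len(fields) < 3:
        raise ValueError("malformed GMT line (need name, description, >=1 gene)")
    set_name, genes = fields[0], [g.strip() for g in fields[2:] if g.strip()]
    if not genes:
        raise ValueError("GMT gene set has no genes")
    roles: dict[str, str] = {}
    if roles_path is not None:
        tab = pd.read_csv(roles_path, sep="\t")
        roles = dict(zip(tab["gene"].astype(str), tab["role"].astype(str)))
        roles = {g: roles[g] for g in genes if g in roles}
    return GeneSignature(name=name or set_name, genes=genes, roles=roles)


def write_signature(sig: GeneSignature, path, description: str = "") -> None:
    line = "\t".join([sig.name, description or sig.name, *sig.genes])
    Path(path).write_text(line + "\n")


def packaged_signature() -> GeneSignature:
    """The packaged 27-gene PANoptosis signature with role annotations."""
    data_dir = importlib.resources.files("panoptikit") / "data"
    with importlib.resources.as_file(data_dir / "panoptosis_signature.gmt") as gmt, \
            importlib.resources.as_file(data_dir / "panoptosis_roles.tsv") as roles:
        return read_signature(gmt, roles_path=roles)


def read_clinical(path, event_coding: dict | None = None) -> SurvivalTable:
    """Read a clinical/survival TSV (sample_id, time_days, event, covariates).

    ``event`` may be coded as text ("Dead"/"Alive"); the coding map translates
    it to the 0/1 indicator.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing clinical columns: {sorted(missing)}")
    coding = dict(DEFAULT_EVENT_CODING)
    if event_coding:
        coding.update(event_coding)

    def _code(v):
        key = v.lower() if isinstance(v, str) else v
        if key in coding:
            return coding[key]
        raise ValueError(f"uncodable event value: {v!r}")

    df = df.copy()
    df["event"] = [_code(v) for v in df["event"]]
    df["time_days"] = df["time_days"].astype(float)
    if (df["time_days"] < 0).any():
        raise ValueError("negative follow-up time in clinical table")
    df["sample_id"] = df["sample_id"].astype(str)
    return SurvivalTable(df)


def write_clinical(t: SurvivalTable, path) -> None:
    t.data.to_csv(path, sep="\t", index=False)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples against the mean order statistics.

    Every sample's sorted values are replaced by the cross-sample mean of the
    sorted values; tied values within a sample receive the mean of their
    rank-target values (the classic microarray algorithm).
    """
    x = m.data.to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError("empty matrix")
    if not np.isfinite(x).all():
        raise ValueError("missing values not supported by quantile normalization")
    n_genes, n_samples = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        col = x[:, j]
        targets = np.empty(n_genes)
        targets[order[:, j]] = ref
        # ties get the mean reference value across their tied block
        s = pd.Series(targets).groupby(col).transform("mean").to_numpy()
        out[:, j] = s
    return ExpressionMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns))


def log2_and_filter(m: ExpressionMatrix, offset: float = 1.0):
    """log2(x + offset) transform; returns (matrix, zero-variance gene list).

    ``offset`` defaults to 1 for count-like inputs; pass 0 for data already on
    a positive continuous scale.
    """
    x = m.data.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative values before log2 transform")
    if offset == 0 and (x == 0).any():
        raise ValueError("zeros require a positive log offset")
    out = pd.DataFrame(np.log2(x + offset), index=m.data.index, columns=m.data.columns)
    res = ExpressionMatrix(out)
    return res, res.zero_variance_genes()


def harmonize_symbols(m: ExpressionMatrix, mapping_path) -> ExpressionMatrix:
    """Rename gene symbols via a two-column TSV (old, new); unmapped symbols
    are uppercased.  Duplicates after mapping are collapsed by mean."""
    tab = pd.read_csv(mapping_path, sep="\t", header=None, names=["old", "new"])
    mapping = dict(zip(tab["old"].astype(str), tab["new"].astype(str)))
    df = m.data.copy()
    df.index = [mapping.get(g, g.upper()) for g in df.index]
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df)
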
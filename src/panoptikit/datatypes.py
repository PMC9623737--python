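"""Core containers shared across the pipeline.

Expression data live in a pandas DataFrame with gene symbols as the row index
and sample IDs as columns (log2 scale after preprocessing).  Survival data are
a per-sample table with follow-up time in days and a binary event flag.  The
gene signature is an ordered symbol list with a functional role per gene
(sensor/upstream regulator, adaptor or effector of the inflammatory
cell-death pathway).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ROLES = ("sensor/upstream regulator", "adaptor", "effector")

#: required columns of a survival table
SURVIVAL_COLUMNS = ("sample_id", "time_days", "event")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix keyed by unique gene symbols."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("ExpressionMatrix.data must be a DataFrame")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene symbols (collapse before building)")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if (self.data.index.astype(str).str.strip() == "").any():
            raise ValueError("empty gene symbols present")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValueError("non-finite expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def restrict(self, genes) -> "ExpressionMatrix":
        """Sub-matrix of the listed genes, keeping their order; silently drops
        genes absent from the matrix."""
        present = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[present].copy())

    def zero_variance_genes(self) -> list[str]:
        v = self.data.var(axis=1, ddof=0)
        return list(v.index[v.to_numpy() == 0.0])


@dataclass
class GeneSignature:
    """Ordered gene list with per-gene pathway role labels."""

    name: str
    genes: list[str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("empty gene signature")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")
        for g in self.genes:
            self.roles.setdefault(g, "effector")
        bad = {r for r in self.roles.values()} - set(VALID_ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class SurvivalTable:
    """Per-sample follow-up (days), event indicator and clinical covariates."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SURVIVAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing survival columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample IDs in survival table")
        ev = set(pd.unique(self.data["event"]))
        if not ev <= {0, 1}:
            raise ValueError(f"event indicator must be 0/1, got {sorted(ev)}")
        if (self.data["time_days"].to_numpy() < 0).any():
            raise ValueError("negative follow-up time")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def time(self) -> np.ndarray:
        return self.data["time_days"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, sample_ids) -> "SurvivalTable":
        idx = self.data["sample_id"].isin(list(sample_ids))
        return SurvivalTable(self.data.loc[idx].reset_index(drop=True).copy())

    def aligned_to(self, sample_ids) -> "SurvivalTable":
        """Rows reordered to match ``sample_ids`` exactly (all must exist)."""
        d = self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SurvivalTable(d)
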
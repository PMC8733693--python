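"""Core data containers for the signature pipeline.

The pipeline moves three kinds of data around: a genes x samples expression
matrix (FPKM-like abundances, optionally log2(x+1)-transformed), a per-sample
clinical table (survival, response, tumor mutation burden, covariates), and
named gene sets.  All three are thin, validated wrappers around pandas
objects so that downstream code can rely on their invariants instead of
re-checking them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSet",
    "PipelineConfig",
    "DEFAULT_CTL_GENES",
]

#: Canonical cytotoxic T lymphocyte marker genes whose mean log-expression
#: defines the CTL infiltration proxy.
DEFAULT_CTL_GENES = ("CD8A", "CD8B", "GZMA", "GZMB", "PRF1")


class ExpressionMatrix:
    """Genes x samples abundance matrix.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as index and sample identifiers as
        columns.  Values must be finite, and non-negative unless
        ``log_transformed`` is true.
    log_transformed
        Whether the values are already on the log2(x+1) scale.
    """

    def __init__(self, values: pd.DataFrame, log_transformed: bool = False):
        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(values)
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {values.index[r]!r}, "
                f"sample {values.columns[c]!r}"
            )
        if not log_transformed and np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative abundance at gene {values.index[r]!r}, sample "
                f"{values.columns[c]!r}; raw FPKM-like values must be >= 0"
            )
        self.values = values.astype(float)
        self.log_transformed = bool(log_transformed)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2(self) -> "ExpressionMatrix":
        """Return a log2(x+1)-transformed copy (no-op if already transformed)."""
        if self.log_transformed:
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), log_transformed=True)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], self.log_transformed)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"log_transformed={self.log_transformed})"
        )


#: Columns the clinical table understands, beyond sample_id.
CLINICAL_COLUMNS = ("age", "sex", "time", "event", "response", "tmb", "cancer_type")


class ClinicalTable:
    """Per-sample clinical covariates and outcomes, indexed by sample id.

    ``time``/``event`` carry the survival endpoint (days, 0/1), ``response``
    a binary responder flag, ``tmb`` the tumor mutation burden (count or
    per-Mb density).  All outcome columns are optional; operations check for
    what they need.
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id values: {dups[:5]}")
        if "time" in df.columns:
            t = df["time"].dropna()
            if (t <= 0).any():
                raise ValueError("survival times must be > 0")
            if "event" not in df.columns:
                raise ValueError("'event' column required wherever 'time' is present")
            if df.loc[t.index, "event"].isna().any():
                raise ValueError("'event' missing for samples with a survival time")
            ev = df["event"].dropna()
            if not ev.isin([0, 1]).all():
                raise ValueError("'event' must be 0/1")
        if "response" in df.columns:
            r = df["response"].dropna()
            if not r.isin([0, 1]).all():
                raise ValueError("'response' must be 0/1")
        if "tmb" in df.columns:
            tmb = df["tmb"].dropna()
            if not np.isfinite(tmb.to_numpy(dtype=float)).all() or (tmb < 0).any():
                raise ValueError("'tmb' must be finite and >= 0")
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]

    def __contains__(self, col: str) -> bool:
        return col in self.table.columns

    def aligned_to(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        """Reindex to the given sample order, erroring on missing samples."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing[:5]}")
        return ClinicalTable(self.table.loc[list(sample_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"ClinicalTable({len(self.table)} samples, columns={list(self.table.columns)})"


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (immutable)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __init__(self, name: str, genes: Iterable[str], description: str = ""):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "genes", frozenset(str(g) for g in genes))
        object.__setattr__(self, "description", str(description))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(sorted(self.genes))

    def intersect(self, universe: Iterable[str]) -> "GeneSet":
        return GeneSet(self.name, self.genes & set(universe), self.description)


@dataclass
class PipelineConfig:
    """Tunable parameters of the signature pipeline.

    Defaults mirror the published construction: Spearman correlation screen at
    rho > 0.3 with Benjamini-Hochberg FDR < 0.01, TMB tertiles with a
    rank-sum differential screen, ssGSEA with weight exponent 0.25, the
    0.1..0.9 x 100-repeat subsampling grid, and a 50-400 day window for the
    time-dependent AUC.
    """

    ctl_genes: tuple[str, ...] = DEFAULT_CTL_GENES
    cor_threshold: float = 0.3
    fdr_threshold: float = 0.01
    tgfb_genes: tuple[str, ...] = ()
    ssgsea_alpha: float = 0.25
    subsample_proportions: tuple[float, ...] = tuple(
        round(0.1 * k, 1) for k in range(1, 10)
    )
    subsample_repeats: int = 100
    auc_window: tuple[float, float] = (50.0, 400.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cor_threshold < 1:
            raise ValueError("cor_threshold must be in (0, 1)")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.ssgsea_alpha < 0:
            raise ValueError("ssgsea_alpha must be >= 0")
        for p in self.subsample_proportions:
            if not 0 < p <= 1:
                raise ValueError("subsample proportions must be in (0, 1]")
        if self.subsample_repeats < 1:
            raise ValueError("subsample_repeats must be >= 1")
        t_min, t_max = self.auc_window
        if not t_min < t_max:
            raise ValueError("auc_window must satisfy t_min < t_max")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("ctl_genes", "tgfb_genes", "subsample_proportions", "auc_window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "ctl_genes": list(self.ctl_genes),
            "cor_threshold": self.cor_threshold,
            "fdr_threshold": self.fdr_threshold,
            "tgfb_genes": list(self.tgfb_genes),
            "ssgsea_alpha": self.ssgsea_alpha,
            "subsample_proportions": list(self.subsample_proportions),
            "subsample_repeats": self.subsample_repeats,
            "auc_window": list(self.auc_window),
            "seed": self.seed,
        }
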
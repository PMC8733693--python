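"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices are tab- or comma-separated text with gene ids in the
first column and sample ids in the header; gene sets use the GMT convention
(name TAB description TAB gene...); clinical tables are TSV with a documented
header vocabulary.  Parsers validate and reject rather than silently coerce.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import yaml

from .containers import ClinicalTable, ExpressionMatrix, GeneSet, PipelineConfig

if TYPE_CHECKING:  # pragma: no cover
    from .signature import SignatureResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "read_clinical",
    "read_gmt",
    "write_gmt",
    "write_signature",
    "read_config",
]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path,
    sep: str | None = None,
    log_transform: bool = True,
    log_transformed: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples abundance table.

    Duplicate gene rows are collapsed by keeping the row with the highest mean
    abundance (a warning is logged).  With ``log_transform`` (the default) the
    matrix is returned on the log2(x+1) scale, which is what every screening
    and averaging step downstream expects; set ``log_transformed`` when the
    file already holds log-scale values.
    """
    path = Path(path)
    use_sep = _sep_for(path, sep)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(use_sep)[1:]
    header = [h.strip() for h in header]
    if len(set(header)) < len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate sample columns {dups}")
    df = pd.read_csv(path, sep=use_sep, index_col=0)
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        raise ValueError(
            f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r}, "
            f"row {bad.index[0]!r}"
        )
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.has_duplicates:
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        n_before = len(df)
        df = df[~df.index.duplicated(keep="first")]
        logger.warning(
            "%s: collapsed %d duplicate gene rows (kept highest mean abundance)",
            path,
            n_before - len(df),
        )
    mat = ExpressionMatrix(df, log_transformed=log_transformed)
    if log_transform and not mat.log_transformed:
        mat = mat.log2()
    return mat


def read_clinical(path, sep: str | None = None) -> ClinicalTable:
    """Read a clinical TSV/CSV with a ``sample_id`` column."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table must have a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    return ClinicalTable(df)


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file into a list of gene sets (order preserved)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected name, description and at "
                    f"least one gene, got {len(fields)} fields"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) < len(genes):
                warnings.warn(
                    f"{path}: line {lineno}: duplicate genes in set {name!r} "
                    "were deduplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(name, genes, description))
    return sets


def write_gmt(gene_sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description or ".", *sorted(gs.genes)]) + "\n")


def write_signature(sig: "SignatureResult", path) -> None:
    """Write a built signature as a GMT line plus a provenance table.

    ``path`` is used as a stem: ``<path>.gmt`` holds the gene set (round-trips
    through :func:`read_gmt`), ``<path>.provenance.tsv`` the per-gene screen
    statistics, and ``<path>.sizes.json`` the screen set sizes.
    """
    if len(sig.gene_set) == 0:
        raise ValueError("refusing to write an empty signature")
    stem = Path(path)
    write_gmt([sig.gene_set], stem.with_suffix(".gmt"))
    prov = sig.screen_table.loc[sorted(sig.gene_set.genes)]
    prov.to_csv(stem.parent / (stem.name + ".provenance.tsv"), sep="\t", float_format="%.10g")
    with open(stem.parent / (stem.name + ".sizes.json"), "w", encoding="utf-8") as fh:
        json.dump(sig.set_sizes, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_config(path) -> PipelineConfig:
    """Load a YAML/JSON file mirroring :class:`PipelineConfig`."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)
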
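"""Combinatorial construction of an ICB-response gene signature.

The construction integrates three response axes measured on the same tumor
expression cohort:

* a cytotoxic T lymphocyte (CTL) axis — the mean log-expression of CD8A,
  CD8B, GZMA, GZMB and PRF1 — against which every gene is screened by
  Spearman correlation (rho > 0.3, BH FDR < 0.01, positive side only);
* a tumor mutation burden (TMB) axis — samples are split into TMB tertiles
  and genes differentially high in the TMB-high vs TMB-low group (two-sided
  Wilcoxon rank-sum, BH FDR, up-in-high direction) are retained;
* a TGF-beta/immunosuppression axis — genes positively correlated with a
  TGF-beta response score are flagged for exclusion.

The signature is the set intersection (CTL-passed ∩ TMB-passed) minus the
TGF-beta-passed genes, with full per-gene provenance.  A hypergeometric
over-representation test for annotating any gene list against pathway gene
sets is provided alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    DEFAULT_CTL_GENES,
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    PipelineConfig,
)

__all__ = [
    "SignatureResult",
    "compute_ctl_score",
    "compute_tgfb_score",
    "spearman_screen",
    "tmb_tertiles",
    "tmb_differential",
    "combine_signature",
    "build_signature",
    "hypergeometric_enrichment",
]


@dataclass
class SignatureResult:
    """A built signature with per-gene screen provenance.

    ``screen_table`` is indexed by gene with columns rho_ctl, p_ctl, fdr_ctl,
    rho_tgfb, p_tgfb, fdr_tgfb, tmb_p, tmb_fdr, tmb_direction, passed_ctl,
    passed_tmb, excluded_tgfb, selected (available columns depend on how the
    result was assembled).  ``set_sizes`` counts genes passing each screen and
    the final set.  ``empty`` flags the degenerate outcome where no gene
    survives all screens (a warning, not an error — small or
    mutationally-quiet cohorts legitimately produce it).
    """

    gene_set: GeneSet
    screen_table: pd.DataFrame
    config_snapshot: PipelineConfig | None = None
    set_sizes: dict = field(default_factory=dict)
    empty: bool = False


def _require_log(expr: ExpressionMatrix, what: str) -> ExpressionMatrix:
    if not expr.log_transformed:
        raise ValueError(
            f"{what} expects log2(x+1)-transformed expression; call .log2() first"
        )
    return expr


def compute_ctl_score(
    expr: ExpressionMatrix,
    ctl_genes=DEFAULT_CTL_GENES,
    strict: bool = True,
) -> pd.Series:
    """Per-sample CTL infiltration proxy: mean log-expression of the marker genes.

    With ``strict`` (default) all marker genes must be present; otherwise a
    warned subset is averaged.  At least one marker must always be present.
    """
    _require_log(expr, "compute_ctl_score")
    present = [g for g in ctl_genes if g in expr.values.index]
    missing = [g for g in ctl_genes if g not in expr.values.index]
    if not present:
        raise ValueError(f"no CTL marker genes present in matrix: missing {missing}")
    if missing:
        if strict:
            raise ValueError(f"CTL marker genes absent from matrix: {missing}")
        warnings.warn(
            f"CTL score computed on {len(present)}/{len(ctl_genes)} markers; "
            f"missing {missing}",
            stacklevel=2,
        )
    score = expr.values.loc[present].mean(axis=0)
    score.name = "ctl_score"
    return score


def compute_tgfb_score(expr: ExpressionMatrix, tgfb_genes) -> pd.Series:
    """Per-sample TGF-beta response score: mean of z-standardized log-expression.

    Accepts a :class:`GeneSet` or any iterable of gene ids; genes absent from
    the matrix are dropped, zero-variance genes are dropped with a warning.
    """
    _require_log(expr, "compute_tgfb_score")
    genes = tgfb_genes.genes if isinstance(tgfb_genes, GeneSet) else set(tgfb_genes)
    present = sorted(g for g in genes if g in expr.values.index)
    if not present:
        raise ValueError("no TGF-beta signature genes present in the matrix")
    sub = expr.values.loc[present]
    sd = sub.std(axis=1, ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        warnings.warn(
            f"dropping {len(flat)} zero-variance TGF-beta signature genes", stacklevel=2
        )
        sub, sd = sub.drop(index=flat), sd.drop(index=flat)
    if sub.empty:
        raise ValueError("all TGF-beta signature genes have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    score = z.mean(axis=0)
    score.name = "tgfb_score"
    return score


def spearman_screen(
    expr: ExpressionMatrix,
    axis_score: pd.Series,
    cor_threshold: float = 0.3,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Screen every gene by Spearman correlation against an axis score.

    Returns a gene-indexed frame with rho, two-sided p (t approximation on
    average-ranked data), BH FDR across all well-defined genes, an
    ``undefined`` flag for constant genes (which never pass), and
    ``passed`` = (rho > cor_threshold) & (fdr < fdr_threshold) — the screen
    is one-sided toward positive association by construction.
    """
    n = expr.n_samples
    if n < 5:
        raise ValueError("spearman_screen needs at least 5 samples")
    axis = axis_score.reindex(expr.sample_ids)
    if axis.isna().any() or not np.all(np.isfinite(axis.to_numpy(dtype=float))):
        raise ValueError("axis_score must be finite for every sample in the matrix")
    a = axis.to_numpy(dtype=float)
    if np.all(a == a[0]):
        raise ValueError("axis_score is constant; correlation undefined")

    X = expr.values.to_numpy()
    rx = stats.rankdata(X, axis=1)
    ra = stats.rankdata(a)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ra_c = ra - ra.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (ra_c**2).sum())
    undefined = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx_c @ ra_c) / denom
    rho = np.where(undefined, np.nan, np.clip(rho, -1.0, 1.0))

    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(undefined, np.nan, p)

    fdr = np.full_like(p, np.nan)
    ok = ~undefined
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    passed = ok & (rho > cor_threshold) & (fdr < fdr_threshold)
    return pd.DataFrame(
        {"rho": rho, "p": p, "fdr": fdr, "undefined": undefined, "passed": passed},
        index=expr.values.index,
    )


def tmb_tertiles(clinical: ClinicalTable, samples=None) -> pd.Series:
    """Split samples into low/middle/high TMB tertiles.

    Samples are ranked by TMB ascending with ties broken by sample id, then
    cut at ranks ceil(n/3) and ceil(2n/3); group sizes differ by at most one
    and the assignment is fully deterministic.
    """
    tab = clinical.table if samples is None else clinical.aligned_to(samples).table
    if "tmb" not in tab.columns or tab["tmb"].isna().any():
        raise ValueError("tmb must be present for all samples")
    n = len(tab)
    if n < 6:
        raise ValueError("tmb_tertiles needs at least 6 samples")
    tmb = tab["tmb"].astype(float)
    if tmb.nunique() == 1:
        raise ValueError("all TMB values are identical; tertiles are meaningless")
    order = sorted(tab.index, key=lambda s: (tmb[s], str(s)))
    c1 = int(np.ceil(n / 3))
    c2 = int(np.ceil(2 * n / 3))
    labels = pd.Series(index=tab.index, dtype=object, name="tmb_group")
    labels[order[:c1]] = "low"
    labels[order[c1:c2]] = "middle"
    labels[order[c2:]] = "high"
    return labels


def tmb_differential(
    expr: ExpressionMatrix,
    groups: pd.Series,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-gene TMB-high vs TMB-low differential screen.

    Two-sided Wilcoxon rank-sum p per gene, BH FDR across genes, direction by
    comparing group medians; ``passed`` requires FDR below threshold *and*
    the gene being higher in the TMB-high group.  The middle tertile is
    ignored.
    """
    groups = groups.reindex(expr.sample_ids)
    high = [s for s in expr.sample_ids if groups[s] == "high"]
    low = [s for s in expr.sample_ids if groups[s] == "low"]
    if len(high) < 3 or len(low) < 3:
        raise ValueError(
            f"need >= 3 samples per extreme tertile, got high={len(high)}, low={len(low)}"
        )
    Xh = expr.values[high].to_numpy()
    Xl = expr.values[low].to_numpy()

    both = np.concatenate([Xh, Xl], axis=1)
    constant = np.all(both == both[:, [0]], axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(Xh, Xl, axis=1, alternative="two-sided", method="auto")
    p = np.asarray(res.pvalue, dtype=float)
    p[constant | ~np.isfinite(p)] = 1.0

    med_h = np.median(Xh, axis=1)
    med_l = np.median(Xl, axis=1)
    direction = np.where(
        med_h > med_l, "up_in_high", np.where(med_h < med_l, "up_in_low", "flat")
    )
    fdr = multipletests(p, method="fdr_bh")[1]
    passed = (fdr < fdr_threshold) & (direction == "up_in_high")
    return pd.DataFrame(
        {"p": p, "fdr": fdr, "direction": direction, "passed": passed},
        index=expr.values.index,
    )


def combine_signature(
    ctl_passed,
    tmb_passed,
    tgfb_passed,
    screen_table: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    name: str = "ITS",
) -> SignatureResult:
    """Set algebra of the three screens: (CTL ∩ TMB) \\ TGF-beta.

    Emits a warning (not an error) when the result is empty — the outcome a
    cohort with discordant CTL and TMB axes produces.
    """
    ctl, tmb, tgfb = (set(x) for x in (ctl_passed, tmb_passed, tgfb_passed))
    selected = (ctl & tmb) - tgfb
    empty = len(selected) == 0
    if empty:
        warnings.warn(
            "signature is empty: no gene passed both the CTL and TMB screens "
            "after TGF-beta exclusion",
            stacklevel=2,
        )
    if screen_table is None:
        screen_table = pd.DataFrame(index=sorted(ctl | tmb | tgfb))
        screen_table["passed_ctl"] = screen_table.index.isin(ctl)
        screen_table["passed_tmb"] = screen_table.index.isin(tmb)
        screen_table["excluded_tgfb"] = screen_table.index.isin(tgfb)
    screen_table = screen_table.copy()
    screen_table["selected"] = screen_table.index.isin(selected)
    return SignatureResult(
        gene_set=GeneSet(name, selected, "combinatorial ICB response signature"),
        screen_table=screen_table,
        config_snapshot=config,
        set_sizes={
            "ctl_passed": len(ctl),
            "tmb_passed": len(tmb),
            "tgfb_excluded": len(tgfb),
            "final": len(selected),
        },
        empty=empty,
    )


def build_signature(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    tgfb_genes,
    config: PipelineConfig | None = None,
    strict_ctl: bool = True,
) -> SignatureResult:
    """Run the full construction on one cohort.

    Computes the CTL and TGF-beta axis scores, screens every gene by Spearman
    correlation against each, screens TMB-high vs TMB-low tertile
    differential expression, and combines the three screens into the final
    signature with a full provenance table.  Raw (non-log) matrices are
    log2(x+1)-transformed first.
    """
    config = config or PipelineConfig()
    if not expr.log_transformed:
        expr = expr.log2()
    clin = clinical.aligned_to(expr.sample_ids)

    ctl_score = compute_ctl_score(expr, config.ctl_genes, strict=strict_ctl)
    tgfb_score = compute_tgfb_score(expr, tgfb_genes)
    ctl_scr = spearman_screen(expr, ctl_score, config.cor_threshold, config.fdr_threshold)
    tgfb_scr = spearman_screen(expr, tgfb_score, config.cor_threshold, config.fdr_threshold)
    groups = tmb_tertiles(clin)
    tmb_scr = tmb_differential(expr, groups, config.fdr_threshold)

    table = pd.DataFrame(
        {
            "rho_ctl": ctl_scr["rho"],
            "p_ctl": ctl_scr["p"],
            "fdr_ctl": ctl_scr["fdr"],
            "rho_tgfb": tgfb_scr["rho"],
            "p_tgfb": tgfb_scr["p"],
            "fdr_tgfb": tgfb_scr["fdr"],
            "tmb_p": tmb_scr["p"],
            "tmb_fdr": tmb_scr["fdr"],
            "tmb_direction": tmb_scr["direction"],
            "passed_ctl": ctl_scr["passed"],
            "passed_tmb": tmb_scr["passed"],
            "excluded_tgfb": tgfb_scr["passed"],
        },
        index=expr.values.index,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        result = combine_signature(
            set(table.index[table["passed_ctl"]]),
            set(table.index[table["passed_tmb"]]),
            set(table.index[table["excluded_tgfb"]]),
            screen_table=table,
            config=config,
        )
    if result.empty:
        warnings.warn("built signature is empty for this cohort", stacklevel=2)
    return result


def hypergeometric_enrichment(
    query, pathways: list[GeneSet], universe
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a gene list in pathways.

    For each pathway, p = P(X >= k) with population |universe|, |pathway|
    successes and |query| draws, where k is the observed overlap; BH FDR is
    taken across pathways.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    qgenes = set(query.genes if isinstance(query, GeneSet) else query) & universe
    if not qgenes:
        raise ValueError("query has no genes inside the universe")
    rows = []
    for pw in pathways:
        pset = set(pw.genes) & universe
        k = len(pset & qgenes)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(pset), len(qgenes)))
        rows.append({"pathway": pw.name, "size": len(pset), "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("pathway")
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1] if len(out) else []
    return out
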
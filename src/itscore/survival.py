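"""Outcome evaluation of a per-sample score.

Stratification at the median, Kaplan-Meier curves, log-rank testing, Cox
proportional-hazards fits (Efron tie handling, via lifelines), responder
comparison with Mann-Whitney AUC, cumulative/dynamic time-dependent AUC with
inverse-probability-of-censoring weights, head-to-head biomarker comparison,
and the gene-subsampling robustness experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .containers import ClinicalTable, ExpressionMatrix, PipelineConfig
from .scoring import ScoreVector, build_ssgsea_cache, score_with_subset, ssgsea_score

__all__ = [
    "median_split",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "compare_responders",
    "time_dependent_auc",
    "stratify_survival",
    "subsample_robustness",
    "compare_biomarkers",
    "SurvivalStratification",
]


def _as_series(scores) -> pd.Series:
    if isinstance(scores, ScoreVector):
        return scores.scores
    return pd.Series(scores)


def median_split(scores) -> pd.Series:
    """High/low split at the median score; ties at the median go to ``low``
    so that ``high`` is a strict exceedance set."""
    s = _as_series(scores)
    if len(s) < 4:
        raise ValueError("median_split needs at least 4 samples")
    med = float(np.median(s.to_numpy(dtype=float)))
    if s.nunique() == 1:
        raise ValueError("all scores identical; median split is degenerate")
    group = pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")
    if (group == "high").sum() == 0 or (group == "low").sum() == 0:
        raise ValueError("median split produced an empty group")
    return group


def km_estimate(time, event, group=None) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves, one per group.

    Returns, per group, a frame with columns time, survival and at_risk.
    With ``group=None`` a single curve named ``all`` is returned.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time <= 0):
        raise ValueError("times must be > 0")
    group = np.full(len(time), "all") if group is None else np.asarray(group)
    curves = {}
    for g in pd.unique(group):
        mask = group == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        curves[str(g)] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(),
                "at_risk": at_risk.to_numpy(dtype=float),
            }
        )
    return curves


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"logrank_test needs exactly 2 groups, got {len(levels)}")
    m0, m1 = group == levels[0], group == levels[1]
    if m0.sum() == 0 or m1.sum() == 0:
        raise ValueError("a group has zero subjects")
    if event[m0].sum() == 0 and event[m1].sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(time[m0], time[m1], event_observed_A=event[m0], event_observed_B=event[m1])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    time,
    event,
    covariates: pd.DataFrame,
    robust: bool = False,
) -> pd.DataFrame:
    """Cox proportional-hazards fit with Efron tie handling.

    ``covariates`` is a samples x covariates frame (categorical columns are
    dummy-coded); returns per-covariate hazard ratio, 95% Wald CI bounds and
    p-value.  Warns below 10 events; errors on constant covariates.
    """
    cov = pd.get_dummies(covariates, drop_first=True).astype(float)
    for c in cov.columns:
        if cov[c].nunique() == 1:
            raise ValueError(f"covariate {c!r} is constant")
    n_events = int(np.asarray(event).sum())
    if n_events < 10:
        warnings.warn(
            f"only {n_events} events; hazard-ratio estimates will be unstable",
            stacklevel=2,
        )
    df = cov.copy()
    df["time"] = np.asarray(time, dtype=float)
    df["event"] = np.asarray(event, dtype=int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event", robust=robust)
    except Exception as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary
    return pd.DataFrame(
        {
            "hr": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef lower 95%"]),
            "ci_high": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    )


def compare_responders(scores, response) -> dict:
    """Responder vs non-responder score comparison.

    Two-sided Wilcoxon rank-sum p, group medians, and the Mann-Whitney AUC
    (probability a responder outscores a non-responder, ties counted 1/2).
    """
    s = _as_series(scores).to_numpy(dtype=float)
    r = np.asarray(response, dtype=int)
    pos, neg = s[r == 1], s[r == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both responder classes must be present")
    u, p = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="auto")
    return {
        "p": float(p),
        "median_responder": float(np.median(pos)),
        "median_nonresponder": float(np.median(neg)),
        "auc": float(u) / (len(pos) * len(neg)),
        "n_responder": int(len(pos)),
        "n_nonresponder": int(len(neg)),
    }


def _censor_km_left(time, event):
    """KM of the censoring distribution; returns a step-lookup G(t-)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), 1 - np.asarray(event, dtype=int))
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy()

    def g_left(t: np.ndarray) -> np.ndarray:
        # value of the (right-continuous) KM step just before t
        idx = np.searchsorted(times, t, side="left") - 1
        out = np.ones_like(t, dtype=float)
        ok = idx >= 0
        out[ok] = surv[idx[ok]]
        return out

    return g_left


def time_dependent_auc(scores, time, event, eval_times) -> pd.DataFrame:
    """Cumulative/dynamic AUC(t) with IPCW over a grid of evaluation times.

    Cases at t are subjects with an observed event by t, weighted by
    1/G(T-)^2 where G is the Kaplan-Meier censoring-survival estimate;
    controls are subjects still at risk beyond t.  Grid points with no
    evaluable case or control are flagged (``defined=False``) with AUC NaN
    rather than fabricated.
    """
    s = _as_series(scores).to_numpy(dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eval_times = np.asarray(eval_times, dtype=float)
    if event.sum() == 0:
        raise ValueError("no events at all; time-dependent AUC undefined")
    g_left = _censor_km_left(time, event)
    g_at_event = g_left(time)
    rows = []
    for t in eval_times:
        case = (time <= t) & (event == 1) & (g_at_event > 0)
        ctrl = time > t
        n_case, n_ctrl = int(case.sum()), int(ctrl.sum())
        if n_case == 0 or n_ctrl == 0:
            rows.append({"t": t, "auc": np.nan, "n_cases": n_case, "n_controls": n_ctrl, "defined": False})
            continue
        w = 1.0 / g_at_event[case] ** 2
        sc, st = s[case], s[ctrl]
        conc = (sc[:, None] > st[None, :]) + 0.5 * (sc[:, None] == st[None, :])
        num = (w[:, None] * conc).sum()
        den = w.sum() * n_ctrl
        rows.append({"t": t, "auc": num / den, "n_cases": n_case, "n_controls": n_ctrl, "defined": True})
    return pd.DataFrame(rows)


@dataclass
class SurvivalStratification:
    """Median-split survival evaluation bundle."""

    group: pd.Series
    km_curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    cox_p: float
    adjusted_for: tuple[str, ...]


def stratify_survival(
    scores,
    clinical: ClinicalTable,
    adjust: tuple[str, ...] = (),
) -> SurvivalStratification:
    """Median-split a score and evaluate survival separation.

    Runs KM estimation per group, the log-rank test, and a Cox model for the
    high-vs-low indicator optionally adjusted for clinical covariates (e.g.
    age and sex).  The hazard ratio is high vs low.
    """
    s = _as_series(scores)
    clin = clinical.aligned_to(list(s.index))
    time = clin["time"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=int)
    group = median_split(s)
    km = km_estimate(time, event, group.to_numpy())
    chi2, p = logrank_test(time, event, group.to_numpy())
    cov = pd.DataFrame({"high": (group == "high").astype(float)}, index=s.index)
    for c in adjust:
        cov[c] = clin[c]
    fit = cox_fit(time, event, cov)
    return SurvivalStratification(
        group=group,
        km_curves=km,
        logrank_chi2=chi2,
        logrank_p=p,
        hr=float(fit.loc["high", "hr"]),
        hr_ci=(float(fit.loc["high", "ci_low"]), float(fit.loc["high", "ci_high"])),
        cox_p=float(fit.loc["high", "p"]),
        adjusted_for=tuple(adjust),
    )


def subsample_robustness(
    expr: ExpressionMatrix,
    gene_set,
    clinical: ClinicalTable,
    config: PipelineConfig | None = None,
    method: str = "ssgsea",
    compute_hr: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random-gene-subset robustness of the signature's prognostic power.

    For each proportion (default 0.1..0.9) and repeat (default 100) the gene
    set is subsampled, rescored, and compared to the full-set score (Spearman
    correlation) and to survival (median-split log-rank p, and the
    high-vs-low hazard ratio when ``compute_hr``).  Returns the per-repeat
    table and a per-proportion summary (median and IQR of the correlation,
    fraction of repeats with log-rank p < 0.05).
    """
    config = config or PipelineConfig()
    if not expr.log_transformed:
        expr = expr.log2()
    clin = clinical.aligned_to(expr.sample_ids)
    time = clin["time"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=int)

    cache = build_ssgsea_cache(expr, alpha=config.ssgsea_alpha) if method == "ssgsea" else None
    if method == "ssgsea":
        full = ssgsea_score(expr, gene_set, alpha=config.ssgsea_alpha, cache=cache)
    else:
        full = score_with_subset(expr, gene_set, 1.0, 1, method=method, seed=0)[0]
    full_s = full.scores.to_numpy()

    rows = []
    for prop in config.subsample_proportions:
        kwargs = {"alpha": config.ssgsea_alpha} if method == "ssgsea" else {}
        subs = score_with_subset(
            expr,
            gene_set,
            prop,
            config.subsample_repeats,
            method=method,
            seed=config.seed + int(round(prop * 1000)),
            cache=cache,
            **kwargs,
        )
        for rep, sv in enumerate(subs):
            sub_s = sv.scores.to_numpy()
            rho = stats.spearmanr(sub_s, full_s).statistic
            try:
                grp = median_split(sv.scores)
                _, lr_p = logrank_test(time, event, grp.to_numpy())
                hr = np.nan
                if compute_hr:
                    fit = cox_fit(
                        time,
                        event,
                        pd.DataFrame({"high": (grp == "high").astype(float)}, index=sv.scores.index),
                    )
                    hr = float(fit.loc["high", "hr"])
            except ValueError:
                lr_p, hr = np.nan, np.nan
            rows.append(
                {"proportion": prop, "repeat": rep, "correlation": rho, "logrank_p": lr_p, "hr": hr}
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("proportion")
        .agg(
            median_correlation=("correlation", "median"),
            iqr_correlation=("correlation", lambda x: x.quantile(0.75) - x.quantile(0.25)),
            frac_significant=("logrank_p", lambda x: float(np.mean(x < 0.05))),
        )
        .reset_index()
    )
    return table, summary


def compare_biomarkers(
    biomarkers: dict[str, pd.Series],
    clinical: ClinicalTable,
    max_missing: float = 0.2,
) -> pd.DataFrame:
    """Head-to-head prognostic and response comparison of per-sample markers.

    Each marker is standardized to unit variance and entered as a continuous
    covariate in a univariate Cox model (so hazard ratios are per-SD and
    comparable across markers), and its responder-vs-non-responder AUC is
    computed on the same cohort.  Markers missing for more than
    ``max_missing`` of samples are excluded with a warning.
    """
    rows = []
    for name, series in biomarkers.items():
        s = pd.Series(series, dtype=float)
        clin = clinical.aligned_to(list(s.index))
        miss = s.isna().mean()
        if miss > max_missing:
            warnings.warn(
                f"biomarker {name!r} missing for {miss:.0%} of samples; excluded",
                stacklevel=2,
            )
            continue
        keep = s.notna()
        s = s[keep]
        clin = clinical.aligned_to(list(s.index))
        z = (s - s.mean()) / s.std(ddof=1)
        fit = cox_fit(
            clin["time"].to_numpy(dtype=float),
            clin["event"].to_numpy(dtype=int),
            pd.DataFrame({"marker": z}),
        )
        hr = float(fit.loc["marker", "hr"])
        cox_p = float(fit.loc["marker", "p"])
        auc = np.nan
        if "response" in clin and clin["response"].notna().all():
            auc = compare_responders(s, clin["response"].to_numpy(dtype=int))["auc"]
        stars = "***" if cox_p < 0.001 else "**" if cox_p < 0.01 else "*" if cox_p < 0.05 else ""
        rows.append(
            {"biomarker": name, "hr": hr, "cox_p": cox_p, "response_auc": auc, "significance": stars}
        )
    return pd.DataFrame(rows).set_index("biomarker")
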
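"""Associating a signature score with per-sample features.

Each feature (an immune-cell fraction, an expression program, a mutation
indicator, ...) is tested by comparing two nested linear mixed models fit by
maximum likelihood:

    score ~ feature + age + sex + (1 | cancer_type)      (full)
    score ~           age + sex + (1 | cancer_type)      (reduced)

The likelihood-ratio statistic 2*(ll_full - ll_reduced) is referred to
chi-square with 1 df, Benjamini-Hochberg FDR is taken across the feature
family, and the conditional R-squared of the full model — the variance
explained by fixed plus random terms over the total — is reported following
the variance-partition definition: R2_c = (var_fixed + var_random) /
(var_fixed + var_random + var_residual).

ML (not REML) is used for both fits so the likelihood-ratio test on a fixed
effect is valid.  With a single grouping level the random intercept is not
identifiable and an ordinary-least-squares fallback is used and flagged;
fits whose random-intercept variance collapses to zero are legitimate with
few groups (two cancer types is the typical design) and are flagged rather
than dropped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .scoring import ScoreVector

__all__ = ["associate_features", "feature_heatmap_table"]

_P_FLOOR = 1e-300


def _design(covariates: pd.DataFrame | None, index: pd.Index) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0}, index=index)
    if covariates is not None:
        cov = covariates.loc[index]
        for c in cov.columns:
            col = cov[c]
            if not pd.api.types.is_numeric_dtype(col):
                codes, _ = pd.factorize(col, sort=True)
                col = pd.Series(codes, index=col.index, dtype=float)
            X[c] = col.astype(float)
    return X


def _fit_ml(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray | None):
    """Fit by ML; returns (loglik, fe_params, re_var, resid_var, converged)."""
    if groups is None:
        res = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        beta = res[0]
        resid = y - X.to_numpy() @ beta
        n = len(y)
        sigma2 = float(resid @ resid) / n  # ML variance
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        return ll, beta, 0.0, sigma2, True
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM(y, X.to_numpy(), groups=groups)
        # optimizers differ in robustness when the random-intercept variance
        # sits on the boundary; take the first with a finite likelihood
        for method in ("bfgs", "powell", "nm"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(cand.llf):
                if fit is None or cand.llf > fit.llf:
                    fit = cand
                if cand.converged:
                    break
    if fit is None:
        raise ValueError("mixed-model log-likelihood is not finite")
    # fit.cov_re is on the response scale (cov_re_unscaled is the profiled one)
    re_var = float(np.atleast_2d(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
    return float(fit.llf), np.asarray(fit.fe_params), re_var, float(fit.scale), bool(fit.converged)


def associate_features(
    score,
    features: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    grouping: pd.Series | None = None,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Mixed-model scan of per-sample features against a signature score.

    Parameters
    ----------
    score
        :class:`~itscore.scoring.ScoreVector` or Series indexed by sample.
    features
        Samples x features numeric frame; each feature is standardized
        internally and tested on its complete cases.
    covariates
        Fixed covariates (e.g. age, sex); categorical columns are coded.
    grouping
        Random-intercept grouping factor (e.g. cancer type).  With fewer
        than 2 levels the fixed-effects fallback is used and flagged.

    Returns
    -------
    DataFrame indexed by feature with lrt_stat, p, fdr, conditional_r2,
    direction, n_used, significant, converged and fallback columns.
    Constant features are skipped with a warning.
    """
    y_all = score.scores if isinstance(score, ScoreVector) else pd.Series(score)
    features = features.loc[y_all.index]
    grp_all = None
    if grouping is not None:
        grp_all = pd.Series(grouping).loc[y_all.index]
        if grp_all.nunique() < 2:
            grp_all = None

    rows = []
    for feat in features.columns:
        f = pd.to_numeric(features[feat], errors="coerce")
        mask = f.notna() & y_all.notna()
        if covariates is not None:
            mask &= covariates.loc[y_all.index].notna().all(axis=1)
        idx = y_all.index[mask]
        f = f.loc[idx]
        if f.nunique() <= 1:
            warnings.warn(f"feature {feat!r} is constant; skipped", stacklevel=2)
            continue
        y = y_all.loc[idx].to_numpy(dtype=float)
        fz = ((f - f.mean()) / f.std(ddof=1)).to_numpy()
        X0 = _design(covariates, idx)
        X1 = X0.copy()
        X1.insert(1, "feature", fz)
        grp = grp_all.loc[idx].to_numpy() if grp_all is not None else None

        try:
            ll1, beta1, re_var, resid_var, conv1 = _fit_ml(y, X1, grp)
            ll0, _, _, _, conv0 = _fit_ml(y, X0, grp)
        except (np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"feature {feat!r}: fit failed ({exc}); skipped", stacklevel=2)
            continue
        lrt = max(2.0 * (ll1 - ll0), 0.0)
        p = max(float(stats.chi2.sf(lrt, df=1)), _P_FLOOR)
        var_fixed = float(np.var(X1.to_numpy() @ beta1))
        total = var_fixed + re_var + resid_var
        r2c = (var_fixed + re_var) / total if total > 0 else 1.0
        rows.append(
            {
                "feature": feat,
                "lrt_stat": lrt,
                "p": p,
                "conditional_r2": min(max(r2c, 0.0), 1.0),
                "direction": int(np.sign(beta1[1])),
                "n_used": len(idx),
                "converged": conv1 and conv0,
                "fallback": grp is None and grouping is not None,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "lrt_stat", "p", "fdr", "conditional_r2", "direction",
                "n_used", "significant", "converged", "fallback",
            ]
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out[
        [
            "lrt_stat", "p", "fdr", "conditional_r2", "direction",
            "n_used", "significant", "converged", "fallback",
        ]
    ]


def feature_heatmap_table(
    records: pd.DataFrame, features: pd.DataFrame, score
) -> pd.DataFrame:
    """Plotting-ready matrix: features (rows) x samples (columns).

    Samples are ordered by ascending score (ties broken by sample id for a
    stable, reproducible order), features are z-scaled across samples and
    rows are ordered by conditional R-squared descending.
    """
    s = score.scores if isinstance(score, ScoreVector) else pd.Series(score)
    order = sorted(s.index, key=lambda i: (s[i], str(i)))
    feats = [f for f in records.sort_values("conditional_r2", ascending=False).index
             if f in features.columns]
    sub = features.loc[order, feats].astype(float)
    z = (sub - sub.mean()) / sub.std(ddof=1)
    return z.T
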
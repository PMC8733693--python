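"""Synthetic bulk-expression cohorts with planted signature structure.

The generator emulates the statistical skeleton the signature pipeline
assumes in real tumor cohorts: three per-sample latent factors — immune
activation (driving cytotoxic T-cell infiltration), mutational load (driving
tumor mutation burden), and a TGF-beta-like suppression axis — each loading
onto a dedicated gene block, with an overlap block driven jointly by the
immune and mutational factors.  That overlap block is the planted "true
signature" the construction pipeline is supposed to recover.  Survival
follows a Weibull proportional-hazards model on the immune+mutational
composite (high signal protective), response is a logistic function of the
same composite, and cancer-type groups shift the immune baseline so that
random-intercept models have something to absorb.

Every draw flows from one ``numpy.random.Generator`` seeded by the config, so
regeneration is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import DEFAULT_CTL_GENES, ClinicalTable, ExpressionMatrix, GeneSet

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_feature_table",
    "truth_overlap_report",
]


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Block sizes: ``n_ctl_only`` genes (including the five CTL marker genes)
    load on the immune factor only, ``n_tmb_only`` on the mutational factor
    only, ``n_overlap`` on both (the planted signature), ``n_tgfb`` on the
    suppression factor; all remaining genes are pure noise.

    ``effect_r`` is the target Pearson/Spearman correlation between a block
    gene's log-expression and its latent factor.  ``hr_true`` is the hazard
    ratio per standard deviation of the immune+mutational composite (values
    below 1 mean high signal is protective).  ``factor_corr`` gives the
    pairwise latent correlations (immune-mutational, immune-suppression,
    mutational-suppression).
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_ctl_only: int = 60
    n_overlap: int = 60
    n_tmb_only: int = 60
    n_tgfb: int = 40
    effect_r: float = 0.5
    factor_corr: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hr_true: float = 0.5
    response_intercept: float = -1.0
    response_slope: float = 1.0
    censor_rate: float = 0.3
    weibull_shape: float = 1.0
    baseline_median_days: float = 365.0
    tmb_mean: float = 150.0
    tmb_dispersion: float = 5.0
    tmb_beta: float = 0.8
    n_groups: int = 2
    group_shift_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        n_block = self.n_ctl_only + self.n_overlap + self.n_tmb_only + self.n_tgfb
        if n_block >= self.n_genes:
            raise ValueError(
                f"block sizes ({n_block}) must sum to less than n_genes ({self.n_genes})"
            )
        if self.n_ctl_only < len(DEFAULT_CTL_GENES):
            raise ValueError("n_ctl_only must fit the five CTL marker genes")
        if not 0 <= self.effect_r < 1:
            raise ValueError("effect_r must be in [0, 1)")
        if 2 * self.effect_r**2 > 1:
            raise ValueError("effect_r too large for jointly-driven overlap genes")
        if self.hr_true <= 0:
            raise ValueError("hr_true must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure of a generated cohort, for recovery tests."""

    ctl_block: frozenset[str]
    tmb_block: frozenset[str]
    tgfb_block: frozenset[str]
    overlap_block: frozenset[str]
    effect_r: float
    hr_true: float
    response_logit_slope: float
    censor_rate: float

    def __post_init__(self) -> None:
        if not self.overlap_block <= (self.ctl_block & self.tmb_block):
            raise ValueError("overlap_block must lie inside ctl_block ∩ tmb_block")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth: SyntheticTruth
    seed: int
    #: Per-sample latent factors (immune, mutational, suppression, composite).
    latent: pd.DataFrame = field(repr=False, default=None)


def _factor_chol(corr: tuple[float, float, float]) -> np.ndarray:
    r_im, r_is, r_ms = corr
    C = np.array([[1.0, r_im, r_is], [r_im, 1.0, r_ms], [r_is, r_ms, 1.0]])
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"factor_corr {corr} is not positive definite") from exc


def _calibrate_censor_horizon(event_times: np.ndarray, censor_rate: float) -> float:
    """Bisection for the uniform-censoring horizon hitting the target rate.

    With C ~ Uniform(0, c_max) independent of T, the expected censored
    fraction is mean(min(T_i / c_max, 1)), monotone decreasing in c_max.
    """
    lo, hi = 1e-9, float(event_times.max()) / max(censor_rate, 1e-9) + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = np.minimum(event_times / mid, 1.0).mean()
        if frac > censor_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort with planted signature blocks and linked outcomes."""
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    r = config.effect_r

    # latent factors with configurable pairwise correlation
    L = _factor_chol(config.factor_corr)
    z = rng.standard_normal((n, 3)) @ L.T
    # cancer-type groups shift the immune baseline; re-standardize so block
    # correlations still target effect_r
    groups = rng.integers(0, config.n_groups, size=n)
    shifts = rng.normal(0.0, config.group_shift_sd, size=config.n_groups)
    z_immune = (z[:, 0] + shifts[groups]) / np.sqrt(1.0 + config.group_shift_sd**2)
    z_mut, z_supp = z[:, 1], z[:, 2]
    composite = (z_immune + z_mut) / np.sqrt(2.0)

    # gene identifiers: five CTL markers inside the immune-only block, the
    # rest synthetic ids; blocks occupy the leading rows (order carries no
    # information for any rank- or correlation-based step)
    markers = list(DEFAULT_CTL_GENES)
    other = [f"G{i:05d}" for i in range(g - len(markers))]
    it = iter(other)
    ctl_only = markers + [next(it) for _ in range(config.n_ctl_only - len(markers))]
    overlap = [next(it) for _ in range(config.n_overlap)]
    tmb_only = [next(it) for _ in range(config.n_tmb_only)]
    tgfb = [next(it) for _ in range(config.n_tgfb)]
    noise_genes = list(it)
    gene_ids = ctl_only + overlap + tmb_only + tgfb + noise_genes

    # log2-scale expression: baseline + factor loading + unit-variance noise,
    # clipped at zero so FPKM = 2^x - 1 stays non-negative
    baseline = rng.uniform(2.0, 8.0, size=g)
    logx = np.empty((g, n))
    sl = np.cumsum(
        [0, config.n_ctl_only, config.n_overlap, config.n_tmb_only, config.n_tgfb]
    )
    single = np.sqrt(1.0 - r**2)
    joint = np.sqrt(max(1.0 - 2.0 * r**2, 0.0))
    eps = rng.standard_normal((g, n))
    logx[sl[0]:sl[1]] = r * z_immune + single * eps[sl[0]:sl[1]]
    logx[sl[1]:sl[2]] = r * z_immune + r * z_mut + joint * eps[sl[1]:sl[2]]
    logx[sl[2]:sl[3]] = r * z_mut + single * eps[sl[2]:sl[3]]
    logx[sl[3]:sl[4]] = r * z_supp + single * eps[sl[3]:sl[4]]
    logx[sl[4]:] = eps[sl[4]:]
    logx += baseline[:, None]
    np.clip(logx, 0.0, None, out=logx)
    fpkm = np.exp2(logx) - 1.0

    sample_ids = [f"S{i:04d}" for i in range(n)]
    expr = ExpressionMatrix(
        pd.DataFrame(fpkm, index=gene_ids, columns=sample_ids), log_transformed=False
    )

    # TMB: negative binomial around an exponential link of the mutational factor
    mu = config.tmb_mean * np.exp(config.tmb_beta * z_mut)
    p_nb = config.tmb_dispersion / (config.tmb_dispersion + mu)
    tmb = rng.negative_binomial(config.tmb_dispersion, p_nb)

    # survival: Weibull proportional hazards on the composite, beta = log(hr)
    beta = np.log(config.hr_true)
    k = config.weibull_shape
    scale = config.baseline_median_days / np.log(2.0) ** (1.0 / k)
    u = rng.uniform(size=n)
    t_event = scale * (-np.log(u) / np.exp(beta * composite)) ** (1.0 / k)
    if config.censor_rate > 0:
        c_max = _calibrate_censor_horizon(t_event, config.censor_rate)
        t_cens = rng.uniform(0.0, c_max, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    time = np.maximum(time, 1e-6)

    p_resp = 1.0 / (
        1.0 + np.exp(-(config.response_intercept + config.response_slope * composite))
    )
    response = rng.binomial(1, p_resp)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "age": np.round(rng.normal(65.0, 9.0, size=n), 1),
                "sex": rng.choice(["F", "M"], size=n),
                "time": time,
                "event": event,
                "response": response,
                "tmb": tmb,
                "cancer_type": [f"CT{gi + 1}" for gi in groups],
            }
        )
    )

    truth = SyntheticTruth(
        ctl_block=frozenset(ctl_only) | frozenset(overlap),
        tmb_block=frozenset(tmb_only) | frozenset(overlap),
        tgfb_block=frozenset(tgfb),
        overlap_block=frozenset(overlap),
        effect_r=r,
        hr_true=config.hr_true,
        response_logit_slope=config.response_slope,
        censor_rate=config.censor_rate,
    )
    latent = pd.DataFrame(
        {
            "immune": z_immune,
            "mutational": z_mut,
            "suppression": z_supp,
            "composite": composite,
        },
        index=sample_ids,
    )
    return SyntheticCohort(expr, clinical, truth, config.seed, latent)


def generate_feature_table(
    cohort: SyntheticCohort,
    n_true: int = 10,
    n_null: int = 10,
    feature_r: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Fabricate per-sample microenvironment-style features.

    ``n_true`` features correlate with the cohort's immune+mutational
    composite at target strength ``feature_r``; ``n_null`` features are
    independent noise.  Returns the feature table (samples x features) and a
    boolean Series marking which features are truly associated — the ground
    truth for mixed-model calibration tests.
    """
    if not 0 <= feature_r < 1:
        raise ValueError("feature_r must be in [0, 1)")
    rng = np.random.default_rng(seed)
    comp = cohort.latent["composite"].to_numpy()
    comp = (comp - comp.mean()) / comp.std()
    n = len(comp)
    cols, truths = {}, {}
    for j in range(n_true):
        cols[f"F_true{j:03d}"] = feature_r * comp + np.sqrt(
            1 - feature_r**2
        ) * rng.standard_normal(n)
        truths[f"F_true{j:03d}"] = True
    for j in range(n_null):
        cols[f"F_null{j:03d}"] = rng.standard_normal(n)
        truths[f"F_null{j:03d}"] = False
    table = pd.DataFrame(cols, index=cohort.latent.index)
    return table, pd.Series(truths, name="associated")


def truth_overlap_report(signature_genes, truth: SyntheticTruth) -> dict:
    """Recovery metrics of a built signature against the planted overlap block.

    Returns sensitivity (fraction of the planted block recovered), the
    false-discovery proportion among selected genes, and the number of
    suppression-block genes wrongly retained.  An empty signature is reported
    with sensitivity 0, FDP 0 and ``empty=True``.
    """
    genes = set(signature_genes.genes if isinstance(signature_genes, GeneSet) else signature_genes)
    planted = set(truth.overlap_block)
    if not genes:
        return {
            "sensitivity": 0.0,
            "false_discovery_proportion": 0.0,
            "retained_suppressors": 0,
            "n_selected": 0,
            "empty": True,
        }
    return {
        "sensitivity": len(genes & planted) / len(planted),
        "false_discovery_proportion": len(genes - planted) / len(genes),
        "retained_suppressors": len(genes & set(truth.tgfb_block)),
        "n_selected": len(genes),
        "empty": False,
    }
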
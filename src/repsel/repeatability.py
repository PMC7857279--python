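"""Repeatability of per-group fitness across mating groups.

Each focal contributes up to three per-group values of a fitness measure.
After a variance-stabilizing transformation and relativization to mean 1,
the repeatability R is the intraclass correlation of a Gaussian
random-intercept model: among-focal variance over total variance. Two
estimators are provided -- a REML linear mixed model (default) and a fast
method-of-moments one-way ANOVA ICC used inside large bootstraps; on
balanced data with an interior solution they coincide.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .types import ALL_MEASURES, ValidationError
from .variance import BootstrapConfig

logger = logging.getLogger(__name__)

#: Variance-stabilizing transformations applied to per-group values before
#: relativization. MS is deliberately left untransformed.
TRANSFORMS = {
    "mRS": lambda x: np.sqrt(x),
    "F": lambda x: np.sqrt(x + 0.5),
    "MS": lambda x: x,
    "STE": lambda x: np.sqrt(x),
    "SFE": lambda x: np.log10(x + 1),
}


@dataclass
class RepeatabilityEstimate:
    component: str
    R: float
    var_among: float
    var_residual: float
    ci: Optional[Tuple[float, float]]
    p_value: Optional[float]
    n_replicates: int
    n_values: int
    method: str


@dataclass
class TrendModelSummary:
    component: str
    terms: Dict[str, Dict[str, float]]  # term -> {statistic, df, p_value}
    var_random: float
    var_residual: float
    method: str = "LRT (ML refits)"


def transform_component(per_group: pd.DataFrame, component: str) -> pd.DataFrame:
    """Build the long repeatability table for one fitness measure.

    ``per_group`` holds one row per focal x group with a column named after
    the component (missing values NaN). The stated transformation is
    applied, then all values are divided by their grand mean so the
    component has mean 1. Rows with missing values contribute nothing.

    Returns columns: replicate_id, batch, group_label, component, value.
    """
    if component not in TRANSFORMS:
        raise ValidationError(f"unknown component {component!r}; expected one of {ALL_MEASURES}")
    if component not in per_group.columns:
        raise ValidationError(f"column {component!r} not in per-group table")
    x = per_group[component].to_numpy(dtype=float)
    if np.any(x[~np.isnan(x)] < 0):
        raise ValidationError(f"negative {component} values cannot be transformed")
    with np.errstate(invalid="ignore"):
        t = TRANSFORMS[component](x)
    ok = ~np.isnan(t)
    if not ok.any():
        raise ValidationError(f"no usable {component} values")
    mean = t[ok].mean()
    if mean <= 0:
        raise ValidationError(f"cannot relativize {component}: transformed mean {mean}")
    out = per_group.loc[ok, ["replicate_id", "batch", "group_label"]].copy()
    out["component"] = component
    out["value"] = t[ok] / mean
    return out.reset_index(drop=True)


def icc_anova(values: np.ndarray, group_codes: np.ndarray) -> Tuple[float, float, float]:
    """Method-of-moments one-way ANOVA ICC for unbalanced groups.

    Returns (R, among-group variance, residual variance); the among-group
    variance is truncated at 0. Group codes must be integers 0..k-1.
    """
    values = np.asarray(values, dtype=float)
    group_codes = np.asarray(group_codes)
    n = values.size
    counts = np.bincount(group_codes)
    counts = counts[counts > 0]
    k = counts.size
    if k < 2 or n - k < 1:
        return np.nan, np.nan, np.nan
    sums = np.bincount(group_codes, weights=values)
    nz = np.bincount(group_codes) > 0
    means = np.zeros_like(sums)
    means[nz] = sums[nz] / np.bincount(group_codes)[nz]
    grand = values.mean()
    ss_between = float(np.sum(np.bincount(group_codes) * (means - grand) ** 2))
    ss_within = float(np.sum((values - means[group_codes]) ** 2))
    ms_a = ss_between / (k - 1)
    ms_w = ss_within / (n - k)
    n0 = (n - (counts**2).sum() / n) / (k - 1)
    var_among = max((ms_a - ms_w) / n0, 0.0)
    total = var_among + ms_w
    r = var_among / total if total > 0 else np.nan
    return float(r), float(var_among), float(ms_w)


def _profile_deviance_parts(values: np.ndarray, group_codes: np.ndarray):
    """Sufficient statistics for the intercept-only random-intercept model."""
    n_i = np.bincount(group_codes).astype(float)
    keep = n_i > 0
    n_i = n_i[keep]
    sums = np.bincount(group_codes, weights=values)[keep]
    ybar_i = sums / n_i
    ss_total_fn = lambda mu: float(np.sum((values - mu) ** 2))  # noqa: E731
    return n_i, ybar_i, values.size, ss_total_fn


def _reml_random_intercept(values: np.ndarray, group_codes: np.ndarray,
                           reml: bool = True):
    """Exact REML (or ML) for ``y_ij = mu + u_i + e_ij`` by 1-D profiling.

    For a single random intercept, mu and the residual variance profile out
    in closed form, leaving a one-dimensional optimization over the variance
    ratio -- solved to machine precision, unlike a generic mixed-model
    optimizer. Returns (var_among, var_residual, max log-likelihood).
    """
    from scipy.optimize import minimize_scalar

    n_i, ybar_i, n, ss_total_fn = _profile_deviance_parts(values, group_codes)

    def neg_loglik(log_ratio: float) -> float:
        r = np.exp(log_ratio)
        d = 1.0 + r * n_i
        w = n_i / d
        mu = float(np.sum(w * ybar_i) / np.sum(w))
        # (y-mu)' V^-1 (y-mu) * sigma_e^2
        q = ss_total_fn(mu) - float(np.sum(r * n_i**2 / d * (ybar_i - mu) ** 2))
        if q <= 0:
            return np.inf
        dof = n - 1 if reml else n
        s2 = q / dof
        ll = -0.5 * (dof * np.log(2 * np.pi * s2) + np.sum(np.log(d)) + dof)
        if reml:
            ll -= 0.5 * np.log(np.sum(w))
        return -ll

    # bracket the ratio on the log scale, including the near-boundary case
    grid = np.linspace(-30, 10, 81)
    best = grid[np.argmin([neg_loglik(g) for g in grid])]
    res = minimize_scalar(
        neg_loglik,
        bounds=(best - 1.0, best + 1.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    log_ratio = res.x if res.fun <= neg_loglik(best) else best
    r = float(np.exp(log_ratio))
    d = 1.0 + r * n_i
    w = n_i / d
    mu = float(np.sum(w * ybar_i) / np.sum(w))
    q = ss_total_fn(mu) - float(np.sum(r * n_i**2 / d * (ybar_i - mu) ** 2))
    dof = n - 1 if reml else n
    var_resid = q / dof
    var_among = r * var_resid
    if r < 1e-10:  # boundary solution: no among-group variance
        var_among = 0.0
    return var_among, var_resid, -neg_loglik(np.log(max(r, 1e-300)))


def _fit_mixedlm(model, reml: bool):
    """Fit with a ladder of optimizers; numerical failures try the next."""
    err = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell", "cg", "nm"):
            try:
                return model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError, OverflowError) as exc:
                err = exc
    raise ValidationError(f"mixed model failed to fit: {err}")


def _lmm_variances(values: np.ndarray, group_codes: np.ndarray, reml: bool = True):
    """Random-intercept model variances via REML (or ML)."""
    var_among, var_resid, ll = _reml_random_intercept(values, group_codes, reml)
    return var_among, var_resid, ll


def _boundary_lrt_pvalue(values: np.ndarray, group_codes: np.ndarray) -> float:
    """LRT of the random intercept vs no random effect, boundary-corrected.

    Both models are fit by ML; the null distribution is the 50:50 mixture of
    a point mass at 0 and chi-square(1), so the chi-square tail is halved.
    """
    _, _, ll_full = _reml_random_intercept(values, group_codes, reml=False)
    n = values.size
    ss = float(np.sum((values - values.mean()) ** 2))
    ll_null = -0.5 * n * (np.log(2 * np.pi * ss / n) + 1)
    stat = max(2 * (ll_full - ll_null), 0.0)
    return float(0.5 * scipy.stats.chi2.sf(stat, 1)) if stat > 0 else 1.0


def _codes(ids: pd.Series) -> np.ndarray:
    return pd.factorize(ids)[0]


def estimate_repeatability(
    table: pd.DataFrame,
    config: Optional[BootstrapConfig] = None,
    method: str = "lmm",
    boot_method: Optional[str] = None,
    significance: bool = True,
) -> RepeatabilityEstimate:
    """Estimate R = among/(among+residual) from a long repeatability table.

    Parameters
    ----------
    table:
        Output of :func:`transform_component` (single component).
    config:
        Bootstrap settings for the percentile CI (resampling whole focals,
        each resampled focal becoming a new level). None skips the CI.
    method:
        ``"lmm"`` (REML mixed model, default) or ``"anova"``
        (method-of-moments ICC).
    boot_method:
        Estimator inside the bootstrap; defaults to ``method``.
    """
    comps = table["component"].unique()
    if len(comps) != 1:
        raise ValidationError(f"table must hold one component, found {list(comps)}")
    values = table["value"].to_numpy(dtype=float)
    codes = _codes(table["replicate_id"])
    n_rep = int(codes.max()) + 1
    per_focal = np.bincount(codes)
    if n_rep < 2 or (per_focal >= 2).sum() < 2:
        raise ValidationError("need at least 2 focals with at least 2 values each")
    if np.var(values) == 0:
        raise ValidationError("no variance to partition")

    if method == "anova":
        r, var_a, var_e = icc_anova(values, codes)
    elif method == "lmm":
        var_a, var_e, _ = _lmm_variances(values, codes, reml=True)
        r = var_a / (var_a + var_e) if (var_a + var_e) > 0 else np.nan
    else:
        raise ValueError("method must be 'lmm' or 'anova'")

    p_value = _boundary_lrt_pvalue(values, codes) if significance else None

    ci = None
    if config is not None:
        boot = boot_method or method
        rng = config.rng(f"repeatability:{comps[0]}")
        focal_values = [values[codes == i] for i in range(n_rep)]
        draws = np.empty(config.iterations)
        size = config.resample_size or n_rep
        for b in range(config.iterations):
            pick = rng.integers(0, n_rep, size=size)
            vals = np.concatenate([focal_values[i] for i in pick])
            grp = np.repeat(np.arange(size), [len(focal_values[i]) for i in pick])
            try:
                if boot == "anova":
                    draws[b] = icc_anova(vals, grp)[0]
                else:
                    va, ve, _ = _lmm_variances(vals, grp, reml=True)
                    draws[b] = va / (va + ve) if (va + ve) > 0 else np.nan
            except Exception:
                draws[b] = np.nan
        n_bad = int(np.isnan(draws).sum())
        if n_bad > 0.5 * config.iterations:
            raise ValidationError(f"repeatability undefined on {n_bad} resamples")
        lo_q, hi_q = config.ci_bounds()
        ci = (float(np.nanpercentile(draws, lo_q)), float(np.nanpercentile(draws, hi_q)))

    return RepeatabilityEstimate(
        component=str(comps[0]),
        R=float(np.clip(r, 0.0, 1.0)),
        var_among=var_a,
        var_residual=var_e,
        ci=ci,
        p_value=p_value,
        n_replicates=n_rep,
        n_values=int(values.size),
        method=method,
    )


def fit_trend_model(table: pd.DataFrame) -> TrendModelSummary:
    """Mixed model testing for mating-group and batch trends.

    Fits ``value ~ group x batch`` (both categorical) with a random
    intercept per focal, and tests each fixed term by a likelihood-ratio
    test between ML refits: the interaction against the additive model, and
    each main effect against the additive model without it.
    """
    comps = table["component"].unique()
    if len(comps) != 1:
        raise ValidationError(f"table must hold one component, found {list(comps)}")
    df = table.copy()
    df["group_label"] = df["group_label"].astype(str)
    df["batch"] = df["batch"].astype(int)
    if df["group_label"].nunique() < 2 or df["batch"].nunique() < 2:
        raise ValidationError("need >= 2 mating-group and >= 2 batch levels")

    formulas = {
        "full": "value ~ C(group_label) * C(batch)",
        "additive": "value ~ C(group_label) + C(batch)",
        "no_group": "value ~ C(batch)",
        "no_batch": "value ~ C(group_label)",
    }
    # design-rank check on the full fixed-effect matrix
    X = np.asarray(smf.ols(formulas["full"], df).exog)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify the offending term by incremental rank
        aliased = []
        base = np.asarray(smf.ols(formulas["additive"], df).exog)
        if np.linalg.matrix_rank(base) < base.shape[1]:
            aliased.append("C(group_label) + C(batch)")
        aliased.append("C(group_label):C(batch)")
        raise ValidationError(f"rank-deficient fixed-effect design; aliased terms: {aliased}")

    fits = {}
    for name, f in formulas.items():
        fits[name] = _fit_mixedlm(
            smf.mixedlm(f, df, groups=df["replicate_id"]), reml=False
        )

    def lrt(full, reduced):
        stat = max(2 * (fits[full].llf - fits[reduced].llf), 0.0)
        dof = fits[full].df_modelwc - fits[reduced].df_modelwc
        p = float(scipy.stats.chi2.sf(stat, dof)) if dof > 0 else np.nan
        return {"statistic": float(stat), "df": float(dof), "p_value": p}

    terms = {
        "group": lrt("additive", "no_group"),
        "batch": lrt("additive", "no_batch"),
        "group:batch": lrt("full", "additive"),
    }
    full = fits["full"]
    return TrendModelSummary(
        component=str(comps[0]),
        terms=terms,
        var_random=max(float(np.asarray(full.cov_re)[0, 0]), 0.0),
        var_residual=float(full.scale),
    )
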
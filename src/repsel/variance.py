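"""Variance decomposition of relative reproductive success with bootstrap inference.

After relativization (every component mean = 1), the variance in relative
reproductive success approximately equals the sum of the component
variances plus twice their pairwise covariances. Two derived ratio
components (STE, SFE) additionally carry binomial sampling-error variance,
which is estimated and subtracted to obtain unbiased opportunity-for-selection
estimates. All interval estimates are nonparametric percentile bootstraps
resampling whole replicates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .fitness import COUNT_COLUMNS, components_from_counts, relativize, relativize_matrix
from .types import COMPONENTS, ValidationError

logger = logging.getLogger(__name__)

PAIRS: Tuple[Tuple[str, str], ...] = tuple(combinations(COMPONENTS, 2))


@dataclass
class BootstrapConfig:
    """Settings shared by every bootstrap in the pipeline."""

    iterations: int = 10_000
    resample_size: Optional[int] = None  # default: number of replicates
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")

    def rng(self, stream: str = "") -> np.random.Generator:
        """Deterministic per-operation stream derived from the root seed."""
        entropy = [self.seed] + [ord(c) for c in stream]
        return np.random.default_rng(np.random.SeedSequence(entropy))

    def ci_bounds(self) -> Tuple[float, float]:
        alpha = 1 - self.ci_level
        return 100 * alpha / 2, 100 * (1 - alpha / 2)


@dataclass
class VarianceDecomposition:
    """Point estimates of all decomposition terms (relativized scale).

    ``percentages`` expresses each term relative to the chosen denominator
    (default: the model-predicted total, i.e. sum of raw variances plus
    doubled covariances), under which the four corrected variances, the two
    sampling-error terms, and the six doubled covariances sum to 100.
    """

    variances_raw: Dict[str, float]
    error_variances: Dict[str, float]
    variances_corrected: Dict[str, float]
    covariances: Dict[Tuple[str, str], float]
    var_mrs_observed: float
    model_total: float
    denominator: str
    percentages: Dict[str, float] = field(default_factory=dict)
    n_used: Dict[str, int] = field(default_factory=dict)
    ci: Optional[Dict[str, Tuple[float, float]]] = None

    def percentage_denominator(self) -> float:
        return self.model_total if self.denominator == "model_total" else self.var_mrs_observed


def _component_matrix(data: pd.DataFrame, needed=COMPONENTS) -> pd.DataFrame:
    """Accept either summed counts or an already-computed components table."""
    if set(COUNT_COLUMNS).issubset(data.columns):
        return components_from_counts(data)
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValidationError(
            f"data has neither count columns nor component columns (missing {missing})"
        )
    return data


def decompose_variance(
    rel: pd.DataFrame,
    error_variances: Optional[Dict[str, float]] = None,
    denominator: str = "model_total",
) -> VarianceDecomposition:
    """Decompose Var(mRS*) into component variances and covariances.

    Parameters
    ----------
    rel:
        Relativized component matrix with columns F, MS, STE, SFE, mRS
        (missing entries NaN). Variances use the replicates where the
        component is defined; covariances use pairwise-complete replicates.
    error_variances:
        Optional ``{"STE": e, "SFE": e}`` sampling-error variances to
        subtract (see :func:`binomial_error_variance`).
    denominator:
        ``"model_total"`` (default) or ``"observed"`` -- what the percentage
        scale is relative to.
    """
    if denominator not in ("model_total", "observed"):
        raise ValueError("denominator must be 'model_total' or 'observed'")
    err = {c: 0.0 for c in COMPONENTS}
    if error_variances:
        bad = set(error_variances) - {"STE", "SFE"}
        if bad:
            raise ValidationError(f"no sampling-error correction defined for {sorted(bad)}")
        err.update(error_variances)

    variances, n_used = {}, {}
    for comp in COMPONENTS:
        x = rel[comp].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        n_used[comp] = x.size
        if x.size < 2:
            logger.warning("component %s has <2 usable replicates; variance missing", comp)
            variances[comp] = np.nan
        else:
            variances[comp] = float(np.var(x, ddof=1))

    covariances = {}
    for a, b in PAIRS:
        sub = rel[[a, b]].dropna()
        n_used[f"cov_{a}:{b}"] = len(sub)
        if len(sub) < 2:
            logger.warning("pair %s:%s has <2 complete replicates; covariance missing", a, b)
            covariances[(a, b)] = np.nan
        else:
            covariances[(a, b)] = float(np.cov(sub[a], sub[b], ddof=1)[0, 1])

    mrs = rel["mRS"].dropna().to_numpy(dtype=float)
    var_mrs = float(np.var(mrs, ddof=1)) if mrs.size >= 2 else np.nan
    model_total = float(
        np.nansum(list(variances.values())) + 2 * np.nansum(list(covariances.values()))
    )

    corrected = {}
    for comp in COMPONENTS:
        c = variances[comp] - err[comp]
        if c < 0:
            logger.warning(
                "corrected variance of %s negative (%.4g); clipped to 0", comp, c
            )
            c = 0.0
        corrected[comp] = c

    dec = VarianceDecomposition(
        variances_raw=variances,
        error_variances=err,
        variances_corrected=corrected,
        covariances=covariances,
        var_mrs_observed=var_mrs,
        model_total=model_total,
        denominator=denominator,
        n_used=n_used,
    )
    denom = dec.percentage_denominator()
    pct = {}
    for comp in COMPONENTS:
        pct[comp] = 100 * corrected[comp] / denom
    for comp in ("STE", "SFE"):
        pct[f"err_{comp}"] = 100 * err[comp] / denom
    for a, b in PAIRS:
        pct[f"cov_{a}:{b}"] = 100 * 2 * covariances[(a, b)] / denom
    dec.percentages = pct
    return dec


# ---------------------------------------------------------------------------
# binomial sampling-error variance of the derived ratio components
# ---------------------------------------------------------------------------

def _error_inputs(aggregates: pd.DataFrame, component: str):
    """Per-replicate (ratio value, binomial p-hat, denominator n, divisor)."""
    comp = components_from_counts(aggregates)
    if component == "STE":
        defined = comp["STE"].notna().to_numpy()
        p = (aggregates["s_f"] / aggregates["s_t"]).to_numpy(dtype=float)[defined]
        n = aggregates["s_t"].to_numpy(dtype=float)[defined]
        divisor = comp["MS"].to_numpy(dtype=float)[defined]
        values = comp["STE"].to_numpy(dtype=float)[defined]
    elif component == "SFE":
        defined = comp["SFE"].notna().to_numpy()
        p = (aggregates["o_f"] / aggregates["o_t"]).to_numpy(dtype=float)[defined]
        n = aggregates["o_t"].to_numpy(dtype=float)[defined]
        divisor = (aggregates["s_f"] / aggregates["s_t"]).to_numpy(dtype=float)[defined]
        values = comp["SFE"].to_numpy(dtype=float)[defined]
    else:
        raise ValidationError(
            f"component {component!r} carries no binomial sampling error "
            "(only STE and SFE are derived ratios)"
        )
    return values, p, n, divisor


def binomial_error_variance(
    aggregates: pd.DataFrame,
    component: str,
    method: str = "closed_form",
    draws: int = 1000,
    seed: int = 0,
) -> float:
    """Across-replicate variance of the relativized component expected from
    binomial sampling alone.

    The underlying observed proportion of replicate *i* (focal sperm share
    for STE, focal offspring share for SFE) has sampling variance
    ``p(1-p)/n``. ``closed_form`` propagates it through the ratio and the
    relativization by the delta method; ``monte_carlo`` redraws the focal
    counts binomially, recomputes the relativized component, and measures
    how much extra across-replicate variance the redrawing creates. The two
    agree within Monte-Carlo error.
    """
    values, p, n, divisor = _error_inputs(aggregates, component)
    if values.size < 2:
        return np.nan
    if method == "closed_form":
        var_i = p * (1 - p) / n / divisor**2
        mean = values.mean()
        # E[sample variance] = variance of the means + mean per-replicate noise
        return float(var_i.mean() / mean**2)
    if method == "monte_carlo":
        # the relativization divisor is held at the observed mean so the term
        # captures noise in the redrawn proportions only; this is the quantity
        # the delta method approximates, and the two coincide up to O(1/m)
        rng = np.random.default_rng(seed)
        mean = values.mean()
        base = float(np.var(values / mean, ddof=1))
        redraw = rng.binomial(n.astype(int)[None, :].repeat(draws, axis=0),
                              p[None, :].repeat(draws, axis=0)) / n[None, :]
        rel = redraw / divisor[None, :] / mean
        vars_new = rel.var(axis=1, ddof=1)
        return float(max(vars_new.mean() - base, 0.0))
    raise ValueError("method must be 'closed_form' or 'monte_carlo'")


# ---------------------------------------------------------------------------
# bootstrap engine
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    point: object  # float or pd.Series
    ci: object  # (lo, hi) or DataFrame with lo/hi
    draws: np.ndarray  # (B,) or (B, k)
    n_failures: int


def bootstrap_statistic(
    statistic: Callable[[pd.DataFrame], object],
    data: pd.DataFrame,
    config: BootstrapConfig,
    stream: str = "bootstrap",
) -> BootstrapResult:
    """Percentile bootstrap of ``statistic`` over resampled replicates.

    The resampling unit is the row of ``data`` (one replicate: all of a
    focal's groups and recipients move together -- callers pass one row per
    replicate). The statistic may return a float or a pandas Series (all
    terms bootstrapped on shared resamples). Iterations where it raises or
    returns all-NaN count as failures; more than 50% failures is an error.
    """
    n = len(data)
    if n == 0:
        raise ValidationError("cannot bootstrap an empty dataset")
    size = config.resample_size or n
    rng = config.rng(stream)
    point = statistic(data)
    is_series = isinstance(point, pd.Series)
    draws = []
    failures = 0
    for _ in range(config.iterations):
        idx = rng.integers(0, n, size=size)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            val = statistic(sample)
        except Exception:
            failures += 1
            val = pd.Series(np.nan, index=point.index) if is_series else np.nan
        else:
            arr = val.to_numpy(dtype=float) if is_series else np.asarray([val], dtype=float)
            if np.all(np.isnan(arr)):
                failures += 1
        draws.append(val.to_numpy(dtype=float) if is_series else float(val))
    draws = np.asarray(draws, dtype=float)
    if failures > 0.5 * config.iterations:
        raise ValidationError(
            f"statistic undefined on {failures}/{config.iterations} resamples"
        )
    if failures:
        logger.info("bootstrap: %d/%d failed iterations", failures, config.iterations)
    lo_q, hi_q = config.ci_bounds()
    if is_series:
        lo = np.nanpercentile(draws, lo_q, axis=0)
        hi = np.nanpercentile(draws, hi_q, axis=0)
        ci = pd.DataFrame({"lo": lo, "hi": hi}, index=point.index)
    else:
        ci = (float(np.nanpercentile(draws, lo_q)), float(np.nanpercentile(draws, hi_q)))
    return BootstrapResult(point=point, ci=ci, draws=draws, n_failures=failures)


def component_variance(
    data: pd.DataFrame,
    component: str,
    corrected: bool = False,
    error_method: str = "closed_form",
    error_draws: int = 200,
    error_seed: int = 0,
) -> float:
    """Variance of one relativized component; optionally error-corrected.

    ``data`` is a replicate-level table of summed counts (or a plain
    components table when ``corrected`` is false).
    """
    comp = _component_matrix(data, needed=(component,))
    x = relativize(comp[component].to_numpy(dtype=float))
    x = x[~np.isnan(x)]
    if x.size < 2:
        return np.nan
    v = float(np.var(x, ddof=1))
    if corrected and component in ("STE", "SFE"):
        e = binomial_error_variance(data, component, error_method, error_draws, error_seed)
        v = max(v - e, 0.0)
    return v


def signed_difference_test(
    data: pd.DataFrame,
    comp_a: str,
    comp_b: str,
    config: BootstrapConfig,
    statistic: Optional[Callable[[pd.DataFrame, str], float]] = None,
    corrected: bool = False,
) -> Dict[str, object]:
    """Two-tailed bootstrap sign test for a difference between two components.

    Per iteration, replicates are resampled once and the target statistic
    (default: variance of the relativized component, optionally
    error-corrected) is computed for both components on the same resample.
    The p-value is twice the smaller tail frequency of the signed
    difference, with exact ties split equally between the signs, floored at
    2/B and capped at 1.
    """
    if statistic is None:
        def statistic(df, comp):
            return component_variance(df, comp, corrected=corrected)

    def diff(df):
        return statistic(df, comp_a) - statistic(df, comp_b)

    res = bootstrap_statistic(diff, data, config, stream=f"signdiff:{comp_a}:{comp_b}")
    return {"p_value": sign_test_pvalue(res.draws, config.iterations),
            "draws": res.draws, "n_failures": res.n_failures}


def sign_test_pvalue(diffs: np.ndarray, iterations: Optional[int] = None) -> float:
    """p = 2 x min(freq positive, freq negative), ties split, floor 2/B."""
    diffs = np.asarray(diffs, dtype=float)
    ok = ~np.isnan(diffs)
    b = int(ok.sum())
    if b == 0:
        return np.nan
    pos = float(np.sum(diffs[ok] > 0))
    neg = float(np.sum(diffs[ok] < 0))
    ties = b - pos - neg
    pos += ties / 2
    neg += ties / 2
    p = 2 * min(pos, neg) / b
    return float(min(max(p, 2 / b), 1.0))


def decompose(
    aggregates: pd.DataFrame,
    config: Optional[BootstrapConfig] = None,
    error_method: str = "closed_form",
    error_draws: int = 1000,
    denominator: str = "model_total",
) -> VarianceDecomposition:
    """Full decomposition of a replicate-level table of summed counts.

    Computes the components, relativizes, estimates the binomial
    sampling-error variances of STE and SFE, decomposes, and (when a
    bootstrap config is given) attaches percentile CIs for every term, with
    the error subtraction redone inside each iteration.
    """
    comp = components_from_counts(aggregates)
    rel = relativize_matrix(comp)
    seed = config.seed if config is not None else 0
    errors = {
        c: binomial_error_variance(aggregates, c, error_method, error_draws, seed)
        for c in ("STE", "SFE")
    }
    dec = decompose_variance(rel, errors, denominator)

    if config is not None:
        def all_terms(df: pd.DataFrame) -> pd.Series:
            c = components_from_counts(df)
            r = relativize_matrix(c)
            e = {
                k: binomial_error_variance(df, k, "closed_form")
                for k in ("STE", "SFE")
            }
            d = decompose_variance(r, e, denominator)
            out = {f"var_{k}": v for k, v in d.variances_corrected.items()}
            out.update({f"raw_var_{k}": v for k, v in d.variances_raw.items()})
            out.update({f"cov_{a}:{b}": v for (a, b), v in d.covariances.items()})
            out.update({f"err_{k}": d.error_variances[k] for k in ("STE", "SFE")})
            out["var_mRS_observed"] = d.var_mrs_observed
            out["model_total"] = d.model_total
            out.update({f"pct_{k}": v for k, v in d.percentages.items()})
            return pd.Series(out)

        res = bootstrap_statistic(all_terms, aggregates, config, stream="decompose")
        dec.ci = {k: (float(res.ci.loc[k, "lo"]), float(res.ci.loc[k, "hi"]))
                  for k in res.ci.index}
    return dec
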
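"""The repeatable opportunity for selection: I_R = R x I.

For each fitness component, the opportunity for selection I (variance of
the relativized component, expressed as a percentage of the decomposed
total) is weighted by the repeatability R of the focal's per-group success,
isolating the portion of fitness variance attributable to consistent
among-individual differences. Inside the joint bootstrap the product always
uses the *total* (uncorrected) variance; the displayed I column is the
error-corrected one.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import io_data, fitness, repeatability as rpt
from .types import COMPONENTS, ValidationError
from .variance import BootstrapConfig, PAIRS, sign_test_pvalue

logger = logging.getLogger(__name__)


@dataclass
class IRRow:
    component: str
    I_pct: float  # error-corrected, as displayed
    I_pct_ci: Tuple[float, float]
    I_total_pct: float  # uncorrected, used inside the product
    I_total_pct_ci: Tuple[float, float]
    R: float
    R_ci: Tuple[float, float]
    IR_pct_plugin: float
    IR_pct_mean: float
    IR_pct_ci: Tuple[float, float]


@dataclass
class IRTable:
    rows: Dict[str, IRRow]
    p_values_I: pd.DataFrame
    p_values_IR: pd.DataFrame
    var_mrs_observed: float
    model_total: float
    n_replicates: int
    iterations: int
    n_failures: Dict[str, int] = field(default_factory=dict)
    draws: Optional[Dict[str, np.ndarray]] = None  # kept only on request

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for comp in COMPONENTS:
            r = self.rows[comp]
            recs.append({
                "component": comp,
                "I_pct": r.I_pct,
                "I_pct_lo": r.I_pct_ci[0],
                "I_pct_hi": r.I_pct_ci[1],
                "I_total_pct": r.I_total_pct,
                "I_total_pct_lo": r.I_total_pct_ci[0],
                "I_total_pct_hi": r.I_total_pct_ci[1],
                "R": r.R,
                "R_lo": r.R_ci[0],
                "R_hi": r.R_ci[1],
                "IR_pct_plugin": r.IR_pct_plugin,
                "IR_pct_mean": r.IR_pct_mean,
                "IR_pct_lo": r.IR_pct_ci[0],
                "IR_pct_hi": r.IR_pct_ci[1],
            })
        return pd.DataFrame(recs)

    def to_dict(self) -> dict:
        return {
            "rows": {c: vars(self.rows[c]) | {} for c in COMPONENTS},
            "p_values_I": self.p_values_I.to_dict(),
            "p_values_IR": self.p_values_IR.to_dict(),
            "var_mrs_observed": self.var_mrs_observed,
            "model_total": self.model_total,
            "n_replicates": self.n_replicates,
            "iterations": self.iterations,
            "n_failures": self.n_failures,
        }


def _prepare_arrays(ds: io_data.Dataset):
    """Precompute per-replicate quantities the joint bootstrap resamples.

    Returns (replicate ids, pooled raw component arrays, error-variance
    inputs, transformed per-group value lists per component).
    """
    if ds.recipients["total_sperm"].isna().any():
        ds, _ = fitness.impute_total_sperm(ds)
    agg = io_data.aggregate_replicates(ds)
    per_group = fitness.components_from_counts(io_data.group_counts(ds))
    comp = fitness.components_from_counts(agg)

    ids = agg["replicate_id"].to_numpy()
    n = len(ids)
    pooled = {c: comp[c].to_numpy(dtype=float) for c in COMPONENTS + ("mRS",)}

    # per-replicate binomial noise variance of the underlying proportion,
    # propagated through the ratio (delta method); NaN where undefined
    err_var = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (agg["s_f"] / agg["s_t"]).to_numpy(dtype=float)
        ms = pooled["MS"]
        e = p * (1 - p) / agg["s_t"].to_numpy(dtype=float) / ms**2
        err_var["STE"] = np.where(np.isnan(pooled["STE"]), np.nan, e)
        q = (agg["o_f"] / agg["o_t"]).to_numpy(dtype=float)
        e = q * (1 - q) / agg["o_t"].to_numpy(dtype=float) / p**2
        err_var["SFE"] = np.where(np.isnan(pooled["SFE"]), np.nan, e)

    # transformed (unrelativized) per-group values per focal; repeatability
    # is scale invariant so relativization inside resamples is a no-op for R
    group_values = {}
    for c in COMPONENTS:
        x = per_group[c].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            t = rpt.TRANSFORMS[c](x)
        by_id = {}
        rid = per_group["replicate_id"].to_numpy()
        for i in range(len(rid)):
            if not np.isnan(t[i]):
                by_id.setdefault(rid[i], []).append(t[i])
        group_values[c] = [np.asarray(by_id.get(r, []), dtype=float) for r in ids]
    return ids, n, pooled, err_var, group_values


def _terms_for_indices(idx, pooled, err_var, group_values, r_method):
    """All per-iteration quantities for one resample (index array)."""
    variances, cov_terms, errors = {}, 0.0, {}
    means = {}
    for c in COMPONENTS:
        x = pooled[c][idx]
        ok = ~np.isnan(x)
        if ok.sum() < 2:
            raise ValidationError(f"<2 defined {c} values in resample")
        m = x[ok].mean()
        if m <= 0:
            raise ValidationError(f"non-positive {c} mean in resample")
        means[c] = m
        variances[c] = float(np.var(x[ok], ddof=1)) / m**2
    for a, b in PAIRS:
        xa, xb = pooled[a][idx], pooled[b][idx]
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        if ok.sum() >= 2:
            cov = float(np.cov(xa[ok], xb[ok], ddof=1)[0, 1])
            cov_terms += 2 * cov / (xa[ok].mean() * xb[ok].mean())
    for c in ("STE", "SFE"):
        ev = err_var[c][idx]
        ok = ~np.isnan(ev)
        errors[c] = float(np.nanmean(ev)) / means[c] ** 2 if ok.any() else 0.0
    model_total = sum(variances.values()) + cov_terms
    if not np.isfinite(model_total) or model_total <= 0:
        raise ValidationError("non-positive decomposed total in resample")

    r_est = {}
    for c in COMPONENTS:
        vals, codes = [], []
        for new_id, i in enumerate(idx):
            v = group_values[c][i]
            if v.size:
                vals.append(v)
                codes.append(np.full(v.size, new_id))
        if not vals:
            raise ValidationError(f"no per-group {c} values in resample")
        values = np.concatenate(vals)
        codes = pd.factorize(np.concatenate(codes))[0]
        if r_method == "anova":
            r = rpt.icc_anova(values, codes)[0]
        else:
            va, ve, _ = rpt._lmm_variances(values, codes, reml=True)
            r = va / (va + ve) if (va + ve) > 0 else np.nan
        r_est[c] = float(np.clip(r, 0.0, 1.0)) if not np.isnan(r) else np.nan

    mrs = pooled["mRS"][idx]
    ok = ~np.isnan(mrs)
    var_mrs = float(np.var(mrs[ok] / mrs[ok].mean(), ddof=1)) if ok.sum() >= 2 else np.nan

    out = {}
    for c in COMPONENTS:
        i_total_pct = 100 * variances[c] / model_total
        i_corr_pct = 100 * max(variances[c] - errors.get(c, 0.0), 0.0) / model_total
        out[f"I_total_pct_{c}"] = i_total_pct
        out[f"I_pct_{c}"] = i_corr_pct
        out[f"R_{c}"] = r_est[c]
        out[f"IR_pct_{c}"] = r_est[c] * i_total_pct
    out["model_total"] = model_total
    out["var_mrs"] = var_mrs
    return out


def compute_ir(
    ds: io_data.Dataset,
    config: BootstrapConfig,
    r_method: str = "lmm",
    resample: bool = True,
    max_failure_rate: float = 0.10,
    return_draws: bool = False,
) -> IRTable:
    """Joint bootstrap of I, R, and I_R = R x I for all four components.

    Per iteration, whole replicates are resampled with replacement; each
    component's total (uncorrected) relativized variance -- expressed as a
    percentage of that iteration's decomposed total -- and the repeatability
    of its transformed per-group values are recomputed on the same resample
    and multiplied. Reported I_R is both the bootstrap mean and the plug-in
    product; pairwise signed-difference p-values for I (corrected) and I_R
    come from the shared draws. ``resample=False`` evaluates every
    iteration on the original data (plug-in identity check).
    """
    if r_method not in ("lmm", "anova"):
        raise ValueError("r_method must be 'lmm' or 'anova'")
    ids, n, pooled, err_var, group_values = _prepare_arrays(ds)
    size = config.resample_size or n
    rng = config.rng("ir")

    plug = _terms_for_indices(np.arange(n), pooled, err_var, group_values, r_method)

    keys = list(plug.keys())
    draws = {k: np.full(config.iterations, np.nan) for k in keys}
    failures = 0
    for b in range(config.iterations):
        idx = rng.integers(0, n, size=size) if resample else np.arange(n)
        try:
            terms = _terms_for_indices(idx, pooled, err_var, group_values, r_method)
        except (ValidationError, ValueError):
            failures += 1
            continue
        for k in keys:
            draws[k][b] = terms[k]
    if failures > max_failure_rate * config.iterations:
        raise ValidationError(
            f"{failures}/{config.iterations} degenerate bootstrap iterations"
        )
    if failures:
        logger.info("compute_ir: skipped %d degenerate iterations", failures)

    lo_q, hi_q = config.ci_bounds()

    def ci(key):
        return (float(np.nanpercentile(draws[key], lo_q)),
                float(np.nanpercentile(draws[key], hi_q)))

    rows = {}
    for c in COMPONENTS:
        rows[c] = IRRow(
            component=c,
            I_pct=plug[f"I_pct_{c}"],
            I_pct_ci=ci(f"I_pct_{c}"),
            I_total_pct=plug[f"I_total_pct_{c}"],
            I_total_pct_ci=ci(f"I_total_pct_{c}"),
            R=plug[f"R_{c}"],
            R_ci=ci(f"R_{c}"),
            IR_pct_plugin=plug[f"R_{c}"] * plug[f"I_total_pct_{c}"],
            IR_pct_mean=float(np.nanmean(draws[f"IR_pct_{c}"])),
            IR_pct_ci=ci(f"IR_pct_{c}"),
        )

    def pmatrix(prefix):
        mat = pd.DataFrame(np.nan, index=COMPONENTS, columns=COMPONENTS)
        for a, b in PAIRS:
            p = sign_test_pvalue(draws[f"{prefix}_{a}"] - draws[f"{prefix}_{b}"])
            mat.loc[a, b] = mat.loc[b, a] = p
        np.fill_diagonal(mat.values, 1.0)
        return mat

    return IRTable(
        rows=rows,
        p_values_I=pmatrix("I_pct"),
        p_values_IR=pmatrix("IR_pct"),
        var_mrs_observed=plug["var_mrs"],
        model_total=plug["model_total"],
        n_replicates=n,
        iterations=config.iterations,
        n_failures={"total": failures},
        draws=draws if return_draws else None,
    )


def render_report(table: IRTable, decomposition=None, out_prefix=None):
    """Emit the summary as CSV + JSON (identical numbers) and a stacked-bar plot.

    Returns (DataFrame, dict). When ``out_prefix`` is given, writes
    ``<prefix>.csv``, ``<prefix>.json`` and ``<prefix>.png``.
    """
    frame = table.to_frame()
    payload = table.to_dict()
    payload["rows"] = {
        c: {k: (list(v) if isinstance(v, tuple) else v) for k, v in payload["rows"][c].items()}
        for c in payload["rows"]
    }
    if decomposition is not None:
        payload["decomposition"] = {
            "variances_raw": decomposition.variances_raw,
            "variances_corrected": decomposition.variances_corrected,
            "error_variances": decomposition.error_variances,
            "covariances": {f"{a}:{b}": v for (a, b), v in decomposition.covariances.items()},
            "var_mrs_observed": decomposition.var_mrs_observed,
            "model_total": decomposition.model_total,
            "percentages": decomposition.percentages,
            "ci": decomposition.ci,
        }
    if out_prefix is not None:
        from pathlib import Path

        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_prefix.with_suffix(".csv"), index=False)
        with open(out_prefix.with_suffix(".json"), "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
        _plot_stacked(table, out_prefix.with_suffix(".png"))
    return frame, payload


def _plot_stacked(table: IRTable, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    xs = np.arange(len(COMPONENTS))
    totals = [table.rows[c].I_total_pct for c in COMPONENTS]
    repeatable = [table.rows[c].IR_pct_plugin for c in COMPONENTS]
    ax.bar(xs, totals, color="white", edgecolor="black", label="total variance (I)")
    ax.bar(xs, repeatable, color="0.6", edgecolor="black",
           label="repeatable portion (I_R)")
    for i, c in enumerate(COMPONENTS):
        lo, hi = table.rows[c].I_total_pct_ci
        ax.errorbar(i, totals[i], yerr=[[totals[i] - lo], [hi - totals[i]]],
                    fmt="none", ecolor="black", capsize=3)
    ax.set_xticks(xs)
    ax.set_xticklabels([f"{c}*" for c in COMPONENTS])
    ax.set_ylabel("% of decomposed variance in mRS*")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
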
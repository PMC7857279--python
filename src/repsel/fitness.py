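"""Fitness components of male reproductive success.

Reproductive success factors multiplicatively into four components::

    mRS = F x MS x STE x SFE

with F the partners' total offspring, MS the focal's share of copulations,
STE the focal's share of stored sperm normalized by MS, and SFE the focal's
share of offspring normalized by its sperm share. STE and SFE are undefined
(missing) whenever their defining ratio divides by zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_data import Dataset
from .types import FitnessVector, ValidationError

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["m_t", "m_f", "s_t", "s_f", "o_t", "o_f"]


@dataclass
class ImputationSummary:
    n_observable: int
    n_imputed: int
    n_raised_to_focal: int
    mean_total_sperm: float
    imputed_value: float


def impute_total_sperm(
    ds: Dataset,
    fallback_mean: Optional[float] = None,
    round_mean: bool = True,
):
    """Fill unobservable sperm totals with the observable mean.

    Recipients carrying an egg in the antrum have no usable total-sperm
    count; each receives the mean total of all recipients that could be
    counted, computed dataset-wide (rounded to the nearest integer unless
    ``round_mean`` is false). If the imputed total would fall below the
    recipient's focal-sperm count, it is raised to that count and flagged.

    Returns (new Dataset with a ``sperm_imputed`` column on recipients,
    :class:`ImputationSummary`).
    """
    out = ds.copy()
    rec = out.recipients
    observed = rec["total_sperm"].notna()
    missing = ~observed
    if not missing.any():
        rec["sperm_imputed"] = False
        return out, ImputationSummary(int(observed.sum()), 0, 0,
                                      float(rec.loc[observed, "total_sperm"].mean())
                                      if observed.any() else np.nan,
                                      np.nan)
    if observed.any():
        mean = float(rec.loc[observed, "total_sperm"].mean())
        value = float(np.rint(mean)) if round_mean else mean
    elif fallback_mean is not None:
        mean = float(fallback_mean)
        value = float(np.rint(mean)) if round_mean else mean
    else:
        raise ValidationError(
            "no recipient with an observable total_sperm and no fallback_mean"
        )
    rec["sperm_imputed"] = missing
    rec.loc[missing, "total_sperm"] = value
    # the imputed total may not undercut the directly counted focal sperm
    low = missing & (rec["total_sperm"] < rec["focal_sperm"])
    rec.loc[low, "total_sperm"] = rec.loc[low, "focal_sperm"].astype(float)
    summary = ImputationSummary(
        n_observable=int(observed.sum()),
        n_imputed=int(missing.sum()),
        n_raised_to_focal=int(low.sum()),
        mean_total_sperm=mean,
        imputed_value=value,
    )
    logger.info(
        "imputed total_sperm=%s for %d of %d recipients (%d raised to focal count)",
        value, summary.n_imputed, len(rec), summary.n_raised_to_focal,
    )
    return out, summary


def components_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Compute F, MS, STE, SFE, mRS from summed counts (vectorized).

    ``counts`` needs the six columns m_t, m_f, s_t, s_f, o_t, o_f; any other
    columns (replicate_id, batch, group_label, ...) are carried through.
    Undefined ratios become NaN:

    * MS  = m_f / m_t            (NaN if m_t == 0)
    * STE = (s_f/s_t) / MS       (NaN if s_t == 0 or m_f == 0)
    * SFE = (o_f/o_t) / (s_f/s_t)  (NaN if o_t == 0 or s_f == 0)
    """
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValidationError(f"count columns missing: {missing}")
    c = counts
    with np.errstate(divide="ignore", invalid="ignore"):
        ms = np.where(c["m_t"] > 0, c["m_f"] / c["m_t"], np.nan)
        sperm_share = np.where(c["s_t"] > 0, c["s_f"] / c["s_t"], np.nan)
        off_share = np.where(c["o_t"] > 0, c["o_f"] / c["o_t"], np.nan)
        ste = np.where((c["m_f"] > 0) & (c["s_t"] > 0), sperm_share / ms, np.nan)
        sfe = np.where((c["s_f"] > 0) & (c["o_t"] > 0), off_share / sperm_share, np.nan)
    if (c["m_t"] == 0).any():
        logger.warning("%d rows with no matings observed; MS set to missing",
                       int((c["m_t"] == 0).sum()))
    carried = [col for col in c.columns if col not in COUNT_COLUMNS]
    out = c[carried].copy()
    out["F"] = c["o_t"].astype(float)
    out["MS"] = ms
    out["STE"] = ste
    out["SFE"] = sfe
    out["mRS"] = c["o_f"].astype(float)
    return out


def compute_components(aggregate) -> FitnessVector:
    """Fitness vector of one replicate's summed counts.

    Accepts a :class:`~repsel.types.ReplicateAggregate` or any object/row
    with attributes m_t, m_f, s_t, s_f, o_t, o_f and replicate_id.
    """
    df = pd.DataFrame(
        [{c: getattr(aggregate, c) for c in COUNT_COLUMNS + ["replicate_id"]}]
    )
    row = components_from_counts(df).iloc[0]

    def opt(v):
        return None if pd.isna(v) else float(v)

    return FitnessVector(
        replicate_id=str(row["replicate_id"]),
        F=float(row["F"]),
        MS=opt(row["MS"]),
        STE=opt(row["STE"]),
        SFE=opt(row["SFE"]),
        mRS=float(row["mRS"]),
    )


def compute_components_per_group(group) -> FitnessVector:
    """Fitness vector of a single mating group (unit of the repeatability fit).

    Accepts a :class:`~repsel.types.GroupObservation` (with its recipients)
    or any row with the six count columns.
    """
    if hasattr(group, "recipients"):
        recs = group.recipients
        row = {
            "replicate_id": group.replicate_id,
            "m_t": group.total_matings,
            "m_f": group.focal_matings,
            "s_t": sum(r.total_sperm for r in recs),
            "s_f": sum(r.focal_sperm for r in recs),
            "o_t": sum(r.total_offspring for r in recs),
            "o_f": sum(r.focal_offspring for r in recs),
        }
        if any(r.total_sperm is None for r in recs):
            raise ValidationError(
                f"group {group.replicate_id}/{group.group_label} has "
                "unimputed total_sperm"
            )
        return compute_components(pd.Series(row))
    return compute_components(group)


def relativize(values) -> np.ndarray:
    """Divide by the mean of the non-missing entries (relative fitness).

    The non-missing output has mean exactly 1; missing entries stay missing.
    Raises :class:`ValidationError` on an all-missing or zero/negative-mean
    vector.
    """
    arr = np.asarray(values, dtype=float)
    finite = ~np.isnan(arr)
    if not finite.any():
        raise ValidationError("cannot relativize an all-missing vector")
    mean = arr[finite].mean()
    if mean <= 0:
        raise ValidationError(f"cannot relativize: mean {mean} is not positive")
    return arr / mean


def relativize_matrix(components: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Relativize each component column of a components table.

    Missing values are preserved; each non-missing column mean becomes 1.
    """
    out = components.copy()
    cols = columns if columns is not None else ["F", "MS", "STE", "SFE", "mRS"]
    for col in cols:
        out[col] = relativize(out[col].to_numpy(dtype=float))
    return out
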